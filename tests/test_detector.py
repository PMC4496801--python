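"""Octamer-dictionary screen and dot-matrix confirmation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from alphaclass.detector import (
    DictionaryProfile,
    Phase1Screen,
    calibrate_f_random,
    detect,
    octamer_dictionary,
    phase2_dotmatrix,
    revcomp,
    ro_distance,
)
from alphaclass.synth import _mutate_subs

from conftest import random_dna


def _profile(words):
    return DictionaryProfile(frozenset(words))


class TestOctamerDictionary:
    def test_enumeration(self):
        prof = octamer_dictionary("ACGTACGTA")
        assert prof.octamers == {"ACGTACGT", "CGTACGTA"}
        assert prof.size == 2

    def test_degenerate_homopolymer(self):
        assert octamer_dictionary("A" * 20).octamers == {"AAAAAAAA"}

    def test_short_sequence_empty(self):
        assert octamer_dictionary("ACGT").size == 0

    def test_ambiguous_bases_skipped(self):
        prof = octamer_dictionary("ACGTACGN" + "ACGTACGT")
        assert all("N" not in w for w in prof.octamers)

    def test_random_size_matches_collision_expectation(self):
        # E[distinct] = 65536 * (1 - (1 - 4^-8)^n_words)
        rng = np.random.default_rng(0)
        n = 5000
        sizes = [octamer_dictionary(random_dna(rng, n)).size for _ in range(5)]
        n_words = n - 7
        expected = 65536 * (1 - (1 - 4.0 ** -8) ** n_words)
        assert abs(np.mean(sizes) - expected) < 50


class TestRoDistance:
    def test_identity_is_zero(self, asc):
        prof = octamer_dictionary(asc.sequence)
        assert ro_distance(asc.sequence, prof, 1.0).ro == 0.0

    def test_disjoint_is_infinite(self):
        a = _profile({"AAAAAAAA"})
        b = _profile({"CCCCCCCC"})
        assert np.isinf(ro_distance(a, b, 1.0).ro)

    def test_closed_form(self):
        # N1 = N2 = 100, nc = 50 -> f = log 2
        shared = {f"W{i:07d}" for i in range(50)}  # synthetic word tokens
        a = _profile(shared | {f"A{i:07d}" for i in range(50)})
        b = _profile(shared | {f"B{i:07d}" for i in range(50)})
        score = ro_distance(a, b, f_random=2.0)
        assert score.f == pytest.approx(np.log(2.0))
        assert score.ro == pytest.approx(np.log(2.0) / 2.0)

    def test_empty_dictionary_rejected(self):
        with pytest.raises(ValueError):
            ro_distance(_profile(set()), _profile({"AAAAAAAA"}), 1.0)

    @given(nc=st.integers(1, 98))
    def test_strictly_decreasing_in_nc(self, nc):
        """For fixed dictionary sizes, more shared words means smaller ro."""

        def profiles(k):
            shared = {f"W{i:07d}" for i in range(k)}
            a = shared | {f"A{i:07d}" for i in range(100 - k)}
            b = shared | {f"B{i:07d}" for i in range(100 - k)}
            return _profile(a), _profile(b)

        a_lo, b_lo = profiles(nc)
        a_hi, b_hi = profiles(nc + 1)
        assert (
            ro_distance(a_hi, b_hi, 1.0).ro < ro_distance(a_lo, b_lo, 1.0).ro
        )

    def test_symmetric_in_dictionary_order(self):
        shared = {f"W{i:07d}" for i in range(30)}
        a = _profile(shared | {f"A{i:07d}" for i in range(50)})
        b = _profile(shared | {f"B{i:07d}" for i in range(70)})
        assert ro_distance(a, b, 1.5).ro == ro_distance(b, a, 1.5).ro


class TestCalibration:
    def test_stable_across_seeds(self, asc):
        prof = octamer_dictionary(asc.sequence)
        f1 = calibrate_f_random(171, prof, n_samples=1000, seed=1)
        f2 = calibrate_f_random(171, prof, n_samples=1000, seed=2)
        assert f1 > 0 and np.isfinite(f1)
        assert abs(f1 - f2) / f1 < 0.05

    def test_saturated_reference(self, asc):
        """Against the full 65536-octamer dictionary nc = N1 always, so f
        collapses to log((N1+N2)/2N1), below the ASC calibration."""
        import itertools

        full = _profile(
            {"".join(w) for w in itertools.product("ACGT", repeat=8)}
        )
        f_sat = calibrate_f_random(171, full, n_samples=100, seed=0)
        # N1 <= 164 for a 171 bp fragment
        assert f_sat == pytest.approx(np.log((164 + 65536) / (2 * 164)), abs=0.05)
        f_asc = calibrate_f_random(
            171, octamer_dictionary(asc.sequence), n_samples=100, seed=0
        )
        assert f_sat < f_asc

    def test_sample_count_precondition(self, asc):
        prof = octamer_dictionary(asc.sequence)
        with pytest.raises(ValueError):
            calibrate_f_random(171, prof, n_samples=0, seed=0)


class TestPhase1:
    def test_asc_dimer_passes(self, screen, asc):
        assert screen.passes(asc.sequence * 2)

    def test_reverse_complement_passes(self, screen, asc):
        assert screen.passes(revcomp(asc.sequence * 2))

    def test_strand_symmetry(self, screen, asc):
        rng = np.random.default_rng(11)
        for _ in range(5):
            w = random_dna(rng, 2000)
            assert screen.passes(w) == screen.passes(revcomp(w))

    def test_random_windows_rejected(self, screen):
        rng = np.random.default_rng(4)
        fails = sum(screen.passes(random_dna(rng, 342)) for _ in range(100))
        assert fails <= 1

    def test_full_monomer_detected_up_to_15pct_divergence(self, screen, asc):
        """Windows holding one full monomer pass both phases (100% to 15%,
        near-100% at the 20% divergence extreme where octamer survival
        occasionally drops below what the ro<=0.6 threshold can see)."""
        rng = np.random.default_rng(7)
        miss15 = miss20 = 0
        n = 200
        for _ in range(n):
            w = random_dna(rng, 5000)
            pos = int(rng.integers(0, 5000 - 171))
            for div, counter in ((0.15, "m15"), (0.20, "m20")):
                mono = _mutate_subs(asc.sequence, div, rng)
                win = w[:pos] + mono + w[pos + 171 :]
                hit = detect("t", win, 0, len(win), screen) is not None
                if not hit:
                    if counter == "m15":
                        miss15 += 1
                    else:
                        miss20 += 1
        assert miss15 == 0
        assert miss20 <= 0.05 * n


class TestPhase2:
    def test_identity_statistic_near_zero(self, asc):
        ok, stat = phase2_dotmatrix(asc.sequence, asc)
        assert ok and stat < 1e-20

    def test_divergent_monomer_confirmed(self, asc):
        rng = np.random.default_rng(9)
        for _ in range(20):
            ok, _ = phase2_dotmatrix(_mutate_subs(asc.sequence, 0.10, rng), asc)
            assert ok

    def test_random_rejected(self, asc):
        rng = np.random.default_rng(10)
        rejections = sum(
            not phase2_dotmatrix(random_dna(rng, 342), asc)[0] for _ in range(100)
        )
        assert rejections >= 99

    def test_statistic_decreases_with_diagonal_quality(self, asc):
        rng = np.random.default_rng(12)
        _, s_clean = phase2_dotmatrix(asc.sequence, asc)
        _, s_div = phase2_dotmatrix(_mutate_subs(asc.sequence, 0.15, rng), asc)
        _, s_rand = phase2_dotmatrix(random_dna(rng, 171), asc)
        assert s_clean < s_div < s_rand


def test_detect_records_minus_strand(screen, asc):
    rng = np.random.default_rng(13)
    w = random_dna(rng, 2000) + revcomp(asc.sequence * 4) + random_dna(rng, 2000)
    seg = detect("t", w, 0, len(w), screen)
    assert seg is not None and seg.strand == "-"
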