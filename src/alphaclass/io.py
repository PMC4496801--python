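"""BED reading/writing for annotation records, regions and masks."""

from __future__ import annotations

from .annotator import AnnotationRecord


def write_bed(records: list[AnnotationRecord], path: str, track_name: str = "AS-SF") -> None:
    """Write records as a BED9 custom track (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write(f'track name="{track_name}" itemRgb="On"\n')
        for r in records:
            fh.write(
                f"{r.seq_id}\t{r.start}\t{r.end}\t{r.name}\t{r.score}\t"
                f"{r.strand}\t{r.start}\t{r.end}\t{r.color}\n"
            )


def read_bed(path: str) -> list[AnnotationRecord]:
    """Reparse a BED9 track written by :func:`write_bed`."""
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "browser", "#")) or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            seq_id, start, end, name, score, strand = fields[:6]
            label, box = name.split("/")
            # canonical case: labels are letter+digit or Um/Xm
            label = label[0].upper() + label[1:]
            if label in ("UM", "XM"):
                label = label[0] + label[1].lower()
            records.append(
                AnnotationRecord(
                    seq_id,
                    int(start),
                    int(end),
                    label,
                    box,
                    strand,
                    posterior=int(score) / 1000.0,
                )
            )
    return records


def read_intervals(path: str) -> list[tuple[str, int, int]]:
    """Read a plain BED3+ file as (seq_id, start, end) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "browser", "#")) or not line.strip():
                continue
            f = line.split()
            out.append((f[0], int(f[1]), int(f[2])))
    return out
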