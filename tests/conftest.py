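import numpy as np
import pytest
from hypothesis import settings

from alphaclass.annotator import Annotator
from alphaclass.classifier import BayesClassifier
from alphaclass.consensus_model import load_models
from alphaclass.detector import Phase1Screen

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


@pytest.fixture(scope="session")
def model_set():
    return load_models()


@pytest.fixture(scope="session")
def asc(model_set):
    return model_set[0]


@pytest.fixture(scope="session")
def models(model_set):
    return model_set[1]


@pytest.fixture(scope="session")
def class_models(models):
    return {m.label: m for m in models if m.label != "Xm"}


@pytest.fixture(scope="session")
def box_model(model_set):
    return model_set[2]


@pytest.fixture(scope="session")
def screen(asc):
    return Phase1Screen(asc)


@pytest.fixture(scope="session")
def classifier(models, box_model, asc):
    return BayesClassifier(models, box_model, asc_len=len(asc))


@pytest.fixture(scope="session")
def annotator(model_set):
    asc, models, box = model_set
    return Annotator(asc, models, box)
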