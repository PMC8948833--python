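import importlib.resources
from types import SimpleNamespace

import pytest
import yaml

from medimatch import (
    SimulationConfig,
    annotate_cohort,
    call_detection,
    end_to_end_fixture,
    load_default_vocabulary,
    normalize_rundays,
    usage_sets,
)


@pytest.fixture(scope="session")
def vocab():
    return load_default_vocabulary()


@pytest.fixture(scope="session")
def lexicon():
    ref = importlib.resources.files("medimatch.data") / "indications.yaml"
    return yaml.safe_load(ref.read_text())


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic bundle (3000 participants, seed 1)."""
    return end_to_end_fixture(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline(default_bundle, vocab, lexicon):
    """Default bundle pushed through curation, normalization and detection."""
    bundle = default_bundle
    meds = annotate_cohort(bundle.participants, vocab, lexicon)
    matrix = normalize_rundays(bundle.matrix)
    det = call_detection(matrix)
    linked = bundle.participants[: bundle.config.n_samples_linked]
    return SimpleNamespace(
        bundle=bundle,
        meds=meds,
        matrix=matrix,
        det=det,
        linked=linked,
        cohort={p.participant_id for p in linked},
        usage=usage_sets(meds),
    )
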