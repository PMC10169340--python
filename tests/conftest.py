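import pytest

from temporeg.codes import load_code_lists
from temporeg.cohort import build_cohort
from temporeg.regularity import dichotomize, score_cohort
from temporeg.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def code_lists():
    return load_code_lists()


@pytest.fixture(scope="session")
def small_bundle():
    """A modest synthetic extract shared across tests (one calibration)."""
    cfg = GeneratorConfig(n_patients=2500, n_clinics=25, seed=11)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def scored_cohort(small_bundle):
    """Eligible patients with TR scores and the least-regular flag."""
    _, bundle = small_bundle
    cohort = build_cohort(bundle.tables())
    scores = score_cohort(cohort.visit_dates)
    merged = cohort.patients.merge(scores, on="patient_id")
    flags, _ = dichotomize(merged["tr"].to_numpy())
    merged["flagged"] = flags
    return merged
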