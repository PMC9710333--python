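import pytest

from akicohort import synth


@pytest.fixture(scope="session")
def default_cohort():
    """One paper-default synthetic cohort (n=101) with its ground truth."""
    return synth.generate_cohort(synth.paper_default_config(seed=11))


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free, fully observed cohort: classifications must equal truth."""
    cfg = synth.paper_default_config(
        seed=5, noise_cv=0.0, missing_cr48=0.0, missing_cr3m=0.0,
        lost_to_followup=0.0, p_hiv_missing=0.0)
    return synth.generate_cohort(cfg)
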