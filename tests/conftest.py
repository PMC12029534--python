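import numpy as np
import pytest

from gcmet import core_data as cd
from gcmet import synthetic_data as sd

SMALL_COHORT = dict(
    n_patients=20,
    stage_counts={"I": 5, "II": 6, "III": 7, "IV": 2},
    n_metabolites=60,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 20-patient, 60-metabolite synthetic cohort (raw table + metadata)."""
    cfg = sd.SyntheticConfig(**SMALL_COHORT, seed=11)
    return sd.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_normalized(small_cohort):
    """The same cohort after IS + tissue-weight normalization, tissue samples only."""
    pt, samples, mets, truth = small_cohort
    norm = cd.normalize_intensities(pt, samples, mets)
    tissue = [s for s in samples if not s.is_qc]
    tissue_pt = norm.subset_samples([s.sample_id for s in tissue])
    return tissue_pt, tissue, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
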