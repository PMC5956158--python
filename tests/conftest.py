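import numpy as np
import pytest

from miror.diffusion_maps import ivim_signal
from miror.imaging_io import ParametricMap, ROIMask
from miror.repository import FeatureRecord
from miror.synthetic_phantom import (
    DEFAULT_BVALUES,
    CohortSpec,
    Lesion,
    PhantomSpec,
    TissueParams,
    generate_feature_cohort,
    generate_phantom,
)

PAPER_BVALUES = list(DEFAULT_BVALUES)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def noise_free_phantom():
    """Small noise-free phantom with one lesion of known IVIM parameters."""
    spec = PhantomSpec(
        shape=(8, 8, 2),
        snr_b0=float("inf"),
        seed=3,
        background=TissueParams(S0=1000.0, D=1.8e-3, Dstar=10e-3, f=0.08),
        lesions=[Lesion(center=(3.5, 3.5, 0.5), radii=(2.5, 2.5, 1.0), label="tumor")],
        tissues={"tumor": TissueParams(S0=1200.0, D=0.9e-3, Dstar=18e-3, f=0.18)},
    )
    return generate_phantom(spec)


@pytest.fixture
def separated_cohort():
    """40-case two-group cohort with means far apart relative to the SDs."""
    stats = {
        "malignant": {"mean": (0.0, 1.0), "kurtosis": (3.0, 0.5)},
        "benign": {"mean": (100.0, 1.0), "kurtosis": (3.1, 0.5)},
    }
    spec = CohortSpec(group_stats=stats, n_per_group={"malignant": 20, "benign": 20},
                      seed=11)
    return generate_feature_cohort(spec)


@pytest.fixture
def default_cohort():
    """Cohort drawn from the published two-group ADC feature statistics."""
    return generate_feature_cohort(CohortSpec(seed=5))


def make_records(malignant_values, benign_values, feature="mean"):
    """Build minimal single-feature records for classifier tests."""
    records = []
    for i, v in enumerate(malignant_values):
        records.append(FeatureRecord(case_id=f"m{i}", group="malignant",
                                     map_kind="ADC", features={feature: float(v)}))
    for i, v in enumerate(benign_values):
        records.append(FeatureRecord(case_id=f"b{i}", group="benign",
                                     map_kind="ADC", features={feature: float(v)}))
    return records


@pytest.fixture
def simple_map():
    values = np.arange(24, dtype=float).reshape(4, 3, 2)
    return ParametricMap(values=values, kind="ADC", spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def full_mask(simple_map):
    return ROIMask(mask=np.ones(simple_map.shape, dtype=bool),
                   spacing=simple_map.spacing)
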