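import numpy as np
import pandas as pd
import pytest

from ringms import (
    FeatureTable,
    LabProfile,
    default_design,
    make_ground_truth,
)
from ringms.simulate import simulate_ring_trial


def mini_profile(lab_id: str = "lab_x", **kw) -> LabProfile:
    """A small, sensitive instrument profile for fast deterministic tests."""
    defaults = dict(
        lab_id=lab_id,
        rt_sigma=0.02,
        sensitivity=1.0,
        response_sigma=0.3,
        mass_error_ppm_bias=0.0,
        mass_error_ppm_sd=1.0,
        intensity_cv=0.2,
        cycle_time=2.0,
        top_k=3,
        dynamic_exclusion=True,
        exclusion_duration=12.0,
        detection_limit=2000.0,
        background_level=1500.0,
    )
    defaults.update(kw)
    return LabProfile(**defaults)


@pytest.fixture(scope="session")
def small_truth():
    return make_ground_truth(40, 40, 8, seed=11)


@pytest.fixture(scope="session")
def small_design():
    return default_design(replicates=3)


@pytest.fixture(scope="session")
def small_panel():
    return [
        mini_profile("lab_a", mass_error_ppm_bias=1.0, rt_offset=0.1),
        mini_profile("lab_b", mass_error_ppm_bias=-2.0, rt_offset=-0.2, sensitivity=1.4),
        mini_profile("lab_c", mass_error_ppm_bias=3.0, rt_slope=1.02, cycle_time=2.5),
    ]


@pytest.fixture(scope="session")
def small_trial(small_truth, small_design, small_panel):
    """Three simulated laboratories with DDA event logs (session-cached)."""
    return simulate_ring_trial(small_truth, small_design, small_panel, seed=21)


def toy_table(values, feature_meta=None, sample_names=None, lab_id="lab_t"):
    """Build a FeatureTable from a dense array; blanks inferred from names."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    fids = [f"F{i:03d}" for i in range(n_feat)]
    if sample_names is None:
        sample_names = [f"A_{j + 1}" for j in range(n_samp)]
    types = [s.rsplit("_", 1)[0] for s in sample_names]
    intensities = pd.DataFrame(values, index=fids, columns=sample_names)
    if feature_meta is None:
        feature_meta = pd.DataFrame(
            {
                "mz": np.linspace(100, 200, n_feat),
                "rt": np.linspace(1, 5, n_feat),
                "annotation": [None] * n_feat,
            },
            index=fids,
        )
    else:
        feature_meta = feature_meta.set_axis(fids, axis=0)
    samples = pd.DataFrame(
        {"sample_type": types, "is_blank": [t == "blank" for t in types]},
        index=pd.Index(sample_names, name="sample"),
    )
    return FeatureTable(intensities, feature_meta, samples, lab_id=lab_id)
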