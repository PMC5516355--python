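import numpy as np
import pytest
from hypothesis import settings

import ladspectra as ls

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_matrix(values, labels, centers=None, ids=None):
    """Small labeled FeatureMatrix from plain arrays."""
    values = np.asarray(values, dtype=float)
    if centers is None:
        centers = 500.0 + 2.0 * np.arange(values.shape[1])
    if ids is None:
        ids = [f"p{i:02d}" for i in range(values.shape[0])]
    return ls.FeatureMatrix(patient_ids=ids, labels=list(labels),
                            bin_centers=np.asarray(centers, float),
                            values=values)


@pytest.fixture(scope="session")
def recovery_cohort():
    """Strong-effect, low-noise planted cohort (57 rapid / 59 slow) and its
    preprocessed feature matrix."""
    cfg = ls.planted_recovery_config(seed=1)
    records = ls.generate_cohort(cfg)
    spec = ls.BinningSpec(low=cfg.mz_range[0], high=cfg.mz_range[1] - 2.0, width=2.0)
    matrix, qc = ls.build_feature_matrix(records, spec, standard_mz=cfg.standard_mz)
    return {"config": cfg, "records": records, "spec": spec,
            "matrix": matrix, "qc": qc}


@pytest.fixture(scope="session")
def cv_cohort():
    """Default-noise desk-scale cohort (~200 features) for CV harness tests."""
    cfg = ls.cv_scale_config(seed=2)
    records = ls.generate_cohort(cfg)
    spec = ls.BinningSpec(low=cfg.mz_range[0], high=cfg.mz_range[1] - 2.0, width=2.0)
    matrix, _ = ls.build_feature_matrix(records, spec, standard_mz=cfg.standard_mz)
    return {"config": cfg, "matrix": matrix}


def planted_bin_centers(cfg):
    """Bin centers (2-Da grid from mz_range[0]) holding the planted masses."""
    low = cfg.mz_range[0]
    return sorted({low + 2.0 * round((pm.mz - low) / 2.0) for pm in cfg.planted_masses})
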