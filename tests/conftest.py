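import numpy as np
import pytest

from sclcmet.synthetic_data import SimConfig, simulate_bulk, simulate_sc


@pytest.fixture(scope="session")
def small_cfg():
    """Small but structurally complete simulation config for unit tests."""
    return SimConfig(
        seed=42,
        n_genes=400,
        n_tf=40,
        n_planted_drivers=4,
        cohort_sizes={"never_met": 6, "met_primary": 4, "metastasis": 8},
        n_patients_sc=3,
        cells_per_patient=400,
        foxa2_module_size=6,
    )


@pytest.fixture(scope="session")
def small_bulk(small_cfg):
    return simulate_bulk(small_cfg)


@pytest.fixture(scope="session")
def small_sc(small_cfg):
    return simulate_sc(small_cfg)


@pytest.fixture(scope="session")
def qc_sc(small_sc):
    """QC-filtered, normalized copy of the small single-cell dataset.

    The gene-count floor is scaled down to the 400-gene toy genome (the
    default of 200 detected genes presumes a transcriptome-scale panel).
    """
    from sclcmet import sc_malignant as scm

    adata, anno, truth = small_sc
    ad2 = scm.qc_filter(adata.copy(), min_genes=50)
    scm.normalize_log1p(ad2)
    return ad2, anno, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
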