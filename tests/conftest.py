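import numpy as np
import pytest

import rvarch as rv
from rvarch.pipeline import synthetic_annotations
from rvarch.synthetic import default_gene_panel


@pytest.fixture(scope="session")
def small_cohort():
    """A modest two-cluster cohort with one strongly spiked gene."""
    cfg = rv.CohortConfig(
        n_cases=400,
        n_controls=1200,
        n_clusters=2,
        seed=11,
        genes=default_gene_panel(6, 7, spiked={"GENE000": {"lof_hc": 2.0, "16of16": 1.5}}),
        common_variants=[
            rv.CommonVariantSpec("cv1", 0.25, 0.35),
            rv.CommonVariantSpec("cv2", 0.40, 0.0),
        ],
    )
    return rv.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_annotations(small_cohort):
    return synthetic_annotations(small_cohort)


@pytest.fixture(scope="session")
def burden_results(small_cohort, small_annotations):
    from rvarch.burden import gene_results_frame

    res = rv.gene_burden_scan(
        small_cohort.dosages,
        small_cohort.variants["variant_id"].tolist(),
        small_cohort.phenotype,
        small_annotations,
        small_cohort.covariate_matrix(n_pcs=2),
    )
    return res, gene_results_frame(res)


def rng(seed=0):
    return np.random.default_rng(seed)
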