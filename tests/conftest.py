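import numpy as np
import pytest
from hypothesis import settings

import regulonsurv as rs

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """One modest planted-effect cohort shared across read-only tests."""
    cfg = rs.CohortConfig(
        n_samples=150,
        n_genes=300,
        n_regulators=5,
        regulon_size=20,
        prognostic_regulators=((0, 0.7), (1, -0.7)),
        n_stages=4,
        seed=11,
    )
    expr, surv, tmap, truth = rs.generate_cohort(cfg)
    return cfg, expr, surv, tmap, truth


@pytest.fixture(scope="session")
def small_regulons(small_cohort):
    """Regulons refined from the shared cohort with the fast co-expression mode."""
    _, expr, _, tmap, _ = small_cohort
    imp = rs.infer_importances(expr, list(tmap.entries), mode="spearman", seed=1)
    pairs = rs.select_top_pairs(imp, 0.05)
    return rs.build_regulons(pairs, tmap, min_size=5)


@pytest.fixture(scope="session")
def small_activity(small_cohort, small_regulons):
    _, expr, _, _, _ = small_cohort
    return rs.score_activity_matrix(expr, small_regulons)
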