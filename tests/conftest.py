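"""Shared fixtures: one default-scale synthetic run reused across suites."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mesoconn.synthetic import generate_dataset, generate_ground_truth
from mesoconn.workflow import run_pipeline

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")

PIPELINE_SEED = 1


@pytest.fixture(scope="session")
def default_run():
    """End-to-end run at the default config (200 areas, 500 genes, K_true=10,
    5 % noise/NaN, 30 % zero-inflation, 60+15+15+15 injections)."""
    return run_pipeline(seed=PIPELINE_SEED)


@pytest.fixture(scope="session")
def anchor_run():
    """Noiseless, unmasked, un-inflated run: the self-consistency anchor in
    which the planted expression-to-projection map is exactly linear after
    the cube-root rescale."""
    return run_pipeline(
        seed=PIPELINE_SEED,
        noise_sd_expr=0.0,
        noise_sd_proj=0.0,
        zero_frac=0.0,
        nan_frac_expr=0.0,
        nan_frac_proj=0.0,
        with_binary=False,
    )


@pytest.fixture(scope="session")
def small_gt():
    """Small, fully observed ground truth for factorization/recovery tests."""
    return generate_ground_truth(
        n_areas=60,
        n_genes=120,
        k_true=8,
        category_sizes={"wild-type": 20, "cre_line_1": 8},
        noise_sd_expr=0.0,
        noise_sd_proj=0.0,
        zero_frac=0.0,
        nan_frac_expr=0.0,
        nan_frac_proj=0.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """Tiny noisy dataset with NaNs, for IO / preprocessing / CLI tests."""
    gt = generate_ground_truth(
        n_areas=30,
        n_genes=40,
        k_true=4,
        category_sizes={"wild-type": 8, "cre_line_1": 4},
        nan_frac_expr=0.1,
        nan_frac_proj=0.1,
        seed=7,
    )
    return generate_dataset(gt, n_terms=10, term_size_range=(5, 10), n_enriched=2)
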