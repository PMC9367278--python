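"""Shared fixtures: small and full-size synthetic cohorts, protocol runs.

The expensive repeated-protocol fixtures are session-scoped so the power,
recovery and stability tests all reuse the same 20-run batches.
"""

from __future__ import annotations

import numpy as np
import pytest

from tcoxnet import evalprotocol, netweights
from tcoxnet.syndata import SyntheticConfig, generate_dataset

#: indices of the true prognostic genes in the default synthetic world
TRUE_SUPPORT = (0, 25, 50, 100, 150)


@pytest.fixture(scope="session")
def small_world():
    """A quick cohort (40 genes, 120 tumor / 100 normal) for unit tests."""
    cfg = SyntheticConfig(
        n_genes=40,
        n_tumor=120,
        n_normal=100,
        block_sizes=(10, 10),
        diffcorr_genes=frozenset({0, 1, 2}),
        de_genes={0: 2.0, 20: -2.0},
        beta_true={0: 0.8, 15: -0.8},
        seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def stated_world():
    """The full-size testing world: p=200, n=300 per tissue, ~67% censoring."""
    return generate_dataset(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def stated_world_truth():
    cfg = SyntheticConfig(seed=11)
    ids = cfg.gene_ids()
    return [ids[i] for i in TRUE_SUPPORT]


@pytest.fixture(scope="session")
def stated_world_weights(stated_world):
    """Correlation-dissimilarity penalty factors on the full-size world."""
    ds = stated_world
    return netweights.penalty_weights(
        ds.expression[ds.tumor_samples()], ds.expression[ds.normal_samples()]
    )


@pytest.fixture(scope="session")
def protocol_records_en(stated_world):
    """20 elastic-net protocol runs (alpha=0.2) on the full-size world."""
    ds = stated_world
    return evalprotocol.run_protocol(
        ds.expression[ds.tumor_samples()], ds.survival, alpha=0.2,
        n_runs=20, base_seed=100,
    )


@pytest.fixture(scope="session")
def protocol_records_tcox(stated_world, stated_world_weights):
    """20 correlation-weighted protocol runs (alpha=0.1)."""
    ds = stated_world
    return evalprotocol.run_protocol(
        ds.expression[ds.tumor_samples()], ds.survival, alpha=0.1,
        q=stated_world_weights.q, n_runs=20, base_seed=100,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
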