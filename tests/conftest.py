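import numpy as np
import pandas as pd
import pytest

from corestress.preprocessing import combat_adjust, filter_zero_variance, log_transform
from corestress.simulate import SimConfig, generate_compendium


@pytest.fixture(scope="session")
def small_compendium():
    """Fast 300-gene compendium with planted structure for unit tests."""
    cfg = SimConfig(
        n_genes=300,
        n_core_up=15,
        n_core_down=10,
        n_specific_per_stressor=4,
        n_tfs=12,
        targets_per_tf=6,
        n_coexpr_blocks=2,
        block_size=20,
        samples_per_group=4,
        n_bioprojects_per_stressor=2,
        seed=42,
    )
    expr, meta, truth = generate_compendium(cfg)
    return cfg, expr, meta, truth


@pytest.fixture(scope="session")
def corrected_small(small_compendium):
    """Batch-corrected log2 expression of the small compendium."""
    _, expr, meta, _ = small_compendium
    filtered = filter_zero_variance(log_transform(expr))
    return combat_adjust(filtered, meta.loc[filtered.columns, "bioproject"]), meta


@pytest.fixture()
def toy_matrix():
    """Tiny deterministic genes x samples matrix."""
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        rng.gamma(2.0, 3.0, size=(10, 6)),
        index=[f"g{i}" for i in range(10)],
        columns=[f"s{j}" for j in range(6)],
    )
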