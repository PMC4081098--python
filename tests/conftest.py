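import numpy as np
import pandas as pd
import pytest

import mircor as mc
from mircor.counts import ExpressionMatrix


@pytest.fixture(scope="session")
def small_config():
    """A fast simulation with strong enough effects to populate every stage."""
    return mc.SimulationConfig(
        n_transcripts=600,
        n_true_targets=60,
        n_predicted=80,
        overlap_fraction=0.5,
        effect_log2fc_range=(0.5, 1.0),
        latent_factor_sd=0.5,
        libsize_range=(150_000, 250_000),
        n_indirect=100,
        rng_seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    counts, truth = mc.simulate_counts(small_config)
    return counts, truth


@pytest.fixture(scope="session")
def small_expr(small_dataset):
    counts, _ = small_dataset
    filtered = mc.filter_low_counts(counts)
    return mc.compute_precision_weights(mc.normalize_logcpm(filtered))


@pytest.fixture(scope="session")
def small_de(small_expr):
    return mc.fit_moderated_model(small_expr)


def make_expression(values: np.ndarray, conditions=None, weights=None) -> ExpressionMatrix:
    """Wrap a raw array as an ExpressionMatrix with a default 9-sample design."""
    G, n = values.shape
    if conditions is None:
        reps = n // 3
        conditions = ["WT"] * reps + ["KD"] * reps + ["OE"] * (n - 2 * reps)
    samples = [f"S{i}" for i in range(n)]
    design = pd.Series(conditions, index=samples, name="condition")
    vals = pd.DataFrame(values, index=[f"T{i}" for i in range(G)], columns=samples)
    w = None
    if weights is not None:
        w = pd.DataFrame(weights, index=vals.index, columns=vals.columns)
    return ExpressionMatrix(vals, design, w)
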