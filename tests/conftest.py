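import numpy as np
import pandas as pd
import pytest

from panelgrid.simdata import ExpressionMatrix, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """300 probe-sets, 24+24 samples, probe-level blocks included."""
    cfg = SimConfig(n_probesets=300, seed=11)
    coll, expr, truth, annot = simulate_cohort(cfg)
    return cfg, coll, expr, truth, annot


@pytest.fixture(scope="session")
def midsize_cohort():
    """2,000 probe-sets at the generator's default scale, features only."""
    cfg = SimConfig(seed=5)
    _, expr, truth, annot = simulate_cohort(cfg, probe_level=False)
    return cfg, expr, truth, annot


def make_expr(values: np.ndarray, n_case: int, prefix: str = "f") -> ExpressionMatrix:
    """Wrap a raw features x samples array as an ExpressionMatrix whose
    first n_case columns are the case group."""
    n_feat, n_samp = values.shape
    feats = [f"{prefix}{i:03d}" for i in range(n_feat)]
    samps = [f"s{j:03d}" for j in range(n_samp)]
    labels = pd.Series(["AR"] * n_case + ["NR"] * (n_samp - n_case), index=samps)
    return ExpressionMatrix(pd.DataFrame(values, index=feats, columns=samps), labels)
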