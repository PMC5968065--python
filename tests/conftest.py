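import warnings

import numpy as np
import pytest

from voigex import AnalysisConfig, run_analysis
from voigex import synth
from voigex.anova import DesignTable


def make_one_way_table(values, labels, unit_id="u"):
    """DesignTable with constant nuisance covariates (pure one-way design)."""
    n = len(values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return DesignTable(
            unit_id=unit_id,
            gene_symbol=unit_id,
            sample_ids=[f"s{i}" for i in range(n)],
            response=np.asarray(values, dtype=float),
            tsl=np.asarray(labels, dtype=object),
            donor=np.array(["d1"] * n, dtype=object),
            age=np.full(n, 40.0),
            sex=np.array(["M"] * n, dtype=object),
            ethnicity=np.array(["c"] * n, dtype=object),
        )


def one_way_f_oracle(values, labels):
    """Textbook one-way ANOVA F, independent of the package's fitting path."""
    y = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    grand = y.mean()
    ssb = ssw = 0.0
    k = 0
    for lev in np.unique(labels):
        g = y[labels == lev]
        ssb += len(g) * (g.mean() - grand) ** 2
        ssw += ((g - g.mean()) ** 2).sum()
        k += 1
    df_b, df_w = k - 1, len(y) - k
    if ssw == 0.0:
        return np.inf if ssb > 0 else 0.0
    return (ssb / df_b) / (ssw / df_w)


@pytest.fixture(scope="session")
def scene():
    """Default synthetic study geometry: maps, cohort, assignment (no expression)."""
    return synth.simulate_dataset(seed=0, n_background=10)


@pytest.fixture(scope="session")
def spiked_dataset():
    return synth.simulate_dataset(
        spiked_effects={"GENE001": 2.0}, seed=11, n_background=5
    )


def run_quiet(es, assignment, cfg, report=None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_analysis(es, assignment, cfg, report=report)


@pytest.fixture()
def fast_cfg():
    return AnalysisConfig(n_permutations=500, rng_seed=42)
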