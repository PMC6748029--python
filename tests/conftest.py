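import numpy as np
import pandas as pd
import pytest

from immunomir import SimulationConfig, generate_cohort
from immunomir.config import CorrelationPlanEntry


@pytest.fixture(scope="session")
def small_cohort():
    """Compact deterministic cohort reused by read-only tests."""
    cfg = SimulationConfig(
        n_control=12, n_per_subgroup={"high": 8, "normal": 8, "low": 8},
        n_mirna=60, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-sized cohort (expensive; shared, never mutated)."""
    return generate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def planted_correlation_cohort():
    cfg = SimulationConfig(
        seed=5,
        n_control=30, n_per_subgroup={"high": 20, "normal": 20, "low": 30},
        n_mirna=80,
        correlation_plan=[
            CorrelationPlanEntry(50, "cytokine", "TNF-a", "low", 0.6, "LPS"),
            CorrelationPlanEntry(51, "ratio", "IL-1b/IL-10", "control", 0.6, "zymosan"),
        ])
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def nb_counts(rng, n_genes, n_samples, mean_log=np.log(50), sd_log=1.0, phi=0.2):
    """Plain NB count frame with equal nominal library sizes (null data)."""
    means = rng.lognormal(mean_log, sd_log, size=n_genes)
    if phi > 0:
        size = 1.0 / phi
        counts = rng.negative_binomial(size, size / (size + means[:, None]),
                                       size=(n_genes, n_samples))
    else:
        counts = rng.poisson(means[:, None], size=(n_genes, n_samples))
    frame = pd.DataFrame(counts, columns=[f"s{i}" for i in range(n_samples)])
    frame.index = [f"g{i}" for i in range(n_genes)]
    lib = pd.Series(1_000_000.0, index=frame.columns)
    return frame, lib
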