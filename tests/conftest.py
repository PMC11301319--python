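"""Shared fixtures: small simulated panels reused across test modules."""

import numpy as np
import pytest

from plastiqtl import simdata
from plastiqtl.growth import LogisticParams, TimeGrid


@pytest.fixture(scope="session")
def grid8() -> TimeGrid:
    return TimeGrid.weekly(8)


@pytest.fixture(scope="session")
def small_map() -> simdata.GeneticMap:
    return simdata.GeneticMap(
        [(f"chr{c + 1}", np.arange(30) * 3.0) for c in range(2)]
    )


@pytest.fixture(scope="session")
def small_genotypes(small_map) -> simdata.RILGenotypes:
    return simdata.simulate_ril_genotypes(small_map, n_ril=60, seed=11)


def planted_qtl(marker_index: int, gap: float, treatment: str = "L") -> simdata.QTLSpec:
    """QTL that splits the asymptote of one treatment symmetrically by ``gap``."""
    base = simdata.default_baselines()[treatment]
    return simdata.QTLSpec(
        marker_index,
        {
            treatment: {
                0: LogisticParams(base.a + gap / 2, base.b, base.r),
                2: LogisticParams(base.a - gap / 2, base.b, base.r),
            }
        },
    )


@pytest.fixture(scope="session")
def null_experiment(small_genotypes):
    return simdata.simulate_trajectories(
        small_genotypes, [], n_replicates=10, seed=21
    )


@pytest.fixture(scope="session")
def planted_experiment(small_genotypes):
    """One strong pWPP QTL at marker 10 (low-light asymptote gap 6)."""
    return simdata.simulate_trajectories(
        small_genotypes, [planted_qtl(10, 6.0)], n_replicates=20, seed=22
    )
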