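"""Shared fixtures: small cached simulation runs and the full-scale study.

The full-scale study fixture mirrors the experimental conditions of the
simulation study (4300 base animals, six years of selection, ten
replicates) and is computed once per session; individual tests read the
summaries they need from it.
"""

from __future__ import annotations

import numpy as np
import pytest

from lrval import TraitArchitecture, run_scenario, scenario_config
from lrval.runner import ExperimentSpec, run_replicate

MASTER_SEED = 1


@pytest.fixture(scope="session")
def arch():
    return TraitArchitecture()


@pytest.fixture(scope="session")
def small_ben(arch):
    """One benchmark replicate at 1/10 scale (30 bulls, 400 cows)."""
    cfg = scenario_config("BEN", scale=0.1)
    return run_scenario(cfg, arch, seed=MASTER_SEED)


@pytest.fixture(scope="session")
def small_pe(arch):
    """One 25% pedigree-error replicate at 1/4 scale."""
    cfg = scenario_config("PE-25", scale=0.25)
    return run_scenario(cfg, arch, seed=MASTER_SEED)


@pytest.fixture(scope="session")
def small_wco_sco(arch):
    """Three scaled-down replicates each of WCO and SCO with the final
    mixed-model system retained for connectedness measures."""
    results = {}
    for name in ("WCO", "SCO"):
        cfg = scenario_config(name, scale=0.15)
        results[name] = [
            run_scenario(cfg, arch, seed=100 + r, keep_final_system=True)
            for r in range(3)
        ]
    return results


@pytest.fixture(scope="session")
def study_runs(arch):
    """Ten full-scale replicates of BEN, PE-25, PE-40 and WCO.

    Returns {scenario: [per-replicate dicts with 'lr', 'trend', 'counts',
    and 'herd_blues' where the model has herd-year effects]}.
    """
    spec = ExperimentSpec(
        scenarios=("BEN", "PE-25", "PE-40", "WCO"),
        replicates=10,
        master_seed=MASTER_SEED,
        arch=arch,
    )
    return {
        scen: [run_replicate(scen, spec, r) for r in range(spec.replicates)]
        for scen in spec.scenarios
    }


def kinship(sire, dam, i, j, cache=None):
    """Independent recursive kinship oracle (1-based ids, 0 unknown).

    a(i, j) = 2 * kinship(i, j); used to cross-check the tabular and
    Henderson-rule A-matrix machinery on tiny pedigrees.
    """
    if cache is None:
        cache = {}
    if i == 0 or j == 0:
        return 0.0
    if i > j:
        i, j = j, i
    key = (i, j)
    if key in cache:
        return cache[key]
    if i == j:
        f = 0.5 * (1.0 + kinship(sire, dam, sire[i - 1], dam[i - 1], cache))
    else:
        # j is the younger animal (larger id): recurse through its parents
        f = 0.5 * (
            kinship(sire, dam, i, sire[j - 1], cache)
            + kinship(sire, dam, i, dam[j - 1], cache)
        )
    cache[key] = f
    return f


def relationship_matrix_oracle(sire, dam):
    n = len(sire)
    cache = {}
    A = np.empty((n, n))
    for i in range(1, n + 1):
        for j in range(i, n + 1):
            A[i - 1, j - 1] = A[j - 1, i - 1] = 2.0 * kinship(sire, dam, i, j, cache)
    return A
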