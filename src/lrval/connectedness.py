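"""Connectedness between contemporary groups (herd-year cells).

Two complementary views are provided to verify that the weak (WCO) and
strong (SCO) connectedness designs actually contrast:

* scaled PEVD — the prediction-error variance of the difference between
  group-mean EBVs, divided by the additive variance. Small values mean the
  two groups' EBVs are comparable (well connected); each entry costs one
  sparse solve against the mixed-model coefficient matrix.
* common sires — the number of sires shared between the offspring of two
  contemporary groups in the evaluation pedigree.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .blup import EvaluationResult, pev_contrast
from .breeding import PopulationState


def contemporary_groups(
    state: PopulationState, cutoff: int
) -> dict[tuple[int, int], np.ndarray]:
    """(herd, year) -> ids of recorded animals, partitioning the records."""
    rec = state.recorded_ids(cutoff)
    herd = state.herd[rec - 1]
    year = state.birth_year[rec - 1]
    groups: dict[tuple[int, int], np.ndarray] = {}
    for h in np.unique(herd):
        for t in np.unique(year[herd == h]):
            ids = rec[(herd == h) & (year == t)]
            if ids.size:
                groups[(int(h), int(t))] = ids
    return groups


def _label(key: tuple[int, int]) -> str:
    return f"{key[0]}.{key[1]}"


def pevd_matrix(
    result: EvaluationResult,
    groups: dict[tuple[int, int], np.ndarray],
) -> pd.DataFrame:
    """Symmetric matrix of scaled PEVD between group-mean EBVs.

    Entry (i, j) = PEV of the difference of group means, scaled by
    sigma2_a; the diagonal is zero. Requires the evaluation to have been
    solved with ``keep_system=True``.
    """
    keys = sorted(groups)
    if any(groups[k].size == 0 for k in keys):
        raise ValueError("empty contemporary group")
    m = len(keys)
    M = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            pevd = pev_contrast(result, groups[keys[i]] - 1, groups[keys[j]] - 1)
            M[i, j] = M[j, i] = pevd / result.sigma2_a
    labels = [_label(k) for k in keys]
    return pd.DataFrame(M, index=labels, columns=labels)


def common_sires(
    sire: np.ndarray,
    groups: dict[tuple[int, int], np.ndarray],
) -> pd.DataFrame:
    """Counts of sires shared between contemporary groups.

    ``sire`` is the evaluation-file sire array (aligned on id-1, 0 for
    unknown). The diagonal holds each group's own sire count.
    """
    keys = sorted(groups)
    sets = {}
    for k in keys:
        s = sire[groups[k] - 1]
        sets[k] = set(s[s > 0].tolist())
    m = len(keys)
    M = np.zeros((m, m), dtype=np.int64)
    for i in range(m):
        for j in range(i, m):
            M[i, j] = M[j, i] = len(sets[keys[i]] & sets[keys[j]])
    labels = [_label(k) for k in keys]
    return pd.DataFrame(M, index=labels, columns=labels)


def cross_herd_summary(matrix: pd.DataFrame) -> float:
    """Mean of the entries whose row and column belong to different herds."""
    herds = np.array([int(lab.split(".")[0]) for lab in matrix.index])
    M = matrix.to_numpy()
    mask = herds[:, None] != herds[None, :]
    return float(M[mask].mean())
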