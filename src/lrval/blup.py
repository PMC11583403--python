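"""Pedigree BLUP engine.

Builds the inverse numerator relationship matrix directly from parent links
(Henderson's rules, with inbreeding from the Meuwissen & Luo algorithm),
assembles and solves the mixed-model equations for an animal model with
known variance components, and exposes prediction-error variances of
arbitrary contrasts through the inverse coefficient matrix.

Conventions: animals are coded 1..n with parents preceding offspring and 0
meaning "parent unknown" (BLUPF90-style). Animals with both parents unknown
are treated as unrelated base animals; no unknown-parent groups are fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import scipy.sparse as sp
from numba import njit
from scipy.sparse.linalg import splu


def _factorize(C: sp.csc_matrix):
    """Sparse LU of the (symmetric positive-definite) coefficient matrix.

    Symmetric-mode minimum-degree ordering keeps fill-in manageable on
    animal-model equations; the caller checks the solve residual.
    """
    return splu(C, permc_spec="MMD_AT_PLUS_A", options=dict(SymmetricMode=True))


@njit(cache=True)
def _inbreeding_kernel(sire: np.ndarray, dam: np.ndarray):
    """Meuwissen & Luo (1992) inbreeding coefficients.

    Parents are 0-based with -1 for unknown and must precede offspring.
    Returns (F, D) where D[i] = 0.5 - 0.25*(F_s + F_d) is the Mendelian
    sampling variance scaling (with F = -1 for an unknown parent, so D = 1
    for a founder).
    """
    n = sire.size
    F = np.zeros(n)
    D = np.zeros(n)
    L = np.zeros(n)
    point = np.full(n, -1, np.int64)
    for i in range(n):
        s = sire[i]
        d = dam[i]
        fs = F[s] if s >= 0 else -1.0
        fd = F[d] if d >= 0 else -1.0
        D[i] = 0.5 - 0.25 * (fs + fd)
        if s < 0 or d < 0:
            F[i] = 0.0
            continue
        # a_ii = sum over ancestors j of L_ij^2 * D_j, accumulated along a
        # linked list of ancestors kept in decreasing id order.
        aii = 0.0
        L[i] = 1.0
        j = i
        while j != -1:
            r = L[j]
            ks = sire[j]
            kd = dam[j]
            if ks >= 0:
                L[ks] += 0.5 * r
                k = j
                while point[k] > ks:
                    k = point[k]
                if point[k] != ks:
                    point[ks] = point[k]
                    point[k] = ks
            if kd >= 0:
                L[kd] += 0.5 * r
                k = j
                while point[k] > kd:
                    k = point[k]
                if point[k] != kd:
                    point[kd] = point[k]
                    point[k] = kd
            aii += r * r * D[j]
            L[j] = 0.0
            nxt = point[j]
            point[j] = -1
            j = nxt
        F[i] = aii - 1.0
    return F, D


def _validate_pedigree(sire: np.ndarray, dam: np.ndarray) -> None:
    n = sire.size
    ids = np.arange(1, n + 1)
    for name, par in (("sire", sire), ("dam", dam)):
        if np.any(par < 0) or np.any(par > n):
            raise ValueError(f"{name} codes must be in 0..n")
        if np.any(par == ids):
            raise ValueError("animal recorded as its own parent")
        if np.any(par > ids):
            raise ValueError("parents must precede offspring (sorted pedigree)")


def inbreeding(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Inbreeding coefficients for a sorted pedigree (1-based, 0 unknown)."""
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    _validate_pedigree(sire, dam)
    F, _ = _inbreeding_kernel(sire - 1, dam - 1)
    return F


def a_inverse(sire: np.ndarray, dam: np.ndarray) -> tuple[sp.csc_matrix, np.ndarray]:
    """Sparse inverse of the numerator relationship matrix.

    Returns (A_inv, F). Accounts for inbreeding through the Mendelian
    sampling variances d_i = 0.5 - 0.25*(F_s + F_d).
    """
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    _validate_pedigree(sire, dam)
    n = sire.size
    s = sire - 1
    d = dam - 1
    F, D = _inbreeding_kernel(s, d)
    alpha = 1.0 / D

    i = np.arange(n)
    hs = s >= 0
    hd = d >= 0
    both = hs & hd
    rows = [i]
    cols = [i]
    vals = [alpha]
    # parent-offspring and parent-parent contributions
    rows += [s[hs], i[hs], s[hs]]
    cols += [i[hs], s[hs], s[hs]]
    vals += [-0.5 * alpha[hs], -0.5 * alpha[hs], 0.25 * alpha[hs]]
    rows += [d[hd], i[hd], d[hd]]
    cols += [i[hd], d[hd], d[hd]]
    vals += [-0.5 * alpha[hd], -0.5 * alpha[hd], 0.25 * alpha[hd]]
    rows += [s[both], d[both]]
    cols += [d[both], s[both]]
    vals += [0.25 * alpha[both], 0.25 * alpha[both]]

    A_inv = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsc()
    return A_inv, F


def tabular_a(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method (oracle-size only)."""
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    _validate_pedigree(sire, dam)
    n = sire.size
    A = np.zeros((n, n))
    for i in range(n):
        s = sire[i] - 1
        d = dam[i] - 1
        asd = A[s, d] if (s >= 0 and d >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
    return A


@dataclass
class EvaluationResult:
    """Solutions of one genetic evaluation (one data cut-off).

    ``ebv`` covers every animal in the evaluation pedigree (including
    record-less parents); ``beta`` are the BLUEs of the fixed effects with
    ``fixed_labels`` naming each level. When the coefficient matrix is kept
    the factorization is cached for prediction-error-variance contrasts.
    """

    cutoff: int
    ebv: np.ndarray
    beta: np.ndarray
    fixed_labels: list
    n_records: int
    lambda_: float
    sigma2_a: float
    sigma2_e: float
    coeff: sp.csc_matrix | None = None
    _factor: object = field(default=None, repr=False)

    @property
    def n_animals(self) -> int:
        return self.ebv.size

    @property
    def n_fixed(self) -> int:
        return self.beta.size

    def factor(self):
        if self._factor is None:
            if self.coeff is None:
                raise ValueError("coefficient matrix was not retained; "
                                 "re-solve with keep_system=True")
            self._factor = _factorize(self.coeff)
        return self._factor

    def drop_system(self) -> None:
        self.coeff = None
        self._factor = None


def solve_mme(
    y: np.ndarray,
    animal: np.ndarray,
    fixed_level: np.ndarray,
    n_levels: int,
    fixed_labels: Sequence[Hashable],
    sire: np.ndarray,
    dam: np.ndarray,
    lambda_: float,
    sigma2_a: float = 0.4,
    sigma2_e: float = 0.6,
    cutoff: int = 0,
    keep_system: bool = False,
) -> EvaluationResult:
    """Solve Henderson's mixed-model equations for an animal model.

    y : phenotypic records; animal : 0-based animal index per record;
    fixed_level : 0-based fixed-effect level per record (all ``n_levels``
    levels must be observed). The coefficient matrix is

        [X'X      X'Z          ]
        [Z'X      Z'Z + A^-1 λ ]

    solved by direct sparse LU; the relative residual of the normal
    equations is checked to 1e-8.
    """
    y = np.asarray(y, dtype=float)
    animal = np.asarray(animal, dtype=np.int64)
    fixed_level = np.asarray(fixed_level, dtype=np.int64)
    if lambda_ <= 0:
        raise ValueError("lambda must be positive")
    if np.bincount(fixed_level, minlength=n_levels).min() == 0:
        raise ValueError("unobserved fixed-effect level (singular block)")
    n = len(sire)
    if animal.min() < 0 or animal.max() >= n:
        raise ValueError("record refers to an animal outside the pedigree")

    A_inv, _ = a_inverse(sire, dam)
    r = y.size
    ones = np.ones(r)
    X = sp.csr_matrix((ones, (np.arange(r), fixed_level)), shape=(r, n_levels))
    Z = sp.csr_matrix((ones, (np.arange(r), animal)), shape=(r, n))
    XtX = (X.T @ X).tocsc()
    XtZ = (X.T @ Z).tocsc()
    ZtZ = (Z.T @ Z).tocsc()
    C = sp.bmat(
        [[XtX, XtZ], [XtZ.T, ZtZ + lambda_ * A_inv]], format="csc"
    )
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    factor = _factorize(C)
    sol = factor.solve(rhs)
    res = np.linalg.norm(C @ sol - rhs)
    if res > 1e-8 * max(np.linalg.norm(rhs), 1.0):
        raise FloatingPointError(f"MME solve did not converge (residual {res:.3e})")
    result = EvaluationResult(
        cutoff=cutoff,
        ebv=sol[n_levels:],
        beta=sol[:n_levels],
        fixed_labels=list(fixed_labels),
        n_records=r,
        lambda_=lambda_,
        sigma2_a=sigma2_a,
        sigma2_e=sigma2_e,
        coeff=C if keep_system else None,
    )
    if keep_system:
        result._factor = factor
    return result


def write_evaluation(result: EvaluationResult, ebv_path, blue_path=None) -> None:
    """Write solutions as flat files: `id ebv` rows, and `level blue` rows."""
    with open(ebv_path, "w") as fh:
        for i, v in enumerate(result.ebv, start=1):
            fh.write(f"{i} {v:.10g}\n")
    if blue_path is not None:
        with open(blue_path, "w") as fh:
            for lab, v in zip(result.fixed_labels, result.beta):
                lab = ".".join(str(x) for x in lab) if isinstance(lab, tuple) else lab
                fh.write(f"{lab} {v:.10g}\n")


def herd_blues(result: EvaluationResult, n_herds: int = 3) -> np.ndarray:
    """Per-herd mean herd-year BLUE, re-based so the last herd's mean is zero.

    Requires the evaluation to have been run with herd-year fixed effects
    (labels are ``(herd, year)`` tuples).
    """
    if not all(isinstance(lab, tuple) and len(lab) == 2 for lab in result.fixed_labels):
        raise ValueError("herd_blues requires a herd-year fixed-effect model")
    herds = np.array([lab[0] for lab in result.fixed_labels])
    means = np.empty(n_herds)
    for h in range(1, n_herds + 1):
        mask = herds == h
        if not mask.any():
            raise ValueError(f"no herd-year levels observed for herd {h}")
        means[h - 1] = result.beta[mask].mean()
    return means - means[n_herds - 1]


def pev_contrast(
    result: EvaluationResult,
    group_a: np.ndarray,
    group_b: np.ndarray,
) -> float:
    """Prediction-error variance of the difference of two group-mean EBVs.

    PEVD = k' C^aa k * sigma2_e where k is the signed group-mean contrast
    over the animal equations and C^aa the animal block of the inverse
    coefficient matrix; computed with one sparse solve.
    """
    group_a = np.asarray(group_a, dtype=np.int64)
    group_b = np.asarray(group_b, dtype=np.int64)
    if group_a.size == 0 or group_b.size == 0:
        raise ValueError("empty group")
    if np.intersect1d(group_a, group_b).size and not np.array_equal(
        np.sort(group_a), np.sort(group_b)
    ):
        raise ValueError("groups must be disjoint")
    if np.array_equal(np.sort(group_a), np.sort(group_b)):
        return 0.0
    k = np.zeros(result.n_animals)
    np.add.at(k, group_a, 1.0 / group_a.size)
    np.add.at(k, group_b, -1.0 / group_b.size)
    rhs = np.concatenate([np.zeros(result.n_fixed), k])
    x = result.factor().solve(rhs)
    return float(k @ x[result.n_fixed:]) * result.sigma2_e
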