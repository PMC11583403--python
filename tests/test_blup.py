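"""A-inverse, mixed-model equations, herd BLUEs and PEV contrasts."""

import numpy as np
import pytest

from lrval import (a_inverse, herd_blues, inbreeding, pev_contrast,
                   solve_mme, tabular_a)

from conftest import relationship_matrix_oracle


def random_pedigree(n, rng, p_known=0.8):
    """Random sorted pedigree with some inbreeding loops."""
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    for i in range(2, n):
        if rng.random() < p_known:
            sire[i], dam[i] = rng.choice(i, size=2, replace=False) + 1
    return sire, dam


def test_unrelated_animals_give_identity():
    A_inv, F = a_inverse(np.zeros(3, dtype=int), np.zeros(3, dtype=int))
    np.testing.assert_array_equal(A_inv.toarray(), np.eye(3))
    np.testing.assert_array_equal(F, np.zeros(3))


def test_trio_closed_form():
    # sire 1, dam 2 unrelated; offspring 3
    A_inv, _ = a_inverse(np.array([0, 0, 1]), np.array([0, 0, 2]))
    expected = np.array([
        [1.5, 0.5, -1.0],
        [0.5, 1.5, -1.0],
        [-1.0, -1.0, 2.0],
    ])
    np.testing.assert_allclose(A_inv.toarray(), expected, atol=1e-12)


def test_a_inverse_matches_dense_tabular_inverse_with_inbreeding():
    rng = np.random.default_rng(7)
    sire, dam = random_pedigree(150, rng)
    A = tabular_a(sire, dam)
    F = inbreeding(sire, dam)
    np.testing.assert_allclose(F, np.diag(A) - 1.0, atol=1e-10)
    assert F.max() > 0  # the pedigree really contains inbreeding
    A_inv, _ = a_inverse(sire, dam)
    np.testing.assert_allclose(A_inv.toarray(), np.linalg.inv(A), atol=1e-8)


def test_tabular_a_agrees_with_recursive_kinship():
    rng = np.random.default_rng(8)
    sire, dam = random_pedigree(40, rng)
    np.testing.assert_allclose(
        tabular_a(sire, dam), relationship_matrix_oracle(sire, dam), atol=1e-12
    )


def test_pedigree_validation():
    with pytest.raises(ValueError):
        a_inverse(np.array([0, 1, 3]), np.array([0, 0, 0]))  # own parent
    with pytest.raises(ValueError):
        a_inverse(np.array([2, 0]), np.array([0, 0]))  # parent after offspring


def test_single_record_absorbed_by_mean():
    res = solve_mme(
        y=np.array([3.7]), animal=np.array([0]), fixed_level=np.array([0]),
        n_levels=1, fixed_labels=["mean"], sire=np.array([0]),
        dam=np.array([0]), lambda_=1.5,
    )
    assert res.beta[0] == pytest.approx(3.7)
    assert res.ebv[0] == pytest.approx(0.0, abs=1e-12)


def test_mme_matches_dense_first_principles_oracle():
    """Sparse MME solutions equal a dense solve assembled independently."""
    rng = np.random.default_rng(9)
    n = 120
    sire, dam = random_pedigree(n, rng)
    recorded = rng.choice(n, size=90, replace=False)
    y = rng.normal(1.0, 1.0, size=90)
    levels = rng.integers(0, 3, size=90)
    lam = 1.5
    res = solve_mme(
        y=y, animal=recorded, fixed_level=levels, n_levels=3,
        fixed_labels=list("abc"), sire=sire, dam=dam, lambda_=lam,
    )
    # dense oracle from first principles: tabular A, explicit incidence
    X = np.zeros((90, 3))
    X[np.arange(90), levels] = 1.0
    Z = np.zeros((90, n))
    Z[np.arange(90), recorded] = 1.0
    A = tabular_a(sire, dam)
    C = np.block([
        [X.T @ X, X.T @ Z],
        [Z.T @ X, Z.T @ Z + lam * np.linalg.inv(A)],
    ])
    sol = np.linalg.solve(C, np.concatenate([X.T @ y, Z.T @ y]))
    np.testing.assert_allclose(res.beta, sol[:3], atol=1e-8)
    np.testing.assert_allclose(res.ebv, sol[3:], atol=1e-8)
    # normal-equation identity: residuals orthogonal to fixed-effect columns
    resid = y - X @ res.beta - Z @ res.ebv
    np.testing.assert_allclose(X.T @ resid, 0.0, atol=1e-8)


def test_infinite_shrinkage_limit_recovers_least_squares():
    rng = np.random.default_rng(10)
    y = rng.normal(size=20)
    res = solve_mme(
        y=y, animal=np.arange(20), fixed_level=np.zeros(20, dtype=int),
        n_levels=1, fixed_labels=["mean"], sire=np.zeros(20, dtype=int),
        dam=np.zeros(20, dtype=int), lambda_=1e12,
    )
    assert res.beta[0] == pytest.approx(y.mean(), abs=1e-8)
    np.testing.assert_allclose(res.ebv, 0.0, atol=1e-8)


def test_unobserved_fixed_level_raises():
    with pytest.raises(ValueError):
        solve_mme(
            y=np.array([1.0]), animal=np.array([0]),
            fixed_level=np.array([0]), n_levels=2, fixed_labels=["a", "b"],
            sire=np.array([0]), dam=np.array([0]), lambda_=1.5,
        )


def test_herd_blues_exact_recovery_without_genetic_signal():
    """y carrying only herd-year effects returns them exactly, re-based."""
    H = {1: 2.0, 2: 1.0, 3: 0.0}
    records, labels = [], []
    rng = np.random.default_rng(11)
    n = 60
    herd = rng.integers(1, 4, size=n)
    year = rng.integers(0, 2, size=n)
    codes = [(int(h), int(t)) for h, t in zip(herd, year)]
    labels = sorted(set(codes))
    level = np.array([labels.index(c) for c in codes])
    y = np.array([H[h] for h in herd], dtype=float)
    res = solve_mme(
        y=y, animal=np.arange(n), fixed_level=level, n_levels=len(labels),
        fixed_labels=labels, sire=np.zeros(n, dtype=int),
        dam=np.zeros(n, dtype=int), lambda_=1.5,
    )
    np.testing.assert_allclose(herd_blues(res), [2.0, 1.0, 0.0], atol=1e-8)


def test_herd_blues_requires_herd_year_model():
    res = solve_mme(
        y=np.array([1.0, 2.0]), animal=np.array([0, 1]),
        fixed_level=np.zeros(2, dtype=int), n_levels=1, fixed_labels=["mean"],
        sire=np.zeros(2, dtype=int), dam=np.zeros(2, dtype=int), lambda_=1.5,
    )
    with pytest.raises(ValueError):
        herd_blues(res)


def test_pev_contrast_limits_and_dense_oracle():
    rng = np.random.default_rng(12)
    n = 50
    sire, dam = random_pedigree(n, rng)
    recorded = np.arange(0, 40)  # animals 40..49 unrecorded
    y = rng.normal(size=40)
    res = solve_mme(
        y=y, animal=recorded, fixed_level=np.zeros(40, dtype=int),
        n_levels=1, fixed_labels=["mean"], sire=sire, dam=dam,
        lambda_=1.5, keep_system=True,
    )
    ga, gb = np.arange(0, 5), np.arange(5, 12)
    # same group vs itself
    assert pev_contrast(res, ga, ga) == 0.0
    # dense-inverse oracle
    C = res.coeff.toarray()
    Cinv = np.linalg.inv(C)
    k = np.zeros(n)
    k[ga] = 1.0 / ga.size
    k[gb] -= 1.0 / gb.size
    expected = k @ Cinv[1:, 1:] @ k * res.sigma2_e
    assert pev_contrast(res, ga, gb) == pytest.approx(expected, abs=1e-8)
    with pytest.raises(ValueError):
        pev_contrast(res, np.arange(3), np.arange(2, 5))  # overlap


def test_pev_of_two_unrelated_unrecorded_animals_is_prior():
    # one recorded animal identifies the mean; animals 2 and 3 carry no data
    res = solve_mme(
        y=np.array([1.0]), animal=np.array([0]),
        fixed_level=np.array([0]), n_levels=1, fixed_labels=["mean"],
        sire=np.zeros(3, dtype=int), dam=np.zeros(3, dtype=int),
        lambda_=1.5, keep_system=True,
    )
    pevd = pev_contrast(res, np.array([1]), np.array([2]))
    assert pevd == pytest.approx(2 * res.sigma2_a)


def test_write_evaluation_flat_files(tmp_path):
    res = solve_mme(
        y=np.array([1.0, 2.0]), animal=np.array([0, 1]),
        fixed_level=np.array([0, 1]), n_levels=2,
        fixed_labels=[(1, 0), (2, 0)], sire=np.zeros(2, dtype=int),
        dam=np.zeros(2, dtype=int), lambda_=1.5,
    )
    from lrval.blup import write_evaluation
    write_evaluation(res, tmp_path / "ebv.txt", tmp_path / "blue.txt")
    lines = (tmp_path / "ebv.txt").read_text().splitlines()
    assert len(lines) == 2 and lines[0].startswith("1 ")
    blues = dict(l.split() for l in (tmp_path / "blue.txt").read_text().splitlines())
    assert set(blues) == {"1.0", "2.0"}
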