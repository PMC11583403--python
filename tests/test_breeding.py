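"""Herd allocation, phenotypes, mating, selection and pedigree-error injection."""

import numpy as np
import pytest
from scipy import stats

from lrval import (TraitArchitecture, TraitModel, allocate_base_herds,
                   build_founder_pedigree, inject_pedigree_errors,
                   mate_and_drop, scenario_config, simulate_base_tbv,
                   simulate_phenotypes)
from lrval.breeding import (PopulationState, read_pedigree, read_phenotypes,
                            write_pedigree, write_phenotypes)


def make_founders(males, females, seed=0, n_gen=0):
    arch = TraitArchitecture()
    ped = build_founder_pedigree(n_gen, males, females, seed=seed)
    return simulate_base_tbv(arch, ped, seed=seed)


def test_sorted_allocation_forced_by_ranking():
    founders = make_founders(3, 9, seed=1)
    # give the 9 females TBVs 1..9 (by id order) to force the split
    state = PopulationState(founders)
    females = state.base_ids[state.sex[state.base_ids - 1] == 0]
    founders.tbv[females - 1] = np.arange(1.0, 10.0)
    state = allocate_base_herds(founders, "sorted_by_tbv", 3, seed=0)
    herd_of = {int(t): h for t, h in
               zip(state.tbv[females - 1], state.herd[females - 1])}
    assert {t for t, h in herd_of.items() if h == 1} == {9, 8, 7}
    assert {t for t, h in herd_of.items() if h == 2} == {6, 5, 4}
    assert {t for t, h in herd_of.items() if h == 3} == {3, 2, 1}


def test_random_allocation_balanced_and_unbiased():
    founders = make_founders(300, 4000, seed=2)
    state = allocate_base_herds(founders, "random", 3, seed=2)
    base = state.base_ids
    sizes = np.bincount(state.herd[base - 1])[1:]
    assert sizes.sum() == 4300 and sizes.max() - sizes.min() <= 2
    se = np.sqrt(0.4 / (4300 / 3))
    for h in (1, 2, 3):
        assert abs(state.tbv[base - 1][state.herd[base - 1] == h].mean()) < 3 * se


def test_sorted_allocation_matches_truncated_normal_moment():
    """mean(TBV herd1) - mean(TBV herd3) ~ 2 * E[top third of N(0, 0.4)]."""
    founders = make_founders(3, 4000, seed=3)
    state = allocate_base_herds(founders, "sorted_by_tbv", 3, seed=3)
    females = state.base_ids[state.sex[state.base_ids - 1] == 0]
    tbv, herd = state.tbv[females - 1], state.herd[females - 1]
    observed = tbv[herd == 1].mean() - tbv[herd == 3].mean()
    z = stats.norm.ppf(2 / 3)
    top_third_mean = stats.norm.pdf(z) / (1 / 3) * np.sqrt(0.4)
    assert observed == pytest.approx(2 * top_third_mean, abs=0.08)


def test_phenotypes_noise_free_limits():
    founders = make_founders(10, 20, seed=4)
    state = allocate_base_herds(founders, "random", 3, seed=4)
    rng = np.random.default_rng(0)
    trait = TraitModel(mu=0.0, herd_effects=(0.0, 0.0, 0.0), sigma2_e=0.0)
    simulate_phenotypes(state, trait, 0, rng)
    base = state.base_ids
    np.testing.assert_allclose(state.y[base - 1], state.tbv[base - 1])
    # additive herd effects shift herd means exactly
    trait2 = TraitModel(mu=0.0, herd_effects=(2.0, 1.0, 0.0), sigma2_e=0.0)
    simulate_phenotypes(state, trait2, 0, rng)
    herd = state.herd[base - 1]
    d13 = (state.y[base - 1][herd == 1].mean() - state.y[base - 1][herd == 3].mean())
    t13 = (state.tbv[base - 1][herd == 1].mean() - state.tbv[base - 1][herd == 3].mean())
    assert d13 == pytest.approx(2.0 + t13)


def test_realized_heritability_near_target():
    founders = make_founders(300, 4000, seed=5)
    state = allocate_base_herds(founders, "random", 3, seed=5)
    rng = np.random.default_rng(1005)  # independent of the TBV stream
    simulate_phenotypes(state, TraitModel(), 0, rng)
    base = state.base_ids
    h2 = np.var(state.tbv[base - 1], ddof=1) / np.var(state.y[base - 1], ddof=1)
    assert h2 == pytest.approx(0.4, abs=0.03)


def test_mendelian_sampling_variance():
    """Offspring of TBV-zero, non-inbred parents: mean 0, variance sigma2_a/2."""
    founders = make_founders(2, 600, seed=6)
    founders.tbv[:] = 0.0
    state = allocate_base_herds(founders, "random", 3, seed=6)
    rng = np.random.default_rng(6)
    mate_and_drop(state, 1, rng, sigma2_a=0.4)
    calves = state.ids_born(1)
    assert calves.size == 600
    tbv = state.tbv[calves - 1]
    assert tbv.mean() == pytest.approx(0.0, abs=0.06)
    assert np.var(tbv, ddof=1) == pytest.approx(0.2, abs=0.04)


def test_mating_conservation_and_records():
    founders = make_founders(6, 120, seed=7)
    state = allocate_base_herds(founders, "random", 3, seed=7)
    rng = np.random.default_rng(7)
    n0 = state.n
    mate_and_drop(state, 1, rng)
    calves = state.ids_born(1)
    assert state.n - n0 == 120  # one calf per cow
    # calves inherit the dam's herd; true parents recorded
    np.testing.assert_array_equal(
        state.herd[calves - 1], state.herd[state.dam_true[calves - 1] - 1]
    )
    assert np.all(state.sire_true[calves - 1] > 0)
    # every sire's offspring count sums to the cow census
    sires, counts = np.unique(state.sire_true[calves - 1], return_counts=True)
    assert counts.sum() == 120
    assert np.all(np.isin(sires, state.active_bulls))


def test_error_injection_counts_and_classes():
    founders = make_founders(30, 400, seed=8)
    state = allocate_base_herds(founders, "random", 3, seed=8)
    rng = np.random.default_rng(8)
    mate_and_drop(state, 1, rng)
    cohort = state.ids_born(1)
    true_sire = state.sire_true[cohort - 1].copy()
    true_dam = state.dam_true[cohort - 1].copy()

    inject_pedigree_errors(state, 0.0, 1, rng)
    np.testing.assert_array_equal(state.sire_eval[cohort - 1], true_sire)

    inject_pedigree_errors(state, 0.40, 1, rng)
    es, ed = state.sire_eval[cohort - 1], state.dam_eval[cohort - 1]
    n_err = int(round(0.40 * cohort.size))
    unknown = (es == 0) & (ed == 0)
    wrong = (es != true_sire) & (es != 0)
    assert unknown.sum() == n_err // 2
    assert wrong.sum() == n_err - n_err // 2
    # wrong-sire animals keep their dam; all wrong sires served that year
    np.testing.assert_array_equal(ed[wrong], true_dam[wrong])
    assert np.all(np.isin(es[wrong], state.service_by_year[1]))
    # true parents and TBVs untouched
    np.testing.assert_array_equal(state.sire_true[cohort - 1], true_sire)
    # fraction with a changed evaluation sire equals the error rate
    assert (es != true_sire).mean() == pytest.approx(0.40, abs=1e-12)


def test_flat_file_round_trip(tmp_path, small_ben):
    state = small_ben.state
    pped = tmp_path / "ped.txt"
    pphe = tmp_path / "phe.txt"
    write_pedigree(state, pped)
    write_phenotypes(state, pphe)
    ped = read_pedigree(pped)
    assert len(ped) == state.n
    np.testing.assert_array_equal(ped["sire"].to_numpy(), state.sire_eval)
    phe = read_phenotypes(pphe)
    rec = state.recorded_ids(6)
    assert len(phe) == rec.size
    np.testing.assert_allclose(phe["y"].to_numpy(), state.y[rec - 1])


def test_bad_configs_rejected():
    with pytest.raises(ValueError):
        scenario_config("XYZ")
    with pytest.raises(ValueError):
        scenario_config("BEN", scale=0.0)


class TestScenarioRun:
    """Structural invariants of a small benchmark replicate."""

    def test_seven_evaluations(self, small_ben):
        assert sorted(small_ben.evaluations) == list(range(7))

    def test_breeder_census_constant(self, small_ben):
        cfg = small_ben.cfg
        state = small_ben.state
        assert state.active_cows.size == cfg.n_cows
        assert state.active_bulls.size == cfg.n_bulls

    def test_pedigree_integrity(self, small_ben):
        state = small_ben.state
        ids = np.arange(1, state.n + 1)
        for par in (state.sire_true, state.dam_true):
            known = par > 0
            assert np.all(par[known] < ids[known])
            assert np.all(
                state.birth_year[par[known] - 1] < state.birth_year[known]
            )
        # benchmark: evaluation pedigree identical to the true pedigree
        np.testing.assert_array_equal(state.sire_eval, state.sire_true)

    def test_selected_bulls_are_newborn_males(self, small_ben):
        state = small_ben.state
        for year, ids in small_ben.selected_bulls.items():
            assert np.all(state.birth_year[ids - 1] == year)
            assert np.all(state.sex[ids - 1] == 1)
            n_expected = int(round(0.6 * small_ben.cfg.n_bulls))
            assert ids.size == n_expected

    def test_eval_file_differs_only_at_injected_rows(self, small_pe):
        state = small_pe.state
        diff = (state.sire_eval != state.sire_true) | (
            state.dam_eval != state.dam_true
        )
        # only recorded, post-base cohorts are ever altered
        assert np.all(state.birth_year[diff] >= 1)
        per_year = {
            t: diff[state.ids_born(t) - 1].mean()
            for t in range(1, small_pe.cfg.n_years + 1)
        }
        for t, frac in per_year.items():
            assert frac == pytest.approx(0.25, abs=0.01)
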