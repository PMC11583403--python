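"""Six-year selection experiment for a beef-cattle-like population.

Each scenario runs the same engine: allocate the base animals to three
herds, phenotype every cohort once in its birth year, fit a yearly
pedigree BLUP on the accumulating records, and replace the bottom 40% of
cows (within herd) and 60% of bulls (per the scenario's bull-access rule)
with the top newborns ranked on EBV. Scenarios differ in

* how base animals are allocated to herds (at random, or sorted by TBV so
  genetic level and herd are confounded),
* which bulls a cow can be mated to (a common AI-like pool, strictly
  within herd, or within herd for a first service then a common pool),
* whether evaluation-file pedigree errors are injected into each cohort,
* the fixed part of the evaluation model (overall mean vs herd-year).

True parents and true breeding values are always kept alongside the
evaluation-file pedigree, so "true" validation statistics can be computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import blup
from .blup import EvaluationResult, _inbreeding_kernel
from .founders import FounderPopulation, TraitArchitecture, sample_gametes


@dataclass
class TraitModel:
    """Phenotype model y_ij = mu + H_i + TBV_j + e_ij."""

    mu: float = 0.0
    herd_effects: tuple[float, ...] = (0.0, 0.0, 0.0)
    sigma2_a: float = 0.4
    sigma2_e: float = 0.6


@dataclass
class ScenarioConfig:
    """All knobs distinguishing the BEN / PE-25 / PE-40 / WCO / SCO designs."""

    name: str
    error_rate: float = 0.0
    herd_allocation: str = "random"  # or "sorted_by_tbv"
    bull_replacement: str = "common_pool"  # "within_herd" | "pool_after_first_service"
    cow_replacement_rate: float = 0.40
    bull_replacement_rate: float = 0.60
    n_years: int = 6
    n_herds: int = 3
    fixed_effects: str = "mean_only"  # or "mean_and_herd_year"
    n_bulls: int = 300
    n_cows: int = 4000

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if self.herd_allocation not in ("random", "sorted_by_tbv"):
            raise ValueError(f"unknown herd allocation {self.herd_allocation!r}")
        if self.bull_replacement not in (
            "common_pool", "within_herd", "pool_after_first_service"
        ):
            raise ValueError(f"unknown bull replacement {self.bull_replacement!r}")
        if self.fixed_effects not in ("mean_only", "mean_and_herd_year"):
            raise ValueError(f"unknown fixed-effect spec {self.fixed_effects!r}")


_PRESETS = {
    "BEN": dict(error_rate=0.0, herd_allocation="random",
                bull_replacement="common_pool", fixed_effects="mean_only"),
    "PE-25": dict(error_rate=0.25, herd_allocation="random",
                  bull_replacement="common_pool", fixed_effects="mean_only"),
    "PE-40": dict(error_rate=0.40, herd_allocation="random",
                  bull_replacement="common_pool", fixed_effects="mean_only"),
    "WCO": dict(error_rate=0.0, herd_allocation="sorted_by_tbv",
                bull_replacement="within_herd", fixed_effects="mean_and_herd_year"),
    "SCO": dict(error_rate=0.0, herd_allocation="sorted_by_tbv",
                bull_replacement="pool_after_first_service",
                fixed_effects="mean_and_herd_year"),
}

SCENARIOS = tuple(_PRESETS)


def scenario_config(name: str, scale: float = 1.0) -> ScenarioConfig:
    """Preset configuration for a named scenario, optionally scaled down.

    ``scale`` multiplies the base census (bulls rounded to a multiple of
    the herd count so within-herd designs stay balanced); all rates are
    held fixed so selection intensities are approximately preserved.
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must be in (0, 1]")
    n_bulls = 3 * max(1, round(300 * scale / 3))
    n_cows = max(3, round(4000 * scale))
    return ScenarioConfig(name=name, n_bulls=n_bulls, n_cows=n_cows, **_PRESETS[name])


def default_trait(cfg: ScenarioConfig, arch: TraitArchitecture) -> TraitModel:
    """Herd effects (2, 1, 0) for the connectedness designs, zero otherwise."""
    if cfg.fixed_effects == "mean_and_herd_year":
        herd_effects = (2.0, 1.0, 0.0)
    else:
        herd_effects = (0.0,) * cfg.n_herds
    return TraitModel(mu=0.0, herd_effects=herd_effects,
                      sigma2_a=arch.sigma2_a, sigma2_e=arch.sigma2_e)


class PopulationState:
    """Growing pedigree + phenotype store with the active breeding sets.

    Animals are 1-based; arrays are aligned on id-1. Ancestral animals from
    the founder stage carry negative birth years and no records. The
    evaluation-file parents start equal to the true parents and diverge
    only where pedigree errors are injected.
    """

    def __init__(self, founders: FounderPopulation, n_herds: int = 3):
        ped = founders.pedigree
        n = ped.n
        self.n_herds = n_herds
        self.sire_true = ped.sire.copy()
        self.dam_true = ped.dam.copy()
        self.sire_eval = ped.sire.copy()
        self.dam_eval = ped.dam.copy()
        self.sex = ped.sex.copy()
        self.birth_year = (ped.generation - ped.generation.max()).astype(np.int64)
        self.herd = np.zeros(n, dtype=np.int64)
        self.tbv = founders.tbv.copy()
        self.y = np.full(n, np.nan)
        self.F = founders.inbreeding.copy()
        self.base_ids = ped.base_ids.copy()
        self.base_sd_g = founders.base_sd_g
        self.base_tbv_mean = float(founders.base_tbv.mean())
        self.qtl_genotypes = (
            None if founders.qtl_genotypes is None else founders.qtl_genotypes.copy()
        )
        self.qtl_effects = founders.qtl_effects
        self.active_cows = np.empty(0, dtype=np.int64)
        self.active_bulls = np.empty(0, dtype=np.int64)
        self.bull_service_herd = np.empty(0, dtype=np.int64)
        self.service_by_year: dict[int, np.ndarray] = {}

        # ancestral animals are founders only in truth; the evaluation file
        # never reaches behind the base generation
        pre_base = self.birth_year < 0
        self.sire_eval[self.base_ids - 1] = 0
        self.dam_eval[self.base_ids - 1] = 0
        self.sire_eval[pre_base] = 0
        self.dam_eval[pre_base] = 0

    @property
    def n(self) -> int:
        return self.sire_true.size

    def ids_born(self, year: int) -> np.ndarray:
        return np.nonzero(self.birth_year == year)[0] + 1

    def recorded_ids(self, cutoff: int) -> np.ndarray:
        mask = (self.birth_year >= 0) & (self.birth_year <= cutoff)
        return np.nonzero(mask)[0] + 1

    def founder_ids(self) -> np.ndarray:
        """Base-generation animals with both evaluation-file parents unknown.

        Error-induced unknown-parent animals born later are excluded.
        """
        mask = (self.birth_year == 0) & (self.sire_eval == 0) & (self.dam_eval == 0)
        return np.nonzero(mask)[0] + 1

    def append_cohort(self, sire, dam, sex, herd, year, tbv):
        k = len(sire)
        self.sire_true = np.concatenate([self.sire_true, sire])
        self.dam_true = np.concatenate([self.dam_true, dam])
        self.sire_eval = np.concatenate([self.sire_eval, sire])
        self.dam_eval = np.concatenate([self.dam_eval, dam])
        self.sex = np.concatenate([self.sex, np.asarray(sex, dtype=np.int8)])
        self.herd = np.concatenate([self.herd, herd])
        self.birth_year = np.concatenate(
            [self.birth_year, np.full(k, year, dtype=np.int64)]
        )
        self.tbv = np.concatenate([self.tbv, tbv])
        self.y = np.concatenate([self.y, np.full(k, np.nan)])
        self.F = np.concatenate([self.F, np.zeros(k)])


def _split_by_rank(ids: np.ndarray, tbv: np.ndarray, n_herds: int) -> np.ndarray:
    """Herd labels: best third -> herd 1, ..., worst third -> last herd."""
    order = np.lexsort((ids, -tbv[ids - 1]))
    herd = np.empty(ids.size, dtype=np.int64)
    for h, chunk in enumerate(np.array_split(order, n_herds), start=1):
        herd[chunk] = h
    return herd


def allocate_base_herds(
    founders: FounderPopulation,
    strategy: str,
    n_herds: int,
    seed: int | np.random.Generator,
) -> PopulationState:
    """Build the starting population state and assign base animals to herds.

    ``random`` permutes animals within sex before splitting into herds;
    ``sorted_by_tbv`` ranks them on TBV so herd 1 gets the best third. Both
    are applied separately per sex, so herd censuses differ by at most one.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    state = PopulationState(founders, n_herds=n_herds)
    base = state.base_ids
    for sex_code in (1, 0):  # males first for reproducibility
        ids = base[state.sex[base - 1] == sex_code]
        if strategy == "sorted_by_tbv":
            herd = _split_by_rank(ids, state.tbv, n_herds)
        elif strategy == "random":
            perm = rng.permutation(ids.size)
            herd = np.empty(ids.size, dtype=np.int64)
            for h, chunk in enumerate(np.array_split(perm, n_herds), start=1):
                herd[chunk] = h
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
        state.herd[ids - 1] = herd
    sizes = np.bincount(state.herd[base - 1], minlength=n_herds + 1)[1:]
    if sizes.max() - sizes.min() > 2:  # per-sex splits each differ by <= 1
        raise AssertionError("herd allocation out of balance")
    state.active_cows = np.sort(base[state.sex[base - 1] == 0])
    state.active_bulls = np.sort(base[state.sex[base - 1] == 1])
    state.bull_service_herd = np.zeros(state.active_bulls.size, dtype=np.int64)
    return state


def simulate_phenotypes(
    state: PopulationState,
    trait: TraitModel,
    cohort_year: int,
    rng: np.random.Generator,
) -> None:
    """One record per animal in its birth year: y = mu + H_herd + TBV + e."""
    ids = state.ids_born(cohort_year)
    if np.any(state.herd[ids - 1] == 0):
        raise ValueError("cohort contains animals without a herd assignment")
    e = rng.standard_normal(ids.size) * np.sqrt(trait.sigma2_e)
    H = np.asarray(trait.herd_effects)[state.herd[ids - 1] - 1]
    state.y[ids - 1] = trait.mu + H + state.tbv[ids - 1] + e


def _refresh_inbreeding(state: PopulationState) -> None:
    F, _ = _inbreeding_kernel(state.sire_true - 1, state.dam_true - 1)
    state.F = F


def mate_and_drop(
    state: PopulationState,
    year: int,
    rng: np.random.Generator,
    sigma2_a: float = 0.4,
) -> None:
    """Produce one calf per active cow; record true parents and drop TBVs.

    The sire of each calf is drawn uniformly from the bulls accessible to
    the dam's herd (the common pool plus any bulls in service restricted to
    that herd). TBV transmission is parent average plus a Mendelian
    deviation N(0, 0.5*sigma2_a*(1 - (F_s + F_d)/2)) with inbreeding from
    the true pedigree, or per-locus gamete sampling in QTL mode.
    """
    if state.active_cows.size == 0 or state.active_bulls.size == 0:
        raise ValueError("no active breeders")
    _refresh_inbreeding(state)
    state.service_by_year[year] = state.active_bulls.copy()
    dams_all, sires_all = [], []
    for h in range(1, state.n_herds + 1):
        cows = state.active_cows[state.herd[state.active_cows - 1] == h]
        if cows.size == 0:
            continue
        access = state.active_bulls[
            (state.bull_service_herd == 0) | (state.bull_service_herd == h)
        ]
        if access.size == 0:
            raise ValueError(f"no bulls accessible to herd {h}")
        dams_all.append(cows)
        sires_all.append(rng.choice(access, size=cows.size))
    dams = np.concatenate(dams_all)
    sires = np.concatenate(sires_all)
    k = dams.size
    sex = (rng.random(k) < 0.5).astype(np.int8)
    herd = state.herd[dams - 1]

    if state.qtl_genotypes is not None:
        gs = sample_gametes(state.qtl_genotypes[sires - 1], rng)
        gd = sample_gametes(state.qtl_genotypes[dams - 1], rng)
        G = gs + gd
        # same centring offset as the base TBVs
        offset = state.base_tbv_mean - float(
            (state.qtl_genotypes[state.base_ids - 1].astype(float)
             @ state.qtl_effects).mean()
        )
        tbv = G.astype(float) @ state.qtl_effects + offset
        state.qtl_genotypes = np.vstack([state.qtl_genotypes, G])
    else:
        msv = 0.5 * sigma2_a * (
            1.0 - 0.5 * (state.F[sires - 1] + state.F[dams - 1])
        )
        pa = 0.5 * (state.tbv[sires - 1] + state.tbv[dams - 1])
        tbv = pa + rng.standard_normal(k) * np.sqrt(msv)

    state.append_cohort(sires, dams, sex, herd, year, tbv)


def inject_pedigree_errors(
    state: PopulationState,
    error_rate: float,
    cohort_year: int,
    rng: np.random.Generator,
) -> None:
    """Corrupt the evaluation-file parents of a fraction of a cohort.

    Of the round(error_rate * cohort) sampled calves, half lose both
    recorded parents and half keep their dam but get a wrong sire drawn
    uniformly from the other bulls in service in their conception year
    (preferring the true sire's birth-year class). True parents — and hence
    TBV transmission — are untouched.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    if error_rate == 0.0:
        return
    cohort = state.ids_born(cohort_year)
    n_err = int(round(error_rate * cohort.size))
    chosen = rng.choice(cohort, size=n_err, replace=False)
    n_unknown = n_err // 2
    unknown, wrong = chosen[:n_unknown], chosen[n_unknown:]
    state.sire_eval[unknown - 1] = 0
    state.dam_eval[unknown - 1] = 0

    in_service = state.service_by_year.get(cohort_year, state.active_bulls)
    by = state.birth_year
    for aid in wrong:
        ts = state.sire_true[aid - 1]
        cands = in_service[(by[in_service - 1] == by[ts - 1]) & (in_service != ts)]
        if cands.size == 0:
            cands = in_service[in_service != ts]
        if cands.size == 0:
            males = np.nonzero(
                (state.sex == 1) & (np.abs(by - by[ts - 1]) <= 1)
            )[0] + 1
            cands = males[males != ts]
        if cands.size == 0:
            raise ValueError("no alternative sire available")
        state.sire_eval[aid - 1] = rng.choice(cands)


def _rank_bottom(ids: np.ndarray, ebv: np.ndarray, n: int) -> np.ndarray:
    """ids of the n lowest-EBV animals (ties broken by id)."""
    order = np.lexsort((ids, ebv[ids - 1]))
    return ids[order[:n]]

def _rank_top(ids: np.ndarray, ebv: np.ndarray, n: int) -> np.ndarray:
    order = np.lexsort((ids, -ebv[ids - 1]))
    return ids[order[:n]]


def select_replacements(
    state: PopulationState,
    ebv: np.ndarray,
    cfg: ScenarioConfig,
    year: int,
) -> np.ndarray:
    """Truncation selection on EBV; returns the recruited bull ids.

    Cows: within each herd, the bottom ``cow_replacement_rate`` fraction is
    culled and replaced by the top newborn females of that herd. Bulls: the
    bottom ``bull_replacement_rate`` fraction is culled; replacements are
    the top newborn males from a common pool (BEN/PE/SCO) or within herd
    (WCO). Breeder censuses are unchanged: if a cohort is short of newborns
    of the required sex (possible in strongly scaled-down runs), only as
    many breeders are culled as can be replaced.
    """
    newborn = state.ids_born(year)
    new_f = newborn[state.sex[newborn - 1] == 0]
    new_m = newborn[state.sex[newborn - 1] == 1]

    kept_cows = []
    for h in range(1, cfg.n_herds + 1):
        cows = state.active_cows[state.herd[state.active_cows - 1] == h]
        cand = new_f[state.herd[new_f - 1] == h]
        n_cull = min(int(round(cfg.cow_replacement_rate * cows.size)), cand.size)
        culled = _rank_bottom(cows, ebv, n_cull)
        kept_cows.append(np.setdiff1d(cows, culled))
        kept_cows.append(_rank_top(cand, ebv, n_cull))
    state.active_cows = np.sort(np.concatenate(kept_cows))

    if cfg.bull_replacement == "within_herd":
        kept, kept_herd, recruits = [], [], []
        for h in range(1, cfg.n_herds + 1):
            bulls = state.active_bulls[state.bull_service_herd == h]
            cand = new_m[state.herd[new_m - 1] == h]
            n_cull = min(int(round(cfg.bull_replacement_rate * bulls.size)),
                         cand.size)
            culled = _rank_bottom(bulls, ebv, n_cull)
            rec = _rank_top(cand, ebv, n_cull)
            keep = np.setdiff1d(bulls, culled)
            kept.append(np.concatenate([keep, rec]))
            kept_herd.append(np.full(keep.size + rec.size, h, dtype=np.int64))
            recruits.append(rec)
        state.active_bulls = np.concatenate(kept)
        state.bull_service_herd = np.concatenate(kept_herd)
        recruits = np.concatenate(recruits)
    else:
        bulls = state.active_bulls
        n_cull = min(int(round(cfg.bull_replacement_rate * bulls.size)),
                     new_m.size)
        culled = _rank_bottom(bulls, ebv, n_cull)
        recruits = _rank_top(new_m, ebv, n_cull)
        keep_mask = ~np.isin(bulls, culled)
        keep = bulls[keep_mask]
        keep_service = state.bull_service_herd[keep_mask]
        if cfg.bull_replacement == "pool_after_first_service":
            rec_service = state.herd[recruits - 1]
        else:
            rec_service = np.zeros(recruits.size, dtype=np.int64)
        state.active_bulls = np.concatenate([keep, recruits])
        state.bull_service_herd = np.concatenate([keep_service, rec_service])

    order = np.argsort(state.active_bulls)
    state.active_bulls = state.active_bulls[order]
    state.bull_service_herd = state.bull_service_herd[order]
    return np.sort(recruits)


def evaluate(
    state: PopulationState,
    cfg: ScenarioConfig,
    cutoff: int,
    trait: TraitModel,
    keep_system: bool = False,
) -> EvaluationResult:
    """Pedigree BLUP on the evaluation-file pedigree with records y0..y(cutoff)."""
    # animals are appended chronologically, so "born <= cutoff" is a prefix
    n_t = int(np.count_nonzero(state.birth_year <= cutoff))
    sire = state.sire_eval[:n_t]
    dam = state.dam_eval[:n_t]
    rec = state.recorded_ids(cutoff)
    y = state.y[rec - 1]
    if np.any(np.isnan(y)):
        raise ValueError("phenotyped cohort has missing records")
    if cfg.fixed_effects == "mean_only":
        levels = np.zeros(rec.size, dtype=np.int64)
        labels = ["mean"]
        n_levels = 1
    else:
        herd = state.herd[rec - 1]
        byear = state.birth_year[rec - 1]
        codes = (herd - 1) * (cfg.n_years + 1) + byear
        uniq, levels = np.unique(codes, return_inverse=True)
        labels = [(int(c) // (cfg.n_years + 1) + 1, int(c) % (cfg.n_years + 1))
                  for c in uniq]
        n_levels = uniq.size
    lam = trait.sigma2_e / trait.sigma2_a
    return blup.solve_mme(
        y=y, animal=rec - 1, fixed_level=levels, n_levels=n_levels,
        fixed_labels=labels, sire=sire, dam=dam, lambda_=lam,
        sigma2_a=trait.sigma2_a, sigma2_e=trait.sigma2_e,
        cutoff=cutoff, keep_system=keep_system,
    )


@dataclass
class ScenarioResult:
    """Everything one replicate produced: final state, yearly evaluations,
    and the bulls recruited into service each year (the LR focal groups)."""

    cfg: ScenarioConfig
    trait: TraitModel
    state: PopulationState
    evaluations: dict[int, EvaluationResult]
    selected_bulls: dict[int, np.ndarray]

    @property
    def sigma_g(self) -> float:
        return self.state.base_sd_g

    def structural_counts(self) -> dict[str, int]:
        state = self.state
        rec = state.recorded_ids(self.cfg.n_years)
        sires = state.sire_true[rec - 1]
        dams = state.dam_true[rec - 1]
        return {
            "recorded_animals": int(rec.size),
            "distinct_sires": int(np.unique(sires[sires > 0]).size),
            "distinct_dams": int(np.unique(dams[dams > 0]).size),
        }


def run_scenario(
    cfg: ScenarioConfig,
    arch: TraitArchitecture,
    seed: int | np.random.Generator,
    trait: TraitModel | None = None,
    n_founder_generations: int = 0,
    keep_final_system: bool = False,
    eval_year0: bool = True,
) -> ScenarioResult:
    """Run one replicate of a scenario end to end.

    Per year t = 1..n_years: mate and drop TBVs, phenotype the cohort,
    inject pedigree errors (PE scenarios), evaluate with records y0..yt,
    then replace breeders on the resulting EBVs.
    """
    from .founders import build_founder_pedigree, simulate_base_tbv

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fped = build_founder_pedigree(
        n_founder_generations, cfg.n_bulls, cfg.n_cows, rng
    )
    founders = simulate_base_tbv(arch, fped, rng)
    state = allocate_base_herds(founders, cfg.herd_allocation, cfg.n_herds, rng)
    if cfg.bull_replacement in ("within_herd", "pool_after_first_service"):
        state.bull_service_herd = state.herd[state.active_bulls - 1].copy()
    if trait is None:
        trait = default_trait(cfg, arch)

    simulate_phenotypes(state, trait, 0, rng)
    evaluations: dict[int, EvaluationResult] = {}
    selected: dict[int, np.ndarray] = {}
    if eval_year0:
        evaluations[0] = evaluate(state, cfg, 0, trait)
    for t in range(1, cfg.n_years + 1):
        mate_and_drop(state, t, rng, sigma2_a=trait.sigma2_a)
        if cfg.bull_replacement == "pool_after_first_service":
            # first service done: every bull joins the common pool
            state.bull_service_herd[:] = 0
        simulate_phenotypes(state, trait, t, rng)
        if cfg.error_rate > 0:
            inject_pedigree_errors(state, cfg.error_rate, t, rng)
        res = evaluate(
            state, cfg, t, trait,
            keep_system=(keep_final_system and t == cfg.n_years),
        )
        evaluations[t] = res
        selected[t] = select_replacements(state, res.ebv, cfg, t)
    return ScenarioResult(cfg=cfg, trait=trait, state=state,
                          evaluations=evaluations, selected_bulls=selected)


# ---------------------------------------------------------------------------
# flat-file interfaces (BLUPF90-style whitespace-delimited columns)

def write_pedigree(state: PopulationState, path) -> None:
    """`id sire dam birth_year sex herd` (evaluation-file parents, 0 unknown)."""
    df = pd.DataFrame({
        "id": np.arange(1, state.n + 1),
        "sire": state.sire_eval,
        "dam": state.dam_eval,
        "birth_year": state.birth_year,
        "sex": state.sex,
        "herd": state.herd,
    })
    df.to_csv(path, sep=" ", index=False, header=False)


def read_pedigree(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep=r"\s+", header=None,
        names=["id", "sire", "dam", "birth_year", "sex", "herd"],
    )


def write_phenotypes(state: PopulationState, path, n_years: int = 6) -> None:
    """`id y herd_year_code birth_year` for recorded animals."""
    rec = state.recorded_ids(n_years)
    code = (state.herd[rec - 1] - 1) * (n_years + 1) + state.birth_year[rec - 1]
    df = pd.DataFrame({
        "id": rec,
        "y": state.y[rec - 1],
        "herd_year_code": code,
        "birth_year": state.birth_year[rec - 1],
    })
    df.to_csv(path, sep=" ", index=False, header=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep=r"\s+", header=None,
        names=["id", "y", "herd_year_code", "birth_year"],
    )
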