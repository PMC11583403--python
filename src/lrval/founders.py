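"""Synthetic founder stage: ancestral pedigree and base-population breeding values.

The study population starts from a base of 300 males and 4000 females with
true breeding values (TBVs) of additive variance 0.4 for a trait of
heritability 0.4. Two routes are provided:

* ``infinitesimal`` (default): base TBVs are drawn from N(0, sigma2_a * A)
  of a synthetic random-mating ancestral pedigree (i.i.d. normals when the
  pedigree has no ancestral generations).
* ``qtl``: allele substitution effects at ``n_qtl`` biallelic loci are drawn
  as Gamma(shape=0.4) magnitudes with random sign; founder haplotype
  frequencies follow a U-shaped distribution and genotypes are dropped
  through the ancestral pedigree by Mendelian segregation. Effects are
  rescaled post hoc so the realized base TBV variance equals sigma2_a.

The genetic standard deviation used to express all results (sigma_g) is the
realized standard deviation of the base TBVs of each replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blup import _inbreeding_kernel, _validate_pedigree


@dataclass
class TraitArchitecture:
    """Genetic architecture of the simulated trait."""

    n_qtl: int = 10_000
    gamma_shape: float = 0.4
    sigma2_a: float = 0.4
    sigma2_e: float = 0.6
    mode: str = "infinitesimal"

    def __post_init__(self) -> None:
        if self.sigma2_a <= 0 or self.sigma2_e <= 0:
            raise ValueError("variance components must be positive")
        if self.mode not in ("infinitesimal", "qtl"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "qtl" and self.n_qtl < 1:
            raise ValueError("qtl mode requires at least one locus")

    @property
    def heritability(self) -> float:
        return self.sigma2_a / (self.sigma2_a + self.sigma2_e)


@dataclass
class FounderPedigree:
    """Random-mating ancestral pedigree whose final generation is the base.

    Arrays are aligned on animals 1..n (0 = unknown parent), sorted so
    parents precede offspring. ``generation`` runs 0..n_generations; the
    final generation holds exactly the base males followed by base females.
    """

    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray  # 1 = male, 0 = female
    generation: np.ndarray
    n_base_males: int
    n_base_females: int

    @property
    def n(self) -> int:
        return self.sire.size

    @property
    def base_ids(self) -> np.ndarray:
        """1-based ids of the base (final-generation) animals, males first."""
        return np.arange(self.n - self.n_base_males - self.n_base_females,
                         self.n) + 1


@dataclass
class FounderPopulation:
    """Base population with TBVs (and optionally QTL genotypes/effects)."""

    pedigree: FounderPedigree
    tbv: np.ndarray  # over all founder-pedigree animals
    base_sd_g: float
    qtl_genotypes: np.ndarray | None = None  # pedigree animals x loci dosages
    qtl_effects: np.ndarray | None = None
    allele_freq: np.ndarray | None = None
    inbreeding: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def base_ids(self) -> np.ndarray:
        return self.pedigree.base_ids

    @property
    def base_tbv(self) -> np.ndarray:
        return self.tbv[self.base_ids - 1]

    @property
    def base_sex(self) -> np.ndarray:
        return self.pedigree.sex[self.base_ids - 1]


def build_founder_pedigree(
    n_generations: int,
    n_base_males: int,
    n_base_females: int,
    seed: int | np.random.Generator = 0,
) -> FounderPedigree:
    """Random-mating ancestral pedigree ending in the base population.

    With ``n_generations=0`` the base animals are mutually unrelated
    founders. Each ancestral generation has the same census as the base;
    every animal of generation g+1 gets a sire and dam drawn uniformly from
    the males and females of generation g.
    """
    if n_base_males <= 0 or n_base_females <= 0:
        raise ValueError("population sizes must be positive")
    if n_generations < 0:
        raise ValueError("n_generations must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    per_gen = n_base_males + n_base_females
    n = per_gen * (n_generations + 1)
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    sex = np.zeros(n, dtype=np.int8)
    generation = np.zeros(n, dtype=np.int64)
    for g in range(n_generations + 1):
        lo = g * per_gen
        sex[lo:lo + n_base_males] = 1
        generation[lo:lo + per_gen] = g
        if g > 0:
            prev_lo = (g - 1) * per_gen
            males = np.arange(prev_lo, prev_lo + n_base_males) + 1
            females = np.arange(prev_lo + n_base_males, prev_lo + per_gen) + 1
            sire[lo:lo + per_gen] = rng.choice(males, size=per_gen)
            dam[lo:lo + per_gen] = rng.choice(females, size=per_gen)
    return FounderPedigree(sire, dam, sex, generation, n_base_males, n_base_females)


def sample_gametes(dosage: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per parent row: transmit allele 1 with probability dosage/2.

    Loci segregate independently (no linkage), which is adequate for an
    additive trait summarised by its TBV.
    """
    return (rng.random(dosage.shape) < dosage / 2.0).astype(np.int8)


def simulate_base_tbv(
    arch: TraitArchitecture,
    founder_pedigree: FounderPedigree,
    seed: int | np.random.Generator = 0,
) -> FounderPopulation:
    """Simulate TBVs for the founder pedigree under the chosen architecture."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ped = founder_pedigree
    _validate_pedigree(ped.sire, ped.dam)
    F, D = _inbreeding_kernel(ped.sire - 1, ped.dam - 1)
    n = ped.n
    base = ped.base_ids - 1

    if arch.mode == "infinitesimal":
        # gene-drop the polygenic value: founders N(0, sigma2_a), descendants
        # parent average + Mendelian deviation, giving cov = sigma2_a * A.
        tbv = np.empty(n)
        dev = rng.standard_normal(n)
        for i in range(n):
            s = ped.sire[i] - 1
            d = ped.dam[i] - 1
            if s < 0 and d < 0:
                tbv[i] = dev[i] * np.sqrt(arch.sigma2_a)
            else:
                pa = 0.5 * (tbv[s] if s >= 0 else 0.0) + 0.5 * (tbv[d] if d >= 0 else 0.0)
                tbv[i] = pa + dev[i] * np.sqrt(arch.sigma2_a * D[i])
        pop = FounderPopulation(
            pedigree=ped,
            tbv=tbv,
            base_sd_g=float(np.std(tbv[base], ddof=1)),
            inbreeding=F,
        )
        return pop

    # qtl mode: U-shaped founder allele frequencies, Mendelian drop, Gamma effects
    p = rng.beta(0.5, 0.5, size=arch.n_qtl)
    p = np.clip(p, 0.01, 0.99)
    G = np.zeros((n, arch.n_qtl), dtype=np.int8)
    for i in range(n):
        s = ped.sire[i] - 1
        d = ped.dam[i] - 1
        if s < 0 and d < 0:
            G[i] = rng.binomial(2, p).astype(np.int8)
        else:
            gs = sample_gametes(G[s][None, :], rng)[0] if s >= 0 else rng.binomial(1, p).astype(np.int8)
            gd = sample_gametes(G[d][None, :], rng)[0] if d >= 0 else rng.binomial(1, p).astype(np.int8)
            G[i] = gs + gd
    effects = rng.gamma(arch.gamma_shape, 1.0, size=arch.n_qtl)
    effects *= rng.choice([-1.0, 1.0], size=arch.n_qtl)
    raw = G[base].astype(float) @ effects
    v = np.var(raw, ddof=1)
    if v <= 0:
        raise ValueError("degenerate QTL effects: base TBV variance is zero")
    effects *= np.sqrt(arch.sigma2_a / v)
    tbv_all = G.astype(float) @ effects
    tbv_all -= tbv_all[base].mean()
    pop = FounderPopulation(
        pedigree=ped,
        tbv=tbv_all,
        base_sd_g=float(np.std(tbv_all[base], ddof=1)),
        qtl_genotypes=G,
        qtl_effects=effects,
        allele_freq=p,
        inbreeding=F,
    )
    return pop
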