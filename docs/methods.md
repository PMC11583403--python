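# Methods

## The question

The LR ("linear regression") method validates a genetic evaluation by
comparing the EBVs of the same *focal* animals from a *partial* evaluation
(data truncated at year `np`) and a *whole* evaluation (data to a later
year `nw`). Its statistics estimate the bias, dispersion and accuracy of
the evaluation without ever observing true breeding values. This package
asks, by simulation of a beef-cattle-like breeding program, whether those
statistics remain informative when two of the method's core assumptions
fail: a correct pedigree, and genetic connectedness among herds.

Because the simulation knows the true breeding values (TBVs), every LR
statistic has a computable "true" counterpart; the study's output is the
comparison between the two across designed failure modes.

## Population model

**Base population.** 300 males and 4000 females carry TBVs for a single
additive trait with additive variance σ²ₐ = 0.4 and residual variance
σ²ₑ = 0.6 (heritability 0.4). Two routes generate them:

* *infinitesimal* (default): TBVs are drawn N(0, σ²ₐ·A) over a synthetic
  random-mating founder pedigree; with the default of zero ancestral
  generations the base animals are unrelated and TBVs are i.i.d.
  N(0, 0.4).
* *qtl*: 10,000 biallelic loci (U-shaped Beta(½, ½) founder frequencies,
  no linkage) with Gamma(shape 0.4) substitution-effect magnitudes and
  random signs, rescaled so the realized base TBV variance is exactly
  σ²ₐ. This route exists for fidelity checks (e.g. the parent–offspring
  regression of 0.5); the study scenarios use the infinitesimal route,
  which is orders of magnitude faster and equivalent for a purely
  additive trait summarised by its TBV.

All results are expressed in σ_g, the *realized* standard deviation of the
base TBVs of each replicate, not the nominal √0.4.

Real beef-cattle evaluations sit on deep industry pedigrees (and, in
sequence-level simulators, on coalescent haplotypes dropped through them),
so their base animals are related in ways the evaluation file does not
record. This package deliberately replaces that stage with the synthetic
founder pedigree: the quantities the study tracks depend on base TBV
variance and on the selection/connectedness design, not on
linkage-disequilibrium fine structure. The cost is that base relatedness
of any particular real population is not reproduced, so
between-replicate SDs are matched only loosely (see Limitations).

**Phenotypes.** One record per animal in its birth year:
y = μ + H_herd + TBV + e, with μ = 0, e ~ N(0, 0.6). Herd effects are
(0, 0, 0) except in the connectedness designs, where H = (2, 1, 0).

**Breeding cycle (years 1..6).** Every active cow produces one calf per
year (sex Bernoulli ½, herd = dam's herd); the sire is drawn uniformly
from the bulls accessible to her herd. TBV transmission is parent average
plus a Mendelian deviation N(0, ½σ²ₐ(1 − (F_s + F_d)/2)) with inbreeding
F from the true pedigree (per-locus gamete sampling in qtl mode). After
phenotyping (and error injection, below), a pedigree BLUP is fitted to all
records to date and truncation selection is applied: the bottom 40% of
cows per herd are replaced by the herd's top newborn females (≈533 per
herd per year), and the bottom 60% of bulls by top newborn males (180 per
year from a common pool, or 60 per herd within herd, by scenario). Newborns
compete on the EBVs of the evaluation that includes their own first record.
Ties in EBV rank are broken by animal id, so runs are reproducible.
In strongly scaled-down runs a cohort can be short of newborns of one sex;
replacements are then capped at the available candidates so the breeder
census (4000 cows, 300 bulls at full scale) is invariant. At full census
the cap is never reached.

**Scenarios.**

| name  | base herd allocation | bull access            | pedigree errors | fixed effects |
|-------|----------------------|------------------------|-----------------|---------------|
| BEN   | random               | common pool            | none            | mean          |
| PE-25 | random               | common pool            | 25% per cohort  | mean          |
| PE-40 | random               | common pool            | 40% per cohort  | mean          |
| WCO   | sorted by TBV        | within natal herd      | none            | herd-year     |
| SCO   | sorted by TBV        | pool after 1st service | none            | herd-year     |

In WCO/SCO the best third of base animals (per sex) goes to herd 1, the
middle to herd 2, the worst to herd 3, and the true herd effects (2, 1, 0)
run in the same direction — genetic level and environment are confounded
by construction. In SCO each bull serves only its natal herd in its first
year and joins the common pool afterwards; bull replacements are selected
across herds as in BEN.

**Pedigree errors.** Each year, ⌊rate·cohort⌉ calves are sampled; half
lose both recorded parents, half keep the dam but get a wrong sire drawn
uniformly from the *other bulls in service in the conception year*
(preferring the true sire's birth-year class, falling back to all
in-service bulls, then to adjacent birth-year males). Only the
evaluation-file pedigree is corrupted; true transmission is untouched.
Restricting wrong-sire donors to in-service bulls keeps the evaluation
file's distinct-sire count at the designed ~1200: a mis-recorded sire in
practice is another bull that stood in service, not an arbitrary male.

## Evaluation model

Single-trait animal model with known variance components (never
re-estimated): fixed part either an overall mean (BEN/PE) or one level per
herd-year cell with no separate intercept (WCO/SCO; full rank within
observed levels, re-based afterwards). The inverse numerator relationship
matrix is built by Henderson's rules with inbreeding from the
Meuwissen–Luo algorithm; animals with unknown parents are unrelated base
animals — unknown-parent groups and metafounders are deliberately not
fitted, since the point of the pedigree-error scenarios is to observe an
uncorrected misspecification. The mixed-model equations use
λ = σ²ₑ/σ²ₐ = 1.5 and are solved by sparse LU with a symmetric
minimum-degree ordering; the relative residual of the normal equations is
checked to 1e-8. Inbreeding is included in the A-inverse (a switchable
choice; at the inbreeding levels this design produces the effect is far
below the replicate noise).

Herd-effect BLUEs are summarised from the final (year-6) evaluation as the
per-herd mean of herd-year solutions, shifted so herd 3 is zero.
Prediction-error variances of group-mean contrasts come from single sparse
solves against the retained coefficient matrix.

## LR statistics

With â_p, â_w the focal group's partial and whole EBVs — each first
referred to the base by subtracting the mean EBV of the *founder* animals
of that evaluation (born year 0 with both recorded parents unknown;
error-induced unknown-parent animals do not qualify) — and a their TBVs:

* bias Δ̂ = mean(â_p) − mean(â_w), in σ_g; true Δ = mean(â_p) − mean(a)
* dispersion b̂ = cov(â_w, â_p)/var(â_p); true b = cov(a, â_p)/var(â_p)
* accuracy ratio ρ̂ = cor(â_p, â_w); true counterpart acc_p/acc_w with
  acc = cor(EBV, TBV) within the focal group
* reliability ratio ρ̂² = cov(â_w, â_p)/var(â_w); true acc²_p/acc²_w
* selected reliability âcc² = cov(â_p, â_w)/σ²ₐ\*, with σ²ₐ\* the TBV
  variance within the focal group (known from simulation)
* unselected reliability r̂el = 1 − (σ²ₐ\*/σ²ₐ)(1 − âcc²), with σ²ₐ the
  realized base TBV variance; the true version uses cov(â_p, a)/σ²ₐ\*.

Focal groups are the bulls recruited into service in year np ∈ {3, 4, 5}
(grouped by natal herd in WCO/SCO), compared against every later cut-off
nw ≤ 6 — six comparisons. Because np = 3 contributes three comparisons and
np = 5 only one, statistics are averaged in two stages (over nw within np,
then equally over np), "as if the design was balanced" — the two-stage
equal-weight mean. Replicate summaries report the mean and SD of the
balanced averages and the Pearson correlation between estimated and true
values pooled over (np, replicate) cells; the SD-of-balanced-averages
convention was chosen where the alternative (SD over all cells) was also
defensible.

One deliberate divergence of conventions: the *genetic-trend* table
reports raw EBV solutions (what an evaluation program prints), not
founder-referenced ones. For an unbiased evaluation the two coincide; with
pedigree errors the founder mean drifts (≈ −0.33 σ_g at year 6 under
PE-40) and the raw trend is the quantity that exhibits the headline
under-estimation of genetic gain. LR statistics always use the
founder-referenced EBVs.

## Problem sizes and defaults

Full scale is 4300 base animals plus 4000 calves/year for six years
(28,300 records; ~28,600 mixed-model equations at year 6). One replicate
of a scenario takes a few seconds on a laptop-class core. The experiment
driver defaults to 20 replicates per scenario; the acceptance script uses
10, which is enough for every stochastic band it checks. The `scale`
parameter multiplies the base census only (rates and intensities held
fixed) and preserves all qualitative contrasts down to about scale 0.1;
the test suite uses scales 0.1–0.25 for structural checks and full scale
for the quantitative ones.

## Numerical choices

* Direct sparse LU (SuperLU, `MMD_AT_PLUS_A` ordering, symmetric mode) —
  an iterative solver is unnecessary at these sizes and a factorization is
  reused for PEV contrasts.
* PEVD between groups is defined on group-mean contrasts (one solve per
  pair), not averaged over all animal pairs; the cheaper variant preserves
  the weak/strong ordering, which is all the study uses it for. Absolute
  PEVD levels are not comparable to the original supplementary figures,
  whose normalisation is not recoverable.
* Covariances and variances use the n−1 denominator throughout.
* Gamma-distributed QTL effect magnitudes get a random ± sign (a Gamma
  draw is positive by construction) and are rescaled post hoc to hit σ²ₐ
  exactly.
* Degenerate inputs (zero EBV variance, empty groups, unobserved fixed
  levels, pedigree cycles) raise immediately rather than propagating NaNs.

## Limitations

* The synthetic founder stage does not reproduce the base relatedness of
  the real industry pedigree; replicate-to-replicate SDs and
  estimated–true correlations are therefore matched in sign and rough
  magnitude, not digit by digit.
* No maternal effects, age structure beyond survival-by-selection,
  seasonal effects or genomic information; these are outside the study's
  design space.
* The year-0 cohort is phenotyped once and culling starts in year 1;
  re-ranking base animals within year 0 would be an equally defensible
  convention but changes nothing downstream of year 1.
* WCO assumes 100 bulls per herd (300/3), consistent with the stated
  "N = 60 bulls" replaced per herd per year at a 60% replacement rate.
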