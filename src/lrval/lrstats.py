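"""Linear-regression (LR) method statistics and their true counterparts.

The LR method validates a genetic evaluation by comparing EBVs of the same
focal animals from a *partial* evaluation (records up to year np, focal
sires have only their own record) and a *whole* evaluation (records up to
year nw > np, their progeny recorded). The estimated statistics are

    delta_hat = mean(a_p) - mean(a_w)                (bias, in sigma_g)
    b_hat     = cov(a_w, a_p) / var(a_p)             (dispersion)
    rho_hat   = cor(a_p, a_w)                        (ratio of accuracies)
    rho2_hat  = cov(a_w, a_p) / var(a_w)             (ratio of reliabilities)
    acc2_hat  = cov(a_p, a_w) / sigma2_a_star        (selected reliability)
    rel_hat   = 1 - (sigma2_a_star / sigma2_a) * (1 - acc2_hat)
                                                     (unselected reliability)

with sigma2_a_star the additive variance within the focal group and
sigma2_a the base-population additive variance, both known from the
simulation. The "true" counterparts replace the whole EBVs by the TBVs.
Before computing anything, EBVs are referred to the base generation by
subtracting the mean EBV of the founder animals of that evaluation.

Focal sires are grouped by partial-data year np in {3, 4, 5}; each np is
compared against all later cut-offs nw, and statistics are averaged in two
stages (over nw within np, then over np) so the unbalanced comparison
design does not overweight early years.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .breeding import ScenarioResult

ESTIMATORS = ("delta", "b", "rho", "rho2", "acc2", "rel")


def comparison_plan(
    np_years: Iterable[int] = (3, 4, 5), nw_max: int = 6
) -> list[tuple[int, int]]:
    """All (np, nw) cut-off pairs with np < nw <= nw_max."""
    return [(p, w) for p in sorted(np_years) for w in range(p + 1, nw_max + 1)]


def base_reference(ebv: np.ndarray, founder_mean_ebv: float) -> np.ndarray:
    """Express EBVs relative to the founder generation of their evaluation."""
    return np.asarray(ebv, dtype=float) - founder_mean_ebv


@dataclass
class LRInput:
    """Aligned vectors for one (np, nw) comparison of one focal group."""

    a_hat_p: np.ndarray
    a_hat_w: np.ndarray
    a_true: np.ndarray
    sigma2_a_star: float
    sigma2_a_base: float
    sigma_g: float

    def __post_init__(self) -> None:
        if not (len(self.a_hat_p) == len(self.a_hat_w) == len(self.a_true)):
            raise ValueError("vectors must be aligned on the same animals")
        if len(self.a_hat_p) < 3:
            raise ValueError("need at least 3 focal animals")


def _cov(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.cov(x, y, ddof=1)[0, 1])


def lr_estimates(inp: LRInput) -> dict[str, float]:
    """The six LR statistics computed from partial and whole EBVs."""
    ap, aw = inp.a_hat_p, inp.a_hat_w
    vp = np.var(ap, ddof=1)
    vw = np.var(aw, ddof=1)
    if vp <= 0 or vw <= 0:
        raise ValueError("zero variance in an EBV vector")
    c = _cov(ap, aw)
    acc2 = c / inp.sigma2_a_star
    return {
        "delta": (ap.mean() - aw.mean()) / inp.sigma_g,
        "b": c / vp,
        "rho": c / np.sqrt(vp * vw),
        "rho2": c / vw,
        "acc2": acc2,
        "rel": 1.0 - (inp.sigma2_a_star / inp.sigma2_a_base) * (1.0 - acc2),
    }


def lr_truths(inp: LRInput) -> dict[str, float]:
    """True counterparts, replacing the whole EBVs by the TBVs.

    The accuracy-ratio counterparts use acc = cor(EBV, TBV) within the
    focal group: rho_true = acc_p / acc_w and rho2_true = acc_p^2 / acc_w^2,
    matching the stated expectations of the estimators.
    """
    ap, aw, a = inp.a_hat_p, inp.a_hat_w, inp.a_true
    vp = np.var(ap, ddof=1)
    if vp <= 0:
        raise ValueError("zero variance in the partial EBV vector")
    acc_p = float(np.corrcoef(ap, a)[0, 1])
    acc_w = float(np.corrcoef(aw, a)[0, 1])
    acc2 = _cov(ap, a) / inp.sigma2_a_star
    return {
        "delta": (ap.mean() - a.mean()) / inp.sigma_g,
        "b": _cov(a, ap) / vp,
        "rho": acc_p / acc_w,
        "rho2": acc_p**2 / acc_w**2,
        "acc2": acc2,
        "rel": 1.0 - (inp.sigma2_a_star / inp.sigma2_a_base) * (1.0 - acc2),
    }


def balanced_average(values: Mapping[tuple[int, int], float]) -> float:
    """Two-stage mean over an unbalanced (np, nw) comparison design.

    Average each statistic over the nw comparisons of a given np, then
    average the per-np values with equal weight — "as if the design was
    balanced".
    """
    plan = sorted(values)
    np_years = sorted({p for p, _ in plan})
    stage1 = [np.mean([values[(p, w)] for q, w in plan if q == p]) for p in np_years]
    return float(np.mean(stage1))


def focal_groups(
    result: ScenarioResult, np_year: int, by_herd: bool
) -> dict[object, np.ndarray]:
    """Focal sires: bulls born in np_year that were selected into service,
    grouped by natal herd for the connectedness scenarios."""
    ids = result.selected_bulls[np_year]
    if not by_herd:
        return {"all": ids}
    herds = result.state.herd[ids - 1]
    return {int(h): ids[herds == h] for h in np.unique(herds)}


def comparison_input(
    result: ScenarioResult, ids: np.ndarray, np_year: int, nw_year: int
) -> LRInput:
    """Assemble base-referenced partial/whole EBVs and TBVs for one group."""
    state = result.state
    res_p = result.evaluations[np_year]
    res_w = result.evaluations[nw_year]
    founders_p = state.founder_ids()
    # founders exist from year 0, so the same set is present in both cuts
    fm_p = res_p.ebv[founders_p - 1].mean()
    fm_w = res_w.ebv[founders_p - 1].mean()
    base_tbv = state.tbv[state.base_ids - 1]
    return LRInput(
        a_hat_p=base_reference(res_p.ebv[ids - 1], fm_p),
        a_hat_w=base_reference(res_w.ebv[ids - 1], fm_w),
        a_true=state.tbv[ids - 1] - base_tbv.mean(),
        sigma2_a_star=float(np.var(state.tbv[ids - 1], ddof=1)),
        sigma2_a_base=float(np.var(base_tbv, ddof=1)),
        sigma_g=result.sigma_g,
    )


def scenario_lr_table(
    result: ScenarioResult,
    by_herd: bool | None = None,
    np_years: Iterable[int] = (3, 4, 5),
) -> pd.DataFrame:
    """Stage-1 (per-np) LR statistics for one replicate.

    Returns one row per (herd, np) with columns ``est_<stat>`` and
    ``true_<stat>``; the replicate-level balanced average of a statistic is
    the unweighted mean of its per-np values.
    """
    if by_herd is None:
        by_herd = result.cfg.fixed_effects == "mean_and_herd_year"
    nw_max = result.cfg.n_years
    rows = []
    for p in sorted(np_years):
        groups = focal_groups(result, p, by_herd)
        for herd, ids in groups.items():
            est_acc, true_acc = {s: [] for s in ESTIMATORS}, {s: [] for s in ESTIMATORS}
            for w in range(p + 1, nw_max + 1):
                inp = comparison_input(result, ids, p, w)
                for s, v in lr_estimates(inp).items():
                    est_acc[s].append(v)
                for s, v in lr_truths(inp).items():
                    true_acc[s].append(v)
            row = {"scenario": result.cfg.name, "herd": herd, "np": p}
            for s in ESTIMATORS:
                row[f"est_{s}"] = float(np.mean(est_acc[s]))
                row[f"true_{s}"] = float(np.mean(true_acc[s]))
            rows.append(row)
    return pd.DataFrame(rows)


def lr_from_files(
    partial_path,
    whole_path,
    tbv_path=None,
    sigma2_a_star: float | None = None,
    sigma2_a_base: float = 0.4,
    sigma_g: float | None = None,
) -> dict[str, float]:
    """LR statistics from two `id ebv` flat files (plus optional `id tbv`).

    Rows are aligned on the animal ids common to all files. When the focal
    TBV variance is not supplied it is taken from the TBV file; without a
    TBV file only the estimated block is returned.
    """
    def read(path, col):
        return pd.read_csv(path, sep=r"\s+", header=None, names=["id", col]
                           ).set_index("id")[col]

    ap = read(partial_path, "ebv_p")
    aw = read(whole_path, "ebv_w")
    ids = ap.index.intersection(aw.index)
    a = None
    if tbv_path is not None:
        tbv = read(tbv_path, "tbv")
        ids = ids.intersection(tbv.index)
        a = tbv.loc[ids].to_numpy()
    if sigma2_a_star is None:
        if a is None:
            raise ValueError("sigma2_a_star is required without a TBV file")
        sigma2_a_star = float(np.var(a, ddof=1))
    inp = LRInput(
        a_hat_p=ap.loc[ids].to_numpy(),
        a_hat_w=aw.loc[ids].to_numpy(),
        a_true=a if a is not None else ap.loc[ids].to_numpy(),
        sigma2_a_star=sigma2_a_star,
        sigma2_a_base=sigma2_a_base,
        sigma_g=sigma_g if sigma_g is not None else float(np.sqrt(sigma2_a_base)),
    )
    out = {f"est_{k}": v for k, v in lr_estimates(inp).items()}
    if a is not None:
        out.update({f"true_{k}": v for k, v in lr_truths(inp).items()})
    return out


def aggregate_replicates(tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Replicate summary in the layout of the result tables.

    For each (scenario, herd, estimator): the mean and SD across replicates
    of the balanced (two-stage) averages, and the Pearson correlation
    between estimated and true values pooled over the (np, replicate)
    cells.
    """
    frames = []
    for r, t in enumerate(tables):
        t = t.copy()
        t["replicate"] = r
        frames.append(t)
    if len(frames) < 2:
        raise ValueError("need at least 2 replicates to aggregate")
    df = pd.concat(frames, ignore_index=True)
    out = []
    for (scen, herd), g in df.groupby(["scenario", "herd"], sort=False):
        per_rep = g.groupby("replicate").mean(numeric_only=True)  # stage-2 mean
        for s in ESTIMATORS:
            est, tru = g[f"est_{s}"], g[f"true_{s}"]
            corr = float(np.corrcoef(est, tru)[0, 1]) if est.std() > 0 else np.nan
            out.append({
                "estimator": s,
                "scenario": scen,
                "herd": herd,
                "estimate_mean": float(per_rep[f"est_{s}"].mean()),
                "estimate_sd": float(per_rep[f"est_{s}"].std(ddof=1)),
                "true_mean": float(per_rep[f"true_{s}"].mean()),
                "true_sd": float(per_rep[f"true_{s}"].std(ddof=1)),
                "corr": corr,
            })
    return pd.DataFrame(out)
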