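"""Sensitivity diagnostics: heterogeneity, pleiotropy, outliers, influence.

* **Cochran's Q** — heterogeneity of per-SNP Wald ratios about a causal slope;
  drives the fixed vs multiplicative-random-effects choice in IVW.
* **Egger intercept test** — directional pleiotropy (intercept away from 0).
* **MR-PRESSO** — residual-resampling outlier machinery: a *global* test on
  the observed weighted residual sum of squares (RSSobs) against a simulated
  null, a per-SNP *outlier* test (Bonferroni-adjusted empirical p), and a
  *distortion* test on the percent change of the IVW slope after outlier
  removal.
* **Leave-one-out** — IVW re-estimated with each instrument removed in turn.
* Plot-data exports (scatter, funnel, forest, leave-one-out) as plain tables
  for external plotting tools.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import HarmonizedInstrument, usable
from .estimators import MREstimate, ivw, mr_egger, wald_ratio, to_odds_ratio, _arrays

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HeterogeneityResult:
    q: float
    df: int
    pval: float


@dataclass(frozen=True)
class PressoResult:
    rss_obs: float
    global_pval: float
    n_sim: int
    outlier_ids: dict[str, float]      # snp_id -> adjusted per-SNP p
    per_snp_pvals: dict[str, float]    # all SNPs, adjusted
    distortion_coefficient: float | None
    distortion_pval: float | None
    theta_all: float
    theta_without_outliers: float | None
    seed: int | None


@dataclass(frozen=True)
class LooRow:
    dropped_snp_id: str
    beta: float
    se: float
    pval: float


@dataclass(frozen=True)
class LooSummary:
    rows: list[LooRow]
    full_beta: float
    max_abs_deviation: float
    any_ci_excludes_full: bool


def cochrans_q(instruments: Sequence[HarmonizedInstrument],
               theta: float) -> HeterogeneityResult:
    """Cochran's Q of the per-SNP ratios about ``theta``.

    Q = Σ w_j (θ_j − θ)² with θ_j = β_Yj/β_Xj and w_j = β_Xj²/σ_Yj²;
    p from the upper tail of chi-square with k−1 degrees of freedom.
    """
    bx, _, by, sy = _arrays(instruments)
    k = len(bx)
    if k < 2:
        raise ValueError(f"Cochran's Q needs >= 2 instruments, got {k}")
    ratios = by / bx
    w = bx**2 / sy**2
    q = float(np.sum(w * (ratios - theta) ** 2))
    pval = float(max(stats.chi2.sf(q, k - 1), 5e-324))
    return HeterogeneityResult(q=q, df=k - 1, pval=pval)


def egger_intercept_test(egger_fit: MREstimate, alpha: float = 0.05):
    """The pleiotropy triple (intercept, SE, two-sided p) plus a flag at ``alpha``."""
    if egger_fit.method != "egger" or egger_fit.intercept is None:
        raise ValueError("egger_intercept_test needs a fitted MR-Egger estimate")
    flagged = egger_fit.intercept_p < alpha
    return (egger_fit.intercept, egger_fit.intercept_se,
            egger_fit.intercept_p, flagged)


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes θ_{−j}, vectorized."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx * bx)
    num = sxy - w * bx * by
    den = sxx - w * bx * bx
    return num / den


def _presso_rss(bx: np.ndarray, by: np.ndarray, w: np.ndarray):
    """Observed weighted squared leave-one-out residuals and their sum."""
    theta_loo = _loo_slopes(bx, by, w)
    resid = by - theta_loo * bx
    per_snp = w * resid**2
    return per_snp, float(per_snp.sum()), theta_loo


def mr_presso(
    instruments: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int | None = 0,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests.

    For each SNP j the leave-one-out IVW slope θ_{−j} gives a residual
    r_j = β_Yj − θ_{−j}·β_Xj; RSSobs = Σ_j w_j r_j² with w_j = 1/σ_Yj².
    The null distribution comes from ``n_sim`` parametric resamples
    β*_Xj ~ N(β_Xj, σ_Xj²), β*_Yj ~ N(θ_{−j}·β_Xj, σ_Yj²).  Empirical
    p-values use (1 + #exceedances)/(n_sim + 1); per-SNP p-values are
    Bonferroni-adjusted by k, and SNPs below ``outlier_alpha`` are outliers.
    The distortion coefficient is the percent change of the IVW slope when
    outliers are removed, with an empirical p from removing the same number
    of SNPs at random.
    """
    ok = sorted(usable(instruments), key=lambda i: i.snp_id)
    k = len(ok)
    if k < 4:
        raise ValueError(f"MR-PRESSO needs >= 4 instruments, got {k}")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    if n_sim < 1 / outlier_alpha * k:
        logger.warning(
            "n_sim=%d may be too small to resolve Bonferroni-adjusted "
            "per-SNP p-values below %g with k=%d", n_sim, outlier_alpha, k)

    ids = [i.snp_id for i in ok]
    bx, sx, by, sy = _arrays(ok)
    w = 1.0 / sy**2

    per_snp_obs, rss_obs, theta_loo = _presso_rss(bx, by, w)

    rng = np.random.default_rng(seed)
    # parametric resamples under the no-pleiotropy null
    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, k))
    # vectorized LOO residual statistic per simulated dataset
    sxy = np.sum(w * bx_sim * by_sim, axis=1, keepdims=True)
    sxx = np.sum(w * bx_sim * bx_sim, axis=1, keepdims=True)
    th_loo = (sxy - w * bx_sim * by_sim) / (sxx - w * bx_sim * bx_sim)
    per_snp_sim = w * (by_sim - th_loo * bx_sim) ** 2
    rss_sim = per_snp_sim.sum(axis=1)

    global_pval = (1 + int(np.sum(rss_sim >= rss_obs))) / (n_sim + 1)

    raw_p = (1 + np.sum(per_snp_sim >= per_snp_obs[None, :], axis=0)) / (n_sim + 1)
    adj_p = np.minimum(raw_p * k, 1.0)
    per_snp_pvals = dict(zip(ids, adj_p.tolist()))
    outlier_ids = {sid: p for sid, p in per_snp_pvals.items() if p < outlier_alpha}

    theta_all = ivw(ok, variant="fixed").beta
    theta_wo: float | None = None
    distortion = None
    distortion_p = None
    if outlier_ids and len(outlier_ids) < k - 1:
        keep = [i for i in ok if i.snp_id not in outlier_ids]
        theta_wo = ivw(keep, variant="fixed").beta
        if theta_wo != 0:
            distortion = 100.0 * (theta_all - theta_wo) / abs(theta_wo)
            # null: remove the same number of SNPs at random
            n_out = len(outlier_ids)
            coefs = np.empty(n_sim)
            wbxby = w * bx * by
            wbxbx = w * bx * bx
            for s in range(n_sim):
                drop = rng.choice(k, size=n_out, replace=False)
                mask = np.ones(k, dtype=bool)
                mask[drop] = False
                th = wbxby[mask].sum() / wbxbx[mask].sum()
                coefs[s] = 100.0 * (theta_all - th) / abs(th) if th != 0 else np.inf
            distortion_p = (1 + int(np.sum(np.abs(coefs) >= abs(distortion)))) \
                / (n_sim + 1)
    return PressoResult(
        rss_obs=rss_obs, global_pval=global_pval, n_sim=n_sim,
        outlier_ids=outlier_ids, per_snp_pvals=per_snp_pvals,
        distortion_coefficient=distortion, distortion_pval=distortion_p,
        theta_all=theta_all, theta_without_outliers=theta_wo, seed=seed,
    )


def leave_one_out(
    instruments: Sequence[HarmonizedInstrument],
    variant: str = "auto",
    level: float = 0.95,
) -> LooSummary:
    """IVW re-estimated with each instrument dropped in turn.

    The summary reports the largest absolute deviation of any leave-one-out
    slope from the full-set slope, and whether any row's CI excludes the
    full-set point estimate.
    """
    ok = sorted(usable(instruments), key=lambda i: i.snp_id)
    k = len(ok)
    if k < 2:
        raise ValueError(f"leave-one-out needs >= 2 instruments, got {k}")
    full = ivw(ok, variant=variant)
    z = stats.norm.ppf(0.5 + level / 2.0)
    rows: list[LooRow] = []
    any_excludes = False
    max_dev = 0.0
    for j in range(k):
        subset = ok[:j] + ok[j + 1:]
        if len(subset) == 1:
            est = wald_ratio(subset[0])
        else:
            est = ivw(subset, variant=variant)
        rows.append(LooRow(dropped_snp_id=ok[j].snp_id, beta=est.beta,
                           se=est.se, pval=est.pval))
        max_dev = max(max_dev, abs(est.beta - full.beta))
        if not (est.beta - z * est.se <= full.beta <= est.beta + z * est.se):
            any_excludes = True
    return LooSummary(rows=rows, full_beta=full.beta,
                      max_abs_deviation=max_dev, any_ci_excludes_full=any_excludes)


# ---------------------------------------------------------------------------
# Plot-data exports
# ---------------------------------------------------------------------------

def funnel_data(instruments: Sequence[HarmonizedInstrument]) -> pd.DataFrame:
    """Per-SNP Wald ratios and precisions, with IVW/Egger reference slopes.

    Returns a table with columns ``snp_id``, ``theta``, ``precision``
    (1/SE(θ_j)); the reference slopes are carried in ``DataFrame.attrs``
    (``ivw_slope``; ``egger_slope`` is None below 3 SNPs).
    """
    ok = sorted(usable(instruments), key=lambda i: i.snp_id)
    if not ok:
        raise ValueError("no usable instruments")
    theta = [i.beta_out / i.beta_exp for i in ok]
    prec = [abs(i.beta_exp) / i.se_out for i in ok]
    df = pd.DataFrame({"snp_id": [i.snp_id for i in ok],
                       "theta": theta, "precision": prec})
    if len(ok) == 1:
        df.attrs["ivw_slope"] = theta[0]
        df.attrs["egger_slope"] = None
    else:
        df.attrs["ivw_slope"] = ivw(ok).beta
        df.attrs["egger_slope"] = mr_egger(ok).beta if len(ok) >= 3 else None
    return df


def scatter_data(instruments: Sequence[HarmonizedInstrument]) -> pd.DataFrame:
    """Per-SNP (β_X, β_Y) with per-axis SEs, for effect-scatter plots."""
    ok = sorted(usable(instruments), key=lambda i: i.snp_id)
    return pd.DataFrame({
        "snp_id": [i.snp_id for i in ok],
        "beta_exp": [i.beta_exp for i in ok],
        "se_exp": [i.se_exp for i in ok],
        "beta_out": [i.beta_out for i in ok],
        "se_out": [i.se_out for i in ok],
    })


def forest_data(instruments: Sequence[HarmonizedInstrument],
                level: float = 0.95) -> pd.DataFrame:
    """Per-SNP Wald ratio with CI, for forest plots."""
    ok = sorted(usable(instruments), key=lambda i: i.snp_id)
    z = stats.norm.ppf(0.5 + level / 2.0)
    rows = []
    for i in ok:
        est = wald_ratio(i)
        rows.append((i.snp_id, est.beta, est.se,
                     est.beta - z * est.se, est.beta + z * est.se))
    return pd.DataFrame(rows, columns=["snp_id", "beta", "se", "ci_low", "ci_high"])


def loo_table(summary: LooSummary) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.dropped_snp_id, r.beta, r.se, r.pval) for r in summary.rows],
        columns=["dropped_snp_id", "beta", "se", "pval"],
    )
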