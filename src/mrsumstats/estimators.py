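"""Causal-effect estimators for two-sample MR on harmonized instruments.

Given per-SNP exposure effects β_Xj (SE σ_Xj) and outcome effects β_Yj
(SE σ_Yj) on a common effect allele, each SNP yields a Wald ratio
θ_j = β_Yj / β_Xj.  The estimators combine these under different validity
assumptions:

* **IVW** — inverse-variance-weighted meta-analysis of the ratios with
  first-order weights w_j = 1/σ_Yj²; equivalently the zero-intercept weighted
  regression of β_Y on β_X.  The multiplicative random-effects variant scales
  the fixed SE by max(1, sqrt(Q/(k−1))), Q being Cochran's Q about the IVW
  slope, and is selected automatically when the Q test is significant.
* **MR-Egger** — the same regression with a free intercept (after orienting
  every SNP to β_Xj ≥ 0); the intercept estimates average directional
  pleiotropy, the slope the causal effect.
* **Weighted median** — the weighted 50% quantile of the ratio distribution;
  consistent when ≥ 50% of the weight lies on valid instruments.  SE by
  bootstrap.
* **Weighted mode** — the argmax of a normal-kernel weighted density of the
  ratios; consistent when the largest cluster of SNPs is valid.  The kernel
  bandwidth cannot be estimated from data and is exposed as the tuning
  parameter ``phi``.  SE by bootstrap.

All estimators are hand-written closed forms (no regression library), carry
two-sided normal p-values, and report odds ratios with 95% CIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .harmonize import HarmonizedInstrument, usable

__all__ = [
    "MREstimate", "wald_ratio", "ivw", "mr_egger", "weighted_median",
    "weighted_mode", "to_odds_ratio", "all_estimates",
]

_P_FLOOR = 5e-324  # smallest subnormal; keeps p in (0, 1]


@dataclass(frozen=True)
class MREstimate:
    """One estimator's causal effect with normal-theory inference."""

    method: Literal["wald_ratio", "ivw", "egger", "weighted_median", "weighted_mode"]
    beta: float
    se: float
    pval: float
    k: int
    model_variant: Literal["fixed", "multiplicative_random", "n/a"] = "n/a"
    or_: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    # Egger only
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    # heterogeneity about the fit, populated by ivw/egger
    q_statistic: float | None = None


def _norm_p(z: float) -> float:
    return float(max(min(2.0 * stats.norm.sf(abs(z)), 1.0), _P_FLOOR))


def _arrays(instruments: Sequence[HarmonizedInstrument]):
    """Extract (βx, σx, βy, σy) from the estimation-eligible instruments,
    canonically sorted by snp_id so results are order-invariant."""
    ok = sorted(usable(instruments), key=lambda i: i.snp_id)
    bx = np.array([i.beta_exp for i in ok], dtype=float)
    sx = np.array([i.se_exp for i in ok], dtype=float)
    by = np.array([i.beta_out for i in ok], dtype=float)
    sy = np.array([i.se_out for i in ok], dtype=float)
    return bx, sx, by, sy


def to_odds_ratio(estimate: MREstimate, level: float = 0.95) -> MREstimate:
    """Fill the odds ratio exp(beta) and its normal-quantile CI."""
    if not (0 <= level < 1):
        raise ValueError("level must be in [0,1)")
    if estimate.se < 0:
        raise ValueError("se must be >= 0")
    z = stats.norm.ppf(0.5 + level / 2.0) if level > 0 else 0.0
    return replace(
        estimate,
        or_=math.exp(estimate.beta),
        ci_low=math.exp(estimate.beta - z * estimate.se),
        ci_high=math.exp(estimate.beta + z * estimate.se),
    )


def wald_ratio(instrument: HarmonizedInstrument) -> MREstimate:
    """Single-SNP causal estimate β_Y/β_X with first-order delta-method SE."""
    if instrument.beta_exp == 0:
        raise ValueError(f"{instrument.snp_id}: beta_exp is zero, ratio undefined")
    beta = instrument.beta_out / instrument.beta_exp
    se = instrument.se_out / abs(instrument.beta_exp)
    return to_odds_ratio(MREstimate(
        method="wald_ratio", beta=beta, se=se, pval=_norm_p(beta / se), k=1,
    ))


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray):
    """Zero-intercept WLS slope, fixed SE and Cochran's Q about the slope."""
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    if sxx == 0:
        raise ValueError("all exposure effects are zero")
    theta = float(np.sum(w * bx * by)) / sxx
    se_fixed = sxx ** -0.5
    q = float(np.sum(w * (by - theta * bx) ** 2))
    return theta, se_fixed, q


def ivw(
    instruments: Sequence[HarmonizedInstrument],
    variant: Literal["fixed", "multiplicative_random", "auto"] = "auto",
    het_alpha: float = 0.05,
) -> MREstimate:
    """Inverse-variance-weighted estimate across instruments.

    ``variant="auto"`` applies the multiplicative random-effects SE when the
    Cochran Q test about the IVW slope is significant at ``het_alpha``;
    the random-effects scale factor is floored at 1, so the random SE is never
    narrower than the fixed one.
    """
    bx, _, by, sy = _arrays(instruments)
    k = len(bx)
    if k == 0:
        raise ValueError("no usable instruments")
    theta, se_fixed, q = _ivw_core(bx, by, sy)

    scale = max(1.0, math.sqrt(q / (k - 1))) if k > 1 else 1.0
    if variant == "auto":
        q_p = float(stats.chi2.sf(q, k - 1)) if k > 1 else 1.0
        chosen = "multiplicative_random" if q_p < het_alpha else "fixed"
    else:
        chosen = variant
    se = se_fixed * (scale if chosen == "multiplicative_random" else 1.0)
    return to_odds_ratio(MREstimate(
        method="ivw", beta=theta, se=se, pval=_norm_p(theta / se), k=k,
        model_variant=chosen, q_statistic=q,
    ))


def mr_egger(instruments: Sequence[HarmonizedInstrument]) -> MREstimate:
    """MR-Egger regression: weighted fit of β_Y on β_X with a free intercept.

    Each SNP is first oriented so β_Xj ≥ 0 (the fit is otherwise not
    invariant to allele relabeling).  SEs carry the multiplicative scaling
    max(1, sqrt(RSS/(k−2))); the intercept triple is the pleiotropy test.
    """
    bx, _, by, sy = _arrays(instruments)
    k = len(bx)
    if k < 3:
        raise ValueError(f"MR-Egger needs >= 3 instruments, got {k}")
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip

    w = 1.0 / sy**2
    sw = float(np.sum(w))
    sx = float(np.sum(w * bx))
    sxx = float(np.sum(w * bx * bx))
    sy_ = float(np.sum(w * by))
    sxy = float(np.sum(w * bx * by))
    det = sw * sxx - sx * sx
    if det <= 0 or np.allclose(bx, bx[0]):
        raise ValueError("degenerate design: exposure effects collinear with intercept")
    slope = (sw * sxy - sx * sy_) / det
    intercept = (sxx * sy_ - sx * sxy) / det
    resid = by - intercept - slope * bx
    rss = float(np.sum(w * resid * resid))
    scale = max(1.0, math.sqrt(rss / (k - 2)))
    se_slope = math.sqrt(sw / det) * scale
    se_int = math.sqrt(sxx / det) * scale
    return to_odds_ratio(MREstimate(
        method="egger", beta=slope, se=se_slope, pval=_norm_p(slope / se_slope),
        k=k, intercept=intercept, intercept_se=se_int,
        intercept_p=_norm_p(intercept / se_int), q_statistic=rss,
    ))


def _weighted_median_point(theta: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted 50% quantile; each SNP's percentile is its
    cumulative weight minus half its own weight (standardized)."""
    order = np.argsort(theta)
    th = theta[order]
    w = weights[order] / weights.sum()
    perc = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, perc, th))


def weighted_median(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int | None = 0,
) -> MREstimate:
    """Weighted-median causal estimate with bootstrap SE.

    Weights are β_Xj²/σ_Yj², the first-order inverse ratio variances; the
    estimate is robust to up to 50% of the weight lying on invalid
    instruments.
    """
    bx, _, by, sy = _arrays(instruments)
    k = len(bx)
    if k < 3:
        raise ValueError(f"weighted median needs >= 3 instruments, got {k}")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    theta = by / bx
    w = bx**2 / sy**2
    beta = _weighted_median_point(theta, w)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, k, size=k)
        boots[b] = _weighted_median_point(theta[idx], w[idx])
    se = float(np.std(boots, ddof=1))
    return to_odds_ratio(MREstimate(
        method="weighted_median", beta=beta, se=se,
        pval=_norm_p(beta / se) if se > 0 else _P_FLOOR, k=k,
    ))


def _mode_bandwidth(theta: np.ndarray, weights: np.ndarray, phi: float) -> float:
    """phi × a robust default: 1.4826·(weighted MAD of the ratios)·k^(−1/5)."""
    center = _weighted_median_point(theta, weights)
    mad = _weighted_median_point(np.abs(theta - center), weights)
    return phi * 1.4826 * mad * len(theta) ** (-1 / 5)


def _weighted_mode_point(theta: np.ndarray, weights: np.ndarray,
                         phi: float, grid_size: int = 512) -> float:
    h = _mode_bandwidth(theta, weights, phi)
    if h <= 0 or not np.isfinite(h):
        # degenerate spread (e.g. all ratios identical): the mode is exact
        return float(_weighted_median_point(theta, weights))
    lo, hi = theta.min() - 3 * h, theta.max() + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    z = (grid[:, None] - theta[None, :]) / h
    dens = np.exp(-0.5 * z * z) @ weights
    return float(grid[int(np.argmax(dens))])


def weighted_mode(
    instruments: Sequence[HarmonizedInstrument],
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = 0,
    grid_size: int = 512,
) -> MREstimate:
    """Weighted-mode causal estimate (largest-cluster consistency).

    Ratios are smoothed with a normal kernel whose bandwidth is
    ``bandwidth_factor`` (φ) times a weighted-MAD default; the estimate is the
    density argmax on a grid.  SE by bootstrap under ``seed``.
    """
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be > 0")
    bx, _, by, sy = _arrays(instruments)
    k = len(bx)
    if k < 3:
        raise ValueError(f"weighted mode needs >= 3 instruments, got {k}")
    theta = by / bx
    w = bx**2 / sy**2
    beta = _weighted_mode_point(theta, w, bandwidth_factor, grid_size)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, k, size=k)
        boots[b] = _weighted_mode_point(theta[idx], w[idx], bandwidth_factor,
                                        grid_size)
    se = float(np.std(boots, ddof=1))
    return to_odds_ratio(MREstimate(
        method="weighted_mode", beta=beta, se=se,
        pval=_norm_p(beta / se) if se > 0 else _P_FLOOR, k=k,
    ))


def all_estimates(
    instruments: Sequence[HarmonizedInstrument],
    ivw_variant: Literal["fixed", "multiplicative_random", "auto"] = "auto",
    n_boot: int = 1000,
    bandwidth_factor: float = 1.0,
    median_seed: int | None = 0,
    mode_seed: int | None = 1,
) -> list[MREstimate]:
    """Run IVW, MR-Egger, weighted median and weighted mode on one instrument set."""
    return [
        ivw(instruments, variant=ivw_variant),
        mr_egger(instruments),
        weighted_median(instruments, n_boot=n_boot, seed=median_seed),
        weighted_mode(instruments, bandwidth_factor=bandwidth_factor,
                      n_boot=n_boot, seed=mode_seed),
    ]
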