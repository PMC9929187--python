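"""Instrument selection and strength diagnostics.

Selection follows the standard two-sample MR recipe: genome-wide significance
(P < 5e-8), LD clumping (greedy, r² > 0.001 within 10,000 kb), a minor-allele
frequency floor (MAF > 5%), and file-driven exclusion of confounder-associated
or outlier SNPs.  Strength is summarized by the per-SNP variance explained

    R²_j = 2 · EAF_j · (1 − EAF_j) · β_j²

(valid as an R² when effects are on a standardized-trait scale) and the
F-statistic

    F = ((N − K − 1) / K) · (R² / (1 − R²)),

with K = 1 for single-SNP F.  Causal direction is checked with a Steiger-type
test comparing the variance explained in the exposure versus the outcome.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TypeVar

from scipy import stats

from .gwas_io import GwasRecord, LdTable
from .harmonize import HarmonizedInstrument

logger = logging.getLogger(__name__)

R = TypeVar("R", GwasRecord, HarmonizedInstrument)


@dataclass(frozen=True)
class SelectionConfig:
    """Instrument-selection thresholds (defaults: the conventional GWAS ones)."""

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    maf_min: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0,1)")
        if not (0 <= self.clump_r2 <= 1):
            raise ValueError("clump_r2 must be in [0,1]")
        if not self.clump_window_kb > 0:
            raise ValueError("clump_window_kb must be > 0")
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")


@dataclass(frozen=True)
class SteigerResult:
    direction: bool | None  # True: exposure->outcome supported; None: undefined
    pval: float | None
    r2_exposure: float
    r2_outcome: float
    n_used: int


@dataclass(frozen=True)
class InstrumentDiagnostics:
    """Aggregate and per-SNP instrument-strength summary."""

    per_snp_r2: dict[str, float]
    total_r2: float
    k: int
    n: float
    f_statistic: float
    per_snp_f: dict[str, float]
    steiger: SteigerResult | None = None


def _pval(rec) -> float:
    return rec.pval if isinstance(rec, GwasRecord) else rec.pval_exp


def _eaf(rec) -> float | None:
    return rec.eaf if isinstance(rec, GwasRecord) else rec.eaf_exp


def select_significant(records: Sequence[R], p_threshold: float = 5e-8) -> list[R]:
    """Records with (exposure) p-value strictly below the threshold, in order."""
    out = [r for r in records if _pval(r) < p_threshold]
    if not out:
        logger.warning("no records pass p < %g", p_threshold)
    return out


def filter_maf(records: Sequence[R], maf_min: float = 0.05) -> list[R]:
    """Records with minor-allele frequency strictly above the floor.

    Records with missing frequency are retained with a warning.
    """
    out: list[R] = []
    for r in records:
        eaf = _eaf(r)
        if eaf is None:
            logger.warning("%s: missing eaf, retained through MAF filter", r.snp_id)
            out.append(r)
        elif min(eaf, 1.0 - eaf) > maf_min:
            out.append(r)
    return out


def ld_clump(records: Sequence[R], ld: LdTable,
             config: SelectionConfig | None = None) -> list[R]:
    """Greedy LD clumping: keep index SNPs, discard correlated neighbours.

    Repeatedly takes the unclaimed record with the smallest p-value (ties by
    position, then identifier) as an index SNP, and discards every unclaimed
    record on the same chromosome within ``clump_window_kb`` whose r² with the
    index exceeds ``clump_r2``.  Pairs absent from the LD table are treated as
    r² = 0.
    """
    cfg = config or SelectionConfig()
    window_bp = cfg.clump_window_kb * 1000.0

    def sort_key(r):
        return (_pval(r), r.pos if r.pos is not None else 0, r.snp_id)

    remaining = sorted(records, key=sort_key)
    kept: list[R] = []
    claimed: set[str] = set()
    for idx in remaining:
        if idx.snp_id in claimed:
            continue
        kept.append(idx)
        claimed.add(idx.snp_id)
        for other in remaining:
            if other.snp_id in claimed:
                continue
            if idx.chrom is None or other.chrom is None or other.chrom != idx.chrom:
                continue
            if idx.pos is None or other.pos is None:
                continue
            if abs(other.pos - idx.pos) <= window_bp and \
                    ld.r2(idx.snp_id, other.snp_id) > cfg.clump_r2:
                claimed.add(other.snp_id)
    # preserve original input order among the kept index SNPs
    kept_ids = {r.snp_id for r in kept}
    return [r for r in records if r.snp_id in kept_ids]


def variance_explained(eaf: float | None, beta: float) -> float | None:
    """Per-SNP variance explained, 2·eaf·(1−eaf)·beta².

    Assumes a standardized-trait beta; returns ``None`` (with a warning) when
    the frequency is missing.
    """
    if eaf is None:
        logger.warning("variance_explained: missing eaf, result undefined")
        return None
    if not (0 <= eaf <= 1):
        raise ValueError(f"eaf must be in [0,1], got {eaf}")
    return 2.0 * eaf * (1.0 - eaf) * beta * beta


def f_statistic(n: float, k: int, r2_total: float) -> float:
    """Instrument-strength F, ((n − k − 1)/k) · (r2/(1 − r2)).

    ``k`` is the instrument count (1 for a single-SNP F); F < 10 is the
    conventional weak-instrument flag.
    """
    if not (0 <= r2_total < 1):
        raise ValueError(f"r2_total must be in [0,1), got {r2_total}")
    if not n > k + 1:
        raise ValueError(f"need n > k + 1 (n={n}, k={k})")
    if k < 1:
        raise ValueError("k must be >= 1")
    return ((n - k - 1) / k) * (r2_total / (1.0 - r2_total))


def steiger_test(instruments: Sequence[HarmonizedInstrument]) -> SteigerResult:
    """Directionality check: does the instrument set explain more variance in
    the exposure than in the outcome?

    Total R² is accumulated on each side from 2·eaf·(1−eaf)·β²; the two
    implied correlation magnitudes (square roots of the totals) are compared
    with a Fisher-z test using sampling variance 1/(n_exp−3) + 1/(n_out−3)
    with the median sample size of the SNPs used.  SNPs missing a frequency or
    sample size on either side are skipped with a warning.
    """
    r2_exp = r2_out = 0.0
    n_exps: list[float] = []
    n_outs: list[float] = []
    used = 0
    for ins in instruments:
        if (ins.eaf_exp is None or ins.eaf_out is None
                or ins.n_exp is None or ins.n_out is None):
            logger.warning("%s: missing eaf/n, skipped in Steiger test", ins.snp_id)
            continue
        r2_exp += 2.0 * ins.eaf_exp * (1 - ins.eaf_exp) * ins.beta_exp ** 2
        r2_out += 2.0 * ins.eaf_out * (1 - ins.eaf_out) * ins.beta_out ** 2
        n_exps.append(ins.n_exp)
        n_outs.append(ins.n_out)
        used += 1
    if used < 1:
        logger.warning("Steiger test undefined: no usable SNPs")
        return SteigerResult(None, None, r2_exp, r2_out, 0)
    r2_exp = min(r2_exp, 1.0 - 1e-12)
    r2_out = min(r2_out, 1.0 - 1e-12)
    r_exp, r_out = math.sqrt(r2_exp), math.sqrt(r2_out)
    n_exp = sorted(n_exps)[len(n_exps) // 2]
    n_out = sorted(n_outs)[len(n_outs) // 2]
    var = 1.0 / (n_exp - 3.0) + 1.0 / (n_out - 3.0)
    z = (math.atanh(r_exp) - math.atanh(r_out)) / math.sqrt(var)
    pval = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return SteigerResult(direction=r2_exp > r2_out, pval=max(pval, 5e-324),
                         r2_exposure=r2_exp, r2_outcome=r2_out, n_used=used)


def apply_exclusions(
    instruments: Sequence[HarmonizedInstrument],
    confounder_ids: Iterable[str] = (),
    presso_outlier_ids: Iterable[str] = (),
) -> tuple[list[HarmonizedInstrument], dict[str, int]]:
    """Flag instruments on exclusion lists; returns (flagged set, counts).

    Confounder-associated SNPs gain ``excluded_confounder`` and MR-PRESSO
    outliers gain ``excluded_presso_outlier``; ids absent from the collection
    are warned about and ignored.
    """
    conf = set(confounder_ids)
    pres = set(presso_outlier_ids)
    present = {i.snp_id for i in instruments}
    for missing in sorted((conf | pres) - present):
        logger.warning("exclusion id %s not among instruments; ignored", missing)

    out: list[HarmonizedInstrument] = []
    counts = {"excluded_confounder": 0, "excluded_presso_outlier": 0}
    for ins in instruments:
        new_flags = []
        if ins.snp_id in conf:
            new_flags.append("excluded_confounder")
            counts["excluded_confounder"] += 1
        if ins.snp_id in pres:
            new_flags.append("excluded_presso_outlier")
            counts["excluded_presso_outlier"] += 1
        out.append(ins.with_flags(*new_flags) if new_flags else ins)
    return out, counts


def instrument_diagnostics(
    instruments: Sequence[HarmonizedInstrument],
    n_exposure: float | None = None,
    run_steiger: bool = True,
) -> InstrumentDiagnostics:
    """Per-SNP and aggregate R²/F plus the Steiger direction for an instrument set.

    ``n_exposure`` defaults to the median exposure sample size carried by the
    instruments.  SNPs with missing exposure frequency contribute no R² term
    (warned).
    """
    per_r2: dict[str, float] = {}
    for ins in instruments:
        r2 = variance_explained(ins.eaf_exp, ins.beta_exp)
        if r2 is not None:
            per_r2[ins.snp_id] = r2
    total_r2 = sum(per_r2.values())
    k = len(instruments)
    if n_exposure is None:
        ns = sorted(i.n_exp for i in instruments if i.n_exp is not None)
        if not ns:
            raise ValueError("no exposure sample size available; pass n_exposure")
        n_exposure = ns[len(ns) // 2]
    agg_f = f_statistic(n_exposure, k, min(total_r2, 1 - 1e-12)) if k else 0.0
    per_f = {sid: f_statistic(n_exposure, 1, min(r2, 1 - 1e-12))
             for sid, r2 in per_r2.items()}
    steiger = steiger_test(instruments) if run_steiger else None
    return InstrumentDiagnostics(
        per_snp_r2=per_r2, total_r2=total_r2, k=k, n=n_exposure,
        f_statistic=agg_f, per_snp_f=per_f, steiger=steiger,
    )
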