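"""End-to-end two-sample MR pipeline.

Stage order: read → harmonize → significance filter → MAF filter → LD clump
→ confounder exclusions → MR-PRESSO pre-filter → instrument diagnostics
(R², F, Steiger) → four estimators (IVW auto, MR-Egger, weighted median,
weighted mode) → sensitivity suite (Cochran's Q, Egger intercept,
leave-one-out, plot data) → Bonferroni verdicts.

Optional resources (LD table, exclusion list) may be absent; the affected
stage is skipped with a loud log line, never a silent pass.  Every stage
records its input and output SNP counts in an accounting ledger.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import estimators as est
from . import gwas_io
from . import instruments as instr
from . import sensitivity as sens
from .harmonize import HarmonizedInstrument
from .harmonize import harmonize as _harmonize
from .harmonize import usable as _usable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one MR run needs; see the CLI for the YAML mirror."""

    exposure_path: str
    outcome_path: str
    exposure_columns: gwas_io.ColumnMap = field(default_factory=gwas_io.ColumnMap)
    outcome_columns: gwas_io.ColumnMap = field(default_factory=gwas_io.ColumnMap)
    selection: instr.SelectionConfig = field(default_factory=instr.SelectionConfig)
    exclusion_path: str | None = None
    ld_path: str | None = None
    palindrome_eaf_window: float = 0.08
    ivw_variant: str = "auto"
    n_boot: int = 1000
    bandwidth_factor: float = 1.0
    presso_enabled: bool = True
    presso_n_sim: int = 1000
    bonferroni_n: int = 4
    seed: int | None = 0
    median_seed: int | None = None
    mode_seed: int | None = None
    presso_seed: int | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.bonferroni_n < 1:
            raise ValueError("bonferroni_n must be >= 1")

    @property
    def bonferroni_alpha(self) -> float:
        return 0.05 / self.bonferroni_n

    def derived_seeds(self) -> tuple[int | None, int | None, int | None]:
        """(median, mode, presso) seeds; unset entries derive from the master."""
        if self.seed is None:
            return self.median_seed, self.mode_seed, self.presso_seed
        ss = np.random.SeedSequence(self.seed)
        derived = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
        return (self.median_seed if self.median_seed is not None else derived[0],
                self.mode_seed if self.mode_seed is not None else derived[1],
                self.presso_seed if self.presso_seed is not None else derived[2])


@dataclass(frozen=True)
class LedgerEntry:
    stage: str
    n_in: int
    n_out: int
    note: str = ""


@dataclass(frozen=True)
class SensitivityReport:
    heterogeneity: sens.HeterogeneityResult | None
    egger_intercept: tuple | None           # (intercept, se, p, flagged)
    presso: sens.PressoResult | None
    leave_one_out: sens.LooSummary | None


@dataclass(frozen=True)
class MRReport:
    estimates: list[est.MREstimate]
    diagnostics: instr.InstrumentDiagnostics | None
    sensitivity: SensitivityReport
    ledger: list[LedgerEntry]
    bonferroni_alpha: float
    verdicts: dict[str, bool]
    instruments: list[HarmonizedInstrument]
    audit: list[str]

    def estimates_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.estimates:
            rows.append((e.method, e.model_variant, e.k, e.beta, e.se, e.pval,
                         e.or_, e.ci_low, e.ci_high))
        return pd.DataFrame(rows, columns=[
            "method", "variant", "k", "beta", "se", "pval",
            "or", "ci_low", "ci_high"])

    def ledger_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(l.stage, l.n_in, l.n_out, l.note) for l in self.ledger],
            columns=["stage", "n_in", "n_out", "note"])

    def to_text(self) -> str:
        lines = ["# Two-sample MR report", "", "## SNP accounting"]
        for l in self.ledger:
            lines.append(f"  {l.stage:<24} {l.n_in:>6} -> {l.n_out:<6} {l.note}")
        lines += ["", "## Estimates (OR with 95% CI)"]
        for e in self.estimates:
            verdict = "significant" if self.verdicts.get(e.method) else "ns"
            lines.append(
                f"  {e.method:<16} variant={e.model_variant:<22} k={e.k:<5} "
                f"beta={e.beta:+.6g} se={e.se:.6g} p={e.pval:.4g} "
                f"OR={e.or_:.4f} [{e.ci_low:.4f}, {e.ci_high:.4f}]  {verdict}")
        lines += ["", f"Bonferroni-corrected alpha: {self.bonferroni_alpha}"]
        d = self.diagnostics
        if d is not None:
            lines += ["", "## Instrument strength",
                      f"  k={d.k}  total R2={d.total_r2:.6g}  F={d.f_statistic:.4f}"
                      f"  (N={d.n:g})"]
            if d.steiger is not None and d.steiger.direction is not None:
                lines.append(
                    f"  Steiger: exposure->outcome supported={d.steiger.direction} "
                    f"(R2_exp={d.steiger.r2_exposure:.4g}, "
                    f"R2_out={d.steiger.r2_outcome:.4g}, p={d.steiger.pval:.3g})")
        s = self.sensitivity
        lines += ["", "## Sensitivity"]
        if s.heterogeneity is not None:
            h = s.heterogeneity
            lines.append(f"  Cochran's Q = {h.q:.4f} (df={h.df}, p={h.pval:.4g})")
        if s.egger_intercept is not None:
            i0, ise, ip, flagged = s.egger_intercept
            lines.append(f"  Egger intercept = {i0:.4g} (se={ise:.4g}, p={ip:.4g})"
                         f"{'  [pleiotropy flagged]' if flagged else ''}")
        if s.presso is not None:
            p = s.presso
            lines.append(f"  MR-PRESSO RSSobs = {p.rss_obs:.4f}, "
                         f"global p = {p.global_pval:.4g}, "
                         f"outliers = {sorted(p.outlier_ids) or 'none'}")
            if p.distortion_coefficient is not None:
                lines.append(f"  distortion = {p.distortion_coefficient:.3f}% "
                             f"(p = {p.distortion_pval:.4g})")
        if s.leave_one_out is not None:
            lines.append(f"  leave-one-out: max |Δbeta| = "
                         f"{s.leave_one_out.max_abs_deviation:.4g}; any CI excludes "
                         f"full estimate: {s.leave_one_out.any_ci_excludes_full}")
        return "\n".join(lines) + "\n"

    def write(self, out_dir: str | Path) -> None:
        """Serialize report, estimate/ledger tables and plot data as TSV/text."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.txt").write_text(self.to_text())
        self.estimates_frame().to_csv(out / "estimates.tsv", sep="\t", index=False)
        self.ledger_frame().to_csv(out / "ledger.tsv", sep="\t", index=False)
        (out / "audit.log").write_text("\n".join(self.audit) + "\n")
        ok = _usable(self.instruments)
        if ok:
            gwas_io.write_instrument_table(self.instruments,
                                           out / "instruments.tsv")
            sens.scatter_data(ok).to_csv(out / "scatter.tsv", sep="\t", index=False)
            fd = sens.funnel_data(ok)
            fd.to_csv(out / "funnel.tsv", sep="\t", index=False)
            sens.forest_data(ok).to_csv(out / "forest.tsv", sep="\t", index=False)
        if self.sensitivity.leave_one_out is not None:
            sens.loo_table(self.sensitivity.leave_one_out).to_csv(
                out / "leave_one_out.tsv", sep="\t", index=False)


def run_mr(config: PipelineConfig) -> MRReport:
    """Execute the full two-sample MR analysis described by ``config``."""
    cfg = config
    ledger: list[LedgerEntry] = []
    audit: list[str] = []

    def stage(name: str, n_in: int, n_out: int, note: str = "") -> None:
        ledger.append(LedgerEntry(name, n_in, n_out, note))
        logger.info("stage %-22s %6d -> %-6d %s", name, n_in, n_out, note)

    exposure = gwas_io.read_summary_stats(cfg.exposure_path, cfg.exposure_columns)
    outcome = gwas_io.read_summary_stats(cfg.outcome_path, cfg.outcome_columns)
    stage("read", max(len(exposure), len(outcome)),
          min(len(exposure), len(outcome)),
          f"exposure={len(exposure)} outcome={len(outcome)}")

    harmonized = _harmonize(exposure, outcome,
                                palindrome_eaf_window=cfg.palindrome_eaf_window,
                                audit=audit)
    usable = _usable(harmonized)
    stage("harmonize", min(len(exposure), len(outcome)), len(usable),
          f"{len(harmonized) - len(usable)} flagged")

    sel = instr.select_significant(usable, cfg.selection.p_threshold)
    stage("significance", len(usable), len(sel),
          f"p < {cfg.selection.p_threshold:g}")

    maf = instr.filter_maf(sel, cfg.selection.maf_min)
    stage("maf", len(sel), len(maf), f"MAF > {cfg.selection.maf_min:g}")

    if cfg.ld_path is not None:
        ld = gwas_io.read_ld_table(cfg.ld_path)
        clumped = instr.ld_clump(maf, ld, cfg.selection)
        stage("ld_clump", len(maf), len(clumped),
              f"r2 > {cfg.selection.clump_r2:g} within "
              f"{cfg.selection.clump_window_kb:g} kb")
    else:
        logger.warning("no LD table supplied: clumping stage SKIPPED")
        clumped = maf
        stage("ld_clump", len(maf), len(clumped), "skipped (no LD table)")

    if cfg.exclusion_path is not None:
        excl_ids = gwas_io.read_exclusion_list(cfg.exclusion_path)
        flagged, counts = instr.apply_exclusions(clumped, confounder_ids=excl_ids)
        kept = _usable(flagged)
        stage("confounder_exclusion", len(clumped), len(kept),
              f"{counts['excluded_confounder']} excluded")
    else:
        logger.warning("no exclusion list supplied: confounder screen SKIPPED")
        kept = list(clumped)
        stage("confounder_exclusion", len(clumped), len(kept),
              "skipped (no exclusion list)")

    median_seed, mode_seed, presso_seed = cfg.derived_seeds()

    presso_result = None
    if cfg.presso_enabled and len(kept) >= 4:
        presso_result = sens.mr_presso(kept, n_sim=cfg.presso_n_sim,
                                       seed=presso_seed)
        if presso_result.outlier_ids:
            flagged, _ = instr.apply_exclusions(
                kept, presso_outlier_ids=set(presso_result.outlier_ids))
            kept = _usable(flagged)
        stage("presso_prefilter", len(kept) + len(presso_result.outlier_ids),
              len(kept), f"{len(presso_result.outlier_ids)} outlier(s) removed")
    else:
        note = "disabled" if not cfg.presso_enabled else "skipped (k < 4)"
        stage("presso_prefilter", len(kept), len(kept), note)

    if not kept:
        raise ValueError("zero analysable instruments after filtering")

    diagnostics = None
    try:
        diagnostics = instr.instrument_diagnostics(kept)
    except ValueError as exc:
        logger.warning("instrument diagnostics unavailable: %s", exc)

    estimates: list[est.MREstimate] = []
    k = len(kept)
    if k == 1:
        estimates.append(est.wald_ratio(kept[0]))
    if k >= 1:
        estimates.append(est.ivw(kept, variant=cfg.ivw_variant))
    if k >= 3:
        estimates.append(est.mr_egger(kept))
        estimates.append(est.weighted_median(kept, n_boot=cfg.n_boot,
                                             seed=median_seed))
        estimates.append(est.weighted_mode(
            kept, bandwidth_factor=cfg.bandwidth_factor,
            n_boot=cfg.n_boot, seed=mode_seed))
    else:
        logger.warning("k = %d < 3: Egger/median/mode not estimable", k)

    ivw_est = next(e for e in estimates if e.method == "ivw")
    het = sens.cochrans_q(kept, ivw_est.beta) if k >= 2 else None
    egger_fit = next((e for e in estimates if e.method == "egger"), None)
    egger_triple = sens.egger_intercept_test(egger_fit) if egger_fit else None
    loo = sens.leave_one_out(kept, variant=cfg.ivw_variant) if k >= 2 else None

    verdicts = {e.method: e.pval < cfg.bonferroni_alpha for e in estimates}

    report = MRReport(
        estimates=estimates,
        diagnostics=diagnostics,
        sensitivity=SensitivityReport(
            heterogeneity=het, egger_intercept=egger_triple,
            presso=presso_result, leave_one_out=loo),
        ledger=ledger,
        bonferroni_alpha=cfg.bonferroni_alpha,
        verdicts=verdicts,
        instruments=kept,
        audit=audit,
    )
    if cfg.out_dir is not None:
        report.write(cfg.out_dir)
    return report


def reverse_direction(config: PipelineConfig) -> PipelineConfig:
    """Swap exposure and outcome roles (for the reverse-direction analysis)."""
    return replace(
        config,
        exposure_path=config.outcome_path,
        outcome_path=config.exposure_path,
        exposure_columns=config.outcome_columns,
        outcome_columns=config.exposure_columns,
    )
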