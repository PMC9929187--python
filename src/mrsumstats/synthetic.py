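"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generative model matches the assumptions behind the estimators: for SNP j
with effect-allele frequency p_j,

    γ_j  ~ N(0, gamma_sd²)                 per-allele effect on the exposure
    α_j  =  0                               for valid instruments
    α_j  =  sign(γ_j)·δ_j, δ_j ~ N(mu, τ²)  for invalid (pleiotropic) ones
    β_Yj = θ·γ_j + α_j                      true outcome effect

Directional pleiotropy (mu ≠ 0) is defined relative to the exposure-raising
allele — the sign(γ_j) factor — so that "directional" means what the
estimator contrasts assume: all invalid SNPs push the apparent ratio the same
way.  (Allele labels are arbitrary; without the orientation a symmetric γ law
would scramble the direction.)

Sampling noise follows a GWAS of n individuals: se_j = sqrt(v/(2·n·p_j·(1−p_j)))
where v is the phenotypic variance (1 for a standardized trait; c·(1−c) for a
0/1 case-control trait with case fraction c), and observed effects are drawn
β̂_Xj ~ N(γ_j, se_Xj²), β̂_Yj ~ N(β_Yj, se_Yj²).  With the exposure
standardized, 2·p(1−p)·γ² is exactly the per-SNP variance explained, so the
R²/F diagnostics are testable against ground truth.

Exposure and outcome samples are non-overlapping by construction.  Planted
gross outliers displace β̂_Yj by ``outlier_offset`` outcome SEs.  Optional LD
blocks and null background SNPs exercise clumping and significance selection.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import stats

from .gwas_io import (ColumnMap, GwasRecord, LdTable, write_ld_table,
                      write_summary_stats)

# non-palindromic biallelic pairs only; palindrome handling is tested on
# hand-built records, not on simulated panels
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the scale of the UK Biobank GWAS pair this package was
    designed around: exposure n = 454,874 and outcome n = 462,933.
    ``var_out`` is the outcome phenotypic variance (1 = standardized trait;
    use c·(1−c) to emulate a 0/1 case-control GWAS with case fraction c).
    """

    n_snps: int = 100
    n_exp: int = 454_874
    n_out: int = 462_933
    theta: float = 0.0
    gamma_sd: float = 0.02
    pleiotropy: str = "none"           # none | balanced | directional
    mu: float = 0.0                    # mean pleiotropic effect (directional)
    tau: float = 0.0                   # pleiotropy spread
    frac_invalid: float = 0.0
    inside_violation: bool = False     # correlate |alpha| with instrument strength
    n_outliers: int = 0
    outlier_offset: float = 10.0       # displacement in outcome SEs
    maf_range: tuple[float, float] = (0.05, 0.5)
    var_out: float = 1.0
    n_null_snps: int = 0
    ld_block_size: int = 1
    ld_r2: float = 0.0
    seed: int | None = 0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_invalid <= 1):
            raise ValueError("frac_invalid must be in [0,1]")
        if not (self.n_exp > 3 and self.n_out > 3):
            raise ValueError("sample sizes must exceed 3")
        lo, hi = self.maf_range
        if not (0 < lo < hi < 1):
            raise ValueError(f"degenerate maf_range {self.maf_range}")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy regime {self.pleiotropy!r}")
        if not self.var_out > 0:
            raise ValueError("var_out must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    theta: float
    gamma: dict[str, float]
    alpha: dict[str, float]
    outlier_ids: frozenset[str]
    invalid_ids: frozenset[str]


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, 5e-324, 1.0)


def _se(n: int, eaf: np.ndarray, var: float = 1.0) -> np.ndarray:
    return np.sqrt(var / (2.0 * n * eaf * (1.0 - eaf)))


def simulate_two_sample(
    config: SimulationConfig,
    gamma_override: np.ndarray | None = None,
) -> tuple[list[GwasRecord], list[GwasRecord], LdTable, GroundTruth]:
    """Draw one pair of exposure/outcome summary-statistics tables.

    Returns (exposure records, outcome records, LD table, ground truth);
    byte-for-byte reproducible from ``config.seed``.  ``gamma_override``
    replaces the Normal(0, gamma_sd²) exposure-effect draw (used by the
    fixture generator to emulate genome-wide-significant hit panels).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_snps + cfg.n_null_snps

    eaf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    if cfg.gamma_sd == 0 and cfg.theta != 0 and gamma_override is None:
        warnings.warn("gamma_sd = 0 with theta != 0: no signal to propagate")
    gamma = np.zeros(m)
    if gamma_override is not None:
        if len(gamma_override) != cfg.n_snps:
            raise ValueError("gamma_override must have length n_snps")
        gamma[:cfg.n_snps] = gamma_override
    else:
        gamma[:cfg.n_snps] = rng.normal(0.0, cfg.gamma_sd, size=cfg.n_snps)

    alpha = np.zeros(m)
    n_invalid = round(cfg.frac_invalid * cfg.n_snps)
    invalid_idx = rng.choice(cfg.n_snps, size=n_invalid, replace=False) \
        if n_invalid else np.array([], dtype=int)
    if cfg.pleiotropy != "none" and n_invalid:
        mu = 0.0 if cfg.pleiotropy == "balanced" else cfg.mu
        delta = rng.normal(mu, cfg.tau, size=n_invalid)
        if cfg.inside_violation:
            delta = delta * (np.abs(gamma[invalid_idx]) / max(cfg.gamma_sd, 1e-12))
        orient = np.where(gamma[invalid_idx] < 0, -1.0, 1.0)
        alpha[invalid_idx] = orient * delta

    se_exp = _se(cfg.n_exp, eaf)
    se_out = _se(cfg.n_out, eaf, cfg.var_out)
    beta_exp = rng.normal(gamma, se_exp)
    beta_out = rng.normal(cfg.theta * gamma + alpha, se_out)

    outlier_idx = rng.choice(cfg.n_snps, size=cfg.n_outliers, replace=False) \
        if cfg.n_outliers else np.array([], dtype=int)
    beta_out[outlier_idx] += cfg.outlier_offset * se_out[outlier_idx]

    p_exp = _two_sided_p(beta_exp, se_exp)
    p_out = _two_sided_p(beta_out, se_out)

    ids = [f"rs{j + 1}" for j in range(m)]
    # genome layout: members of an LD block share a region; blocks far apart
    block = max(1, cfg.ld_block_size)
    chrom = [str(1 + (j // block) % 22) for j in range(m)]
    pos = [10_000_000 + (j // block) * 20_000_000 + (j % block) * 1000
           for j in range(m)]
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)

    exposure, outcome = [], []
    for j in range(m):
        ea, oa = _ALLELE_PAIRS[pair_idx[j]]
        common = dict(snp_id=ids[j], chrom=chrom[j], pos=pos[j],
                      effect_allele=ea, other_allele=oa, eaf=float(eaf[j]))
        exposure.append(GwasRecord(beta=float(beta_exp[j]), se=float(se_exp[j]),
                                   pval=float(p_exp[j]), n=float(cfg.n_exp),
                                   **common))
        outcome.append(GwasRecord(beta=float(beta_out[j]), se=float(se_out[j]),
                                  pval=float(p_out[j]), n=float(cfg.n_out),
                                  **common))

    ld = LdTable()
    if block > 1 and cfg.ld_r2 > 0:
        for start in range(0, m, block):
            members = ids[start:min(start + block, m)]
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    ld.add(members[a], members[b], cfg.ld_r2)

    truth = GroundTruth(
        theta=cfg.theta,
        gamma=dict(zip(ids, gamma.tolist())),
        alpha=dict(zip(ids, alpha.tolist())),
        outlier_ids=frozenset(ids[j] for j in outlier_idx),
        invalid_ids=frozenset(ids[j] for j in invalid_idx),
    )
    return exposure, outcome, ld, truth


#: Causal effect used by the paper-scale fixture: log(0.9923) per exposure SD.
FIXTURE_THETA = math.log(0.9923)

#: Outcome case fraction of the fixture's emulated case-control GWAS
#: (7,547 cases / 462,933 participants).
FIXTURE_CASE_FRACTION = 7_547 / 462_933


def make_paperlike_fixture(
    out_dir: str | Path,
    seed: int = 0,
    n_instruments: int = 475,
    n_null_snps: int = 2000,
    n_ld_pairs: int = 25,
    n_confounder_exclusions: int = 15,
) -> dict:
    """Write a small file bundle echoing the scale of the real analysis.

    ~475 genome-wide-significant instruments plus null background SNPs, UK
    Biobank sample sizes, a case-control-scale outcome, and a causal effect
    chosen so the IVW odds ratio sits near 0.992.  ``n_ld_pairs`` instrument
    pairs are placed adjacently with r² = 0.5 (LD clumping removes the weaker
    of each), and ``n_confounder_exclusions`` instrument ids are written to an
    exclusion list standing in for a confounder screen.

    Because genome-wide-significant hits are by definition bounded away from
    zero, instrument effect magnitudes are drawn as |z| = 7 + |N(0, 4²)| at
    each SNP's own standard error rather than from the plain Normal law of
    :func:`simulate_two_sample`.

    Returns a manifest dict (also written as ``manifest.json``) with file
    paths and the ground truth needed by integration tests.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(
        n_snps=n_instruments, n_null_snps=n_null_snps,
        theta=FIXTURE_THETA, gamma_sd=0.02,
        var_out=FIXTURE_CASE_FRACTION * (1 - FIXTURE_CASE_FRACTION),
        n_outliers=0, seed=seed,
    )
    # eaf is the generator's first draw, so this preview matches it exactly
    eaf_preview = np.random.default_rng(cfg.seed).uniform(
        cfg.maf_range[0], cfg.maf_range[1], size=n_instruments + n_null_snps)
    se_prev = _se(cfg.n_exp, eaf_preview[:n_instruments])
    rng = np.random.default_rng(None if seed is None else seed + 10_000)
    z = 7.0 + np.abs(rng.normal(0.0, 4.0, size=n_instruments))
    gamma = rng.choice([-1.0, 1.0], size=n_instruments) * z * se_prev

    exposure, outcome, ld, truth = simulate_two_sample(cfg, gamma_override=gamma)

    # plant LD pairs: instruments (2i, 2i+1) become neighbours with r² = 0.5
    for i in range(n_ld_pairs):
        a, b = 2 * i, 2 * i + 1
        for table in (exposure, outcome):
            table[b] = replace(table[b], chrom=table[a].chrom,
                               pos=table[a].pos + 1000)
        ld.add(exposure[a].snp_id, exposure[b].snp_id, 0.5)

    # confounder stand-ins: instruments untouched by the LD pairing
    first_free = 2 * n_ld_pairs
    excluded = [exposure[j].snp_id
                for j in range(first_free, first_free + n_confounder_exclusions)]

    cmap = ColumnMap()
    exp_path = out_dir / "exposure.tsv"
    out_path = out_dir / "outcome.tsv"
    ld_path = out_dir / "ld.tsv"
    excl_path = out_dir / "exclusions.txt"
    write_summary_stats(exposure, exp_path, cmap)
    write_summary_stats(outcome, out_path, cmap)
    write_ld_table(ld, ld_path)
    excl_path.write_text("# confounder-associated instruments\n"
                         + "\n".join(excluded) + "\n")

    manifest = {
        "exposure": str(exp_path), "outcome": str(out_path),
        "ld": str(ld_path), "exclusions": str(excl_path),
        "theta": truth.theta, "seed": seed,
        "n_instruments": n_instruments, "n_null_snps": n_null_snps,
        "n_ld_pairs": n_ld_pairs, "excluded_ids": excluded,
        "n_exp": cfg.n_exp, "n_out": cfg.n_out, "var_out": cfg.var_out,
        "invalid_ids": sorted(truth.invalid_ids),
        "outlier_ids": sorted(truth.outlier_ids),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
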