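"""Harmonization of exposure and outcome summary statistics.

Two-sample MR needs each SNP's exposure and outcome effects expressed on the
same effect allele.  Studies report alleles on arbitrary strands and in
arbitrary order, so merging involves sign flips (allele swap), strand
re-expression (reverse complement), and a policy for palindromic (A/T, C/G)
variants, whose strand cannot be inferred from the alleles alone.

Policy here: a palindromic SNP is dropped when its exposure allele frequency
is too close to 0.5 to orient by frequency (default window 0.08, i.e. eaf in
[0.42, 0.58] drops, as does a missing frequency); otherwise the outcome side
is oriented so the two frequencies agree on the same side of 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .gwas_io import GwasRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Flags an instrument may carry.  Any ``excluded_*`` or ``dropped_*`` flag
#: bars the record from estimation.
FLAGS = frozenset({
    "allele_flipped", "strand_flipped", "palindromic",
    "dropped_palindromic", "excluded_confounder", "excluded_presso_outlier",
})


@dataclass(frozen=True)
class HarmonizedInstrument:
    """A SNP with exposure and outcome effects on a common effect allele."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    pval_exp: float
    beta_out: float
    se_out: float
    pval_out: float
    chrom: str | None = None
    pos: int | None = None
    eaf_exp: float | None = None
    n_exp: float | None = None
    eaf_out: float | None = None
    n_out: float | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (self.se_exp > 0 and self.se_out > 0):
            raise ValueError(f"{self.snp_id}: standard errors must be > 0")
        unknown = self.flags - FLAGS
        if unknown:
            raise ValueError(f"{self.snp_id}: unknown flags {unknown}")

    @property
    def usable(self) -> bool:
        """True when no flag bars the SNP from estimation."""
        return not any(f.startswith(("excluded_", "dropped_")) for f in self.flags)

    def with_flags(self, *new: str) -> "HarmonizedInstrument":
        return replace(self, flags=self.flags | frozenset(new))


def usable(instruments: Iterable[HarmonizedInstrument]) -> list[HarmonizedInstrument]:
    """The subset of instruments free of excluded_*/dropped_* flags."""
    return [i for i in instruments if i.usable]


def _revcomp(allele: str) -> str:
    return allele.translate(_COMPLEMENT)[::-1]


def _is_palindromic(a1: str, a2: str) -> bool:
    return len(a1) == 1 and len(a2) == 1 and _revcomp(a1) == a2


def _dedupe(records: Sequence[GwasRecord], label: str) -> dict[str, GwasRecord]:
    """Key records by snp_id, keeping the smallest p-value on duplicates."""
    best: dict[str, GwasRecord] = {}
    for rec in records:
        prev = best.get(rec.snp_id)
        if prev is None:
            best[rec.snp_id] = rec
        else:
            logger.warning("duplicate %s in %s: keeping smaller p", rec.snp_id, label)
            if rec.pval < prev.pval:
                best[rec.snp_id] = rec
    return best


def harmonize(
    exposure: Sequence[GwasRecord],
    outcome: Sequence[GwasRecord],
    palindrome_eaf_window: float = 0.08,
    audit: list[str] | None = None,
) -> list[HarmonizedInstrument]:
    """Merge exposure and outcome records on shared SNPs, common effect allele.

    Returns one :class:`HarmonizedInstrument` per SNP present in both studies
    whose allele pairs can be reconciled.  Outcome effects are re-expressed on
    the exposure's effect allele:

    * alleles swapped -> outcome beta negated, eaf complemented, ``allele_flipped``;
    * alleles matching only under reverse complement -> ``strand_flipped``;
    * palindromic SNPs -> ``palindromic``, plus either ``dropped_palindromic``
      (ambiguous frequency, see module docstring) or a frequency-based
      orientation;
    * irreconcilable allele pairs are omitted and reported in ``audit``.

    ``audit``, when given, receives one line per modified or dropped SNP.
    """
    if not (0 <= palindrome_eaf_window < 0.5):
        raise ValueError("palindrome_eaf_window must be in [0, 0.5)")
    log = audit if audit is not None else []

    exp_by_id = _dedupe(exposure, "exposure")
    out_by_id = _dedupe(outcome, "outcome")

    result: list[HarmonizedInstrument] = []
    for snp_id, ex in exp_by_id.items():
        ou = out_by_id.get(snp_id)
        if ou is None:
            continue
        flags: set[str] = set()
        beta_out, eaf_out = ou.beta, ou.eaf
        ea, oa = ex.effect_allele, ex.other_allele

        if _is_palindromic(ea, oa):
            flags.add("palindromic")
            if {ou.effect_allele, ou.other_allele} != {ea, oa}:
                log.append(f"{snp_id}: palindromic alleles disagree "
                           f"({ou.effect_allele}/{ou.other_allele} vs {ea}/{oa}); dropped")
                continue
            ambiguous = (
                ex.eaf is None or ou.eaf is None
                # closed window, with a float-representation guard so the
                # documented [0.5-w, 0.5+w] boundary itself drops
                or abs(ex.eaf - 0.5) <= palindrome_eaf_window + 1e-12
            )
            if ambiguous:
                flags.add("dropped_palindromic")
                log.append(f"{snp_id}: palindromic with ambiguous frequency; dropped")
            else:
                # the reported allele letter carries no strand information for
                # a palindrome: orient purely by frequency agreement, i.e. the
                # outcome's reported allele is the exposure's effect allele iff
                # both frequencies fall on the same side of 0.5
                same_side = (ex.eaf - 0.5) * (ou.eaf - 0.5) > 0
                if not same_side:
                    beta_out = -beta_out
                    eaf_out = None if eaf_out is None else 1.0 - eaf_out
                    flags.add("allele_flipped")
                    log.append(f"{snp_id}: palindromic, oriented by frequency (flip)")
        elif (ou.effect_allele, ou.other_allele) == (ea, oa):
            pass  # already aligned
        elif (ou.effect_allele, ou.other_allele) == (oa, ea):
            beta_out = -beta_out
            eaf_out = None if eaf_out is None else 1.0 - eaf_out
            flags.add("allele_flipped")
            log.append(f"{snp_id}: outcome alleles swapped; beta sign flipped")
        elif len(ea) == 1 and len(oa) == 1 and (
            (_revcomp(ou.effect_allele), _revcomp(ou.other_allele)) == (ea, oa)
        ):
            flags.add("strand_flipped")
            log.append(f"{snp_id}: outcome on opposite strand; re-expressed")
        elif len(ea) == 1 and len(oa) == 1 and (
            (_revcomp(ou.effect_allele), _revcomp(ou.other_allele)) == (oa, ea)
        ):
            beta_out = -beta_out
            eaf_out = None if eaf_out is None else 1.0 - eaf_out
            flags.update({"strand_flipped", "allele_flipped"})
            log.append(f"{snp_id}: opposite strand and swapped; flipped both")
        else:
            log.append(
                f"{snp_id}: alleles irreconcilable "
                f"(exposure {ea}/{oa}, outcome {ou.effect_allele}/{ou.other_allele}); dropped"
            )
            continue

        result.append(HarmonizedInstrument(
            snp_id=snp_id,
            chrom=ex.chrom if ex.chrom is not None else ou.chrom,
            pos=ex.pos if ex.pos is not None else ou.pos,
            effect_allele=ea,
            other_allele=oa,
            beta_exp=ex.beta, se_exp=ex.se, pval_exp=ex.pval,
            eaf_exp=ex.eaf, n_exp=ex.n,
            beta_out=beta_out, se_out=ou.se, pval_out=ou.pval,
            eaf_out=eaf_out, n_out=ou.n,
            flags=frozenset(flags),
        ))
    return result


def split_harmonized(
    instruments: Sequence[HarmonizedInstrument],
) -> tuple[list[GwasRecord], list[GwasRecord]]:
    """Project harmonized instruments back to per-study record lists.

    Useful for re-harmonization checks and for swapping exposure/outcome roles.
    """
    exp, out = [], []
    for ins in instruments:
        exp.append(GwasRecord(
            snp_id=ins.snp_id, chrom=ins.chrom, pos=ins.pos,
            effect_allele=ins.effect_allele, other_allele=ins.other_allele,
            beta=ins.beta_exp, se=ins.se_exp, pval=ins.pval_exp,
            eaf=ins.eaf_exp, n=ins.n_exp,
        ))
        out.append(GwasRecord(
            snp_id=ins.snp_id, chrom=ins.chrom, pos=ins.pos,
            effect_allele=ins.effect_allele, other_allele=ins.other_allele,
            beta=ins.beta_out, se=ins.se_out, pval=ins.pval_out,
            eaf=ins.eaf_out, n=ins.n_out,
        ))
    return exp, out
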