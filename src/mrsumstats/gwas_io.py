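"""Reading and writing GWAS summary statistics and ancillary tables.

All formats are delimited text.  Column naming in the wild is chaotic, so
every reader takes an explicit :class:`ColumnMap`; no delimiter or header
auto-detection is attempted, which keeps round trips bit-exact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Default tokens interpreted as a missing value on read.
DEFAULT_NA_TOKENS = ("NA", ".", "")

_VALID_BASES = set("ACGT")


class GwasIOError(Exception):
    """Raised for unrecoverable I/O problems (missing file/column, no valid rows)."""


@dataclass(frozen=True)
class GwasRecord:
    """One SNP's association summary in one study.

    ``beta``/``se`` are treated as opaque trait-unit quantities; ``eaf`` is the
    effect-allele frequency.  ``eaf`` and ``n`` may be missing (``None``).
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(
                f"{self.snp_id}: effect and other allele are identical "
                f"({self.effect_allele})"
            )
        if not (self.se > 0):
            raise ValueError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.snp_id}: pval must be in (0,1], got {self.pval}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.snp_id}: eaf must be in [0,1], got {self.eaf}")
        if self.n is not None and not (self.n > 0):
            raise ValueError(f"{self.snp_id}: n must be > 0, got {self.n}")

    @property
    def maf(self) -> float | None:
        """Minor-allele frequency, ``None`` when eaf is missing."""
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from :class:`GwasRecord` field names to source column headers.

    ``snp_id``, ``effect_allele``, ``other_allele``, ``beta``, ``se`` and
    ``pval`` are mandatory; the rest may be ``None`` (field left missing).
    """

    snp_id: str = "SNP"
    effect_allele: str = "effect_allele"
    other_allele: str = "other_allele"
    beta: str = "beta"
    se: str = "se"
    pval: str = "pval"
    chrom: str | None = "chrom"
    pos: str | None = "pos"
    eaf: str | None = "eaf"
    n: str | None = "n"
    delimiter: str = "\t"
    na_tokens: tuple[str, ...] = DEFAULT_NA_TOKENS

    def required_columns(self) -> list[str]:
        return [self.snp_id, self.effect_allele, self.other_allele,
                self.beta, self.se, self.pval]

    def optional_columns(self) -> dict[str, str]:
        out = {}
        for fld in ("chrom", "pos", "eaf", "n"):
            col = getattr(self, fld)
            if col is not None:
                out[fld] = col
        return out


@dataclass(frozen=True)
class RowDiagnostic:
    """A rejected input row: 1-based data-row number, offending field, reason."""

    row: int
    snp_id: str
    fields: str
    reason: str


class LdTable:
    """Symmetric pairwise r² lookup keyed by SNP identifier pairs.

    Absent pairs resolve to r² = 0 (uncorrelated by assumption).
    """

    def __init__(self, triples: Iterable[tuple[str, str, float]] = ()) -> None:
        self._r2: dict[frozenset[str], float] = {}
        for a, b, r2 in triples:
            self.add(a, b, r2)

    def add(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 must be in [0,1], got {r2} for ({a},{b})")
        self._r2[frozenset((a, b))] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return frozenset(pair) in self._r2

    def __len__(self) -> int:
        return len(self._r2)


def _parse_float(token: str, na_tokens: Sequence[str]) -> float | None:
    if token.strip() in na_tokens:
        return None
    return float(token)


def read_summary_stats(
    path: str | Path,
    column_map: ColumnMap | None = None,
    *,
    collect_diagnostics: list[RowDiagnostic] | None = None,
) -> list[GwasRecord]:
    """Read a delimited summary-statistics table into :class:`GwasRecord` rows.

    Rows whose mandatory fields are missing or violate record invariants are
    rejected, each with a :class:`RowDiagnostic` (logged, and appended to
    ``collect_diagnostics`` when given).  Row order is preserved.

    Raises :class:`GwasIOError` if the file or a mapped column is missing, or
    if no row survives.
    """
    cmap = column_map or ColumnMap()
    path = Path(path)
    if not path.exists():
        raise GwasIOError(f"summary-statistics file not found: {path}")

    df = pd.read_csv(
        path, sep=cmap.delimiter, dtype=str, keep_default_na=False, engine="c"
    )
    missing = [c for c in cmap.required_columns() if c not in df.columns]
    if missing:
        raise GwasIOError(f"{path}: mapped column(s) not in header: {missing}")
    optional = {f: c for f, c in cmap.optional_columns().items() if c in df.columns}

    records: list[GwasRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        snp = row_d[cmap.snp_id].strip()
        try:
            beta = _parse_float(row_d[cmap.beta], cmap.na_tokens)
            se = _parse_float(row_d[cmap.se], cmap.na_tokens)
            pval = _parse_float(row_d[cmap.pval], cmap.na_tokens)
            if beta is None or se is None or pval is None:
                raise ValueError("mandatory numeric field missing")
            kwargs: dict = dict(
                snp_id=snp,
                effect_allele=row_d[cmap.effect_allele].strip().upper(),
                other_allele=row_d[cmap.other_allele].strip().upper(),
                beta=beta,
                se=se,
                pval=pval,
            )
            if "chrom" in optional:
                tok = row_d[optional["chrom"]].strip()
                kwargs["chrom"] = None if tok in cmap.na_tokens else tok
            if "pos" in optional:
                v = _parse_float(row_d[optional["pos"]], cmap.na_tokens)
                kwargs["pos"] = None if v is None else int(v)
            if "eaf" in optional:
                kwargs["eaf"] = _parse_float(row_d[optional["eaf"]], cmap.na_tokens)
            if "n" in optional:
                kwargs["n"] = _parse_float(row_d[optional["n"]], cmap.na_tokens)
            records.append(GwasRecord(**kwargs))
        except (ValueError, TypeError) as exc:
            diag = RowDiagnostic(row=i, snp_id=snp, fields=str(row_d), reason=str(exc))
            logger.warning("rejected row %d (%s): %s", i, snp, exc)
            if collect_diagnostics is not None:
                collect_diagnostics.append(diag)

    if not records:
        raise GwasIOError(f"{path}: zero valid rows")
    return records


def read_exclusion_list(path: str | Path) -> set[str]:
    """Read a plain-text SNP exclusion list (one identifier per line).

    Lines starting with ``#`` and blank lines are ignored; duplicates collapse.
    """
    path = Path(path)
    if not path.exists():
        raise GwasIOError(f"exclusion list not found: {path}")
    ids: set[str] = set()
    for line in path.read_text().splitlines():
        token = line.split("#", 1)[0].strip()
        if token:
            ids.add(token)
    return ids


def read_ld_table(path: str | Path, delimiter: str = "\t") -> LdTable:
    """Read a 3-column (snp_a, snp_b, r2) table, with or without a header."""
    path = Path(path)
    if not path.exists():
        raise GwasIOError(f"LD table not found: {path}")
    triples = []
    with path.open() as fh:
        for line in fh:
            parts = line.rstrip("\n").split(delimiter)
            if len(parts) < 3 or not parts[0] or parts[0].startswith("#"):
                continue
            try:
                r2 = float(parts[2])
            except ValueError:
                continue  # header line
            triples.append((parts[0].strip(), parts[1].strip(), r2))
    return LdTable(triples)


def write_ld_table(ld: LdTable, path: str | Path, delimiter: str = "\t") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(delimiter.join(("snp_a", "snp_b", "r2")) + "\n")
        for pair, r2 in sorted(ld._r2.items(), key=lambda kv: sorted(kv[0])):
            a, b = sorted(pair)
            fh.write(delimiter.join((a, b, repr(r2))) + "\n")


# ---------------------------------------------------------------------------
# Harmonized-instrument tables
# ---------------------------------------------------------------------------

#: Fixed header of the harmonized-instrument table (documented interface).
INSTRUMENT_COLUMNS = (
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta_exp", "se_exp", "pval_exp", "eaf_exp", "n_exp",
    "beta_out", "se_out", "pval_out", "eaf_out", "n_out",
    "flags",
)


def _fmt(value, na: str = "NA") -> str:
    if value is None:
        return na
    if isinstance(value, float):
        if math.isnan(value):
            return na
        return repr(value)  # shortest round-trippable representation
    return str(value)


def write_instrument_table(instruments: Sequence, path: str | Path,
                           delimiter: str = "\t") -> None:
    """Write harmonized instruments as delimited text with a fixed header.

    Floats are serialized with ``repr`` so a round trip through
    :func:`read_instrument_table` is bit-exact; missing values become ``NA``.
    """
    if not instruments:
        raise ValueError("instrument collection is empty")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(delimiter.join(INSTRUMENT_COLUMNS) + "\n")
        for ins in instruments:
            row = [
                ins.snp_id, _fmt(ins.chrom), _fmt(ins.pos),
                ins.effect_allele, ins.other_allele,
                _fmt(ins.beta_exp), _fmt(ins.se_exp), _fmt(ins.pval_exp),
                _fmt(ins.eaf_exp), _fmt(ins.n_exp),
                _fmt(ins.beta_out), _fmt(ins.se_out), _fmt(ins.pval_out),
                _fmt(ins.eaf_out), _fmt(ins.n_out),
                ";".join(sorted(ins.flags)),
            ]
            fh.write(delimiter.join(row) + "\n")


def read_instrument_table(path: str | Path, delimiter: str = "\t") -> list:
    """Read a table written by :func:`write_instrument_table`."""
    from .harmonize import HarmonizedInstrument  # local import, avoids cycle

    path = Path(path)
    if not path.exists():
        raise GwasIOError(f"instrument table not found: {path}")
    out: list[HarmonizedInstrument] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
        if tuple(header) != INSTRUMENT_COLUMNS:
            raise GwasIOError(f"{path}: unexpected header {header}")
        for line in fh:
            d = dict(zip(header, line.rstrip("\n").split(delimiter)))
            na = DEFAULT_NA_TOKENS

            def f(k: str) -> float | None:
                return _parse_float(d[k], na)

            out.append(HarmonizedInstrument(
                snp_id=d["snp_id"],
                chrom=None if d["chrom"] in na else d["chrom"],
                pos=None if d["pos"] in na else int(float(d["pos"])),
                effect_allele=d["effect_allele"],
                other_allele=d["other_allele"],
                beta_exp=f("beta_exp"), se_exp=f("se_exp"), pval_exp=f("pval_exp"),
                eaf_exp=f("eaf_exp"), n_exp=f("n_exp"),
                beta_out=f("beta_out"), se_out=f("se_out"), pval_out=f("pval_out"),
                eaf_out=f("eaf_out"), n_out=f("n_out"),
                flags=frozenset(t for t in d["flags"].split(";") if t),
            ))
    if not out:
        raise GwasIOError(f"{path}: zero rows")
    return out


def write_summary_stats(records: Sequence[GwasRecord], path: str | Path,
                        column_map: ColumnMap | None = None) -> None:
    """Write GWAS records in the dialect described by ``column_map``."""
    cmap = column_map or ColumnMap()
    path = Path(path)
    cols = cmap.required_columns() + list(cmap.optional_columns().values())
    with path.open("w") as fh:
        fh.write(cmap.delimiter.join(cols) + "\n")
        for rec in records:
            row = [rec.snp_id, rec.effect_allele, rec.other_allele,
                   _fmt(rec.beta), _fmt(rec.se), _fmt(rec.pval)]
            for fld in cmap.optional_columns():
                row.append(_fmt(getattr(rec, fld)))
            fh.write(cmap.delimiter.join(row) + "\n")
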