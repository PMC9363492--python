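"""GWAS summary-statistic data model, readers, allele harmonization and QC.

Summary statistics from two populations (a large discovery GWAS, typically of
European ancestry, and a smaller target-population GWAS) are the primary
inputs to the transferability analysis. Everything downstream assumes the two
tables have been harmonized to a common effect-allele orientation, so this
module owns the allele bookkeeping: swaps, strand complements, palindromic
(A/T, G/C) ambiguity and allele-frequency sanity checks.

Coordinates are 1-based on a single genome build per run (no liftover);
callers are responsible for supplying both tables on the same build.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("patloc")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: default column-name candidates, first match wins (case-insensitive)
DEFAULT_SCHEMA: dict[str, tuple[str, ...]] = {
    "snp": ("SNP", "ID", "RSID", "MARKERNAME", "VARIANT_ID"),
    "chrom": ("CHR", "CHROM", "CHROMOSOME"),
    "pos": ("BP", "POS", "POSITION", "BASE_PAIR_LOCATION"),
    "ea": ("EA", "ALT", "A1", "EFFECT_ALLELE"),
    "oa": ("OA", "REF", "A2", "OTHER_ALLELE"),
    "beta": ("BETA", "B", "EFFECT"),
    "or": ("OR", "ODDS_RATIO"),
    "se": ("SE", "STDERR", "STANDARD_ERROR"),
    "p": ("P", "PVAL", "PVALUE", "P_VALUE"),
    "eaf": ("EAF", "AF", "A1FREQ", "EFFECT_ALLELE_FREQUENCY", "FRQ"),
    "n": ("N", "NMISS", "SAMPLE_SIZE"),
    "n_cases": ("N_CASES", "NCASE", "NCASES"),
    "n_controls": ("N_CONTROLS", "NCONTROL", "NCONTROLS"),
    "info": ("INFO", "IMPINFO", "INFO_SCORE"),
}

REQUIRED_FIELDS = ("chrom", "pos", "ea", "oa", "se", "p")


def complement_allele(allele: str) -> str:
    """Reverse-strand complement of an allele string (indels included)."""
    return allele.translate(_COMPLEMENT)[::-1] if len(allele) > 1 else allele.translate(_COMPLEMENT)


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a biallelic variant: chromosome, 1-based position, alleles."""

    chrom: str
    pos: int
    ea: str
    oa: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", str(self.chrom))
        object.__setattr__(self, "ea", self.ea.upper())
        object.__setattr__(self, "oa", self.oa.upper())
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ea == self.oa:
            raise ValueError(f"effect and other allele identical: {self.ea}")

    @property
    def is_palindromic(self) -> bool:
        """True for strand-ambiguous A/T or G/C SNPs."""
        return (
            len(self.ea) == 1
            and len(self.oa) == 1
            and complement_allele(self.ea) == self.oa
        )

    def swapped(self) -> "VariantKey":
        return VariantKey(self.chrom, self.pos, self.oa, self.ea)

    def complemented(self) -> "VariantKey":
        return VariantKey(
            self.chrom, self.pos, complement_allele(self.ea), complement_allele(self.oa)
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ea}:{self.oa}"


@dataclass(frozen=True)
class SumStatRecord:
    """One harmonized variant association.

    ``beta`` is the per-effect-allele effect (log odds ratio for binary
    traits); its sign defines the direction of effect for ``key.ea``.
    """

    key: VariantKey
    beta: float
    se: float
    p: float
    eaf: float
    n: float | None = None
    n_cases: float | None = None
    n_controls: float | None = None
    info: float | None = None
    snp_id: str | None = None

    def __post_init__(self) -> None:
        if self.se is not None and not self.se > 0:
            raise ValueError(f"se must be > 0 at {self.key}, got {self.se}")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p must be in (0, 1] at {self.key}, got {self.p}")
        if not (0.0 < self.eaf < 1.0):
            raise ValueError(f"eaf must be in (0, 1) at {self.key}, got {self.eaf}")

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)


class SumStatTable:
    """Collection of :class:`SumStatRecord` keyed by :class:`VariantKey`.

    Also indexes variants by (chrom, pos) so that credible-set construction
    and flanking-region scans can run window queries without a genome browser.
    """

    def __init__(
        self,
        records: Iterable[SumStatRecord],
        trait_type: str = "quantitative",
        population: str | None = None,
    ) -> None:
        if trait_type not in ("quantitative", "binary"):
            raise ValueError(f"trait_type must be quantitative|binary, got {trait_type!r}")
        self.trait_type = trait_type
        self.population = population
        self._records: dict[VariantKey, SumStatRecord] = {}
        self._by_site: dict[tuple[str, int], list[VariantKey]] = {}
        for rec in records:
            if rec.key in self._records:
                raise ValueError(f"duplicate variant {rec.key}")
            self._records[rec.key] = rec
            self._by_site.setdefault((rec.key.chrom, rec.key.pos), []).append(rec.key)
        self._pos_index: dict[str, tuple[np.ndarray, list[VariantKey]]] | None = None
        #: provenance of rows dropped at read time (reason-coded)
        self.drop_log: pd.DataFrame = pd.DataFrame(columns=["row", "reason"])
        self.qc_counts: dict[str, int] = {}

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[SumStatRecord]:
        return iter(self._records.values())

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._records

    def get(self, key: VariantKey) -> SumStatRecord | None:
        return self._records.get(key)

    def at_site(self, chrom: str, pos: int) -> list[SumStatRecord]:
        """All records at one genomic site (alleles may differ)."""
        return [self._records[k] for k in self._by_site.get((str(chrom), pos), [])]

    def lookup(self, key: VariantKey) -> tuple[SumStatRecord, bool] | None:
        """Find ``key`` at its site regardless of stored allele orientation.

        Returns ``(record, same_orientation)`` where ``same_orientation`` is
        False when the stored record has ea/oa swapped relative to ``key``;
        strand-complement matches are resolved the same way. None if the site
        holds no allele-compatible record.
        """
        for rec in self.at_site(key.chrom, key.pos):
            if rec.key == key or rec.key == key.complemented():
                return rec, True
            if rec.key == key.swapped() or rec.key == key.swapped().complemented():
                return rec, False
        return None

    def _build_pos_index(self) -> dict[str, tuple[np.ndarray, list[VariantKey]]]:
        if self._pos_index is None:
            index: dict[str, tuple[np.ndarray, list[VariantKey]]] = {}
            per_chrom: dict[str, list[VariantKey]] = {}
            for key in self._records:
                per_chrom.setdefault(key.chrom, []).append(key)
            for chrom, keys in per_chrom.items():
                keys.sort(key=lambda k: (k.pos, k.ea, k.oa))
                index[chrom] = (np.array([k.pos for k in keys]), keys)
            self._pos_index = index
        return self._pos_index

    def in_window(self, chrom: str, start: int, end: int) -> list[SumStatRecord]:
        """Records with start <= pos <= end on ``chrom`` (inclusive ends)."""
        index = self._build_pos_index()
        if str(chrom) not in index:
            return []
        positions, keys = index[str(chrom)]
        lo = int(np.searchsorted(positions, start, side="left"))
        hi = int(np.searchsorted(positions, end, side="right"))
        return [self._records[k] for k in keys[lo:hi]]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "snp": r.snp_id or str(r.key),
                "chrom": r.key.chrom,
                "pos": r.key.pos,
                "ea": r.key.ea,
                "oa": r.key.oa,
                "beta": r.beta,
                "se": r.se,
                "p": r.p,
                "eaf": r.eaf,
                "n": r.n,
                "n_cases": r.n_cases,
                "n_controls": r.n_controls,
                "info": r.info,
            }
            for r in self._records.values()
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str) -> None:
        """Write the normalized table with canonical column names."""
        self.to_dataframe().to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _resolve_columns(
    columns: Iterable[str], schema_map: Mapping[str, str] | None
) -> dict[str, str]:
    """Map canonical field names to actual file columns."""
    upper = {c.upper(): c for c in columns}
    resolved: dict[str, str] = {}
    schema_map = {k: v for k, v in (schema_map or {}).items()}
    for fieldname, candidates in DEFAULT_SCHEMA.items():
        if fieldname in schema_map:
            col = schema_map[fieldname]
            if col not in upper.values():
                raise SchemaError(f"mapped column {col!r} for field {fieldname!r} not in file")
            resolved[fieldname] = col
            continue
        for cand in candidates:
            if cand in upper:
                resolved[fieldname] = upper[cand]
                break
    return resolved


class SchemaError(ValueError):
    """A required summary-statistic column is missing or misnamed."""


def read_sumstats(
    path: str,
    schema_map: Mapping[str, str] | None = None,
    trait_type: str = "quantitative",
    population: str | None = None,
    sep: str | None = None,
) -> SumStatTable:
    """Read delimited summary statistics into a :class:`SumStatTable`.

    Odds ratios are converted to the log scale at read time so all downstream
    math works with beta/SE uniformly. Rows whose required fields cannot be
    parsed are dropped, counted and recorded in ``table.drop_log``.

    Parameters
    ----------
    schema_map
        Optional mapping of canonical field names (``beta``, ``se``, ``p``,
        ``ea``, ``oa``, ``chrom``, ``pos``, ``eaf`` ...) to the file's column
        names, overriding the built-in candidates.
    sep
        Field delimiter; default sniffs tab/whitespace.
    """
    df = pd.read_csv(path, sep=sep if sep is not None else r"\s+", dtype=str)
    if df.empty:
        raise ValueError(f"empty summary-statistic file: {path}")
    cols = _resolve_columns(df.columns, schema_map)

    for fieldname in REQUIRED_FIELDS:
        if fieldname not in cols:
            raise SchemaError(
                f"required column for field {fieldname!r} not found in {path}; "
                f"known names: {DEFAULT_SCHEMA[fieldname]}"
            )
    if "beta" not in cols and "or" not in cols:
        raise SchemaError(f"neither a BETA nor an OR column found in {path}")
    if "eaf" not in cols:
        raise SchemaError(f"required column for field 'eaf' not found in {path}")

    records: list[SumStatRecord] = []
    dropped: list[dict[str, object]] = []

    def _num(row: pd.Series, fieldname: str) -> float | None:
        if fieldname not in cols:
            return None
        raw = row[cols[fieldname]]
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            return None
        try:
            val = float(raw)
        except (TypeError, ValueError):
            return None
        return val if math.isfinite(val) else None

    for i, row in df.iterrows():
        reason = None
        try:
            key = VariantKey(
                str(row[cols["chrom"]]).removeprefix("chr"),
                int(float(row[cols["pos"]])),
                str(row[cols["ea"]]),
                str(row[cols["oa"]]),
            )
        except (ValueError, TypeError):
            key = None
            reason = "bad_variant_fields"
        if key is not None:
            beta = _num(row, "beta")
            if beta is None and "or" in cols:
                odds = _num(row, "or")
                beta = math.log(odds) if odds is not None and odds > 0 else None
            se, p, eaf = _num(row, "se"), _num(row, "p"), _num(row, "eaf")
            if beta is None:
                reason = "unparseable_beta"
            elif se is None or se <= 0:
                reason = "unparseable_se"
            elif p is None or not (0 < p <= 1):
                reason = "unparseable_p"
            elif eaf is None or not (0 < eaf < 1):
                reason = "unparseable_eaf"
        if reason is not None:
            dropped.append({"row": i, "reason": reason})
            continue
        records.append(
            SumStatRecord(
                key=key,
                beta=beta,
                se=se,
                p=p,
                eaf=eaf,
                n=_num(row, "n"),
                n_cases=_num(row, "n_cases"),
                n_controls=_num(row, "n_controls"),
                info=_num(row, "info"),
                snp_id=str(row[cols["snp"]]) if "snp" in cols else None,
            )
        )

    table = SumStatTable(records, trait_type=trait_type, population=population)
    table.drop_log = pd.DataFrame(dropped, columns=["row", "reason"])
    if dropped:
        logger.info("read_sumstats(%s): dropped %d unparseable rows", path, len(dropped))
    return table


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HarmonizeResult:
    """Outcome of aligning record ``b`` to record ``a``'s effect allele.

    ``ok`` is False for a drop verdict, with ``reason`` one of
    ``allele_mismatch``, ``ambiguous_palindromic`` or ``eaf_divergent``.
    """

    ok: bool
    record: SumStatRecord | None = None
    reason: str | None = None
    flipped: bool = False
    complemented: bool = False


def _flip(rec: SumStatRecord, key: VariantKey) -> SumStatRecord:
    """Re-express ``rec`` with the opposite allele as effect allele."""
    return replace(rec, key=key, beta=-rec.beta, eaf=1.0 - rec.eaf)


def harmonize_pair(
    a: SumStatRecord, b: SumStatRecord, eaf_max_diff: float = 0.2,
    palindrome_band: tuple[float, float] = (0.4, 0.6),
) -> HarmonizeResult:
    """Align ``b`` to ``a``'s effect-allele orientation, or issue a drop verdict.

    Swapped alleles flip the sign of ``b.beta`` and mirror its frequency;
    alleles reported on the opposite strand are complemented first.
    Strand-ambiguous A/T and G/C pairs are frequency-resolved when both
    frequencies are outside ``palindrome_band``, otherwise dropped. After
    alignment, pairs whose effect-allele frequencies differ by more than
    ``eaf_max_diff`` are dropped (likely mismapped or multi-allelic sites).
    """
    ka, kb = a.key, b.key
    if (ka.chrom, ka.pos) != (kb.chrom, kb.pos):
        raise ValueError(f"harmonize_pair requires a shared site: {ka} vs {kb}")

    if ka.is_palindromic:
        if {kb.ea, kb.oa} != {ka.ea, ka.oa}:
            return HarmonizeResult(False, reason="allele_mismatch")
        lo, hi = palindrome_band
        if lo <= a.eaf <= hi or lo <= b.eaf <= hi:
            return HarmonizeResult(False, reason="ambiguous_palindromic")
        # strand is unknowable; orient by which side of 0.5 the frequencies fall
        same_side = (a.eaf < 0.5) == (b.eaf < 0.5)
        aligned = b if same_side else _flip(b, kb.swapped())
        aligned = replace(aligned, key=ka)
        flipped = not same_side
        comp = False
    elif kb == ka:
        aligned, flipped, comp = b, False, False
    elif kb == ka.swapped():
        aligned, flipped, comp = _flip(b, ka), True, False
    elif kb == ka.complemented():
        aligned, flipped, comp = replace(b, key=ka), False, True
    elif kb == ka.complemented().swapped():
        aligned, flipped, comp = _flip(b, ka), True, True
    else:
        return HarmonizeResult(False, reason="allele_mismatch")

    if abs(aligned.eaf - a.eaf) > eaf_max_diff:
        return HarmonizeResult(False, reason="eaf_divergent", flipped=flipped, complemented=comp)
    return HarmonizeResult(True, record=aligned, flipped=flipped, complemented=comp)


def harmonize_tables(
    reference: SumStatTable, other: SumStatTable, eaf_max_diff: float = 0.2
) -> SumStatTable:
    """Align every shared variant of ``other`` to ``reference`` orientation.

    Variants absent from ``reference`` are carried through unchanged; dropped
    pairs are recorded in the returned table's ``drop_log``.
    """
    out: list[SumStatRecord] = []
    dropped: list[dict[str, object]] = []
    for rec in other:
        match = reference.lookup(rec.key)
        if match is None:
            out.append(rec)
            continue
        ref_rec, _ = match
        result = harmonize_pair(ref_rec, rec, eaf_max_diff=eaf_max_diff)
        if result.ok:
            out.append(result.record)
        else:
            dropped.append({"row": str(rec.key), "reason": result.reason})
    table = SumStatTable(out, trait_type=other.trait_type, population=other.population)
    table.drop_log = pd.DataFrame(dropped, columns=["row", "reason"])
    return table


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------


def qc_filter(
    table: SumStatTable,
    info_min: float = 0.7,
    maf_min: float = 0.005,
) -> SumStatTable:
    """Remove low-imputation-quality and rare variants.

    Records with ``info < info_min`` or minor-allele frequency below
    ``maf_min`` are removed. Missing INFO (typical of directly genotyped
    variants) passes with a logged flag. Removal counts per criterion are
    stored in the result's ``qc_counts``.
    """
    for name, thr in (("info_min", info_min), ("maf_min", maf_min)):
        if not (0.0 <= thr <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {thr}")
    kept: list[SumStatRecord] = []
    counts = {"info": 0, "maf": 0, "info_missing_passed": 0}
    for rec in table:
        if rec.info is not None and rec.info < info_min:
            counts["info"] += 1
            continue
        if rec.maf < maf_min:
            counts["maf"] += 1
            continue
        if rec.info is None:
            counts["info_missing_passed"] += 1
        kept.append(rec)
    if not kept:
        logger.warning("qc_filter removed every record (info_min=%s, maf_min=%s)", info_min, maf_min)
    out = SumStatTable(kept, trait_type=table.trait_type, population=table.population)
    out.qc_counts = counts
    return out
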