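"""LD reference panels, LD-proxy credible sets and clumping.

A published locus is represented not by its sentinel variant alone but by an
LD-proxy credible set: the sentinel plus all variants in high LD with it
(r^2 >= 0.8 by default) within a +/-50 kb window whose discovery p-value is
below 100x the sentinel's. This absorbs differences in LD patterns between
the discovery and target populations when asking whether the locus signal
replicates. r^2 is computed from reference-panel dosages (composite LD),
which is robust to unphased panels.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .sumstats import SumStatRecord, SumStatTable, VariantKey

logger = logging.getLogger("patloc")


class PanelLookupError(KeyError):
    """A variant requested from the panel is not present."""


class GenotypePanel:
    """Reference-panel dosage matrix with lookup by :class:`VariantKey`.

    Dosages are per-sample effect-allele counts in [0, 2]; missing entries
    (NaN) are mean-imputed once at load. A variant stored with swapped
    alleles relative to a query key resolves to the same column (its dosage
    is ``2 - d``; correlations are unaffected either way, scores are not, so
    the orientation flag is tracked).
    """

    def __init__(
        self,
        variants: Sequence[VariantKey],
        dosages: np.ndarray,
        population: str | None = None,
    ) -> None:
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2 or dosages.shape[1] != len(variants):
            raise ValueError(
                f"dosage matrix shape {dosages.shape} does not match {len(variants)} variants"
            )
        # mean-impute missing calls per variant before any correlation
        if np.isnan(dosages).any():
            col_mean = np.nanmean(dosages, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(np.isnan(dosages))
            dosages[idx] = np.take(col_mean, idx[1])
        self._dosages = dosages
        self.population = population
        self.variants: list[VariantKey] = []
        self._index: dict[VariantKey, int] = {}
        for j, key in enumerate(variants):
            if key in self._index:  # deduplicate, keep first occurrence
                continue
            self.variants.append(key)
            self._index[key] = j

    @property
    def n_samples(self) -> int:
        return self._dosages.shape[0]

    def __contains__(self, key: VariantKey) -> bool:
        return self._locate(key) is not None

    def _locate(self, key: VariantKey) -> tuple[int, bool] | None:
        for query, same in (
            (key, True),
            (key.complemented(), True),
            (key.swapped(), False),
            (key.swapped().complemented(), False),
        ):
            j = self._index.get(query)
            if j is not None:
                return j, same
        return None

    def dosage(self, key: VariantKey) -> np.ndarray:
        """Effect-allele dosage vector for ``key`` (orientation-corrected)."""
        loc = self._locate(key)
        if loc is None:
            raise PanelLookupError(f"variant {key} not in panel")
        j, same = loc
        col = self._dosages[:, j]
        return col if same else 2.0 - col

    def subset_window(self, chrom: str, start: int, end: int) -> list[VariantKey]:
        """Panel variants with start <= pos <= end on ``chrom``."""
        chrom = str(chrom)
        return [k for k in self.variants if k.chrom == chrom and start <= k.pos <= end]

    def r2_with(self, anchor: VariantKey, candidates: Sequence[VariantKey]) -> np.ndarray:
        """Vectorised r^2 of one anchor variant against many candidates.

        Monomorphic candidates get r^2 = NaN rather than an error.
        """
        a = self.dosage(anchor)
        a = a - a.mean()
        denom_a = float(np.sqrt(np.sum(a * a)))
        if denom_a == 0.0:
            raise ValueError(f"monomorphic anchor variant {anchor}")
        cols = np.column_stack([self._dosages[:, self._locate(k)[0]] for k in candidates])
        cols = cols - cols.mean(axis=0)
        denom = np.sqrt(np.sum(cols * cols, axis=0)) * denom_a
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (a @ cols) / denom
        r2 = np.where(denom > 0, r * r, np.nan)
        return np.minimum(r2, 1.0)

    # -- readers ----------------------------------------------------------

    @classmethod
    def from_vcf(cls, path: str, population: str | None = None) -> "GenotypePanel":
        """Load biallelic rows from a VCF, preferring DS over GT."""
        from cyvcf2 import VCF

        keys: list[VariantKey] = []
        cols: list[np.ndarray] = []
        vcf = VCF(path, gts012=True)  # gt_types: 0/1/2 = alt count, 3 = missing
        for variant in vcf:
            if len(variant.ALT) != 1:
                continue
            key = VariantKey(str(variant.CHROM), variant.POS, variant.ALT[0], variant.REF)
            try:
                ds = variant.format("DS")
            except KeyError:
                ds = None
            if ds is not None:
                col = np.asarray(ds, dtype=float).reshape(-1)
            else:
                gt = np.asarray(variant.gt_types, dtype=float)
                col = np.where(gt == 3, np.nan, gt)
            keys.append(key)
            cols.append(col)
        vcf.close()
        if not keys:
            raise ValueError(f"no biallelic variants in {path}")
        return cls(keys, np.column_stack(cols), population=population)

    @classmethod
    def from_plink(cls, prefix: str, population: str | None = None) -> "GenotypePanel":
        """Load a PLINK bed/bim/fam triple (SNP-major .bed, 2-bit codes)."""
        prefix = str(prefix)
        bim = [line.split() for line in Path(prefix + ".bim").read_text().splitlines() if line]
        fam = [line for line in Path(prefix + ".fam").read_text().splitlines() if line.strip()]
        n_samples, n_variants = len(fam), len(bim)
        raw = Path(prefix + ".bed").read_bytes()
        magic, mode = struct.unpack_from("<HB", raw)
        if magic != 0x1B6C or mode != 1:
            raise ValueError(f"{prefix}.bed is not a SNP-major PLINK bed file")
        bytes_per_variant = (n_samples + 3) // 4
        body = np.frombuffer(raw, dtype=np.uint8, offset=3)
        if body.size != bytes_per_variant * n_variants:
            raise ValueError(f"{prefix}.bed size inconsistent with bim/fam")
        body = body.reshape(n_variants, bytes_per_variant)
        # unpack two-bit genotype codes, sample-fastest within each byte
        shifts = np.arange(4, dtype=np.uint8) * 2
        codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
        codes = codes.reshape(n_variants, -1)[:, :n_samples]
        # 00=hom A1 (2 copies of allele1), 01=missing, 10=het, 11=hom A2
        lut = np.array([2.0, np.nan, 1.0, 0.0])
        dosages = lut[codes].T  # samples x variants, counting allele1 (bim col 5)
        keys = [VariantKey(row[0], int(row[3]), row[4], row[5]) for row in bim]
        return cls(keys, dosages, population=population)


def ld_r2(panel: GenotypePanel, v1: VariantKey, v2: VariantKey) -> float:
    """Squared Pearson correlation of dosage vectors (composite LD)."""
    d1, d2 = panel.dosage(v1), panel.dosage(v2)
    s1, s2 = d1.std(), d2.std()
    if s1 == 0.0 or s2 == 0.0:
        raise ValueError(f"monomorphic variant in panel: {v1 if s1 == 0 else v2}")
    r = float(np.corrcoef(d1, d2)[0, 1])
    return min(r * r, 1.0)


# ---------------------------------------------------------------------------
# credible sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CredMember:
    """One credible-set member with its LD to the sentinel and discovery stats."""

    key: VariantKey
    r2: float
    beta: float
    p: float


@dataclass
class CredibleSet:
    """Sentinel variant plus LD proxies defining one published locus."""

    locus_id: str
    sentinel: VariantKey
    members: list[CredMember]
    trait: str | None = None
    window: int = 50_000

    def __post_init__(self) -> None:
        keys = [m.key for m in self.members]
        if self.sentinel not in keys:
            raise ValueError(f"sentinel {self.sentinel} missing from members of {self.locus_id}")
        sentinel_member = self.members[keys.index(self.sentinel)]
        if sentinel_member.r2 != 1.0:
            raise ValueError("sentinel must carry r2 = 1 to itself")
        for m in self.members:
            if abs(m.key.pos - self.sentinel.pos) > self.window:
                raise ValueError(f"member {m.key} outside window of {self.locus_id}")

    @property
    def sentinel_p(self) -> float:
        return next(m.p for m in self.members if m.key == self.sentinel)

    @property
    def member_keys(self) -> set[VariantKey]:
        return {m.key for m in self.members}

    @property
    def span(self) -> tuple[int, int]:
        positions = [m.key.pos for m in self.members]
        return min(positions), max(positions)


def build_credible_set(
    discovery: SumStatTable,
    panel: GenotypePanel,
    sentinel: VariantKey,
    r2_min: float = 0.8,
    window: int = 50_000,
    p_mult: float = 100.0,
    locus_id: str | None = None,
    trait: str | None = None,
) -> CredibleSet:
    """LD-proxy credible set around a sentinel variant.

    Members are the sentinel plus every discovery variant within
    ``sentinel.pos +/- window`` (inclusive) with ``r2 >= r2_min`` to the
    sentinel and discovery p-value below ``p_mult`` times the sentinel's.
    Proxies present in the panel but absent from the discovery table are
    excluded (their p-value cannot be checked) and logged; a sentinel absent
    from the panel yields the degenerate singleton set with a warning.
    """
    sent_rec = discovery.get(sentinel)
    if sent_rec is None:
        match = discovery.lookup(sentinel)
        if match is None:
            raise KeyError(f"sentinel {sentinel} absent from discovery stats")
        sent_rec, _ = match
        sentinel = sent_rec.key
    locus_id = locus_id or str(sentinel)
    members = [CredMember(sentinel, 1.0, sent_rec.beta, sent_rec.p)]

    if sentinel not in panel:
        logger.warning("sentinel %s absent from LD panel; degenerate credible set", sentinel)
        return CredibleSet(locus_id, sentinel, members, trait=trait, window=window)

    p_cap = p_mult * sent_rec.p
    n_skipped = 0
    candidates = [
        cand
        for cand in panel.subset_window(sentinel.chrom, sentinel.pos - window, sentinel.pos + window)
        if not (cand.pos == sentinel.pos and {cand.ea, cand.oa} == {sentinel.ea, sentinel.oa})
    ]
    if candidates:
        r2_all = panel.r2_with(sentinel, candidates)
        for cand, r2 in zip(candidates, r2_all):
            match = discovery.lookup(cand)
            if match is None:
                n_skipped += 1
                continue
            rec, same = match
            if np.isfinite(r2) and r2 >= r2_min and rec.p < p_cap:
                # store discovery orientation so member signs are comparable
                members.append(CredMember(rec.key, float(r2), rec.beta, rec.p))
    if n_skipped:
        logger.info(
            "credible set %s: %d panel proxies absent from discovery stats excluded",
            locus_id, n_skipped,
        )
    return CredibleSet(locus_id, sentinel, members, trait=trait, window=window)


def _tiebreak(cs: CredibleSet) -> tuple:
    return (cs.sentinel_p, cs.sentinel.chrom, cs.sentinel.pos, cs.sentinel.ea)


def dedupe_loci(credsets: Iterable[CredibleSet]) -> list[CredibleSet]:
    """Resolve overlapping loci, keeping the most strongly associated.

    Sets conflict when they share any member variant or their sentinels lie
    within one window of each other. Conflicts are resolved greedily by
    ascending sentinel p (ties broken by genomic coordinates), so the output
    is deterministic and order-independent.
    """
    ordered = sorted(credsets, key=_tiebreak)
    kept: list[CredibleSet] = []
    for cs in ordered:
        clash = False
        for other in kept:
            if cs.member_keys & other.member_keys:
                clash = True
                break
            if (
                cs.sentinel.chrom == other.sentinel.chrom
                and abs(cs.sentinel.pos - other.sentinel.pos) <= max(cs.window, other.window)
            ):
                clash = True
                break
        if not clash:
            kept.append(cs)
    return kept


def clump(
    table: SumStatTable,
    panel: GenotypePanel,
    r2_max: float = 0.2,
    window: int = 50_000,
    p_threshold: float = 5e-8,
) -> list[VariantKey]:
    """Greedy LD clumping: approximately independent index variants.

    Candidates with ``p < p_threshold`` are visited by ascending p (ties by
    coordinates); a candidate is accepted when its r^2 with every previously
    accepted variant within ``window`` bp is below ``r2_max``. Variants
    absent from the panel cannot be assessed for independence and are
    skipped with a warning.
    """
    if not (0.0 < p_threshold <= 1.0):
        raise ValueError(f"p_threshold must be in (0, 1], got {p_threshold}")
    candidates = sorted(
        (r for r in table if r.p < p_threshold),
        key=lambda r: (r.p, r.key.chrom, r.key.pos, r.key.ea),
    )
    accepted: list[VariantKey] = []
    n_skipped = 0
    for rec in candidates:
        if rec.key not in panel:
            n_skipped += 1
            continue
        independent = True
        for idx in accepted:
            if idx.chrom == rec.key.chrom and abs(idx.pos - rec.key.pos) <= window:
                if ld_r2(panel, rec.key, idx) >= r2_max:
                    independent = False
                    break
        if independent:
            accepted.append(rec.key)
    if n_skipped:
        logger.warning("clump: %d significant variants absent from panel skipped", n_skipped)
    return accepted


def credsets_to_dataframe(credsets: Iterable[CredibleSet]):
    """Flatten credible sets to a TSV-ready table."""
    import pandas as pd

    rows = []
    for cs in credsets:
        for m in cs.members:
            rows.append(
                {
                    "locus_id": cs.locus_id,
                    "sentinel": str(cs.sentinel),
                    "member": str(m.key),
                    "r2": m.r2,
                    "discovery_beta": m.beta,
                    "discovery_p": m.p,
                }
            )
    return pd.DataFrame(rows, columns=["locus_id", "sentinel", "member", "r2", "discovery_beta", "discovery_p"])
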