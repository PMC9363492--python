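"""Power-adjusted transferability (PAT) of GWAS loci across populations.

A published locus is called *transferable* when at least one credible-set
variant is associated in the target population at two-sided p < 0.05 with a
direction of effect matching discovery. Raw transferable counts conflate
causal-variant sharing with statistical power, so the observed count O is
compared with the expected count E = sum of per-locus replication powers
(the count expected if every causal variant were shared). Their ratio O/E is
the PAT ratio; a one-sided lower-tail binomial test P(X <= O) with
X ~ Binomial(n_loci, E/n_loci) asks whether transferability falls short of
full sharing. The lower tail is used regardless of whether O exceeds E, so a
surplus of transferable loci yields p near 1 and a deficit yields small p.

Loci that fail to transfer despite high power are flagged separately: at
least one credible-set member with >80% replication power, yet no member
reaching p < 0.05 and no variant within 50 kb of the locus reaching
p < 1e-3 in the target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .ldcred import CredibleSet
from .power import PowerEstimate
from .sumstats import SumStatTable, VariantKey


@dataclass(frozen=True)
class TransferCall:
    """Transferability verdict for one published locus."""

    locus_id: str
    transferable: bool
    best_variant: VariantKey | None
    best_p: float | None
    direction_consistent: bool
    n_members_tested: int
    untestable: bool = False

    def __post_init__(self) -> None:
        if self.transferable and not self.direction_consistent:
            raise ValueError("a transferable call must be direction-consistent")


@dataclass(frozen=True)
class PATSummary:
    """Observed vs power-expected transferable loci for one trait."""

    trait: str
    n_loci: int
    observed: int
    expected: float
    observed_pct: float
    expected_pct: float
    pat_ratio: float
    binom_p: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass(frozen=True)
class NonTransferableFlag:
    """A well-powered locus with no replication signal in or near its span."""

    locus_id: str
    max_member_power: float
    min_member_p: float
    min_nearby_p: float


def call_transferable(
    credset: CredibleSet,
    target: SumStatTable,
    p_thresh: float = 0.05,
) -> TransferCall:
    """Call one locus transferable or not against target-population stats.

    The target table must already be harmonized to discovery orientation;
    direction consistency compares each member's own discovery sign with its
    target sign. Members absent from the target stats are skipped and
    counted; a locus with no testable member is an untestable
    non-transferable call.
    """
    best_qualifying: tuple[float, VariantKey] | None = None
    best_any: tuple[float, VariantKey, bool] | None = None
    n_tested = 0
    for member in credset.members:
        match = target.lookup(member.key)
        if match is None:
            continue
        rec, same = match
        n_tested += 1
        target_beta = rec.beta if same else -rec.beta
        consistent = np.sign(target_beta) == np.sign(member.beta) and member.beta != 0
        if best_any is None or rec.p < best_any[0]:
            best_any = (rec.p, member.key, bool(consistent))
        if rec.p < p_thresh and consistent:
            if best_qualifying is None or rec.p < best_qualifying[0]:
                best_qualifying = (rec.p, member.key)
    if n_tested == 0:
        return TransferCall(
            locus_id=credset.locus_id,
            transferable=False,
            best_variant=None,
            best_p=None,
            direction_consistent=False,
            n_members_tested=0,
            untestable=True,
        )
    if best_qualifying is not None:
        p, key = best_qualifying
        return TransferCall(credset.locus_id, True, key, p, True, n_tested)
    p, key, consistent = best_any
    return TransferCall(credset.locus_id, False, key, p, consistent, n_tested)


def binomial_deficit_p(observed: int, n_loci: int, expected_prop: float) -> float:
    """One-sided lower-tail binomial p-value P(X <= O), X ~ Bin(n, E/n)."""
    if not (0.0 < expected_prop <= 1.0):
        raise ValueError(f"expected proportion must be in (0, 1], got {expected_prop}")
    return float(stats.binom.cdf(observed, n_loci, expected_prop))


def poisson_binomial_deficit_p(observed: int, powers: Sequence[float]) -> float:
    """Exact lower-tail P(X <= O) for X a sum of heterogeneous Bernoullis.

    Sensitivity-analysis alternative to the binomial test, which collapses
    per-locus powers to their mean. Computed by direct convolution.
    """
    pmf = np.array([1.0])
    for p in powers:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return float(pmf[: observed + 1].sum())


def pat_summary(
    calls: Sequence[TransferCall],
    powers: Sequence[PowerEstimate],
    trait: str = "",
    exact: bool = False,
) -> PATSummary:
    """Summarise transferability for one trait.

    ``calls`` and ``powers`` must cover the same loci (one lead-variant
    power per published locus). With ``exact=True`` the binomial test is
    replaced by the exact Poisson-binomial lower tail over the per-locus
    powers.
    """
    if len(calls) != len(powers):
        raise ValueError(f"{len(calls)} calls vs {len(powers)} powers; must match per locus")
    call_ids = {c.locus_id for c in calls}
    power_ids = {p.locus_id for p in powers}
    if call_ids != power_ids:
        raise ValueError("calls and powers index different loci")
    n = len(calls)
    observed = sum(c.transferable for c in calls)
    expected = float(sum(p.power for p in powers))
    if expected <= 0.0:
        raise ValueError("expected transferable count is zero; PAT ratio undefined")
    if exact:
        binom_p = poisson_binomial_deficit_p(observed, [p.power for p in powers])
    else:
        binom_p = binomial_deficit_p(observed, n, expected / n)
    return PATSummary(
        trait=trait,
        n_loci=n,
        observed=observed,
        expected=expected,
        observed_pct=100.0 * observed / n,
        expected_pct=100.0 * expected / n,
        pat_ratio=observed / expected,
        binom_p=binom_p,
    )


def pat_ratio_from_percent(observed_pct: float, expected_pct: float) -> float:
    """PAT ratio from published observed/expected percentages.

    Worked-example entry point for reproducing reported tables where only
    rounded percentages are printed: the ratio of percentages equals O/E.
    """
    if expected_pct <= 0:
        raise ValueError("expected percentage must be positive")
    return observed_pct / expected_pct


def flag_nontransferable(
    credsets: Sequence[CredibleSet],
    member_powers: Mapping[str, Sequence[PowerEstimate]],
    target: SumStatTable,
    power_min: float = 0.80,
    set_p: float = 0.05,
    flank: int = 50_000,
    nearby_p: float = 1e-3,
) -> list[NonTransferableFlag]:
    """Flag well-powered loci with no replication signal.

    A locus is flagged when (i) its best credible-set member has replication
    power above ``power_min`` (each member powered with its own discovery
    effect), (ii) every member present in the target has p >= ``set_p``, and
    (iii) every target variant within ``flank`` bp of the locus span has
    p >= ``nearby_p`` (a nearby independent signal rescues the locus).
    """
    flags: list[NonTransferableFlag] = []
    for cs in credsets:
        powers = member_powers.get(cs.locus_id)
        if not powers:
            continue
        max_power = max(p.power for p in powers)
        if max_power <= power_min:
            continue
        member_ps = []
        for member in cs.members:
            match = target.lookup(member.key)
            if match is not None:
                member_ps.append(match[0].p)
        if not member_ps or min(member_ps) < set_p:
            continue
        lo, hi = cs.span
        nearby = target.in_window(cs.sentinel.chrom, lo - flank, hi + flank)
        min_nearby = min((r.p for r in nearby), default=1.0)
        if min_nearby < nearby_p:
            continue
        flags.append(
            NonTransferableFlag(
                locus_id=cs.locus_id,
                max_member_power=max_power,
                min_member_p=min(member_ps),
                min_nearby_p=min_nearby,
            )
        )
    return flags


def calls_to_dataframe(calls: Iterable[TransferCall]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "locus_id": c.locus_id,
                "transferable": c.transferable,
                "best_variant": str(c.best_variant) if c.best_variant else "",
                "best_p": c.best_p,
                "direction_consistent": c.direction_consistent,
                "n_members_tested": c.n_members_tested,
                "untestable": c.untestable,
            }
            for c in calls
        ]
    )
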