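"""Per-locus statistical power to replicate a discovery association.

The replication test in the target population is a two-sided association
test at level alpha combined with a direction-of-effect match. Under the
alternative, the association z-statistic is shifted by the square root of
the non-centrality parameter

    lambda = beta^2 * 2 f (1 - f) * N

with beta the discovery effect on a unit-variance phenotype (log odds ratio
for binary traits), f the effect-allele frequency in the target population
and N the target sample size (effective sample size
N_eff = 4 / (1/N_cases + 1/N_controls) for case-control designs). Power for
a direction-consistent rejection counts only the tail on the correct side:

    power = Phi(sqrt(lambda) - z_{1 - alpha/2})

which gives a floor of alpha/2 at beta = 0 (a null effect can still be
"replicated" by chance in the right direction) and saturates at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .sumstats import VariantKey


@dataclass(frozen=True)
class PowerEstimate:
    """Replication power of one locus (or credible-set member) in the target."""

    locus_id: str
    variant: VariantKey | None
    power: float
    ncp: float
    alpha: float
    trait_type: str

    def __post_init__(self) -> None:
        if self.ncp < 0:
            raise ValueError("non-centrality parameter must be >= 0")
        if not (0.0 <= self.power <= 1.0):
            raise ValueError("power must lie in [0, 1]")


def effective_sample_size(n_cases: float, n_controls: float) -> float:
    """Balanced-design equivalent of a case-control sample: 4/(1/Ncase + 1/Nctrl)."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("n_cases and n_controls must be positive")
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def replication_power(
    beta_discovery: float,
    eaf_target: float,
    n_target: float | None = None,
    alpha: float = 0.05,
    trait_type: str = "quantitative",
    n_cases: float | None = None,
    n_controls: float | None = None,
    locus_id: str = "",
    variant: VariantKey | None = None,
) -> PowerEstimate:
    """Power to observe a direction-consistent association in the target.

    Parameters
    ----------
    beta_discovery
        Discovery effect size per effect allele, on a standardized
        (unit-variance) phenotype scale for quantitative traits or the
        log odds ratio for binary traits.
    eaf_target
        Effect-allele frequency in the target population, in (0, 1).
    n_target
        Target sample size (quantitative traits). For binary traits supply
        ``n_cases`` and ``n_controls`` instead; the effective sample size
        is used in the non-centrality parameter.
    alpha
        Two-sided significance level of the replication test.
    """
    if not (0.0 < eaf_target < 1.0):
        raise ValueError(f"eaf_target must be in (0, 1), got {eaf_target}")
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if trait_type == "binary":
        if n_cases is None or n_controls is None:
            raise ValueError("binary trait power requires n_cases and n_controls")
        n_eff = effective_sample_size(n_cases, n_controls)
    elif trait_type == "quantitative":
        if n_target is None or n_target <= 0:
            raise ValueError("quantitative trait power requires n_target > 0")
        n_eff = float(n_target)
    else:
        raise ValueError(f"unknown trait_type {trait_type!r}")

    ncp = beta_discovery**2 * 2.0 * eaf_target * (1.0 - eaf_target) * n_eff
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    power = float(stats.norm.cdf(np.sqrt(ncp) - z_crit))
    return PowerEstimate(
        locus_id=locus_id,
        variant=variant,
        power=power,
        ncp=float(ncp),
        alpha=alpha,
        trait_type=trait_type,
    )


def expected_transferable(powers: Sequence[PowerEstimate]) -> tuple[float, float]:
    """Expected transferable-locus count and proportion under full sharing.

    Summing per-locus replication powers gives the number of loci expected
    to reach significance in the target if every causal variant were shared;
    the proportion is that sum over the number of loci.
    """
    if len(powers) == 0:
        raise ValueError("expected_transferable requires at least one locus")
    expected = float(sum(p.power for p in powers))
    return expected, expected / len(powers)


def power_table(powers: Iterable[PowerEstimate]):
    """TSV-ready per-locus power table."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "locus_id": p.locus_id,
                "variant": str(p.variant) if p.variant is not None else "",
                "lambda": p.ncp,
                "power": p.power,
                "alpha": p.alpha,
                "trait_type": p.trait_type,
            }
            for p in powers
        ]
    )
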