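"""Two-sample Mendelian randomisation with transferability-aware instruments.

Estimates the causal effect of an exposure (e.g. LDL cholesterol) on an
outcome (e.g. coronary artery disease) from summary statistics, using
genetic variants as instruments. Three instrument-selection strategies are
supported, reflecting the trans-ancestry setting:

``published``
    loci genome-wide significant (p < 5e-8) in the large discovery-ancestry
    exposure GWAS;
``transferable``
    the subset of those loci that transfer to the target population
    (credible-set replication with direction match), keeping the precise
    discovery-ancestry effect sizes — valid instruments in the target
    without sacrificing precision;
``ancestry_matched``
    loci significant in an independent ancestry-matched exposure GWAS
    (fallback threshold 5e-5 when genome-wide significant hits are too few),
    LD-clumped to r^2 < 0.2 in a 50 kb window.

The primary estimator is inverse-variance weighted (IVW) under a
multiplicative random-effects model; Cochran's Q, the MR-Egger intercept,
and weighted median/mode estimators probe heterogeneity and pleiotropy.
A weighted multivariable regression (MVMR) estimates direct effects of
correlated exposures (e.g. the three lipid fractions) jointly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .ldcred import CredibleSet, GenotypePanel, clump
from .pat import TransferCall
from .sumstats import SumStatTable, VariantKey, harmonize_pair

logger = logging.getLogger("patloc")


@dataclass(frozen=True)
class Instrument:
    """Per-variant exposure and outcome associations on one effect allele."""

    variant: VariantKey
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float

    def __post_init__(self) -> None:
        if self.se_x <= 0 or self.se_y <= 0:
            raise ValueError(f"standard errors must be positive at {self.variant}")

    @property
    def wald_ratio(self) -> float:
        return self.beta_y / self.beta_x

    @property
    def wald_se(self) -> float:
        """First-order delta-method SE of the ratio (exposure error ignored)."""
        return self.se_y / abs(self.beta_x)


@dataclass(frozen=True)
class MREstimate:
    """One causal-effect estimate with heterogeneity diagnostics."""

    method: str
    beta: float
    se: float
    p: float
    n_snp: int
    Q: float | None = None
    Q_p: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    exposure: str = ""

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95(self) -> tuple[float, float]:
        return self.beta - 1.959963984540054 * self.se, self.beta + 1.959963984540054 * self.se


# ---------------------------------------------------------------------------
# instrument selection
# ---------------------------------------------------------------------------


def _pair_with_outcome(
    exposure: SumStatTable, outcome: SumStatTable, keys: Sequence[VariantKey]
) -> list[Instrument]:
    """Harmonize selected exposure variants to the outcome and build instruments."""
    instruments: list[Instrument] = []
    n_dropped = 0
    seen: set[tuple[str, int]] = set()
    for key in keys:
        site = (key.chrom, key.pos)
        if site in seen:
            n_dropped += 1
            continue
        exp_match = exposure.lookup(key)
        out_match = outcome.lookup(key)
        if exp_match is None or out_match is None:
            n_dropped += 1
            continue
        exp_rec, _ = exp_match
        result = harmonize_pair(exp_rec, out_match[0])
        if not result.ok:
            logger.info("instrument %s dropped during harmonization: %s", key, result.reason)
            n_dropped += 1
            continue
        out_rec = result.record
        seen.add(site)
        instruments.append(
            Instrument(
                variant=exp_rec.key,
                beta_x=exp_rec.beta,
                se_x=exp_rec.se,
                beta_y=out_rec.beta,
                se_y=out_rec.se,
            )
        )
    if n_dropped:
        logger.info("instrument selection: %d variants dropped (missing/ambiguous/duplicate)", n_dropped)
    return instruments


Strategy = Literal["published_eur", "transferable", "ancestry_matched"]


def select_instruments(
    strategy: Strategy,
    exposure: SumStatTable,
    outcome: SumStatTable,
    p_threshold: float = 5e-8,
    fallback_p: float = 5e-5,
    credsets: Sequence[CredibleSet] | None = None,
    calls: Sequence[TransferCall] | None = None,
    panel: GenotypePanel | None = None,
    clump_r2: float = 0.2,
    clump_window: int = 50_000,
) -> list[Instrument]:
    """Select and harmonize MR instruments under one of three strategies.

    ``published_eur`` filters the exposure table at ``p_threshold``.
    ``transferable`` takes sentinels of credible sets whose transferability
    call is positive, retaining the discovery effect sizes (and SEs).
    ``ancestry_matched`` filters the (ancestry-matched) exposure table at
    ``p_threshold``, engaging ``fallback_p`` when no variant qualifies, then
    LD-clumps using ``panel``.
    """
    if strategy == "published_eur":
        keys = [r.key for r in exposure if r.p < p_threshold]
        keys.sort(key=lambda k: (exposure.get(k).p, k.chrom, k.pos, k.ea))
    elif strategy == "transferable":
        if credsets is None or calls is None:
            raise ValueError("transferable strategy requires credsets and calls")
        transferable_ids = {c.locus_id for c in calls if c.transferable}
        keys = [cs.sentinel for cs in credsets if cs.locus_id in transferable_ids]
    elif strategy == "ancestry_matched":
        if panel is None:
            raise ValueError("ancestry_matched strategy requires an LD panel for clumping")
        threshold = p_threshold
        if not any(r.p < threshold for r in exposure):
            logger.warning(
                "no instrument at p < %.1e; engaging permissive fallback p < %.1e",
                p_threshold, fallback_p,
            )
            threshold = fallback_p
        keys = clump(exposure, panel, r2_max=clump_r2, window=clump_window, p_threshold=threshold)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    instruments = _pair_with_outcome(exposure, outcome, keys)
    if not instruments:
        raise ValueError(
            f"no instruments selected under strategy {strategy!r} "
            f"(p_threshold={p_threshold}, fallback={fallback_p})"
        )
    return instruments


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def _usable(instruments: Sequence[Instrument]) -> list[Instrument]:
    usable = [i for i in instruments if i.beta_x != 0.0]
    excluded = len(instruments) - len(usable)
    if excluded:
        logger.warning("%d instruments with zero exposure effect excluded", excluded)
    if not usable:
        raise ValueError("no usable instruments (all exposure effects zero)")
    return usable


def ivw_estimate(instruments: Sequence[Instrument], exposure: str = "") -> MREstimate:
    """Inverse-variance weighted estimate, multiplicative random effects.

    Per-SNP Wald ratios are combined with weights 1/se^2 (first-order SEs).
    Cochran's Q measures heterogeneity around the pooled estimate; the
    random-effects SE inflates the fixed-effect SE by
    sqrt(max(1, Q/(n_snp - 1))), never deflating it. A single instrument
    reduces to the Wald ratio.
    """
    inst = _usable(instruments)
    ratios = np.array([i.wald_ratio for i in inst])
    ses = np.array([i.wald_se for i in inst])
    weights = 1.0 / ses**2
    beta = float(np.sum(weights * ratios) / np.sum(weights))
    se_fixed = float(np.sqrt(1.0 / np.sum(weights)))
    n = len(inst)
    if n > 1:
        Q = float(np.sum(weights * (ratios - beta) ** 2))
        inflation = float(np.sqrt(max(1.0, Q / (n - 1))))
        Q_p = float(stats.chi2.sf(Q, n - 1))
    else:
        Q, Q_p, inflation = None, None, 1.0
    se = se_fixed * inflation
    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return MREstimate(
        method="ivw_random_effects" if n > 1 else "wald_ratio",
        beta=beta, se=se, p=p, n_snp=n, Q=Q, Q_p=Q_p, exposure=exposure,
    )


@dataclass(frozen=True)
class HeterogeneityReport:
    Q: float | None
    Q_p: float | None
    egger_intercept: float | None
    egger_intercept_se: float | None
    egger_intercept_p: float | None
    egger_beta: float | None
    egger_beta_se: float | None


def heterogeneity(
    instruments: Sequence[Instrument], ivw: MREstimate | None = None
) -> HeterogeneityReport:
    """Cochran's Q and the MR-Egger intercept (directional pleiotropy).

    Q is taken from (or recomputed as in) the IVW fit, with a chi-square
    reference on n_snp - 1 degrees of freedom. The Egger regression of
    outcome effects on exposure effects (weights 1/se_y^2, instruments
    oriented to positive exposure effect) needs at least 3 instruments; its
    intercept estimates the average directional pleiotropic effect.
    """
    inst = _usable(instruments)
    n = len(inst)
    if ivw is None and n >= 2:
        ivw = ivw_estimate(inst)
    Q = ivw.Q if ivw is not None else None
    Q_p = ivw.Q_p if ivw is not None else None
    if n < 3:
        return HeterogeneityReport(Q, Q_p, None, None, None, None, None)

    # orient all instruments to positive exposure effect (Egger convention)
    sign = np.array([1.0 if i.beta_x > 0 else -1.0 for i in inst])
    bx = np.array([i.beta_x for i in inst]) * sign
    by = np.array([i.beta_y for i in inst]) * sign
    w = np.array([1.0 / i.se_y**2 for i in inst])
    X = np.column_stack([np.ones(n), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ by)
    resid = by - X @ coef
    # multiplicative over-dispersion, floored at 1 (as for IVW)
    scale = max(1.0, float(np.sum(w * resid**2) / (n - 2)))
    cov = np.linalg.inv(xtwx) * scale
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    p_int = float(2.0 * stats.norm.sf(abs(intercept) / se_int))
    return HeterogeneityReport(Q, Q_p, intercept, se_int, p_int, slope, se_slope)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """50th weighted percentile with linear interpolation (Bowden estimator)."""
    order = np.argsort(values)
    values, weights = values[order], weights[order]
    cum = np.cumsum(weights) - 0.5 * weights
    cum /= np.sum(weights)
    return float(np.interp(0.5, cum, values))


def _weighted_mode(values: np.ndarray, weights: np.ndarray, phi: float = 1.0) -> float:
    """Mode of the kernel-smoothed weighted ratio density.

    Bandwidth follows the modified Silverman rule
    h = phi * 0.9 * min(sd, mad/0.6745) * n^(-1/5).
    """
    n = len(values)
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    mad = float(stats.median_abs_deviation(values, scale="normal"))
    spread = min(x for x in (sd, mad) if x > 0) if (sd > 0 or mad > 0) else 0.0
    if spread == 0.0:
        return float(values[0])
    h = phi * 0.9 * spread * n ** (-1 / 5)
    grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, 2048)
    dens = np.zeros_like(grid)
    wnorm = weights / weights.sum()
    for v, w in zip(values, wnorm):
        dens += w * np.exp(-0.5 * ((grid - v) / h) ** 2)
    return float(grid[np.argmax(dens)])


def robust_estimates(
    instruments: Sequence[Instrument],
    method: Literal["weighted_median", "weighted_mode"],
    n_boot: int = 1000,
    seed: int = 0,
    phi: float = 1.0,
    exposure: str = "",
) -> MREstimate:
    """Pleiotropy-robust estimators: weighted median and weighted mode.

    The weighted median is consistent when instruments carrying at least
    half the weight are valid; the weighted mode when the largest cluster
    of ratio estimates is valid. SEs come from a parametric bootstrap of
    the per-instrument effect estimates with a fixed seed.
    """
    inst = _usable(instruments)
    if len(inst) < 3:
        raise ValueError(f"{method} requires at least 3 instruments, got {len(inst)}")
    ratios = np.array([i.wald_ratio for i in inst])
    weights = 1.0 / np.array([i.wald_se for i in inst]) ** 2
    estimator = _weighted_median if method == "weighted_median" else (
        lambda v, w: _weighted_mode(v, w, phi=phi)
    )
    beta = estimator(ratios, weights)

    rng = np.random.default_rng(seed)
    bx = np.array([i.beta_x for i in inst])
    by = np.array([i.beta_y for i in inst])
    sx = np.array([i.se_x for i in inst])
    sy = np.array([i.se_y for i in inst])
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        ok = bx_b != 0
        r_b = by_b[ok] / bx_b[ok]
        w_b = (np.abs(bx_b[ok]) / sy[ok]) ** 2
        boots[b] = estimator(r_b, w_b)
    se = float(np.std(boots, ddof=1))
    p = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 1.0
    return MREstimate(method=method, beta=beta, se=se, p=p, n_snp=len(inst), exposure=exposure)


def mvmr_estimate(
    beta_x: np.ndarray,
    beta_y: np.ndarray,
    se_y: np.ndarray,
    exposures: Sequence[str] | None = None,
) -> list[MREstimate]:
    """Multivariable MR: direct effects of K exposures on the outcome.

    Weighted least-squares regression of outcome effects on the K columns of
    exposure effects without intercept, weights 1/se_y^2. With K = 1 the
    point estimate equals the fixed-effect IVW estimate exactly. SEs use a
    multiplicative over-dispersion factor floored at 1 (nesting the IVW
    random-effects model).
    """
    beta_x = np.atleast_2d(np.asarray(beta_x, dtype=float))
    if beta_x.shape[0] == 1 and len(beta_y) > 1:
        beta_x = beta_x.T
    beta_y = np.asarray(beta_y, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    n, k = beta_x.shape
    if n <= k:
        raise ValueError(f"MVMR needs more instruments ({n}) than exposures ({k})")
    if np.linalg.matrix_rank(beta_x) < k:
        raise ValueError("exposure effect matrix is rank-deficient (collinear exposures)")
    exposures = list(exposures) if exposures is not None else [f"exposure_{j}" for j in range(k)]
    w = 1.0 / se_y**2
    WX = beta_x * w[:, None]
    xtwx = beta_x.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ beta_y)
    resid = beta_y - beta_x @ coef
    scale = max(1.0, float(np.sum(w * resid**2) / (n - k))) if n > k else 1.0
    cov = np.linalg.inv(xtwx) * scale
    out = []
    for j, name in enumerate(exposures):
        se = float(np.sqrt(cov[j, j]))
        b = float(coef[j])
        out.append(
            MREstimate(
                method="mvmr", beta=b, se=se,
                p=float(2.0 * stats.norm.sf(abs(b) / se)),
                n_snp=n, exposure=name,
            )
        )
    return out


def mr_report(
    instruments: Sequence[Instrument],
    n_boot: int = 1000,
    seed: int = 0,
    exposure: str = "",
) -> dict:
    """Run the full estimator battery and return a JSON-ready report."""
    ivw = ivw_estimate(instruments, exposure=exposure)
    het = heterogeneity(instruments, ivw)
    report = {
        "exposure": exposure,
        "n_snp": ivw.n_snp,
        "ivw": _est_dict(ivw),
        "heterogeneity": {
            "Q": het.Q, "Q_p": het.Q_p,
            "egger_intercept": het.egger_intercept,
            "egger_intercept_se": het.egger_intercept_se,
            "egger_intercept_p": het.egger_intercept_p,
        },
        "mr_presso": "not run (external method)",
    }
    if ivw.n_snp >= 3:
        for method in ("weighted_median", "weighted_mode"):
            est = robust_estimates(instruments, method, n_boot=n_boot, seed=seed, exposure=exposure)
            report[method] = _est_dict(est)
    return report


def _est_dict(est: MREstimate) -> dict:
    lo, hi = est.ci95
    return {
        "method": est.method,
        "beta": est.beta,
        "se": est.se,
        "p": est.p,
        "odds_ratio": est.odds_ratio,
        "or_ci95": [float(np.exp(lo)), float(np.exp(hi))],
        "n_snp": est.n_snp,
        "Q": est.Q,
        "Q_p": est.Q_p,
    }
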