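"""Polygenic score computation and clinical-performance evaluation.

A polygenic score (PGS) is a weighted sum of effect-allele dosages. Its
clinical value in a cohort is judged against a covariate baseline (sex, age,
age^2 and the first 10 genetic principal components):

* incremental R^2 / AUC — gain in variance explained (linear model) or
  discrimination (logistic model, AUC by the Mann-Whitney rank statistic)
  when the standardized PGS is added to the covariate-only model;
* relative accuracy — ratio of the incremental metric in a target
  population to that in a reference population, the standard measure of
  PGS portability;
* OR per SD and per-quantile ORs — effect sizes from the full logistic
  model, with quantile cut-points defined among controls;
* net reclassification improvement (NRI) — for an updated risk score
  against an established clinical one,
  NRI = P(up|case) - P(down|case) + P(down|noncase) - P(up|noncase),
  in categorical form (crossing a 10% high-risk threshold) or continuous
  form (any change in predicted risk).

Confidence intervals come from percentile bootstrap over individuals with a
fixed seed (bit-reproducible).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ldcred import GenotypePanel
from .sumstats import VariantKey

logger = logging.getLogger("patloc")

COVARIATE_COLUMNS = ["sex", "age"] + [f"pc{i}" for i in range(1, 11)]


# ---------------------------------------------------------------------------
# PGS weights and scoring
# ---------------------------------------------------------------------------


@dataclass
class PGSWeights:
    """Scoring weights: one (variant, effect allele, weight) entry per SNP."""

    entries: pd.DataFrame  # columns: chrom, pos, ea, oa, weight
    score_id: str = ""

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "ea", "oa", "weight"}
        if not required.issubset(self.entries.columns):
            raise ValueError(f"weight table needs columns {sorted(required)}")
        if not np.isfinite(self.entries["weight"]).all():
            raise ValueError("weights must be finite")
        keys = self.keys()
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate variants in weight file")

    def keys(self) -> list[VariantKey]:
        return [
            VariantKey(str(r.chrom), int(r.pos), str(r.ea), str(r.oa))
            for r in self.entries.itertuples()
        ]

    def __len__(self) -> int:
        return len(self.entries)


def read_pgs_weights(path: str, score_id: str | None = None) -> PGSWeights:
    """Read a PGS Catalog scoring file.

    Metadata lines starting with ``#`` are skipped; the header provides
    ``effect_allele``, ``effect_weight`` and either ``rsID`` or
    ``chr_name``/``chr_position`` columns (harmonized position columns
    ``hm_chr``/``hm_pos`` are preferred when present).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    chrom_col = cols.get("hm_chr") or cols.get("chr_name")
    pos_col = cols.get("hm_pos") or cols.get("chr_position")
    if chrom_col is None or pos_col is None:
        raise ValueError(f"{path}: no chromosome/position columns found")
    if "effect_allele" not in cols or "effect_weight" not in cols:
        raise ValueError(f"{path}: missing effect_allele or effect_weight column")
    other = cols.get("other_allele") or cols.get("reference_allele")
    entries = pd.DataFrame(
        {
            "chrom": df[chrom_col].astype(str),
            "pos": df[pos_col].astype(float).astype(int),
            "ea": df[cols["effect_allele"]].str.upper(),
            "oa": df[other].str.upper() if other else "N",
            "weight": df[cols["effect_weight"]].astype(float),
        }
    )
    return PGSWeights(entries, score_id=score_id or str(path))


def score_pgs(
    dosages: GenotypePanel, weights: PGSWeights
) -> tuple[np.ndarray, float]:
    """Per-individual PGS: weighted sum of effect-allele dosages.

    Dosages are orientation-corrected to each weight's effect allele via the
    panel lookup (swapped storage yields ``2 - d``). Variants absent from
    the dosage data are skipped and counted; returns the score vector and
    the coverage fraction (variants scored / variants in the file).

    Raises if no weight-file variant overlaps the dosage data.
    """
    scores = np.zeros(dosages.n_samples)
    n_used = 0
    for key, weight in zip(weights.keys(), weights.entries["weight"].to_numpy()):
        try:
            d = dosages.dosage(key)
        except KeyError:
            continue
        scores += weight * d
        n_used += 1
    if n_used == 0:
        raise ValueError(f"no overlap between weight file {weights.score_id!r} and dosage data")
    coverage = n_used / len(weights)
    if coverage < 1.0:
        logger.info("score_pgs: %d/%d weight variants found (coverage %.1f%%)",
                    n_used, len(weights), 100 * coverage)
    return scores, coverage


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """Per-individual phenotypes and covariates for PGS evaluation.

    ``data`` columns: ``id``, ``sex``, ``age``, ``pc1``..``pc10``, the
    outcome column, optionally a clinical 10-year risk in [0, 1] and a
    ``pgs`` column. Age is the age relevant to the outcome (at recruitment
    for disease status, at measurement for quantitative traits); the caller
    selects which to load.
    """

    data: pd.DataFrame
    outcome: str
    binary: bool
    clinical_risk: str | None = None

    def __post_init__(self) -> None:
        missing = [c for c in COVARIATE_COLUMNS + ["id", self.outcome] if c not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        if self.data["id"].duplicated().any():
            raise ValueError("duplicate individual ids in cohort table")
        if self.clinical_risk is not None:
            risk = self.data[self.clinical_risk]
            if ((risk < 0) | (risk > 1)).any():
                raise ValueError("clinical risk must lie in [0, 1]")
        if self.binary:
            values = set(self.data[self.outcome].dropna().unique())
            if not values.issubset({0, 1}):
                raise ValueError(f"binary outcome must be 0/1, found {sorted(values)[:5]}")

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_tsv(cls, path: str, outcome: str, binary: bool,
                 clinical_risk: str | None = None) -> "CohortTable":
        return cls(pd.read_csv(path, sep="\t"), outcome, binary, clinical_risk)


def _design(df: pd.DataFrame, with_pgs: bool) -> np.ndarray:
    cols = [df["sex"], df["age"], df["age"] ** 2] + [df[f"pc{i}"] for i in range(1, 11)]
    if with_pgs:
        pgs = df["pgs"].to_numpy(dtype=float)
        cols.append(pd.Series(pgs, index=df.index))
    X = np.column_stack([np.ones(len(df))] + [np.asarray(c, dtype=float) for c in cols])
    return X


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("PGS has zero variance; cannot standardize")
    return (x - x.mean()) / sd


def _auc_rank(y: np.ndarray, score: np.ndarray) -> float:
    """AUC via the Mann-Whitney rank statistic."""
    from scipy.stats import rankdata

    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined without both cases and noncases")
    ranks = rankdata(score)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _fit_metric(df: pd.DataFrame, metric: str) -> float:
    """Incremental metric on one (possibly resampled) cohort frame."""
    y = df["__y"].to_numpy(dtype=float)
    X_full, X_ref = _design(df, True), _design(df, False)
    if metric == "r2":
        full = sm.OLS(y, X_full).fit()
        ref = sm.OLS(y, X_ref).fit()
        return float(full.rsquared - ref.rsquared)
    # logistic AUC
    full = sm.Logit(y, X_full).fit(disp=0, maxiter=200)
    ref = sm.Logit(y, X_ref).fit(disp=0, maxiter=200)
    return _auc_rank(y, full.predict(X_full)) - _auc_rank(y, ref.predict(X_ref))


@dataclass(frozen=True)
class MetricEstimate:
    """A point estimate with percentile-bootstrap CI and the bootstrap draws."""

    value: float
    ci_low: float
    ci_high: float
    n_boot: int
    boot: np.ndarray = field(repr=False, default=None)


def incremental_metric(
    cohort: CohortTable,
    metric: Literal["r2", "auc"],
    n_boot: int = 1000,
    seed: int = 0,
) -> MetricEstimate:
    """Incremental R^2 or AUC of the PGS over the covariate baseline.

    Fits the full model (standardized PGS + sex, age, age^2, 10 PCs) and the
    reference model (covariates only); the incremental metric is their
    difference, with a percentile bootstrap CI over individuals.
    """
    if metric not in ("r2", "auc"):
        raise ValueError(f"metric must be r2|auc, got {metric!r}")
    if metric == "auc" and not cohort.binary:
        raise ValueError("AUC requires a binary outcome")
    if "pgs" not in cohort.data.columns:
        raise ValueError("cohort table has no 'pgs' column")
    df = cohort.data.copy()
    if cohort.binary and df[cohort.outcome].sum() < 10:
        raise ValueError("fewer than 10 cases; incremental metric unreliable")
    df["pgs"] = _standardize(df["pgs"].to_numpy(dtype=float))
    df["__y"] = df[cohort.outcome]
    value = _fit_metric(df, metric)

    rng = np.random.default_rng(seed)
    n = len(df)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = df.iloc[idx]
        if cohort.binary and sample["__y"].nunique() < 2:
            boots[b] = np.nan
            continue
        try:
            boots[b] = _fit_metric(sample, metric)
        except (np.linalg.LinAlgError, ValueError):
            boots[b] = np.nan
    good = boots[~np.isnan(boots)]
    lo, hi = np.percentile(good, [2.5, 97.5])
    return MetricEstimate(value, float(lo), float(hi), n_boot, boot=boots)


def relative_accuracy(
    target: MetricEstimate, reference: MetricEstimate, seed: int = 0
) -> MetricEstimate:
    """Portability: incremental metric in target over reference population.

    The CI pairs the two (independent) bootstrap distributions draw-by-draw
    after a seeded shuffle, so cohorts bootstrapped with different replicate
    counts or orderings still combine correctly.
    """
    if reference.value <= 0:
        raise ValueError("reference incremental metric must be positive for a ratio")
    ratio = target.value / reference.value
    if target.boot is None or reference.boot is None:
        return MetricEstimate(ratio, np.nan, np.nan, 0)
    rng = np.random.default_rng(seed)
    t = target.boot[~np.isnan(target.boot)]
    r = reference.boot[~np.isnan(reference.boot)]
    m = min(len(t), len(r))
    t = rng.permutation(t)[:m]
    r = rng.permutation(r)[:m]
    ok = r > 0
    ratios = t[ok] / r[ok]
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return MetricEstimate(ratio, float(lo), float(hi), m, boot=ratios)


# ---------------------------------------------------------------------------
# odds ratios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuantileOR:
    quantile: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    n: int


def quantile_or(
    cohort: CohortTable, q: int = 5, reference: int | None = None
) -> tuple[list[QuantileOR], tuple[float, float, float]]:
    """Per-quantile odds ratios and OR per SD of the PGS.

    Quantile cut-points are computed among controls only and applied to
    everyone (ties go to the lower quantile; the reference is the middle
    quantile). Each OR comes from a logistic model of the outcome on the
    quantile indicators plus the covariates; OR per SD from the continuous
    model. Returns (per-quantile ORs, (or_per_sd, ci_low, ci_high)).
    """
    if not cohort.binary:
        raise ValueError("quantile ORs require a binary outcome")
    df = cohort.data.copy()
    df["pgs"] = _standardize(df["pgs"].to_numpy(dtype=float))
    y = df[cohort.outcome].to_numpy(dtype=float)
    controls = df.loc[y == 0, "pgs"]
    cuts = np.quantile(controls, np.linspace(0, 1, q + 1)[1:-1])
    bins = np.searchsorted(cuts, df["pgs"].to_numpy(), side="right")
    counts = np.bincount(bins, minlength=q)
    if (counts == 0).any():
        raise ValueError(f"empty PGS quantile (counts {counts.tolist()})")
    reference = (q - 1) // 2 if reference is None else reference

    covar = _design(df, False)
    indicators = np.column_stack(
        [(bins == j).astype(float) for j in range(q) if j != reference]
    )
    X = np.column_stack([covar, indicators])
    fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    out: list[QuantileOR] = []
    j_param = covar.shape[1]
    for j in range(q):
        if j == reference:
            out.append(QuantileOR(j + 1, 1.0, 1.0, 1.0, int(counts[j])))
            continue
        b, se = fit.params[j_param], fit.bse[j_param]
        out.append(
            QuantileOR(
                j + 1,
                float(np.exp(b)),
                float(np.exp(b - 1.959963984540054 * se)),
                float(np.exp(b + 1.959963984540054 * se)),
                int(counts[j]),
            )
        )
        j_param += 1

    X_cont = _design(df, True)
    fit_cont = sm.Logit(y, X_cont).fit(disp=0, maxiter=200)
    b, se = fit_cont.params[-1], fit_cont.bse[-1]
    per_sd = (
        float(np.exp(b)),
        float(np.exp(b - 1.959963984540054 * se)),
        float(np.exp(b + 1.959963984540054 * se)),
    )
    return out, per_sd


# ---------------------------------------------------------------------------
# net reclassification improvement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReclassificationTable:
    """Up/down/same movements of predicted risk, split by case status."""

    up_cases: int
    down_cases: int
    same_cases: int
    up_noncases: int
    down_noncases: int
    same_noncases: int
    mode: str  # "categorical@<threshold>" or "continuous"

    @property
    def n_cases(self) -> int:
        return self.up_cases + self.down_cases + self.same_cases

    @property
    def n_noncases(self) -> int:
        return self.up_noncases + self.down_noncases + self.same_noncases


@dataclass(frozen=True)
class NRIResult:
    nri: float
    nri_cases: float
    nri_noncases: float
    ci_low: float
    ci_high: float
    table: ReclassificationTable


def _classify_moves(
    old: np.ndarray, new: np.ndarray, mode: str, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    if mode == "categorical":
        old_high = old >= threshold
        new_high = new >= threshold
        up = new_high & ~old_high
        down = ~new_high & old_high
    else:
        up = new > old
        down = new < old
    return up, down


def _nri_components(
    old: np.ndarray, new: np.ndarray, case: np.ndarray, mode: str, threshold: float
) -> tuple[float, float, ReclassificationTable]:
    up, down = _classify_moves(old, new, mode, threshold)
    n_case = int(case.sum())
    n_non = int((~case).sum())
    if n_case == 0 or n_non == 0:
        raise ValueError("NRI requires both cases and noncases")
    nri_cases = (up[case].sum() - down[case].sum()) / n_case
    nri_non = (down[~case].sum() - up[~case].sum()) / n_non
    table = ReclassificationTable(
        up_cases=int(up[case].sum()),
        down_cases=int(down[case].sum()),
        same_cases=int(n_case - up[case].sum() - down[case].sum()),
        up_noncases=int(up[~case].sum()),
        down_noncases=int(down[~case].sum()),
        same_noncases=int(n_non - up[~case].sum() - down[~case].sum()),
        mode=f"categorical@{threshold:g}" if mode == "categorical" else "continuous",
    )
    return float(nri_cases), float(nri_non), table


def nri(
    old_risk: Sequence[float],
    new_risk: Sequence[float],
    case_status: Sequence[int],
    mode: Literal["categorical", "continuous"] = "categorical",
    threshold: float = 0.10,
    n_boot: int = 1000,
    seed: int = 0,
    strata: Mapping[str, np.ndarray] | None = None,
) -> NRIResult | dict[str, NRIResult]:
    """Net reclassification improvement of ``new_risk`` over ``old_risk``.

    Categorical mode counts crossings of the high-risk ``threshold``
    (upward and downward); continuous mode counts any change in predicted
    risk. NRI = P(up|case) - P(down|case) + P(down|noncase) - P(up|noncase),
    bounded in [-2, 2]. The bootstrap resamples individuals jointly (cases
    and noncases together) with a fixed seed. When ``strata`` maps labels to
    boolean masks, a per-stratum result dict is returned (e.g. age bands).
    """
    old = np.asarray(old_risk, dtype=float)
    new = np.asarray(new_risk, dtype=float)
    case = np.asarray(case_status).astype(bool)
    if not (len(old) == len(new) == len(case)):
        raise ValueError("old_risk, new_risk, case_status must have equal length")
    if mode == "categorical" and (
        (old < 0).any() or (old > 1).any() or (new < 0).any() or (new > 1).any()
    ):
        raise ValueError("risks must lie in [0, 1]")

    if strata is not None:
        return {
            label: nri(old[mask], new[mask], case[mask], mode=mode,
                       threshold=threshold, n_boot=n_boot, seed=seed)
            for label, mask in strata.items()
        }

    nri_cases, nri_non, table = _nri_components(old, new, case, mode, threshold)
    point = nri_cases + nri_non

    rng = np.random.default_rng(seed)
    n = len(old)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        c = case[idx]
        if c.all() or not c.any():
            boots[b] = np.nan
            continue
        bc, bn, _ = _nri_components(old[idx], new[idx], c, mode, threshold)
        boots[b] = bc + bn
    good = boots[~np.isnan(boots)]
    lo, hi = (np.percentile(good, [2.5, 97.5]) if len(good) else (np.nan, np.nan))
    return NRIResult(point, nri_cases, nri_non, float(lo), float(hi), table)
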