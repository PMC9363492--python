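"""Synthetic GWAS and cohort data with controllable causal-variant sharing.

The generator produces matched discovery/target GWAS summary statistics, an
LD reference panel, and individual-level cohorts, so the whole analysis
stack is testable without any restricted data.

Loci are AR(1) LD blocks: adjacent variants correlate at rho, so the
correlation to the causal variant decays as rho^distance, with a closed
form for every expected marginal association. Within a block, summary
z-scores follow the standard summary-statistic model

    z ~ MVN(mu, R),   mu_i = r_ic * sqrt(2 f (1 - f) N) * beta_c,

where R is the block LD matrix, r_ic the correlation of variant i with the
causal variant c, f the effect-allele frequency and N the GWAS sample size
(effective sample size for case-control designs). The target population
shares each causal effect with probability ``sharing``; unshared loci have
their target effect set to zero. Allele-frequency divergence between the
populations follows a Balding-Nichols perturbation with a fixed F
parameter, emulating modest continental drift without claiming demographic
realism.

Every entry point takes a mandatory seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ldcred import GenotypePanel
from .pgseval import PGSWeights
from .sumstats import SumStatRecord, SumStatTable, VariantKey

_P_FLOOR = 1e-300


@dataclass
class SimConfig:
    """Study conditions for a discovery/target GWAS pair.

    Defaults emulate a large European-ancestry discovery meta-analysis
    (N = 300k) read out in a target cohort of ~16k individuals (the scale of
    a community biobank), with a 500-sample LD reference panel, 25-variant
    AR(1) blocks (rho = 0.97, 2 kb spacing) and modest allele-frequency
    divergence (F = 0.01).
    """

    n_loci: int = 100
    sharing: float = 1.0
    effect_sd: float = 0.04
    effect_size: float | None = None  # fixed |beta| overriding effect_sd
    block_size: int = 25
    rho: float = 0.97
    spacing_bp: int = 2_000
    af_range: tuple[float, float] = (0.05, 0.95)
    fst: float = 0.01
    n_discovery: int = 300_000
    n_target: int = 16_000
    n_cases: int | None = None
    n_controls: int | None = None
    n_panel: int = 500
    trait_type: str = "quantitative"
    seed: int | None = None

    def __post_init__(self) -> None:
        problems = []
        if not (0.0 <= self.sharing <= 1.0):
            problems.append("sharing must be in [0, 1]")
        if not (0.0 < self.rho < 1.0):
            problems.append("rho must be in (0, 1)")
        if not (0.0 < self.af_range[0] < self.af_range[1] < 1.0):
            problems.append("af_range must satisfy 0 < lo < hi < 1")
        if not (0.0 <= self.fst < 1.0):
            problems.append("fst must be in [0, 1)")
        if self.trait_type not in ("quantitative", "binary"):
            problems.append("trait_type must be quantitative|binary")
        if self.trait_type == "binary" and (self.n_cases is None or self.n_controls is None):
            problems.append("binary target requires n_cases and n_controls")
        if self.seed is None:
            problems.append("seed is mandatory (no silent nondeterminism)")
        if min(self.n_loci, self.block_size, self.n_discovery, self.n_target, self.n_panel) <= 0:
            problems.append("counts must be positive")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))


@dataclass
class SimulatedPair:
    """A simulated discovery/target GWAS pair with its LD panel and truth."""

    discovery: SumStatTable
    target: SumStatTable
    panel: GenotypePanel
    truth: pd.DataFrame  # locus_id, causal variant, shared, beta_discovery, beta_target
    sentinels: list[tuple[str, VariantKey]]  # (locus_id, min-discovery-p variant)


def _ar1_noise(rng: np.random.Generator, m: int, rho: float) -> np.ndarray:
    """MVN(0, R) draw for an AR(1) correlation matrix via the recursion."""
    eta = rng.standard_normal(m)
    z = np.empty(m)
    z[0] = eta[0]
    scale = math.sqrt(1.0 - rho * rho)
    for j in range(1, m):
        z[j] = rho * z[j - 1] + scale * eta[j]
    return z


def _block_haplotypes(
    rng: np.random.Generator, n_hap: int, m: int, f: float, rho: float
) -> np.ndarray:
    """Haplotype alleles with exact AR(1) correlation rho between neighbours.

    A Markov chain over {0, 1} with stationary frequency f and one-step
    correlation rho; the correlation between variants i and j is rho^|i-j|.
    """
    hap = np.empty((n_hap, m), dtype=np.int8)
    hap[:, 0] = rng.random(n_hap) < f
    for j in range(1, m):
        prev = hap[:, j - 1].astype(bool)
        p_next = np.where(prev, f + rho * (1.0 - f), f * (1.0 - rho))
        hap[:, j] = rng.random(n_hap) < p_next
    return hap


def _drift_frequency(rng: np.random.Generator, f: float, fst: float) -> float:
    """Balding-Nichols draw of a derived-population allele frequency."""
    if fst == 0.0:
        return f
    a = f * (1.0 - fst) / fst
    b = (1.0 - f) * (1.0 - fst) / fst
    return float(np.clip(rng.beta(a, b), 0.01, 0.99))


def _records_from_z(
    keys: list[VariantKey], z: np.ndarray, f: float, n: float,
    n_cases: float | None, n_controls: float | None, snp_ids: list[str],
) -> list[SumStatRecord]:
    se = 1.0 / math.sqrt(2.0 * f * (1.0 - f) * n)
    out = []
    for key, zi, sid in zip(keys, z, snp_ids):
        p = max(2.0 * stats.norm.sf(abs(zi)), _P_FLOOR)
        out.append(
            SumStatRecord(
                key=key, beta=float(zi * se), se=se, p=float(p), eaf=f,
                n=n if n_cases is None else n_cases + n_controls,
                n_cases=n_cases, n_controls=n_controls, info=1.0, snp_id=sid,
            )
        )
    return out


def simulate_gwas_pair(config: SimConfig) -> SimulatedPair:
    """Simulate a discovery/target GWAS pair over AR(1) LD blocks.

    Each locus carries one causal variant at the block centre whose
    discovery effect is drawn from N(0, effect_sd) (or has fixed magnitude
    ``effect_size`` with random sign). The target effect equals the
    discovery effect with probability ``sharing`` and is zero otherwise;
    the truth table records the sharing indicator per locus.
    """
    rng = np.random.default_rng(config.seed)
    m = config.block_size
    causal_idx = m // 2
    r_to_causal = config.rho ** np.abs(np.arange(m) - causal_idx)

    if config.trait_type == "binary":
        n_eff_target = 4.0 / (1.0 / config.n_cases + 1.0 / config.n_controls)
    else:
        n_eff_target = float(config.n_target)

    disc_records: list[SumStatRecord] = []
    targ_records: list[SumStatRecord] = []
    panel_keys: list[VariantKey] = []
    panel_cols: list[np.ndarray] = []
    truth_rows = []
    sentinels: list[tuple[str, VariantKey]] = []

    for locus in range(config.n_loci):
        chrom = str(locus % 22 + 1)
        start = 1_000_000 * (locus // 22 + 1)
        positions = start + config.spacing_bp * np.arange(m)
        keys = [VariantKey(chrom, int(pos), "A", "G") for pos in positions]
        snp_ids = [f"locus{locus}_v{j}" for j in range(m)]
        locus_id = f"locus{locus}"

        f_disc = float(rng.uniform(*config.af_range))
        f_targ = _drift_frequency(rng, f_disc, config.fst)

        if config.effect_size is not None:
            beta = config.effect_size * (1.0 if rng.random() < 0.5 else -1.0)
        else:
            beta = float(rng.normal(0.0, config.effect_sd))
        shared = bool(rng.random() < config.sharing)
        beta_target = beta if shared else 0.0

        mu_disc = r_to_causal * math.sqrt(
            2.0 * f_disc * (1.0 - f_disc) * config.n_discovery
        ) * beta
        mu_targ = r_to_causal * math.sqrt(
            2.0 * f_targ * (1.0 - f_targ) * n_eff_target
        ) * beta_target
        z_disc = mu_disc + _ar1_noise(rng, m, config.rho)
        z_targ = mu_targ + _ar1_noise(rng, m, config.rho)

        disc_records.extend(
            _records_from_z(keys, z_disc, f_disc, config.n_discovery, None, None, snp_ids)
        )
        targ_records.extend(
            _records_from_z(
                keys, z_targ, f_targ, config.n_target,
                config.n_cases if config.trait_type == "binary" else None,
                config.n_controls if config.trait_type == "binary" else None,
                snp_ids,
            )
        )

        hap = _block_haplotypes(rng, 2 * config.n_panel, m, f_disc, config.rho)
        dosage = hap[: config.n_panel] + hap[config.n_panel :]
        panel_keys.extend(keys)
        panel_cols.append(dosage.astype(float))

        sentinel = keys[int(np.argmax(np.abs(z_disc)))]
        sentinels.append((locus_id, sentinel))
        truth_rows.append(
            {
                "locus_id": locus_id,
                "causal": str(keys[causal_idx]),
                "shared": shared,
                "beta_discovery": beta,
                "beta_target": beta_target,
                "eaf_discovery": f_disc,
                "eaf_target": f_targ,
            }
        )

    panel = GenotypePanel(panel_keys, np.hstack(panel_cols), population="simulated")
    discovery = SumStatTable(disc_records, trait_type="quantitative", population="discovery")
    target = SumStatTable(targ_records, trait_type=config.trait_type, population="target")
    return SimulatedPair(discovery, target, panel, pd.DataFrame(truth_rows), sentinels)


# ---------------------------------------------------------------------------
# individual-level cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortSimConfig:
    """Study conditions for an individual-level evaluation cohort.

    ``pgs_variance`` is the phenotypic variance fraction the true-weight
    PGS explains in the quantitative trait; ``liability_pgs_variance`` is
    its share of the liability for the binary outcome (alternatively set
    via ``or_per_sd``); covariates (sex, age) explain ``covariate_variance``
    of the quantitative trait and feed the logistic baseline clinical risk.
    """

    n_individuals: int = 10_000
    n_variants: int = 100
    maf_range: tuple[float, float] = (0.1, 0.9)
    pgs_variance: float = 0.05
    covariate_variance: float = 0.10
    prevalence: float = 0.05
    liability_pgs_variance: float | None = 0.05
    or_per_sd: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if not (0.0 <= self.pgs_variance < 1.0):
            raise ValueError("pgs_variance must be in [0, 1)")
        if self.pgs_variance + self.covariate_variance >= 1.0:
            raise ValueError("pgs_variance + covariate_variance must be < 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.or_per_sd is not None and self.or_per_sd <= 0:
            raise ValueError("or_per_sd must be positive")


@dataclass
class SimulatedCohort:
    dosages: GenotypePanel
    weights: PGSWeights
    cohort: pd.DataFrame  # id, sex, age, pc1..pc10, trait, case, clinical_risk, pgs


def logistic_or_from_liability(liability_variance: float, prevalence: float) -> float:
    """Marginal logistic OR per SD of a score explaining liability variance.

    Under the liability-threshold model, P(case | score = x) =
    Phi((a x - T) / sqrt(1 - a^2)) with a = sqrt(liability_variance) and
    T = Phi^{-1}(1 - prevalence). The population logistic regression slope
    is the KL projection of that curve onto the logistic family, computed by
    Gauss-Hermite quadrature; returned as exp(slope).
    """
    a = math.sqrt(liability_variance)
    T = stats.norm.ppf(1.0 - prevalence)
    nodes, weights_q = np.polynomial.hermite_e.hermegauss(80)
    w = weights_q / weights_q.sum()
    p_true = stats.norm.cdf((a * nodes - T) / math.sqrt(1.0 - a * a))

    def negloglik(params):
        b0, b1 = params
        eta = b0 + b1 * nodes
        # E over x of the cross-entropy between true and logistic risks
        return -np.sum(w * (p_true * eta - np.logaddexp(0.0, eta)))

    res = optimize.minimize(negloglik, x0=[math.log(prevalence / (1 - prevalence)), a])
    return float(np.exp(res.x[1]))


def liability_variance_for_or(or_per_sd: float, prevalence: float) -> float:
    """Invert :func:`logistic_or_from_liability` for a target OR per SD."""
    target = math.log(or_per_sd)

    def gap(v):
        return math.log(logistic_or_from_liability(v, prevalence)) - target

    return float(optimize.brentq(gap, 1e-6, 0.95))


def simulate_cohort(config: CohortSimConfig) -> SimulatedCohort:
    """Simulate genotypes, a quantitative trait, a binary outcome and a
    baseline clinical risk score.

    Dosages are Binomial(2, f) per variant; the quantitative trait is the
    true-weight PGS plus a covariate signal and Gaussian noise, scaled so
    the PGS explains ``pgs_variance`` of the phenotype. The binary outcome
    comes from a liability threshold at ``prevalence`` with the PGS
    explaining ``liability_pgs_variance`` of liability (or the share implied
    by ``or_per_sd``). The baseline risk is the logistic transform of a
    covariate-only (age, sex) linear predictor.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_variants

    freqs = rng.uniform(*config.maf_range, size=m)
    dosage = rng.binomial(2, freqs, size=(n, m)).astype(float)
    raw_weights = rng.normal(0.0, 1.0, size=m)
    keys = [VariantKey("1", 1_000 + 1_000 * j, "A", "G") for j in range(m)]
    panel = GenotypePanel(keys, dosage, population="cohort")
    weights = PGSWeights(
        pd.DataFrame(
            {
                "chrom": [k.chrom for k in keys],
                "pos": [k.pos for k in keys],
                "ea": [k.ea for k in keys],
                "oa": [k.oa for k in keys],
                "weight": raw_weights,
            }
        ),
        score_id="true_weights",
    )

    score = dosage @ raw_weights
    score_std = (score - score.mean()) / score.std()

    age = np.clip(rng.normal(45.0, 12.0, size=n), 25.0, 84.0)
    sex = rng.integers(0, 2, size=n).astype(float)
    pcs = rng.standard_normal((n, 10))
    covar_signal = 0.8 * (age - age.mean()) / age.std() + 0.6 * (sex - sex.mean())
    covar_std = covar_signal / covar_signal.std()

    v_g, v_c = config.pgs_variance, config.covariate_variance
    noise_sd = math.sqrt(1.0 - v_g - v_c)
    trait = (
        math.sqrt(v_g) * score_std
        + math.sqrt(v_c) * covar_std
        + rng.normal(0.0, noise_sd, size=n)
    )

    if config.or_per_sd is not None:
        lv = liability_variance_for_or(config.or_per_sd, config.prevalence)
    else:
        lv = config.liability_pgs_variance if config.liability_pgs_variance is not None else 0.05
    liability = math.sqrt(lv) * score_std + math.sqrt(1.0 - lv) * rng.standard_normal(n)
    case = (liability > stats.norm.ppf(1.0 - config.prevalence)).astype(int)

    base = math.log(config.prevalence / (1.0 - config.prevalence))
    clinical_risk = 1.0 / (1.0 + np.exp(-(base + 0.8 * covar_std)))

    cohort = pd.DataFrame(
        {
            "id": [f"ind{i}" for i in range(n)],
            "sex": sex,
            "age": age,
            **{f"pc{i+1}": pcs[:, i] for i in range(10)},
            "trait": trait,
            "case": case,
            "clinical_risk": clinical_risk,
            "pgs": score,
        }
    )
    return SimulatedCohort(panel, weights, cohort)


# ---------------------------------------------------------------------------
# writers (same text formats the analysis modules consume)
# ---------------------------------------------------------------------------


def write_panel_vcf(panel: GenotypePanel, path: str) -> None:
    """Write hard-call dosages as an uncompressed VCF (GT field)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    chroms = list(dict.fromkeys(k.chrom for k in panel.variants))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"S{i}" for i in range(panel.n_samples))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        order = sorted(panel.variants, key=lambda k: (int(k.chrom), k.pos))
        for key in order:
            calls = "\t".join(gt_map[int(round(d))] for d in panel.dosage(key))
            fh.write(
                f"{key.chrom}\t{key.pos}\t{key.chrom}:{key.pos}\t{key.oa}\t{key.ea}"
                f"\t.\tPASS\t.\tGT\t{calls}\n"
            )


def write_gwas_bundle(pair: SimulatedPair, outdir: str) -> dict[str, str]:
    """Write a simulated pair in the formats the CLI pipeline consumes."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "discovery": str(out / "discovery.tsv"),
        "target": str(out / "target.tsv"),
        "panel": str(out / "panel.vcf"),
        "sentinels": str(out / "sentinels.tsv"),
        "truth": str(out / "truth.tsv"),
    }
    pair.discovery.to_tsv(paths["discovery"])
    pair.target.to_tsv(paths["target"])
    write_panel_vcf(pair.panel, paths["panel"])
    pd.DataFrame(
        [
            {"locus_id": lid, "chrom": k.chrom, "pos": k.pos, "ea": k.ea, "oa": k.oa}
            for lid, k in pair.sentinels
        ]
    ).to_csv(paths["sentinels"], sep="\t", index=False)
    pair.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
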