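"""PGS scoring, incremental accuracy, quantile ORs and reclassification."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from patloc.ldcred import GenotypePanel
from patloc.pgseval import (
    CohortTable,
    MetricEstimate,
    PGSWeights,
    incremental_metric,
    nri,
    quantile_or,
    read_pgs_weights,
    relative_accuracy,
    score_pgs,
)
from patloc.simulate import (
    CohortSimConfig,
    liability_variance_for_or,
    simulate_cohort,
)
from patloc.sumstats import VariantKey


def weights_frame(keys, weights):
    return PGSWeights(
        pd.DataFrame(
            {
                "chrom": [k.chrom for k in keys],
                "pos": [k.pos for k in keys],
                "ea": [k.ea for k in keys],
                "oa": [k.oa for k in keys],
                "weight": weights,
            }
        )
    )


class TestScorePGS:
    def test_single_variant_linearity(self):
        key = VariantKey("1", 1000, "A", "G")
        panel = GenotypePanel([key], np.array([[0.0], [1.0], [2.0]]))
        scores, coverage = score_pgs(panel, weights_frame([key], [0.5]))
        assert scores.tolist() == [0.0, 0.5, 1.0]
        assert coverage == 1.0

    def test_zero_weights_zero_scores(self):
        keys = [VariantKey("1", 1000 + j, "A", "G") for j in range(3)]
        panel = GenotypePanel(keys, np.ones((4, 3)))
        scores, _ = score_pgs(panel, weights_frame(keys, [0.0] * 3))
        assert np.all(scores == 0.0)

    def test_matches_naive_double_loop(self):
        """100-variant panel: vectorised scores equal the per-individual loop."""
        rng = np.random.default_rng(4)
        keys = [VariantKey("1", 1000 + 10 * j, "A", "G") for j in range(100)]
        dosage = rng.binomial(2, 0.4, size=(50, 100)).astype(float)
        w = rng.normal(size=100)
        panel = GenotypePanel(keys, dosage)
        scores, coverage = score_pgs(panel, weights_frame(keys, w))
        naive = np.array(
            [sum(w[j] * dosage[i, j] for j in range(100)) for i in range(50)]
        )
        assert np.allclose(scores, naive)
        assert coverage == 1.0

    def test_swapped_alleles_counted_on_effect_allele(self):
        """A weight whose effect allele is the panel's other allele uses 2 - d."""
        stored = VariantKey("1", 1000, "A", "G")
        panel = GenotypePanel([stored], np.array([[0.0], [2.0]]))
        swapped = [VariantKey("1", 1000, "G", "A")]
        scores, _ = score_pgs(panel, weights_frame(swapped, [1.0]))
        assert scores.tolist() == [2.0, 0.0]

    def test_missing_variants_counted_zero_overlap_raises(self):
        keys = [VariantKey("1", 1000, "A", "G")]
        panel = GenotypePanel(keys, np.array([[1.0], [2.0]]))
        half = weights_frame(keys + [VariantKey("2", 5, "C", "T")], [1.0, 3.0])
        scores, coverage = score_pgs(panel, half)
        assert coverage == pytest.approx(0.5)
        with pytest.raises(ValueError, match="no overlap"):
            score_pgs(panel, weights_frame([VariantKey("9", 9, "C", "T")], [1.0]))

    def test_linearity_in_weight_sets(self):
        """Scoring summed weight sets equals summing the scores."""
        rng = np.random.default_rng(6)
        keys = [VariantKey("1", 1000 + j, "A", "G") for j in range(10)]
        panel = GenotypePanel(keys, rng.binomial(2, 0.5, size=(20, 10)).astype(float))
        w1, w2 = rng.normal(size=10), rng.normal(size=10)
        s1, _ = score_pgs(panel, weights_frame(keys, w1))
        s2, _ = score_pgs(panel, weights_frame(keys, w2))
        s12, _ = score_pgs(panel, weights_frame(keys, w1 + w2))
        assert np.allclose(s12, s1 + s2)

    def test_pgs_catalog_reader(self, tmp_path):
        path = tmp_path / "score.txt"
        path.write_text(
            "# PGS Catalog scoring file\n"
            "# pgs_id = PGS000000\n"
            "rsID\tchr_name\tchr_position\teffect_allele\tother_allele\teffect_weight\n"
            "rs1\t1\t1000\tA\tG\t0.5\n"
            "rs2\t2\t2000\tC\tT\t-0.25\n"
        )
        w = read_pgs_weights(str(path), score_id="PGS000000")
        assert len(w) == 2
        assert w.entries["weight"].tolist() == [0.5, -0.25]
        assert w.keys()[1] == VariantKey("2", 2000, "C", "T")


@pytest.fixture(scope="module")
def sim_cohort():
    return simulate_cohort(CohortSimConfig(n_individuals=10_000, seed=42))


def cohort_with_pgs(sim, pgs, outcome="trait", binary=False):
    df = sim.cohort.copy()
    df["pgs"] = pgs
    return CohortTable(df, outcome, binary, clinical_risk="clinical_risk")


class TestIncrementalMetric:
    def test_noise_pgs_adds_nothing(self, sim_cohort):
        rng = np.random.default_rng(0)
        cohort = cohort_with_pgs(sim_cohort, rng.standard_normal(len(sim_cohort.cohort)))
        cohort.data = cohort.data.iloc[:5000]
        est = incremental_metric(cohort, "r2", n_boot=20, seed=1)
        assert abs(est.value) < 0.002

    def test_generative_five_percent_recovered(self, sim_cohort):
        """True-weight PGS explains the configured 5% of trait variance."""
        cohort = cohort_with_pgs(sim_cohort, sim_cohort.cohort["pgs"])
        est = incremental_metric(cohort, "r2", n_boot=50, seed=1)
        assert est.value == pytest.approx(0.05, abs=0.01)
        assert est.ci_low < est.value < est.ci_high

    def test_redundant_covariate_exactly_zero(self, sim_cohort):
        cohort = cohort_with_pgs(sim_cohort, sim_cohort.cohort["pc1"].to_numpy())
        est = incremental_metric(cohort, "r2", n_boot=10, seed=1)
        assert abs(est.value) < 1e-8

    def test_auc_requires_binary(self, sim_cohort):
        cohort = cohort_with_pgs(sim_cohort, sim_cohort.cohort["pgs"])
        with pytest.raises(ValueError, match="binary"):
            incremental_metric(cohort, "auc")

    def test_auc_positive_for_informative_pgs(self, sim_cohort):
        cohort = cohort_with_pgs(sim_cohort, sim_cohort.cohort["pgs"], outcome="case", binary=True)
        est = incremental_metric(cohort, "auc", n_boot=20, seed=3)
        assert est.value > 0.0

    def test_too_few_cases_rejected(self, sim_cohort):
        df = sim_cohort.cohort.copy()
        df["case"] = 0
        df.loc[df.index[:5], "case"] = 1
        df["pgs"] = df["pc1"]
        cohort = CohortTable(df, "case", True)
        with pytest.raises(ValueError, match="cases"):
            incremental_metric(cohort, "auc")

    def test_bootstrap_reproducible(self, sim_cohort):
        cohort = cohort_with_pgs(sim_cohort, sim_cohort.cohort["pgs"])
        cohort.data = cohort.data.iloc[:2000]
        a = incremental_metric(cohort, "r2", n_boot=30, seed=7)
        b = incremental_metric(cohort, "r2", n_boot=30, seed=7)
        assert a.ci_low == b.ci_low and a.ci_high == b.ci_high


class TestRelativeAccuracy:
    def test_fixed_scalar_arithmetic(self):
        t = MetricEstimate(0.01, 0.005, 0.015, 0, boot=None)
        r = MetricEstimate(0.02, 0.015, 0.025, 0, boot=None)
        assert relative_accuracy(t, r).value == pytest.approx(0.5)

    def test_self_comparison_is_one(self, sim_cohort):
        cohort = cohort_with_pgs(sim_cohort, sim_cohort.cohort["pgs"])
        est = incremental_metric(cohort, "r2", n_boot=40, seed=2)
        ratio = relative_accuracy(est, est)
        assert ratio.value == pytest.approx(1.0)

    def test_halved_signal_gives_half_ratio(self):
        """Averaged over replicates to tame single-draw sampling noise."""

        def mean_incremental(variance, seeds):
            vals = []
            for seed in seeds:
                sim = simulate_cohort(
                    CohortSimConfig(n_individuals=10_000, pgs_variance=variance, seed=seed)
                )
                est = incremental_metric(
                    cohort_with_pgs(sim, sim.cohort["pgs"]), "r2", n_boot=5, seed=seed
                )
                vals.append(est.value)
            return float(np.mean(vals))

        ref = mean_incremental(0.05, range(4))
        tgt = mean_incremental(0.025, range(10, 14))
        assert tgt / ref == pytest.approx(0.5, abs=0.1)

    def test_nonpositive_reference_rejected(self):
        t = MetricEstimate(0.01, 0, 0, 0, boot=None)
        r = MetricEstimate(0.0, 0, 0, 0, boot=None)
        with pytest.raises(ValueError):
            relative_accuracy(t, r)


def analytic_quintile_or(liability_variance, prevalence, quintile, reference=2):
    """Liability-threshold oracle: OR of a PGS quintile vs the middle quintile."""
    a = np.sqrt(liability_variance)
    T = stats.norm.ppf(1 - prevalence)

    def case_prob(lo, hi):
        num, _ = integrate.quad(
            lambda x: stats.norm.cdf((a * x - T) / np.sqrt(1 - a**2)) * stats.norm.pdf(x),
            lo, hi,
        )
        return num / (stats.norm.cdf(hi) - stats.norm.cdf(lo))

    edges = stats.norm.ppf(np.linspace(0, 1, 6))
    p_q = case_prob(edges[quintile], edges[quintile + 1])
    p_ref = case_prob(edges[reference], edges[reference + 1])
    return (p_q / (1 - p_q)) / (p_ref / (1 - p_ref))


class TestQuantileOR:
    def test_null_pgs_gives_unit_ors(self, sim_cohort):
        rng = np.random.default_rng(9)
        cohort = cohort_with_pgs(
            sim_cohort, rng.standard_normal(len(sim_cohort.cohort)), outcome="case", binary=True
        )
        ors, (per_sd, lo, hi) = quantile_or(cohort, q=5)
        assert lo < 1.0 < hi
        for entry in ors:
            assert entry.ci_low <= 1.0 <= entry.ci_high or abs(entry.odds_ratio - 1) < 0.5

    def test_liability_simulation_matches_closed_form(self):
        """Top-quintile OR vs middle agrees with the liability-model value."""
        lv = liability_variance_for_or(1.6, 0.05)
        sim = simulate_cohort(
            CohortSimConfig(n_individuals=20_000, prevalence=0.05, or_per_sd=1.6, seed=77)
        )
        cohort = cohort_with_pgs(sim, sim.cohort["pgs"], outcome="case", binary=True)
        ors, (per_sd, _, _) = quantile_or(cohort, q=5)
        expected_top = analytic_quintile_or(lv, 0.05, quintile=4)
        top = ors[4]
        assert top.ci_low < expected_top < top.ci_high
        assert per_sd == pytest.approx(1.6, abs=0.15)

    def test_two_quantile_symmetry(self, sim_cohort):
        cohort = cohort_with_pgs(sim_cohort, sim_cohort.cohort["pgs"], outcome="case", binary=True)
        top_vs_bottom, _ = quantile_or(cohort, q=2, reference=0)
        bottom_vs_top, _ = quantile_or(cohort, q=2, reference=1)
        assert top_vs_bottom[1].odds_ratio == pytest.approx(
            1.0 / bottom_vs_top[0].odds_ratio, rel=1e-6
        )


class TestNRI:
    def test_identical_scores_zero(self):
        rng = np.random.default_rng(1)
        risk = rng.uniform(0, 1, 200)
        case = rng.integers(0, 2, 200)
        for mode in ("categorical", "continuous"):
            result = nri(risk, risk, case, mode=mode, n_boot=20, seed=1)
            assert result.nri == 0.0

    def test_hand_computed_contingency_example(self):
        """10 up / 5 down of 50 cases; 20 down / 10 up of 200 noncases -> 0.15."""
        old = np.concatenate([np.full(50, 0.05), np.full(200, 0.05)])
        new = old.copy()
        new[:10] = 0.2       # cases up
        new[10:15] = 0.05    # cases unchanged-level... moved below via explicit down
        old[10:15] = 0.2     # so these 5 cases cross downward
        new[50:70] = 0.05
        old[50:70] = 0.2     # 20 noncases down
        new[70:80] = 0.2     # 10 noncases up
        case = np.concatenate([np.ones(50, dtype=int), np.zeros(200, dtype=int)])
        result = nri(old, new, case, mode="categorical", threshold=0.10, n_boot=10, seed=1)
        assert result.nri == pytest.approx((10 - 5) / 50 + (20 - 10) / 200)
        assert result.nri == pytest.approx(0.15)
        table = result.table
        assert (table.up_cases, table.down_cases) == (10, 5)
        assert (table.up_noncases, table.down_noncases) == (10, 20)
        assert table.n_cases + table.n_noncases == 250

    def test_antisymmetric_in_score_swap(self):
        rng = np.random.default_rng(3)
        old = rng.uniform(0, 1, 300)
        new = np.clip(old + rng.normal(0, 0.1, 300), 0, 1)
        case = rng.integers(0, 2, 300)
        for mode in ("categorical", "continuous"):
            forward = nri(old, new, case, mode=mode, n_boot=5, seed=1)
            backward = nri(new, old, case, mode=mode, n_boot=5, seed=1)
            assert forward.nri == pytest.approx(-backward.nri)

    def test_informative_update_positive_continuous_nri(self):
        """A new score adding real signal has positive continuous NRI."""
        positives = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n = 500
            signal = rng.standard_normal(n)
            case = (signal + rng.standard_normal(n) > 1.0).astype(int)
            old = np.full(n, case.mean())
            from scipy.special import expit

            new = expit(-1.0 + 1.0 * signal)
            result = nri(old, new, case, mode="continuous", n_boot=2, seed=seed)
            positives += result.nri > 0
        assert positives >= 29

    def test_strata_and_errors(self):
        old = np.array([0.05, 0.2, 0.05, 0.2])
        new = np.array([0.2, 0.05, 0.05, 0.2])
        case = np.array([1, 0, 1, 0])
        strata = {"young": np.array([True, True, False, False]),
                  "old": np.array([False, False, True, True])}
        result = nri(old, new, case, n_boot=5, seed=1, strata=strata)
        assert set(result) == {"young", "old"}
        with pytest.raises(ValueError, match="length"):
            nri(old[:2], new, case, n_boot=2)
        with pytest.raises(ValueError):
            nri(old, new, np.ones_like(case), n_boot=2)
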