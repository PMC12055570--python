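"""Method-validation statistics against brute-force oracles."""

import numpy as np
import pytest

from ureaflux.constants import EXACT_MZ
from ureaflux.validation import (
    GroupComparison,
    InsufficientDataError,
    UndefinedStatisticError,
    aggregate_mass_accuracy,
    carryover_check,
    group_compare,
    inter_experiment_cv,
    lloqd,
    mass_accuracy_ppm,
    matrix_correlation,
    precision_cv,
    stability_delta,
)


class TestLLOQD:
    def test_exactly_three_sigma(self, rng):
        ratios = rng.normal(0.3663, 0.01, 12)
        assert lloqd(ratios) == 3.0 * np.std(ratios, ddof=1)

    def test_plasma_urea_value(self):
        """Baseline replicates constructed with SD = 0.0128% reproduce the
        0.0384% plasma-urea limit."""
        sd = 0.0384 / 3.0
        ratios = np.array([0.3663 - sd, 0.3663, 0.3663 + sd])
        assert np.std(ratios, ddof=1) == pytest.approx(sd)
        assert lloqd(ratios) == pytest.approx(0.0384)

    def test_degenerate_zero_sd(self):
        assert lloqd([0.3663] * 5) == 0.0

    def test_too_few_replicates(self):
        with pytest.raises(InsufficientDataError):
            lloqd([0.36, 0.37])


class TestPrecision:
    def test_identical_values(self):
        assert precision_cv([5.0, 5.0, 5.0]) == 0.0

    def test_sample_sd_convention(self):
        assert precision_cv([9.0, 10.0, 11.0]) == pytest.approx(10.0)

    def test_matches_brute_force(self, rng):
        values = rng.uniform(1, 10, 20)
        brute = 100.0 * np.sqrt(
            np.sum((values - values.mean()) ** 2) / (len(values) - 1)
        ) / values.mean()
        assert precision_cv(values) == pytest.approx(brute)

    def test_monte_carlo_consistency(self, rng):
        """Injected 5% CV noise is recovered at large n."""
        values = 10.0 * (1 + 0.05 * rng.standard_normal(4000))
        assert precision_cv(values) == pytest.approx(5.0, rel=0.05)

    def test_inter_experiment_uses_day_means(self):
        days = [[9.0, 11.0], [10.0, 10.0], [11.0, 13.0]]
        assert inter_experiment_cv(days) == pytest.approx(
            precision_cv([10.0, 10.0, 12.0])
        )

    def test_zero_mean_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            precision_cv([-1.0, 1.0])


class TestMassAccuracy:
    def test_exact_match_zero_ppm(self):
        assert mass_accuracy_ppm(EXACT_MZ["urea"], EXACT_MZ["urea"]) == 0.0

    def test_protonated_urea_offset(self):
        ppm = mass_accuracy_ppm(61.03973, 61.03964)
        assert ppm == pytest.approx(1.47, abs=0.01)

    def test_sign_convention(self):
        assert mass_accuracy_ppm(61.0395, 61.03964) < 0

    def test_aggregation_mean_rms(self, rng):
        ppm = rng.normal(1.5, 0.3, 24)
        mean, rms = aggregate_mass_accuracy(ppm)
        assert mean == pytest.approx(ppm.mean())
        assert rms == pytest.approx(np.sqrt((ppm**2).mean()))


class TestCarryover:
    @pytest.mark.parametrize(
        "blank,sample,expected,passes",
        [(0.0, 100.0, 0.0, True), (100.0, 100.0, 100.0, False), (0.5, 100.0, 0.5, False)],
    )
    def test_percentages(self, blank, sample, expected, passes):
        pct, ok = carryover_check(blank, sample, threshold=0.1)
        assert pct == pytest.approx(expected)
        assert ok is passes


class TestStability:
    def test_percent_change(self):
        assert stability_delta([1.0, 1.0], [0.88, 0.88]) == pytest.approx(-12.0)


class TestMatrixCorrelation:
    def test_identical_vectors(self, rng):
        x = rng.uniform(0, 2, 10)
        assert matrix_correlation(x, x) == pytest.approx(1.0)

    def test_antiproportional(self, rng):
        x = rng.uniform(0, 2, 10)
        assert matrix_correlation(x, -3.0 * x) == pytest.approx(-1.0)

    def test_matches_brute_force(self, rng):
        x, y = rng.uniform(0, 2, 15), rng.uniform(0, 2, 15)
        cx, cy = x - x.mean(), y - y.mean()
        brute = np.sum(cx * cy) / np.sqrt(np.sum(cx**2) * np.sum(cy**2))
        assert matrix_correlation(x, y) == pytest.approx(brute)

    def test_attenuation_by_matrix_noise(self, rng):
        """Shared truth plus independent per-matrix noise attenuates r toward
        the closed-form prediction σ²_t/(σ²_t + σ²_n) and monotonically in
        the noise level."""
        truth = rng.normal(1.0, 0.5, 4000)
        observed = []
        for sigma in (0.1, 0.3, 0.6):
            r = matrix_correlation(
                truth + rng.normal(0, sigma, truth.size),
                truth + rng.normal(0, sigma, truth.size),
            )
            predicted = 0.25 / (0.25 + sigma**2)
            assert r == pytest.approx(predicted, abs=0.05)
            observed.append(r)
        assert observed[0] > observed[1] > observed[2]

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            matrix_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestGroupCompare:
    def test_identical_groups_not_significant(self, rng):
        x = rng.normal(100, 5, 12)
        res = group_compare({"a": x, "b": x.copy()})
        assert res.test == "t-test"
        assert not res.significant

    def test_well_separated_groups_significant(self, rng):
        a = rng.normal(100.0, 5.0, 10)
        b = rng.normal(75.0, 5.0, 10)  # 5 SD separation
        res = group_compare({"control": a, "severe": b})
        assert res.significant and res.pvalue < 0.05

    def test_three_groups_uses_anova_with_tukey(self, rng):
        groups = {
            "control": rng.normal(100, 8, 12),
            "mild": rng.normal(95, 8, 12),
            "severe": rng.normal(40, 8, 12),
        }
        res = group_compare(groups)
        assert res.test == "anova" and res.significant
        pairs = {frozenset((p["group1"], p["group2"])): p["reject"] for p in res.pairwise}
        assert pairs[frozenset(("control", "severe"))]
        assert pairs[frozenset(("mild", "severe"))]
        assert not pairs[frozenset(("control", "mild"))]

    def test_simulated_severe_cohort_scores_lower(self, config):
        """Pipeline RUFs of a severe synthetic cohort differ from controls."""
        from ureaflux.pipeline import run_pipeline
        from ureaflux.simulate import simulate_cohort

        assays = simulate_cohort(8, "CONTROL", seed=21) + simulate_cohort(
            6, "CPS1D", seed=22
        )
        res = run_pipeline(assays, config)
        groups = {
            g: [r.RUF for r in res.results if r.group == g]
            for g in ("CONTROL", "CPS1D")
        }
        assert np.mean(groups["CPS1D"]) < 25.0
        assert group_compare(groups).significant

    def test_degenerate_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            group_compare({"a": [1.0, 2.0], "b": [1.0]})
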