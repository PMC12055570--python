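"""Method-validation computations and cohort statistics.

Covers the analytical figures of merit used to qualify an isotope-ratio
LC-HRMS assay — lower limit of quantitative differentiation (LLOQD),
intra/inter-experiment precision, mass accuracy, carry-over, storage
stability and plasma-vs-DBS matrix agreement — plus the group-comparison
statistics (two-group t-test, one-way ANOVA with Tukey HSD follow-up).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd


class InsufficientDataError(ValueError):
    """Too few replicates/groups for the requested statistic."""


class UndefinedStatisticError(ValueError):
    """Statistic undefined (zero mean, zero variance, degenerate group)."""


def lloqd(baseline_ratios) -> float:
    """LLOQD = 3 × SD of the baseline isotope ratio, in % enrichment units.

    The natural-abundance baseline makes a limit of detection moot; the
    relevant limit is the smallest enrichment reliably distinguishable from
    baseline scatter, taken as three baseline standard deviations (the
    critical difference). Input ratios in % units yield the LLOQD in %.
    """
    ratios = np.asarray(baseline_ratios, dtype=float)
    if ratios.size < 3:
        raise InsufficientDataError("LLOQD needs >= 3 baseline replicates")
    sd = float(ratios.std(ddof=1))
    return 3.0 * sd


def precision_cv(values) -> float:
    """Coefficient of variation, percent (sample SD / mean × 100)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientDataError("CV needs >= 2 values")
    mean = values.mean()
    if mean == 0:
        raise UndefinedStatisticError("zero mean; CV undefined")
    return float(100.0 * values.std(ddof=1) / abs(mean))


def inter_experiment_cv(day_values: list) -> float:
    """Inter-experiment precision: CV across day-level mean ratios."""
    day_means = [np.asarray(day, dtype=float).mean() for day in day_values]
    return precision_cv(day_means)


def mass_accuracy_ppm(measured_mz, exact_mz: float):
    """Signed mass error in ppm: 1e6 · (measured − exact) / exact."""
    if exact_mz <= 0:
        raise UndefinedStatisticError("exact m/z must be > 0")
    measured_mz = np.asarray(measured_mz, dtype=float)
    ppm = 1e6 * (measured_mz - exact_mz) / exact_mz
    return float(ppm) if ppm.ndim == 0 else ppm


def aggregate_mass_accuracy(ppm_values) -> tuple[float, float]:
    """Aggregate per-run ppm errors as (mean, rms)."""
    ppm = np.asarray(ppm_values, dtype=float)
    return float(ppm.mean()), float(np.sqrt(np.mean(ppm**2)))


def carryover_check(
    blank_after_sample: float, sample: float, threshold: float = 0.1
) -> tuple[float, bool]:
    """Percent of analyte persisting into a blank run; pass iff below threshold."""
    if sample <= 0:
        raise UndefinedStatisticError("sample intensity must be > 0")
    pct = 100.0 * blank_after_sample / sample
    return pct, pct < threshold


def stability_delta(before, after) -> float:
    """Percent change of mean enrichment between storage conditions."""
    before = np.asarray(before, dtype=float).mean()
    after = np.asarray(after, dtype=float).mean()
    if before == 0:
        raise UndefinedStatisticError("zero reference enrichment")
    return float(100.0 * (after - before) / before)


def matrix_correlation(plasma_values, dbs_values) -> float:
    """Pearson r between paired plasma and DBS enrichment values."""
    x = np.asarray(plasma_values, dtype=float)
    y = np.asarray(dbs_values, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InsufficientDataError("need >= 3 matched pairs")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedStatisticError("zero variance; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class GroupComparison:
    """Outcome of a two-group t-test or one-way ANOVA + Tukey follow-up."""

    test: str                       # "t-test" or "anova"
    statistic: float
    pvalue: float
    significant: bool
    pairwise: list[dict] = field(default_factory=list)
    alpha: float = 0.05


def group_compare(groups: dict[str, "np.ndarray"], alpha: float = 0.05) -> GroupComparison:
    """Compare cohorts of RUF (or AUC) values.

    Two groups: unpaired two-tailed t-test. Three or more: one-way ANOVA
    followed by Tukey HSD pairwise comparisons.
    """
    if len(groups) < 2:
        raise InsufficientDataError("need >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise InsufficientDataError(f"group {name!r} has fewer than 2 values")

    if len(arrays) == 2:
        (a, b) = arrays.values()
        res = stats.ttest_ind(a, b)
        return GroupComparison(
            test="t-test",
            statistic=float(res.statistic),
            pvalue=float(res.pvalue),
            significant=bool(res.pvalue < alpha),
            alpha=alpha,
        )

    res = stats.f_oneway(*arrays.values())
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * len(v) for k, v in arrays.items()])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pairwise = [
        {
            "group1": str(g1),
            "group2": str(g2),
            "meandiff": float(md),
            "p_adj": float(p),
            "reject": bool(rej),
        }
        for g1, g2, md, p, _, _, rej in zip(
            tukey.groupsunique[tukey._multicomp.pairindices[0]],
            tukey.groupsunique[tukey._multicomp.pairindices[1]],
            tukey.meandiffs,
            tukey.pvalues,
            tukey.confint[:, 0],
            tukey.confint[:, 1],
            tukey.reject,
        )
    ]
    return GroupComparison(
        test="anova",
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        significant=bool(res.pvalue < alpha),
        pairwise=pairwise,
        alpha=alpha,
    )
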