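"""Urea-cycle flux scoring: the R partition, absorbed-tracer fraction T,
relative ureagenesis function (RUF), tracer recovery, control reference
construction and pre/post-therapy comparison.

R is the fraction of observed label residing in urea-cycle products (urea,
citrulline, arginine) out of all six measured pools; T is the percentage of
the administered tracer observed across those pools; RUF expresses a
patient's R·T product as a percentage of the control-cohort mean product:

    RUF = 100 · (R_P · T_P) / (R̄_C · T̄_C)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    ALTERNATIVE_METABOLITES,
    DEFAULT_POOLS_UMOL_L,
    DEFAULT_V_DIST_L_PER_KG,
    METABOLITES,
    T_SPAN_MIN,
    UREA_CYCLE_METABOLITES,
)
from .simulate import dose_umol


class UndefinedMetricError(ValueError):
    """A metric's denominator is zero or required inputs are absent."""


class MatrixMismatchWarning(UserWarning):
    """Pre and post assays were measured in different matrices."""


@dataclass
class RUFResult:
    """Flux scores for one assay."""

    assay_id: str
    R: float                      # urea-cycle fraction of observed label, 0–1
    T: float                      # percent of administered tracer observed
    recovery: float               # same accounting as T, reported as recovery
    RUF: float | None = None      # percent of control mean R·T product
    partition: dict[str, float] = field(default_factory=dict)  # AUC-amount shares
    excluded: tuple[str, ...] = ()
    matrix: str = "plasma"
    group: str = ""


@dataclass
class ControlReference:
    """Cohort summary the patient scores are expressed against."""

    R_bar_C: float
    T_bar_C: float
    ruf_mean: float
    ruf_sd: float
    ruf_range: tuple[float, float]  # mean ± SD band
    n_controls: int
    mean_curves: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    mean_unlabeled_signal: dict[str, float] = field(default_factory=dict)
    t_calibration_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise UndefinedMetricError("control reference needs >= 2 controls")


def compute_R(aucs: dict[str, float], excluded: tuple[str, ...] = ()) -> float:
    """Urea-cycle share of the label: (A_urea + A_cit + A_arg) / ΣA.

    Metabolites excluded by the stability filter are dropped from numerator
    and denominator alike.
    """
    uc = sum(aucs[m] for m in UREA_CYCLE_METABOLITES if m in aucs and m not in excluded)
    total = sum(v for m, v in aucs.items() if m not in excluded)
    if total <= 0:
        raise UndefinedMetricError("non-positive total AUC; R undefined")
    return uc / total


def auc_to_amount(
    auc_value: float,
    pool_umol_l: float,
    v_dist_l_per_kg: float,
    weight_kg: float,
    t_span: float = T_SPAN_MIN,
) -> float:
    """Convert a %·min enrichment AUC into a time-averaged 15N amount (µmol).

    The AUC divided by the span is the time-averaged enrichment fraction
    (·100); multiplying by the pool size (concentration × distribution
    volume × weight) gives the average labelled amount resident in that pool.
    """
    return auc_value / 100.0 * pool_umol_l * v_dist_l_per_kg * weight_kg / t_span


def compute_T(
    aucs: dict[str, float],
    dose_mg_per_kg: float,
    weight_kg: float,
    pools: dict[str, float] | None = None,
    v_dist: float = DEFAULT_V_DIST_L_PER_KG,
    excluded: tuple[str, ...] = (),
    t_span: float = T_SPAN_MIN,
    calibration_scale: float = 1.0,
) -> tuple[float, dict[str, float]]:
    """Percent of the administered tracer observed across the measured pools.

    Returns ``(T, partition)`` where partition holds each metabolite's share
    of the observed label amount. ``calibration_scale`` rescales T in
    control-calibrated mode (1.0 = absolute units).
    """
    if dose_mg_per_kg <= 0 or weight_kg <= 0:
        raise UndefinedMetricError("dose and weight must be > 0")
    pools = dict(DEFAULT_POOLS_UMOL_L) if pools is None else pools
    missing = [m for m in aucs if m not in pools]
    if missing:
        raise UndefinedMetricError(f"no pool concentration for {missing}")
    amounts = {
        m: auc_to_amount(aucs[m], pools[m], v_dist, weight_kg, t_span)
        for m in aucs
        if m not in excluded
    }
    t_measured = sum(amounts.values())
    t_theoretical = dose_umol(dose_mg_per_kg, weight_kg)
    T = 100.0 * t_measured / t_theoretical * calibration_scale
    total = sum(amounts.values())
    partition = (
        {m: a / total for m, a in amounts.items()} if total != 0 else {m: np.nan for m in amounts}
    )
    return T, partition


def tracer_recovery(
    aucs: dict[str, float],
    dose_mg_per_kg: float,
    weight_kg: float,
    **kwargs,
) -> tuple[float, dict[str, float]]:
    """Tracer recovery: the T accounting reported with its label partition.

    The partition separates urea-cycle from alternative-pathway label for the
    pathway-diversion report.
    """
    return compute_T(aucs, dose_mg_per_kg, weight_kg, **kwargs)


def pathway_shares(partition: dict[str, float]) -> dict[str, float]:
    """Collapse the per-metabolite partition into urea-cycle vs alternative."""
    return {
        "urea_cycle": sum(
            v for m, v in partition.items() if m in UREA_CYCLE_METABOLITES
        ),
        "alternative": sum(
            v for m, v in partition.items() if m in ALTERNATIVE_METABOLITES
        ),
    }


def compute_RUF(R_P: float, T_P: float, reference: ControlReference) -> float:
    """RUF = 100 · (R_P · T_P) / (R̄_C · T̄_C)."""
    denom = reference.R_bar_C * reference.T_bar_C
    if denom == 0:
        raise UndefinedMetricError("zero control mean product; RUF undefined")
    return 100.0 * (R_P * T_P) / denom


def build_control_reference(
    control_results: list[RUFResult],
    control_curves: list[dict[str, "np.ndarray"]] | None = None,
    times: np.ndarray | None = None,
    leave_one_out: bool = False,
) -> ControlReference:
    """Aggregate control assays into the reference the RUF is scored against.

    R̄_C and T̄_C are arithmetic means; the RUF reference range is the mean ±
    SD of the controls' own RUFs, each computed against the cohort means
    (leave-in by default, matching how a reference range is normally quoted;
    leave-one-out available as a sensitivity option).
    """
    if len(control_results) < 2:
        raise UndefinedMetricError("need >= 2 controls to build a reference")
    Rs = np.array([r.R for r in control_results])
    Ts = np.array([r.T for r in control_results])
    R_bar, T_bar = float(Rs.mean()), float(Ts.mean())
    if leave_one_out:
        n = len(Rs)
        rufs = np.array(
            [
                100.0
                * Rs[i]
                * Ts[i]
                / (np.delete(Rs, i).mean() * np.delete(Ts, i).mean())
                for i in range(n)
            ]
        )
    else:
        rufs = 100.0 * Rs * Ts / (R_bar * T_bar)
    ruf_mean = float(rufs.mean())
    ruf_sd = float(rufs.std(ddof=1))

    mean_curves: dict[str, dict[str, np.ndarray]] = {}
    if control_curves:
        for m in METABOLITES:
            stack = np.array([c[m] for c in control_curves if m in c])
            if stack.ndim == 2 and stack.shape[0] >= 2:
                mean_curves[m] = {
                    "times": np.asarray(times, dtype=float),
                    "mean": stack.mean(axis=0),
                    "sem": stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0]),
                }
    return ControlReference(
        R_bar_C=R_bar,
        T_bar_C=T_bar,
        ruf_mean=ruf_mean,
        ruf_sd=ruf_sd,
        ruf_range=(ruf_mean - ruf_sd, ruf_mean + ruf_sd),
        n_controls=len(control_results),
        mean_curves=mean_curves,
    )


def ruf_repeatability_cv(rufs) -> float:
    """Intra-individual RUF variation across repeat assays, as a percent CV."""
    rufs = np.asarray(rufs, dtype=float)
    if rufs.size < 2:
        raise UndefinedMetricError("need >= 2 repeat assays")
    return float(100.0 * rufs.std(ddof=1) / rufs.mean())


def compare_pre_post(
    pre: RUFResult, post: RUFResult, pre_aucs: dict[str, float] | None = None,
    post_aucs: dict[str, float] | None = None,
) -> dict:
    """Therapy-response report: deltas of RUF, recovery and pathway partition.

    Emits a warning when the two assays used different matrices, since
    cross-matrix comparison is less precise than within-matrix monitoring.
    """
    if pre.matrix != post.matrix:
        warnings.warn(
            f"pre ({pre.matrix}) and post ({post.matrix}) assays use different "
            "matrices; within-matrix monitoring is recommended",
            MatrixMismatchWarning,
            stacklevel=2,
        )
    report = {
        "assay_id": post.assay_id,
        "delta_ruf": (post.RUF - pre.RUF)
        if (pre.RUF is not None and post.RUF is not None)
        else None,
        "delta_recovery": post.recovery - pre.recovery,
        "delta_pathway": {
            k: pathway_shares(post.partition).get(k, np.nan)
            - pathway_shares(pre.partition).get(k, np.nan)
            for k in ("urea_cycle", "alternative")
        },
    }
    if pre_aucs is not None and post_aucs is not None:
        report["delta_auc"] = {
            m: post_aucs.get(m, np.nan) - pre_aucs.get(m, np.nan)
            for m in sorted(set(pre_aucs) | set(post_aucs))
        }
    return report
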