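"""Isotopic enrichment curves, normalisation, AUC and the stability filter.

Isotopic enrichment is the percentage-point excess of the labeled-isotope
fraction over the pre-dose baseline: IE(t) = 100 · (F_t − F_0). Curves are
summarised by the trapezoidal area under the curve over the 120 min test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import STABILITY_CV_THRESHOLD, T_SPAN_MIN


class CurveSpanError(ValueError):
    """Curve does not span the full test window; AUC refuses to extrapolate."""


class DoubleNormalizationError(ValueError):
    """Normalisation applied twice to the same curve."""


@dataclass
class EnrichmentCurve:
    """Per-metabolite % [15N] enrichment time series for one assay."""

    metabolite: str
    times: np.ndarray
    ie: np.ndarray  # percent enrichment per timepoint, ie[0] == 0
    dose_normalized: bool = False
    conc_normalized: bool = False
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ie = np.asarray(self.ie, dtype=float)
        if self.times[0] != 0.0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must start at 0 and strictly increase")
        if self.times.shape != self.ie.shape:
            raise ValueError("times and ie must have equal length")


@dataclass(frozen=True)
class NormalizationFactors:
    """dose_factor = nominal/actual dose; conc_factor scales a metabolite's
    enrichment by its subject-to-control unlabeled-signal ratio."""

    dose_factor: float = 1.0
    conc_factor: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dose_factor <= 0 or any(v <= 0 for v in self.conc_factor.values()):
            raise ValueError("normalization factors must be > 0")


def compute_enrichment(metabolite, times, f_series, f0) -> EnrichmentCurve:
    """IE(t) = 100 · (F_t − F_0); the t=0 point is anchored to exactly zero.

    Negative excursions (baseline noise) are retained, not clamped.
    """
    times = np.asarray(times, dtype=float)
    f_series = np.asarray(f_series, dtype=float)
    if np.any((f_series < 0) | (f_series > 1)) or not 0 <= f0 <= 1:
        raise ValueError("isotope ratios must lie in [0, 1]")
    ie = 100.0 * (f_series - f0)
    ie[0] = 0.0
    return EnrichmentCurve(metabolite=metabolite, times=times, ie=ie)


def normalize_curve(
    curve: EnrichmentCurve, factors: NormalizationFactors
) -> EnrichmentCurve:
    """Scale a curve by the dose factor and the metabolite's concentration factor."""
    if curve.dose_normalized or curve.conc_normalized:
        raise DoubleNormalizationError(f"{curve.metabolite} curve already normalized")
    scale = factors.dose_factor * factors.conc_factor.get(curve.metabolite, 1.0)
    return EnrichmentCurve(
        metabolite=curve.metabolite,
        times=curve.times.copy(),
        ie=curve.ie * scale,
        dose_normalized=True,
        conc_normalized=curve.metabolite in factors.conc_factor,
        provenance=list(curve.provenance),
    )


def auc(curve: EnrichmentCurve, t_span: float = T_SPAN_MIN) -> float:
    """Trapezoidal area (%·min) under the curve over [0, t_span].

    Uses the actual sample times; refuses to extrapolate beyond the last
    observation. Net-negative curves yield negative areas.
    """
    if curve.times[-1] < t_span:
        raise CurveSpanError(
            f"curve for {curve.metabolite} ends at {curve.times[-1]} min < {t_span}"
        )
    mask = curve.times <= t_span
    return float(np.trapezoid(curve.ie[mask], curve.times[mask]))


def concentration_stability_filter(
    total_signal, threshold: float = STABILITY_CV_THRESHOLD
) -> tuple[bool, float]:
    """Exclude a metabolite whose total signal drifts during the test.

    Returns ``(included, cv)`` where cv is SD/mean of the IS-normalised total
    (labeled + unlabeled) signal across timepoints; exclusion is strict
    (cv > threshold).
    """
    total_signal = np.asarray(total_signal, dtype=float)
    total_signal = total_signal[~np.isnan(total_signal)]
    if total_signal.size < 3:
        raise ValueError("need at least 3 timepoints for the stability check")
    mean = total_signal.mean()
    if mean == 0:
        raise ValueError("zero mean total signal")
    cv = float(total_signal.std(ddof=1) / abs(mean))
    return cv <= threshold, cv
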