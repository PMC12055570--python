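"""Raw peak-area cleanup: IS normalisation, triplicate outlier rejection,
missing-value imputation and isotope-ratio formation.

The working representation is the long-format record table produced by the
generator or read from CSV (columns: subject_id, matrix, time_min,
metabolite, isotopologue, replicate, area, is_area). Ratios are formed per
replicate after outlier removal and only then averaged per timepoint.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import NATURAL_ABUNDANCE_15N, TRIPLICATE_OUTLIER_THRESHOLD


class MissingInternalStandardError(ValueError):
    """A measured area has no positive internal-standard area to scale by."""


class UndefinedRatioError(ValueError):
    """Labeled and unlabeled intensities are both zero."""


class UnusableSeriesError(ValueError):
    """Every timepoint of a metabolite series is missing."""


def normalize_to_is(records: pd.DataFrame) -> pd.DataFrame:
    """Scale each integrated area by its internal-standard response.

    Adds a ``value`` column (area / is_area) and a ``provenance`` column
    ("measured" for observed cells, missing areas keep NaN values). A record
    with a measured area but non-positive or missing IS area invalidates the
    run.
    """
    out = records.copy()
    bad = out["area"].notna() & ~(out["is_area"] > 0)
    if bad.any():
        idx = out.index[bad].tolist()[:5]
        raise MissingInternalStandardError(
            f"{int(bad.sum())} record(s) lack a positive IS area (e.g. rows {idx})"
        )
    out["value"] = out["area"] / out["is_area"]
    out["provenance"] = "measured"
    return out


def isotope_ratio(labeled, unlabeled):
    """F = labeled / (labeled + unlabeled), the labeled fraction of total signal."""
    labeled = np.asarray(labeled, dtype=float)
    unlabeled = np.asarray(unlabeled, dtype=float)
    if np.any((labeled < 0) | (unlabeled < 0)):
        raise UndefinedRatioError("intensities must be non-negative")
    total = labeled + unlabeled
    if np.any(total == 0):
        raise UndefinedRatioError("labeled and unlabeled intensities are both zero")
    result = labeled / total
    return float(result) if result.ndim == 0 else result


def detect_triplicate_outliers(
    values, threshold: float = TRIPLICATE_OUTLIER_THRESHOLD
) -> tuple[np.ndarray, bool]:
    """Apply the >30% triplicate deviation rule.

    A run is an outlier when its relative deviation from the mean of the
    other two exceeds the threshold. Returns ``(keep_mask, invalid)`` over
    the input order; ``invalid`` marks a no-consensus triplicate (all runs
    mutually discordant), which is treated as missing downstream. With fewer
    than three present values no test is applied.
    """
    values = np.asarray(values, dtype=float)
    keep = ~np.isnan(values)
    if keep.sum() < 3:
        return keep, False

    def rel_dev(i: int) -> float:
        others = np.delete(values, i)
        m = others.mean()
        return np.inf if m == 0 else abs(values[i] - m) / abs(m)

    devs = np.array([rel_dev(i) for i in range(3)])
    flagged = devs > threshold
    if not flagged.any():
        return keep, False
    if flagged.sum() == 1:
        keep[np.argmax(flagged)] = False
        return keep, False
    # more than one run flagged: if some pair still agrees, drop the single
    # worst deviator; otherwise the triplicate has no consensus
    pair_ok = False
    for i in range(3):
        a, b = np.delete(values, i)
        m = (abs(a) + abs(b)) / 2
        if m > 0 and abs(a - b) / m <= threshold:
            pair_ok = True
    if not pair_ok:
        return np.zeros_like(keep), True
    keep[int(np.argmax(devs))] = False
    return keep, False


def impute_missing(
    series: pd.DataFrame,
    baseline_value: float = NATURAL_ABUNDANCE_15N,
) -> tuple[pd.Series, pd.Series]:
    """Complete a per-timepoint replicate table of isotope ratios.

    ``series`` is indexed by time with replicate columns. Per timepoint the
    surviving replicates are averaged; a fully missing interior timepoint is
    linearly interpolated between its measured neighbours; a missing baseline
    falls back to the 15N natural-abundance ratio. Returns the completed
    per-timepoint means and a provenance Series ("measured" / "imputed").
    """
    if series.notna().sum().sum() == 0:
        raise UnusableSeriesError("all timepoints missing for this metabolite")
    means = series.mean(axis=1, skipna=True)
    provenance = pd.Series(
        np.where(means.notna(), "measured", "imputed"), index=means.index
    )
    if np.isnan(means.iloc[0]):
        means.iloc[0] = baseline_value
    # linear interpolation on the time axis for fully missing timepoints;
    # a missing trailing timepoint stays NaN (no extrapolation)
    means = means.interpolate(method="index", limit_area="inside")
    return means, provenance
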