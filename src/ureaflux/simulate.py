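"""Synthetic tracer-kinetics generator for the oral [15N]ammonium assay.

Simulates the whole measurement chain: a linear two-compartment oral-bolus
model (gut → central ammonia pool → metabolite product pools, Bateman-type
closed form) produces true per-metabolite enrichment fractions; a noise model
then renders them into IS-normalised triplicate isotopologue peak areas in
the long CSV layout the preprocessing stage reads.

The default control preset is calibrated so that the *designed* tracer
recovery — the time-averaged fraction of the administered 15N residing in the
six measured pools over the 120 min test — equals 51%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constants import (
    ALTERNATIVE_METABOLITES,
    DEFAULT_POOLS_UMOL_L,
    DEFAULT_V_DIST_L_PER_KG,
    METABOLITES,
    MOLAR_MASS_15NH4CL,
    NATURAL_ABUNDANCE_15N,
    NOMINAL_DOSE_MG_PER_KG,
    TIME_GRID_MIN,
    T_SPAN_MIN,
    UREA_CYCLE_METABOLITES,
)

DESIGNED_CONTROL_RECOVERY = 0.51  # fraction of dose, calibration target
DEFAULT_ABSORPTION_KA = 0.045     # 1/min, oral absorption half-time ≈ 15 min


class InvalidParameterError(ValueError):
    """Raised when kinetic or noise parameters violate their invariants."""


def dose_umol(dose_mg_per_kg: float, weight_kg: float) -> float:
    """Administered 15N amount in µmol (one 15N per tracer molecule)."""
    return dose_mg_per_kg * weight_kg / MOLAR_MASS_15NH4CL * 1000.0


@dataclass(frozen=True)
class KineticParameters:
    """Parameters of the two-compartment oral-bolus label model.

    ka : first-order gut absorption rate (1/min)
    ke : first-order systemic label clearance rate (1/min)
    f_uc : fraction of absorbed 15N routed through the urea cycle
    split_uc : partition of urea-cycle label among urea/citrulline/arginine
    split_alt : partition of alternative-route label among gln/gly/glu
    pool : endogenous metabolite concentrations (µmol/L)
    v_dist : distribution volume per body weight (L/kg)
    """

    ka: float
    ke: float
    f_uc: float
    split_uc: dict[str, float] = field(
        default_factory=lambda: {"urea": 0.93, "citrulline": 0.05, "arginine": 0.02}
    )
    split_alt: dict[str, float] = field(
        default_factory=lambda: {"glutamine": 0.70, "glycine": 0.15, "glutamate": 0.15}
    )
    pool: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_POOLS_UMOL_L))
    v_dist: float = DEFAULT_V_DIST_L_PER_KG

    def __post_init__(self) -> None:
        if self.ka <= 0:
            raise InvalidParameterError(f"ka must be > 0, got {self.ka}")
        if self.ke < 0:
            raise InvalidParameterError(f"ke must be >= 0, got {self.ke}")
        if not 0.0 <= self.f_uc <= 1.0:
            raise InvalidParameterError(f"f_uc must lie in [0, 1], got {self.f_uc}")
        for name, split, keys in (
            ("split_uc", self.split_uc, UREA_CYCLE_METABOLITES),
            ("split_alt", self.split_alt, ALTERNATIVE_METABOLITES),
        ):
            if set(split) != set(keys):
                raise InvalidParameterError(f"{name} must have keys {keys}")
            if abs(sum(split.values()) - 1.0) > 1e-9:
                raise InvalidParameterError(f"{name} fractions must sum to 1")
            if any(v < 0 for v in split.values()):
                raise InvalidParameterError(f"{name} fractions must be >= 0")
        if set(self.pool) != set(METABOLITES):
            raise InvalidParameterError(f"pool must have keys {METABOLITES}")
        if any(p <= 0 for p in self.pool.values()):
            raise InvalidParameterError("pool concentrations must be > 0")
        if self.v_dist <= 0:
            raise InvalidParameterError("v_dist must be > 0")


@dataclass(frozen=True)
class DiseasePreset:
    """Qualitative enrichment pattern of one disease group.

    residual_flux scales the urea-cycle routing fraction; split overrides
    redistribute label within the urea-cycle or alternative branch (e.g.
    citrulline accumulation distal-block defects, depleted glycine labelling
    in citrin deficiency). Label lost to the urea cycle is diverted to the
    alternative branch, mirroring glutamine accumulation in patients.
    """

    name: str
    residual_flux: float = 1.0
    split_uc: dict[str, float] | None = None
    split_alt: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.residual_flux <= 1.0:
            raise InvalidParameterError("residual_flux must lie in [0, 1]")
        for split in (self.split_uc, self.split_alt):
            if split is not None and abs(sum(split.values()) - 1.0) > 1e-9:
                raise InvalidParameterError("preset splits must sum to 1")

    def apply(self, params: KineticParameters) -> KineticParameters:
        updates: dict = {}
        if self.split_uc is not None:
            updates["split_uc"] = dict(self.split_uc)
        if self.split_alt is not None:
            updates["split_alt"] = dict(self.split_alt)
        return replace(params, **updates) if updates else params


# Presets encode direction-of-change only: proximal blocks (CPS1, OTC, HHH)
# depress all urea-cycle products; distal blocks accumulate the metabolite
# upstream of the defect (citrulline for ASS/ASL, arginine for arginase);
# citrin deficiency shows near-absent glycine labelling.
PRESETS: dict[str, DiseasePreset] = {
    "CONTROL": DiseasePreset("CONTROL", residual_flux=1.0),
    "CPS1D": DiseasePreset("CPS1D", residual_flux=0.05),
    "OTCD": DiseasePreset("OTCD", residual_flux=0.30),
    "ASSD": DiseasePreset(
        "ASSD",
        residual_flux=0.15,
        split_uc={"urea": 0.15, "citrulline": 0.80, "arginine": 0.05},
    ),
    "ASLD": DiseasePreset(
        "ASLD",
        residual_flux=0.20,
        split_uc={"urea": 0.25, "citrulline": 0.70, "arginine": 0.05},
    ),
    "ARGD": DiseasePreset(
        "ARGD",
        residual_flux=0.50,
        split_uc={"urea": 0.45, "citrulline": 0.05, "arginine": 0.50},
    ),
    "CTND": DiseasePreset(
        "CTND",
        residual_flux=0.60,
        split_alt={"glutamine": 0.846, "glycine": 0.004, "glutamate": 0.15},
    ),
    "HHH": DiseasePreset("HHH", residual_flux=0.40),
}


def bateman_fraction(t, ka: float, ke: float):
    """Fraction of the oral bolus residing in product pools at time t.

    Closed-form solution of gut --ka--> pools --ke--> out for a unit bolus in
    the gut at t=0. Handles ke=0 and the ka=ke degenerate case.
    """
    t = np.asarray(t, dtype=float)
    if ke == 0.0:
        return 1.0 - np.exp(-ka * t)
    if abs(ka - ke) < 1e-12:
        return ka * t * np.exp(-ka * t)
    return ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))


def designed_recovery(ka: float, ke: float, t_span: float = T_SPAN_MIN) -> float:
    """Time-averaged pool-resident fraction of the dose over [0, t_span].

    This is exactly what the pipeline's recovery accounting measures on
    noise-free data (AUC of enrichment × pool ÷ span ÷ dose), so it defines
    the generator's designed recovery in closed form.
    """
    if ke == 0.0:
        return 1.0 - (1.0 - np.exp(-ka * t_span)) / (ka * t_span)
    if abs(ka - ke) < 1e-12:
        integral = (1.0 - (1.0 + ka * t_span) * np.exp(-ka * t_span)) / ka
        return integral / t_span
    integral = (
        ka
        / (ka - ke)
        * ((1.0 - np.exp(-ke * t_span)) / ke - (1.0 - np.exp(-ka * t_span)) / ka)
    )
    return integral / t_span


def calibrate_clearance(
    ka: float = DEFAULT_ABSORPTION_KA,
    target_recovery: float = DESIGNED_CONTROL_RECOVERY,
    t_span: float = T_SPAN_MIN,
) -> float:
    """Solve for ke so the designed recovery hits the target fraction."""
    if not 0 < target_recovery < designed_recovery(ka, 0.0, t_span):
        raise InvalidParameterError(
            "target recovery must lie below the zero-clearance ceiling"
        )
    return brentq(
        lambda ke: designed_recovery(ka, ke, t_span) - target_recovery, 1e-8, 10.0 * ka
    )


def control_parameters() -> KineticParameters:
    """Default control kinetics, clearance calibrated to 51% designed recovery."""
    ke = calibrate_clearance()
    return KineticParameters(ka=DEFAULT_ABSORPTION_KA, ke=ke, f_uc=0.85)


def simulate_true_enrichment(
    params: KineticParameters,
    preset: DiseasePreset,
    times=TIME_GRID_MIN,
    dose_mg_per_kg: float = NOMINAL_DOSE_MG_PER_KG,
    weight_kg: float = 70.0,
) -> pd.DataFrame:
    """Noise-free per-metabolite tracer enrichment fractions over time.

    Returns a DataFrame indexed by time (min) with one column per metabolite
    holding the fraction of that pool's molecules carrying the tracer label
    (excess over natural abundance).
    """
    times = np.asarray(times, dtype=float)
    if times[0] != 0.0 or np.any(np.diff(times) <= 0):
        raise InvalidParameterError("times must start at 0 and strictly increase")
    params = preset.apply(params)
    f_uc_eff = params.f_uc * preset.residual_flux

    weights = {
        m: f_uc_eff * params.split_uc[m] for m in UREA_CYCLE_METABOLITES
    } | {
        m: (1.0 - f_uc_eff) * params.split_alt[m] for m in ALTERNATIVE_METABOLITES
    }
    resident = bateman_fraction(times, params.ka, params.ke)
    d_umol = dose_umol(dose_mg_per_kg, weight_kg)
    data = {
        m: weights[m] * resident * d_umol / (params.pool[m] * params.v_dist * weight_kg)
        for m in METABOLITES
    }
    return pd.DataFrame(data, index=pd.Index(times, name="time_min"))


@dataclass(frozen=True)
class NoiseModel:
    """Technical noise for rendering areas: per-(metabolite, matrix) CV,
    replicate dropout, and aberrant-integration outliers."""

    cv_by_metabolite_matrix: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_CVS)
    )
    missing_rate: float = 0.01
    outlier_rate: float = 0.01
    is_cv: float = 0.02  # run-to-run internal-standard response drift
    seed: int = 0

    def __post_init__(self) -> None:
        if any(cv < 0 for cv in self.cv_by_metabolite_matrix.values()) or self.is_cv < 0:
            raise InvalidParameterError("CVs must be >= 0")
        for rate in (self.missing_rate, self.outlier_rate):
            if not 0.0 <= rate <= 1.0:
                raise InvalidParameterError("rates must lie in [0, 1]")

    def cv(self, metabolite: str, matrix: str) -> float:
        return self.cv_by_metabolite_matrix.get((metabolite, matrix), 0.03)


# Plasma CV magnitudes follow the instrument-precision scale of the assay
# (urea tightest, arginine loosest); DBS runs ~70% noisier.
_DEFAULT_CVS: dict[tuple[str, str], float] = {}
for _m, _cv in {
    "urea": 0.016,
    "citrulline": 0.040,
    "arginine": 0.062,
    "glutamine": 0.030,
    "glycine": 0.030,
    "glutamate": 0.040,
}.items():
    _DEFAULT_CVS[(_m, "plasma")] = _cv
    _DEFAULT_CVS[(_m, "DBS")] = round(_cv * 1.7, 4)

# explicit zeros: cv() falls back to 0.03 for unknown keys
NOISE_FREE = NoiseModel(
    cv_by_metabolite_matrix={(m, mx): 0.0 for m in METABOLITES for mx in ("plasma", "DBS")},
    missing_rate=0.0,
    outlier_rate=0.0,
    is_cv=0.0,
    seed=0,
)

# Arbitrary-intensity scales so areas look like integrated peak areas.
_BASE_INTENSITY_PER_UM = 2.0e3
_IS_BASE_AREA = 5.0e5


def render_assay(
    true_curves: pd.DataFrame,
    noise: NoiseModel,
    dose_mg_per_kg: float = NOMINAL_DOSE_MG_PER_KG,
    weight_kg: float = 70.0,
    matrix: str = "plasma",
    subject_id: str = "S1",
    pools: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Render true enrichment curves into noisy triplicate peak-area records.

    Emits one row per (time, metabolite, isotopologue ∈ {unlabeled, 15N},
    replicate 1–3) with columns matching the long CSV interchange schema.
    Baseline rows carry the 15N natural-abundance ratio. Deterministic for a
    given `noise.seed` (or an explicitly supplied generator).
    """
    if matrix not in ("plasma", "DBS"):
        raise InvalidParameterError(f"unknown matrix {matrix!r}")
    pools = dict(DEFAULT_POOLS_UMOL_L) if pools is None else pools
    rng = np.random.default_rng(noise.seed) if rng is None else rng

    rows = []
    for time in true_curves.index.to_numpy(dtype=float):
        for metabolite in METABOLITES:
            e = float(true_curves.at[time, metabolite])
            # labeled molecule fraction: tracer excess on top of natural abundance
            frac_labeled = NATURAL_ABUNDANCE_15N + e * (1.0 - NATURAL_ABUNDANCE_15N)
            base = pools[metabolite] * _BASE_INTENSITY_PER_UM
            cv = noise.cv(metabolite, matrix)
            for rep in (1, 2, 3):
                is_area = _IS_BASE_AREA * _lognoise(rng, noise.is_cv)
                missing = rng.random() < noise.missing_rate
                a_unl = base * (1.0 - frac_labeled) * _lognoise(rng, cv)
                a_lab = base * frac_labeled * _lognoise(rng, cv)
                if rng.random() < noise.outlier_rate:
                    a_lab *= rng.choice((0.5, 1.8))
                for iso, area in (("unlabeled", a_unl), ("15N", a_lab)):
                    rows.append(
                        {
                            "subject_id": subject_id,
                            "matrix": matrix,
                            "time_min": time,
                            "metabolite": metabolite,
                            "isotopologue": iso,
                            "replicate": rep,
                            "area": np.nan if missing else area,
                            "is_area": is_area,
                        }
                    )
    return pd.DataFrame(rows)


def _lognoise(rng: np.random.Generator, cv: float) -> float:
    """Mean-1 log-normal multiplicative noise with coefficient of variation cv."""
    if cv == 0.0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return float(rng.lognormal(-0.5 * sigma * sigma, sigma))


@dataclass
class SubjectAssay:
    """One simulated test occasion: raw records plus subject metadata."""

    subject_id: str
    group: str
    matrix: str
    weight_kg: float
    dose_mg_per_kg: float
    records: pd.DataFrame
    true_params: KineticParameters | None = None


def simulate_cohort(
    n: int,
    preset: DiseasePreset | str = "CONTROL",
    noise: NoiseModel | None = None,
    inter_subject_cv: float = 0.25,
    seed: int = 0,
    matrix: str = "plasma",
    params: KineticParameters | None = None,
) -> list[SubjectAssay]:
    """Simulate a cohort of assays with log-normal inter-subject jitter.

    Subject-level kinetics (ka, ke, f_uc) jitter around the preset with
    mean-preserving log-normal multipliers of coefficient of variation
    `inter_subject_cv`; body weight varies around 70 kg. Fully reproducible
    given `seed`.
    """
    if n < 1:
        raise InvalidParameterError("cohort size must be >= 1")
    if isinstance(preset, str):
        preset = PRESETS[preset.upper()]
    noise = NoiseModel(seed=seed) if noise is None else noise
    base = control_parameters() if params is None else params

    root = np.random.default_rng(seed)
    assays = []
    for i in range(n):
        rng = np.random.default_rng(root.integers(0, 2**31 - 1))
        ka = base.ka * _lognoise(rng, inter_subject_cv)
        ke = base.ke * _lognoise(rng, inter_subject_cv)
        f_uc = min(base.f_uc * _lognoise(rng, inter_subject_cv), 0.99)
        subject_params = replace(base, ka=ka, ke=ke, f_uc=f_uc)
        # body-weight spread scales with the same variability knob so that
        # inter_subject_cv=0 yields literally identical subjects
        weight_sd = 48.0 * inter_subject_cv
        weight = float(np.clip(rng.normal(70.0, weight_sd), 45.0, 110.0)) if weight_sd else 70.0
        subject_id = f"{preset.name}_{i + 1:03d}"
        curves = simulate_true_enrichment(
            subject_params, preset, TIME_GRID_MIN, NOMINAL_DOSE_MG_PER_KG, weight
        )
        records = render_assay(
            curves,
            noise,
            dose_mg_per_kg=NOMINAL_DOSE_MG_PER_KG,
            weight_kg=weight,
            matrix=matrix,
            subject_id=subject_id,
            rng=rng,
        )
        assays.append(
            SubjectAssay(
                subject_id=subject_id,
                group=preset.name,
                matrix=matrix,
                weight_kg=weight,
                dose_mg_per_kg=NOMINAL_DOSE_MG_PER_KG,
                records=records,
                true_params=subject_params,
            )
        )
    return assays
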