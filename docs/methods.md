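# Methods

## The assay and what the pipeline computes

An oral bolus of [¹⁵N]ammonium chloride (nominal 2 mg/kg ≈ 0.037 mmol/kg)
feeds the hepatic ammonia pool; a functioning urea cycle moves the label into
urea (and transiently into citrulline and arginine), while transamination
routes divert it into glutamine, glycine and glutamate. Blood sampled at 0,
15, 30, 45, 60, 90 and 120 min yields, per metabolite, the labeled and
unlabeled isotopologue peak areas of technical triplicate injections, each
scaled by a co-injected multiply-labeled internal standard.

The pipeline computes, per assay:

1. **Isotope ratios.** F = labeled/(labeled + unlabeled) per replicate,
   after internal-standard scaling and the triplicate outlier rule (below);
   replicate ratios are averaged per timepoint. The baseline ratio of an
   untreated subject is the ¹⁵N natural abundance (0.003663).
2. **Enrichment.** IE(t) = 100·(F_t − F_0), anchored to exactly 0 at t = 0.
   Negative excursions are kept — clamping would bias baseline-level AUCs
   upward.
3. **Normalisation.** IE is multiplied by nominal/actual dose and by the
   subject-to-control-mean ratio of the unlabeled (endogenous) signal. The
   concentration factor converts enrichment toward a label-amount scale
   relative to the control pool: a subject with a 2× pool at equal enrichment
   carries 2× the label. Both factors default to 1 when no deviation exists.
4. **AUC.** Trapezoidal quadrature on the observed timepoints over 0–120
   min; no extrapolation beyond the last sample. Trapezoid is exact for
   piecewise-linear curves and the assay grid keeps the quadrature error of
   the smooth kinetic curves well below the technical noise.
5. **Stability filter.** A metabolite whose total (labeled+unlabeled,
   IS-normalised) signal has CV > 10% across the test is excluded from the
   R and T sums — its concentration was not at steady state, so its
   enrichment is not interpretable semi-quantitatively. Exclusion is strict
   (> 10%), applied consistently to numerator and denominator, and logged.
6. **Scores.** R (urea-cycle AUC share), T (percent of dose observed), RUF
   (percent of the control mean R·T product), tracer recovery (= T, with the
   per-metabolite partition kept for pathway-diversion reports).

## Preprocessing rules

**Triplicate outlier rule.** A run is omitted when it deviates more than 30%
from the *mean of the other two* runs — the symmetric, order-free reading of
"deviation compared to the other two runs". Two edge cases need a policy:

- all three runs mutually discordant (every pairwise relative difference
  > 30%): the triplicate is invalidated (treated as missing) rather than
  keeping an arbitrary pair;
- one extreme value inflating every run's deviation while two runs still
  agree pairwise: the single worst deviator is dropped and the concordant
  pair kept.

The rule is invariant to replicate ordering and uniform rescaling.

**Imputation.** A missing replicate contributes nothing to the timepoint mean
(equivalently: it is imputed as the mean of the surviving replicates); a
fully missing non-baseline timepoint is linearly interpolated between its
measured neighbours; a missing baseline ratio falls back to the natural
abundance constant. Measured values are never altered and the procedure is
idempotent. A metabolite with no measured timepoint at all is marked
unusable.

## The T unit bridge

The ratio T = T_measured/T_theoretical needs enrichment AUCs converted into
amounts commensurable with the administered dose. The bridge used is

    amount_m = AUC_m / 100 · pool_m · V_d · weight / t_span

i.e. the time-averaged enrichment fraction times the pool size, with pool
concentrations in µmol/L (defaults: urea 5000, glutamine 600, glycine 250,
arginine 80, glutamate 60, citrulline 30 — typical fasting plasma values,
configurable per assay), a distribution volume V_d of 0.6 L/kg (total body
water surrogate) and t_span = 120 min. T_theoretical is the administered
¹⁵N amount (one ¹⁵N per tracer molecule, molar mass 54.485 g/mol). This
"absolute" mode is the default because it makes tracer recovery an actual
mass balance. A "control_calibrated" mode is available that rescales T so
the control cohort mean matches a designated value, for cross-cohort
comparability when pool concentrations are uncertain; the RUF is invariant
to that choice because the scale cancels between patient and control means.

## Control reference

R̄_C and T̄_C are arithmetic means over ≥ 2 control assays. Each control's
own RUF is computed against the cohort means including itself (leave-in),
matching how a reference range is normally quoted; leave-one-out is offered
as a sensitivity option. The reference band is mean ± SD of the control
RUFs; per-metabolite mean ± SEM control curves are retained for graphical
comparison. A persisted reference (YAML) also stores the control mean
unlabeled signals, so scoring a later patient against it reproduces the
joint-run result exactly.

## Synthetic-data generator

The generator emulates the assay design end to end so every stage is
testable without patient data. No kinetic model is implied by the assay
itself; the generator uses the simplest model that produces rising 0–120 min
enrichment curves — a linear two-compartment oral-bolus chain
(gut →ka→ central pool →ke→ out) with Bateman-type closed form. The
pool-resident fraction of a unit dose is

    b(t) = ka/(ka−ke) · (e^(−ke·t) − e^(−ka·t))

and metabolite m receives the weight w_m of that label: f_uc·split_uc[m] for
urea-cycle products and (1−f_uc)·split_alt[m] for the alternative branch,
divided by its pool size (pool_m·V_d·weight) to yield an enrichment
fraction. Disease presets scale f_uc by a residual-flux factor in [0, 1] —
the label lost to the urea cycle diverts to the alternative branch, as in
patients — and redistribute the within-branch splits to encode qualitative
disease patterns only (citrulline accumulation in ASS/ASL deficiency,
arginine accumulation in arginase deficiency, near-absent glycine labelling
in citrin deficiency). Magnitudes are not fitted to any cohort.

**Calibration.** The control preset fixes ka = 0.045/min (oral absorption
half-time ≈ 15 min) and solves ke so that the *designed recovery* — the
closed-form time average of b(t) over 0–120 min, which is exactly what the
pipeline's recovery accounting measures on noise-free data — equals 0.51.
The control urea-cycle routing is f_uc = 0.85 with splits 0.93/0.05/0.02
(urea/citrulline/arginine) and 0.70/0.15/0.15 (glutamine/glycine/glutamate).

**Noise model.** Independent mean-1 log-normal multiplicative noise per
isotopologue area with per-(metabolite, matrix) CVs (plasma defaults
urea 1.6% … arginine 6.2%; DBS 1.7× noisier), 2% internal-standard drift,
replicate dropout (default 1%) and aberrant-integration outliers (default
1%, a ×1.8 or ×0.5 distortion of the labeled area). Cohorts add
mean-preserving log-normal inter-subject jitter (default CV 0.25) on ka, ke
and f_uc plus body-weight variation scaled by the same knob. All randomness
flows from a single integer seed; identical seeds give identical fixtures.

**What the generator does not emulate.** Chromatographic drift and
carry-over, matrix-specific recovery bias between plasma and DBS, diurnal
or dietary pool-size changes within a test, the ¹⁵N₂ urea isotopologue
(doubly labeled urea is rare at this dose), age- or severity-dependent
kinetics, and genuine inter-subject pool-concentration variation. Its
inter-subject recovery spread (SD ≈ 5 points) is narrower than real control
cohorts. Passing round-trip tests therefore demonstrates the correctness of
the computations, not the clinical behaviour of real assays.

## Validation statistics

LLOQD is three sample standard deviations of the baseline isotope ratio —
with the natural-abundance baseline there is no meaningful detection limit,
only a smallest reliably distinguishable enrichment. Precision is the
percent CV of replicate ratios; inter-experiment precision aggregates across
day-level means (the pooled-across-preparations alternative is ambiguous and
was not chosen). Mass accuracy is the signed ppm error against monoisotopic
exact masses, aggregated as mean ± rms. Carry-over is the blank-to-sample
percentage. Matrix agreement is Pearson's r over paired plasma/DBS
enrichment values. Group comparisons use an unpaired two-tailed t-test for
two groups and one-way ANOVA with Tukey HSD follow-up for three or more
(α = 0.05); sample (n−1) SD is used throughout.

## Numerical and design choices

- Ratios are formed per replicate, then averaged — at high technical CV this
  differs from pooling areas first; the per-replicate order lets the
  triplicate rule act on the quantity that matters downstream.
- Intra-individual RUF repeatability is reported as a CV across repeat
  assays (an interpretation; a range statistic would also be defensible).
- Degenerate inputs raise typed errors rather than returning NaN: zero
  total AUC (R), zero dose or missing pool (T), zero control product (RUF),
  all-missing series (imputation), both-zero intensities (ratio).
- Problem sizes in the shipped tests and the acceptance script (22-subject
  control cohorts; 50 repetitions of 4-subject cohorts per severity grade
  for the ordering check) mirror the assay's own cohort scale and keep every
  stage exercised end to end.

## Known limitations

- The kinetic model is a deliberate simplification: single central pool, no
  recycling of label between metabolite pools, clearance identical across
  pools. It supports round-trip and ordering tests, not pharmacokinetic
  inference.
- Pool concentrations enter T as configured constants; true per-subject
  concentrations would require quantitative metabolite assays alongside the
  isotope ratios.
- The concentration-normalisation convention (multiplying enrichment by the
  subject/control unlabeled-signal ratio) is one defensible direction of a
  correction whose exact published arithmetic is not fully specified;
  it is configurable and documented here so results remain comparable.
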