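# ureaflux

Quantification of in vivo ureagenesis — the urea cycle's capacity to detoxify
ammonia — from a low-dose oral [¹⁵N]ammonium chloride tracer test. The package
is aimed at laboratories running stable-isotope ureagenesis assays for urea
cycle disorder (UCD) diagnostics and therapy monitoring: it takes integrated
LC-HRMS isotopologue peak areas (after a 2 mg/kg, ≈0.037 mmol/kg oral tracer
dose with sampling at 0, 15, 30, 45, 60, 90 and 120 min) and returns per-
metabolite ¹⁵N enrichment curves, AUC summaries, tracer recovery and the
relative ureagenesis function (RUF), for plasma or dried blood spot (DBS)
samples.

## The score

For each of six metabolites (urea, citrulline, arginine, glutamine, glycine,
glutamate) the isotope ratio F = labeled/(labeled + unlabeled) is formed per
timepoint, and the isotopic enrichment is the baseline-subtracted percentage

    IE(t) = 100 · (F_t − F_0)

Curves are normalised for tracer dose and endogenous metabolite concentration,
then summarised by the trapezoidal area under the curve A over 0–120 min.
Two quantities condense an assay:

    R = (A_urea + A_cit + A_arg) / (A_urea + A_cit + A_arg + A_gln + A_gly + A_glu)
    T = 100 · T_measured / T_theoretical

R is the fraction of observed label carried by urea-cycle products; T (also
reported as *tracer recovery*) is the share of the administered ¹⁵N observed
across all six pools, where each AUC is converted to a label amount via the
metabolite's pool concentration, a distribution-volume constant (0.6 L/kg)
and body weight. A patient assay P is scored against a control cohort C as

    RUF = 100 · (R_P · T_P) / (R̄_C · T̄_C)

so that the control mean sits at 100% by construction. Metabolites whose
total concentration drifts during the test (CV > 10%) are excluded from the
R and T sums; technical triplicate runs deviating > 30% from the other two
are rejected before ratios are averaged.

Because real patient measurements cannot ship with the code, the package
includes a first-class synthetic-data generator: a closed-form two-compartment
oral-bolus label model with disease presets (CPS1, OTC, ASS, ASL and arginase
deficiencies, citrin deficiency, HHH syndrome) and a technical noise model,
which every pipeline stage is tested against. See `docs/methods.md` for the
model and its calibration.

## Worked example

```python
import numpy as np
from ureaflux import AssayConfig, NoiseModel, run_pipeline, simulate_cohort

controls = simulate_cohort(22, "CONTROL", noise=NoiseModel(seed=1), seed=1)
patients = simulate_cohort(3, "OTCD", noise=NoiseModel(seed=2), seed=2)
result = run_pipeline(controls + patients, AssayConfig())

ref = result.reference
print(f"control reference: R̄_C = {ref.R_bar_C:.3f}, T̄_C = {ref.T_bar_C:.1f}%, "
      f"RUF range {ref.ruf_range[0]:.0f}–{ref.ruf_range[1]:.0f}% (n = {ref.n_controls})")
recov = [r.recovery for r in result.results if r.group == "CONTROL"]
print(f"mean control tracer recovery: {np.mean(recov):.1f} ± {np.std(recov, ddof=1):.1f}%")
for r in result.results:
    if r.group == "OTCD":
        print(f"{r.assay_id}: R = {r.R:.3f}, T = {r.T:.1f}%, RUF = {r.RUF:.1f}%")
```

prints

```
control reference: R̄_C = 0.722, T̄_C = 52.1%, RUF range 72–129% (n = 22)
mean control tracer recovery: 52.1 ± 4.7%
OTCD_001: R = 0.181, T = 51.9%, RUF = 25.0%
OTCD_002: R = 0.180, T = 44.8%, RUF = 21.5%
OTCD_003: R = 0.119, T = 46.5%, RUF = 14.7%
```

The 22 simulated controls absorb and retain about half the tracer (the
generator's designed control recovery is 51%), and their RUFs define the
reference band. The simulated OTC-deficient subjects keep near-normal
absorption (T) but route only a fraction of the label through the urea
cycle, so R collapses and their RUF falls far below the control range —
the pattern the score is designed to expose.

The same pipeline is available from the shell:

```bash
ureaflux simulate --preset CONTROL --n 22 --seed 1 --out controls.csv
ureaflux ruf controls.csv --meta controls.meta.csv \
    --out ruf.csv --reference-out reference.yaml
ureaflux ruf patient.csv --reference reference.yaml --out patient_ruf.csv
```

with additional subcommands `preprocess`, `enrich`, `validate` (LLOQD and
baseline precision per metabolite/matrix) and `report` (pre/post-therapy
deltas).

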