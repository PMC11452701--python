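# uteroflow

Personalised reduced-order maternal haemodynamics: predict pressure and
velocity waveforms in the utero-ovarian vasculature downstream of the
uterine artery from routine non-invasive measurements, derive dimensionless
candidate biomarkers, and evaluate them as binary classifiers on synthetic
cohorts.

The package has five parts:

| module | what it does |
| --- | --- |
| `uteroflow.cohort` | synthetic patient cohorts (truncated-normal marginals per group) and parametric uterine Doppler waveform templates with exact peak-systolic (S) and end-diastolic (D) velocities |
| `uteroflow.model` | 1D pulse-wave network solver (Lax–Wendroff finite volume, tube law, Riemann-invariant boundary coupling, numba-JIT inner loop) with three-element Windkessel terminals and a lumped utero-ovarian RC cascade (arcuate + radial/spiral compartments) per side |
| `uteroflow.personalize` | damped multiplicative fixed-point calibration of each patient's "digital twin" against SBP/DBP, HR, CO, PWV and uterine Doppler S/D |
| `uteroflow.biomarkers` | the six dimensionless terms π₁…π₆, pressure pulsatility index PPI = (P_max − P_min)/P_mean, resistance index RI = (V_max − V_min)/V_max, pulsatility index PI = (V_max − V_min)/V_mean, and the per-patient feature table |
| `uteroflow.classify` | Welch t-test, Cohen's d, rank AUC, repeated-holdout logistic regression, exact 1-D 2-means clustering with centroid-midpoint thresholds, paired DeLong test, noncentral-t power/sample-size, [0,1] normalisation |

`uteroflow.pipeline` / the `uteroflow` CLI chain everything together.

## CLI

```bash
uteroflow synth --seed 1 --out cohort.csv          # 12 NPE + 9 PE synthetic patients
uteroflow simulate --site aortic_root --out root.csv
uteroflow calibrate --cohort cohort.csv --out twins.json
uteroflow biomarkers --cohort cohort.csv --out features.csv
uteroflow classify --features features.csv --out report.json
uteroflow run --seed 1 --out-dir out/              # whole pipeline, one seed
uteroflow export-network --preset reduced --out network.yaml
```

`run` writes `cohort.csv`, `twins.json`, `features.csv` and `report.json`
(per-feature accuracy / 95% CI / sensitivity / specificity / AUC for both
supervised and unsupervised evaluation, plus t-test p-values and effect
sizes), with the seed and a config hash recorded for provenance.

Two network presets exist: `reduced` (9 segments, default; desk-scale,
~25 ms per periodic solve after JIT) and `full` (24 segments, aorta and
major branches). Networks round-trip through YAML (`export-network`).

## Notes

* Clinical units (mmHg, cm/s, L/min, bpm) at all I/O boundaries; SI
  internally. Dimensionless terms are computed in SI and are invariant to
  unit-system rescaling (tested to 1e-12).
* Patients whose independently drawn measurements are jointly infeasible
  for the reduced model (e.g. a very low uterine RI combined with a very
  large pulse pressure) are flagged as non-converged, excluded from the
  feature table, and listed in the run report — never silently fitted.
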