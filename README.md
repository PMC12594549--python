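# shiftqa

**Virtual fine-pitch diode-array QA for stereotactic radiosurgery, fully in silico.**

Patient-specific QA of SRS plans must verify dose distributions with very steep
gradients around small (~1 cm) targets. Radiochromic film resolves them but is
disposable and labour-intensive; general-purpose diode arrays are reusable but
their 10 mm detector pitch undersamples the penumbra entirely. A practical
workaround is to repeat the array measurement under small translational couch
shifts (1 mm increments) and merge the shifted acquisitions — re-expressed in
the beam frame via the known couch coordinates — into a single *virtual*
measurement with 5, 4, 3, 2 or 1 mm effective spacing along the shift axis.

`shiftqa` implements that whole workflow end to end with a synthetic stand-in
for the linac/TPS/film chain, for medical physicists and QA-method developers
who want to study when and why the virtual-spacing trick works:

- **Synthetic reference doses** — error-function flat-top fields,
  `D(r) = b·D_max + (1−b)·D_max·Φ((R−r)/σ)`, for a single 1 cm target at the
  isocenter or a two-target single-isocenter (SIMT) geometry with targets at
  SI = ±60 mm, on a 1 mm grid.
- **Detector model** — 10 mm-pitch diode lattice with anisotropic active-area
  averaging over a 7 × 3 mm² (SI × RL) footprint, multiplicative Gaussian
  noise, plus a fine-pitch point-detector "film" mode.
- **Shift planning and merging** — schedules `{0, t, 2t, …} < pitch` per axis
  and exact union merging with coincidence averaging.
- **Scoring** — central-axis profile RMSE,
  `RMSE(%) = sqrt( (1/n) Σᵢ (D_ref,i − D_meas,i)² )`, paired on the reference
  grid positions along the line, and 2D gamma analysis
  `γ(i) = min_r sqrt( |r−rᵢ|²/δ_dta² + (D_ref(r)−D_i)²/δ_dose² )`
  with global or local normalisation, dose threshold, and a dense
  reference-upsampled search.

## Worked example

```python
from shiftqa import ExperimentConfig, run_experiment

report = run_experiment(ExperimentConfig(scenario="single_field", seed=1))
print(report.summary.query("metric == 'rmse'")[["spacing", "mean", "sd"]])
```

prints (three replicates, 0.5% noise):

```
spacing     mean       sd
     10 4.268054 0.034185
      5 4.205785 0.028623
      4 3.245168 0.025729
      3 2.941538 0.013758
      2 2.684731 0.044969
      1 2.498938 0.006665
   film 0.091837 0.035073
```

Reading: at the native 10 mm pitch the array has no sample inside the
penumbra of the 1 cm field, so the measured profile shape misses the gradient
and its RMSE vs the reference is largest; every refinement of the virtual
spacing adds gradient samples and lowers the RMSE monotonically. The floor at
1 mm (≈2.5%, vs ≈0.1% for the point-sampling film stand-in) is the
partial-volume residual of the 7 × 3 mm² diode footprint, which no amount of
resampling removes. The matching gamma table (`metric == 'gamma_pass_rate'`)
shows the complementary effect: at 10 mm pitch only the single flat-top point
survives the 10% threshold (3%/3 mm passes at 100%, every tighter tolerance
fails it), while the 5 and 1 mm virtual spacings add penumbra points that pass
at tight distance criteria.

The same study is available from the shell:

```bash
shiftqa run-experiment --scenario single_field --seed 1 --out out/
shiftqa plan-shifts --target-spacing 5        # -> offsets 0, 5 mm (2 acquisitions)
```

plus `simulate-dose`, `sample`, `merge`, `rmse` and `gamma` subcommands for
the individual steps on plain-text grid/CSV files.

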