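# aquaspec

Water correction and chemometrics for infrared microspectroscopy of live
cells in aqueous chambers, with a forward simulator of the measurement.

## The problem

FTIR microspectroscopy of living cells requires the cell to sit in a
phosphate-buffered saline (PBS) layer 6–12 μm thick. Water absorbs
ferociously in the mid-IR — the OH bending mode near 1640 cm⁻¹ sits right
on top of the protein amide I band, and the OH stretch envelope
(3000–3500 cm⁻¹) swamps everything above 3000 cm⁻¹ — so the bulk-water
contribution must be estimated and subtracted before any biology can be
read out of the spectrum. At the thicker pathlengths that avoid compressing
the cell, the bending mode additionally approaches the detector's
saturation ceiling, distorting the apparent absorbance.

`aquaspec` implements the complete workflow for this experiment class:

1. **Water correction** (`aquaspec.water`). For each cell spectrum
   *s*, paired with a bulk-PBS spectrum *w* measured beside the cell, solve
   over the protein window 1500–1700 cm⁻¹ the least-squares model

   *s*(ν) ≈ α·*m*(ν) + β·*w*(ν) + *b*₀ + *b*₁ν,

   where *m* is a Matrigel (protein) reference spectrum. Only the scaled
   water term β·*w* — the "water to be removed" — is subtracted, over the
   full grid; α and the baseline are diagnostics. Points whose apparent
   absorbance exceeds a photometric-reliability cutoff (default 1.5 AU) are
   excluded from the fit. Two literature alternatives are included for
   comparison: silent-region (1800–2500 cm⁻¹) flatness optimization and
   iterative water re-addition balancing the flanks of the 2900 cm⁻¹ C–H
   stretch.
2. **Preprocessing** (`aquaspec.preprocess`): quality control (amide-signal
   floor, 2.5 AU saturation guard, silent-region noise ceiling),
   Savitzky-Golay smoothing/second derivatives, vector normalization and
   region cutting, in configurable order with two shipped presets
   (`spacer_eval`, `drug_study`).
3. **Classification** (`aquaspec.chemometrics`): PCA compression (95%
   explained variance, capped at 21 components) followed by canonical
   variate analysis — the generalized eigenproblem
   **S**_b **v** = λ(**S**_w + εI)**v** — with nearest-centroid assignment
   in canonical space and stratified, leakage-free k-fold cross-validation
   (PCA and CVA refit per training fold).
4. **Simulation** (`aquaspec.simulate`): a Beer–Lambert forward model of
   the paired acquisition — Gaussian cell bands (amide I/II, phosphate
   1217/1244 cm⁻¹, lipid C–H), pathlength-scaled water, detector
   saturation as a stray-light floor in transmittance space, noise, and
   drug mode-of-action classes as band-height multipliers (a DNA
   cross-linker perturbing the phosphate stretches, a kinase inhibitor
   perturbing amide II).
5. **Orchestration** (`aquaspec.pipeline`, `aquaspec` CLI): end-to-end runs
   with manifests that replay bit-identically.

## Worked example

Simulate the default three-class drug study (120 cells per class, three
replicate loadings, 10 μm water layer), correct, preprocess and
cross-validate:

```python
from aquaspec import (
    ChamberConfig, FitConfig, correct_set, default_grid, generate_study,
    kfold_crossvalidate, matrigel_reference, run_pipeline,
)

grid = default_grid()
study = generate_study(grid, n_per_class=120, seed=0,
                       chamber=ChamberConfig(spacer_um=10.0))
corrected, table = correct_set(study, matrigel_reference(grid), FitConfig())
print(table.head(3).round(4).to_string(index=False))

processed, qc = run_pipeline(corrected, "drug_study")
print(f"QC: {qc.n_passed} passed, {qc.n_failed} excluded")

labels = [s.meta["label"] for s in processed]
report = kfold_crossvalidate(processed, labels, k=5, seed=0)
print(report.to_table().to_string())
```

Output:

```
        cell_id  coefficient  reference_weight  fit_residual_rms  flatness_1800_2500                flags
control_r1_c000       0.8297            0.9997            0.0059              0.0051 saturation_masked_29
control_r1_c001       1.0289            0.9817            0.0071              0.0058 saturation_masked_32
control_r1_c002       1.0871            1.0569            0.0077              0.0062 saturation_masked_34
QC: 360 passed, 0 excluded
             control crosslinker kinase_inhibitor
k
1          95.833333        87.5             87.5
2               87.5       100.0             87.5
3          95.833333        87.5             87.5
4          83.333333   95.833333             75.0
5          83.333333   95.833333        79.166667
Range (%)      83-96      88-100            75-88
Mean (%)          89          93               83
```

The `coefficient` column is β, the per-cell water scale; it tracks each
cell's true local water amount (drawn from U(0.85, 1.15) by the simulator).
The cross-validation table is per-fold, per-class percent correctly
classified: with the default calibrated effect sizes, all three treatment
classes are recovered at ~80–95% despite every spectrum having carried a
2–2.5 AU water background. The same run is available from the shell:

```sh
aquaspec run-all -o myrun --seed 0
```

which writes corrected spectra, QC and correction reports, class mean ± sd
spectra, CVA scores (CV1/CV2), the cross-validation table, a band-level
effect-size report and a replayable `manifest.json`.

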