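# Methods

This note records the models, parameter choices and numerical decisions
behind `aquaspec`, and what the synthetic studies do and do not establish
about real measurements.

## Measurement model

A transmission measurement of a cell in an aqueous chamber is modeled as

    A_true(ν) = A_cell(ν) + c_w · A_water(ν; d)
    A_app(ν)  = −log10( 10^(−A_true(ν)) + 10^(−L) ) + ε_noise

where `d` is the chamber pathlength (spacer thickness, μm), `c_w` a
per-spot water amount, `L` the detector's apparent-absorbance ceiling and
`ε_noise` additive Gaussian noise. The saturation operator is a one-
parameter stray-light floor in transmittance space: it is monotone,
differentiable, exact at low absorbance, and flattens strong bands toward
`L` the way a detector starved of light does. Each simulated cell comes
with a paired bulk-PBS spectrum from "beside" the cell carrying its own
independent water amount near 1 — the paired design the correction method
assumes.

Absorbances are additive over layers (Beer–Lambert), so all components
scale linearly in `d` before saturation.

### Water band model

Unit-bending-peak composition: OH bend 1640 cm⁻¹ (FWHM 85), the weak
association/combination band 2130 cm⁻¹ (height 0.05, FWHM 180) which is
the only feature in the otherwise silent 1800–2500 cm⁻¹ region, and a
two-component OH stretch envelope (0.40 @ 3280, 0.25 @ 3480). The whole
shape is scaled by `water_absorptivity_scale · spacer_um` with a default
scale of 0.2 AU/μm at the bending peak, so the three study pathlengths
6/10/12 μm give bending absorbances of 1.2/2.0/2.4 AU — the thickest
spacer operating close to the default 2.5 AU ceiling, which is the regime
in which saturation artifacts appear in the amide I region.

The stretch envelope is deliberately scaled down relative to pure liquid
water (where it is ~3× the bend). At real pathlengths the stretch region
saturates outright and is discarded; keeping it within the detector's
range in the simulator preserves a usable 2750–3000 cm⁻¹ lipid region and
the flank windows used by the re-addition method, while avoiding a pinned
region whose content is pure artifact. This is a simplification, recorded
here: the simulator understates how badly the >3000 cm⁻¹ region degrades
in practice.

### Cell and reference model

The default cell is a sum of Gaussian bands: amide I (1654, 0.50 AU,
FWHM 45), amide II (1545, 0.30, 40), CH bending (1455), carboxylate
(1396), nucleic-acid phosphate asymmetric stretches (1217, 0.08, 25 and
1244, 0.07, 25), phosphate symmetric stretch (1085), and three lipid C–H
stretches (2852/2925/2958). Band positions follow standard biospectroscopy
assignments; heights are plausible for a ~15 μm cell and widths are fixture
constants. The Matrigel reference is protein-only (amide I + II at the
cell's amide ratio, water-free) — Matrigel is protein-dominated, and the
reference's job in the fit is to model the cellular protein envelope
inside the fit window.

The `intracellular_water_fraction` parameter (0.70) documents that
structural water is ~70% of cell mass; in this band model structural water
is inseparable from the cell signature, so the parameter is descriptive
and the correction never targets it — only bulk water is removed.

### Drug-effect classes and calibration

Treatment classes are multiplicative band-height changes: the DNA
cross-linker class scales both phosphate stretches ×1.30; the kinase-
inhibitor class scales amide II ×0.82. Real effect sizes for such agents
are unknown; these values were calibrated once so that the default study
(120 cells/class, 3 replicates, 10 μm) cross-validates at the per-class
accuracies typical of single-cell FTIR mode-of-action studies (~80–90%),
and then frozen. Detectability is monotone in the multiplier, so they are
the single knob controlling task difficulty.

Per-cell biological variability is lognormal height jitter (sd 5%) on
every band independently; each replicate loading carries a multiplicative
gain (sd 2%) emulating loading-to-loading variation; per-spot water varies
as c_w ~ U(0.85, 1.15) (samples) and U(0.97, 1.03) (paired PBS); noise sd
is 0.004 AU. The default grid is 1000–3600 cm⁻¹ at 2 cm⁻¹ — a typical
mid-IR digitization; nothing in the methods depends on the exact spacing.

## Water correction

The primary method fits, over 1500–1700 cm⁻¹ only, the joint model
`sample ≈ α·matrigel + β·pbs + baseline(linear)` by ordinary least squares
and subtracts β·pbs over the full grid. Decisions:

- **Joint two-component fit.** Fitting the sample to the reference alone
  cannot identify a PBS coefficient; including both terms plus a linear
  baseline is the minimal well-posed model in which β is identified. The
  baseline absorbs offset drift and is never subtracted.
- **Only β·pbs is removed.** The reference weight α and baseline are
  diagnostics; removing fitted cellular signal would defeat the purpose.
- **Non-negativity** of β by clip-and-refit: negative water content is
  unphysical; the clipped path refits α and baseline without the water
  column and flags the result.
- **Photometric reliability mask** (`saturation_cutoff`, default 1.5 AU):
  fit points where sample or PBS apparent absorbance exceeds the cutoff
  are dropped. Transmission-mode response is nonlinear well below full
  saturation; at 10–12 μm the bending peak inside the fit window is
  visibly compressed, and without the mask β is biased low (≈0.96 instead
  of tracking c_w ≈ 1.0) and acquires treatment-class-dependent shifts
  that normalization then smears across the whole spectrum. The mask is
  skipped (and flagged) if fewer than 5× the parameter count of reliable
  points remain.
- **Collinearity guard**: condition number of the column-normalized design
  above 1e8 raises an error rather than returning a silently corrupted β.

The two comparison methods follow their published descriptions: flatness
optimization minimizes the RMS deviation from a straight line of
`sample − β·water` over 1800–2500 cm⁻¹ (bounded scalar minimization on
[0, 3], tolerance 1e-6); iterative re-addition finds γ ≥ 0 balancing the
mean absorbance of 2750–2800 vs 3000–3050 cm⁻¹ (50 cm⁻¹ flanks of the
2900 cm⁻¹ alkyl stretch). The re-addition objective |a + γb| is linear in
γ, so the global minimizer is computed in closed form and clipped at zero;
a vanishing water flank slope is flagged as degenerate instead of
searched.

## Preprocessing

Two shipped presets mirror the two study workflows:

- `spacer_eval`: qc → SG smoothing (9 points, polyorder 2, the standard
  order for pure smoothing — the source protocols state only the point
  count) → vector normalization.
- `drug_study`: qc → vector normalization → second derivative as a single
  SG operator (13 points, 3rd order, deriv 2 — differentiation and
  smoothing are one convolution, the standard reading) → cut to
  1100–1575 ∪ 2750–3000 cm⁻¹, removing the saturated bending/amide I
  region and the information-free 1800–2750 cm⁻¹ range.

Derivative outputs are scaled by (grid spacing)^(−2) so units are
AU·cm². Edges use `scipy.signal.savgol_filter(mode="interp")` — a
polynomial fit within the one-sided window, no truncation. After a cut,
segment boundaries travel in the spectrum metadata and every later filter
runs per contiguous segment, so no convolution window straddles the gap.
Second-derivative spectra are not re-normalized unless the step order says
so; step order is data, not convention, because the two workflows genuinely
differ.

QC thresholds are package defaults (the source workflows name quality
control but no criteria): amide-region (1600–1700) height ≥ 0.05 AU above
the window-edge chord, no point above 2.5 AU (saturation guard), and
detrended silent-region (1800–2500) RMS ≤ 0.01 AU. They pass clean
synthetic spectra and fail flat, saturated or noise-dominated ones;
exclusion is an outcome with named criteria, never an error.

## Chemometrics

PCA is mean-centred (full SVD); the retained count is the smallest whose
cumulative explained fraction reaches `variance_target` (default 0.95)
capped at `pc_cap` (default 21) — reproducing "~21 PCs ≈ 95%" behaviour on
data of this rank while staying defined on any input. CVA solves
`S_b v = λ (S_w + εI) v` with `scipy.linalg.eigh`; the ridge defaults to
1e-8·trace(S_w)/dim, enough to regularize a numerically singular
within-class scatter without disturbing well-posed problems (pass
`ridge=0` to make singularity a hard error). At most classes − 1 canonical
directions are kept; each direction's sign is fixed by making its
largest-magnitude loading positive so repeated fits are comparable.

Classification is nearest class centroid in canonical space (Euclidean;
Mahalanobis behind a flag), with deterministic lexicographic tie-breaking,
flagged. Cross-validation is stratified (per-class counts here are small
enough that unstratified folds would be noisy), seeded, and leakage-free:
PCA and CVA are refit on each training fold and the held-out fold is only
projected in. A `pca_on_all` flag reproduces the whole-data-PCA variant
some reports use; it is not the default. Null calibration (random labels)
sits inside the binomial band of chance; note that fivefold estimates on a
single dataset are mildly overdispersed relative to binomial because the
five folds share training data, and that studies with replicate batch
gains contain a genuine (batch) signal, so calibration nulls must assign
labels independently of replicate structure.

## What the synthetic studies show — and don't

Passing tests establish that the implementation recovers known mixing
coefficients exactly and under noise, that the filters and eigensolvers
match independent oracles, that cross-validation is calibrated at chance
on exchangeable nulls, and that at the calibrated effect sizes the full
pipeline separates the three classes and localizes each drug's effect to
its target window (phosphate 1170–1250; amide II 1480–1560) at 10 and
12 μm pathlengths. They do not establish performance on real cells: the
simulator's bands are Gaussian and independent, scattering and dispersion
artifacts are absent (reasonable for index-matched aqueous holders, where
resonant-Mie distortion is small, but still a simplification), PBS salt
bands are neglected, the >3000 cm⁻¹ water stretch is understated by
design, and real biological covariance between bands is not modeled.

## Problem sizes

Default studies use 120 cells per class in 3 replicates (360 cells plus
360 paired PBS spectra per study) on a 1301-point grid; null calibrations
use 20 independent pools of 200 (two-class) or 198 (three-class) cells;
Monte-Carlo coefficient recovery uses 100 draws; eigensolver agreement
uses 100 random instances up to 30 dimensions. A full study runs in about
a second on one CPU; the entire acceptance script in well under a minute.
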