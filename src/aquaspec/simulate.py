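"""Forward simulator of single-cell FTIR transmission measurements in an
aqueous chamber.

The model is Beer–Lambert: the true absorbance of a measured spot is the
cell band profile plus a bulk-water profile whose amplitude scales linearly
with the chamber pathlength (spacer thickness). Detector nonlinearity at
strong bands is emulated by a stray-light floor in transmittance space,

    A_app = −log10(10^(−A) + 10^(−L)),

a one-parameter, monotone compression toward the apparent-absorbance
ceiling L. Each simulated cell comes with a paired bulk-fluid (PBS)
spectrum taken "beside" it, which sees its own slightly different water
amount — the situation the water-correction fit must handle.

Drug mode-of-action classes are emulated as multiplicative perturbations of
specific band heights: a DNA cross-linker acts on the phosphate stretches
at 1217/1244 cm⁻¹, a protein kinase inhibitor on the amide II band. Effect
multipliers are calibration choices of this simulator, not measured
quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import Spectrum, SpectrumSet, WavenumberGrid
from .errors import ConfigError, RangeError

__all__ = [
    "BandSpec",
    "CellProfile",
    "ChamberConfig",
    "EffectSpec",
    "default_grid",
    "matrigel_reference",
    "make_water_spectrum",
    "make_cell_spectrum",
    "simulate_measurement",
    "generate_study",
    "default_study_classes",
    "apply_saturation",
]


@dataclass(frozen=True)
class BandSpec:
    """One absorption band: center (cm⁻¹), height (AU), FWHM width (cm⁻¹)."""

    center: float
    height: float
    width: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.height < 0 or self.width <= 0:
            raise ConfigError("band height must be ≥ 0 and width > 0")
        if self.shape not in {"gaussian", "lorentzian"}:
            raise ConfigError(f"unknown band shape {self.shape!r}")

    def profile(self, x: np.ndarray) -> np.ndarray:
        if self.shape == "gaussian":
            return self.height * np.exp(-4.0 * np.log(2.0) * ((x - self.center) / self.width) ** 2)
        hw = self.width / 2.0
        return self.height * hw**2 / ((x - self.center) ** 2 + hw**2)


# Default cell band set: protein amides, nucleic-acid phosphates, lipid C-H
# stretches plus minor fingerprint bands. Heights are AU for a ~15 μm cell;
# widths are FWHM in cm⁻¹, fixed as fixture constants.
_DEFAULT_BANDS = (
    BandSpec(1654.0, 0.50, 45.0),   # amide I
    BandSpec(1545.0, 0.30, 40.0),   # amide II
    BandSpec(1455.0, 0.05, 22.0),   # CH2/CH3 bending
    BandSpec(1396.0, 0.06, 24.0),   # COO- symmetric stretch
    BandSpec(1244.0, 0.07, 25.0),   # PO2- asymmetric stretch (DNA/RNA)
    BandSpec(1217.0, 0.08, 25.0),   # PO2- asymmetric stretch (DNA/RNA)
    BandSpec(1085.0, 0.07, 28.0),   # PO2- symmetric stretch
    BandSpec(2852.0, 0.05, 20.0),   # CH2 symmetric stretch (lipid)
    BandSpec(2925.0, 0.10, 22.0),   # CH2 asymmetric stretch (lipid)
    BandSpec(2958.0, 0.06, 20.0),   # CH3 asymmetric stretch (lipid)
)


@dataclass(frozen=True)
class CellProfile:
    """Deterministic cell band composition.

    ``intracellular_water_fraction`` records that structural water is ~70%
    of cell mass; it is carried as a descriptive parameter (structural water
    is part of the cell signature, inseparable from it in this band model).
    """

    bands: tuple[BandSpec, ...] = _DEFAULT_BANDS
    intracellular_water_fraction: float = 0.70


@dataclass(frozen=True)
class ChamberConfig:
    """Aqueous-chamber and detector parameters.

    spacer_um : fluid pathlength; the study holders use 6, 10 and 12 μm.
    water_absorptivity_scale : AU of water-bending absorbance per μm at the
        1640 cm⁻¹ peak (default 0.2, so 6/10/12 μm give 1.2/2.0/2.4 AU —
        the thickest spacer drives the bending mode close to the 2.5 AU
        saturation ceiling, the regime the thicker-spacer measurements
        operate in).
    noise_sd : additive Gaussian noise, AU.
    saturation_limit : apparent-absorbance ceiling L (np.inf disables).
    """

    spacer_um: float = 10.0
    water_absorptivity_scale: float = 0.2
    noise_sd: float = 0.004
    saturation_limit: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacer_um <= 0 or self.saturation_limit <= 0:
            raise ConfigError("spacer_um and saturation_limit must be > 0")


@dataclass(frozen=True)
class EffectSpec:
    """A treatment class: multiplicative height changes on named band centers."""

    class_name: str
    band_multipliers: dict = field(default_factory=dict)
    time_point_h: float = 20.0

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.band_multipliers.values()):
            raise ConfigError("band multipliers must be > 0")


def default_grid() -> WavenumberGrid:
    """1000–3600 cm⁻¹ at 2 cm⁻¹ spacing — typical mid-IR digitization."""
    return WavenumberGrid(np.arange(1000.0, 3600.0 + 1.0, 2.0))


# Water band model, unit bending peak: OH bend at 1640, two overlapping OH
# stretch components spanning 3000-3500, and the weak association/combination
# band near 2130 cm⁻¹ that dominates the otherwise silent region. Stretch
# amplitudes are scaled down relative to pure liquid water so the region
# above 3000 cm⁻¹ stays within the detector's range at study pathlengths
# (in real measurements it saturates outright and is discarded by the cut).
_WATER_COMPONENTS = (
    BandSpec(1640.0, 1.00, 85.0),
    BandSpec(2130.0, 0.05, 180.0),
    BandSpec(3280.0, 0.40, 220.0),
    BandSpec(3480.0, 0.25, 160.0),
)


def make_water_spectrum(grid: WavenumberGrid, chamber: ChamberConfig) -> Spectrum:
    """Bulk-water absorbance at the chamber pathlength (no noise, no saturation).

    Total intensity scales linearly with ``spacer_um`` (Beer–Lambert); the
    1640 cm⁻¹ bending peak reaches ``water_absorptivity_scale · spacer_um`` AU.
    """
    if grid.lo > 1000.0 or grid.hi < 3600.0:
        raise RangeError("water model needs a grid spanning 1000–3600 cm⁻¹")
    x = grid.values
    shape = np.sum([b.profile(x) for b in _WATER_COMPONENTS], axis=0)
    scale = chamber.water_absorptivity_scale * chamber.spacer_um
    return Spectrum(grid, scale * shape, {"role": "water", "spacer_um": chamber.spacer_um})


def make_cell_spectrum(
    grid: WavenumberGrid,
    profile: CellProfile | None = None,
    effect: EffectSpec | None = None,
) -> Spectrum:
    """Deterministic cell absorbance: sum of bands, effect multipliers applied.

    A multiplier keyed on a band center (±0.5 cm⁻¹) scales that band's
    height; bands are local, so unperturbed regions are bit-identical to the
    no-effect spectrum.
    """
    profile = profile or CellProfile()
    x = grid.values
    total = np.zeros_like(x)
    for band in profile.bands:
        height = band.height
        if effect is not None:
            for center, mult in effect.band_multipliers.items():
                if abs(center - band.center) <= 0.5:
                    height = height * mult
        total += replace(band, height=height).profile(x)
    meta = {"role": "cell"}
    if effect is not None:
        meta["label"] = effect.class_name
        meta["time_point_h"] = effect.time_point_h
    return Spectrum(grid, total, meta)


def matrigel_reference(grid: WavenumberGrid, scale: float = 1.0) -> Spectrum:
    """Protein-only reference spectrum (amide I + II, no phosphate/lipid).

    Matrigel is a protein-dominated basement-membrane extract; its synthetic
    stand-in keeps the default amide band shapes at ``scale`` times the cell
    amide heights and is generated water-free.
    """
    bands = (
        BandSpec(1654.0, 0.50 * scale, 45.0),
        BandSpec(1545.0, 0.30 * scale, 40.0),
    )
    x = grid.values
    total = np.sum([b.profile(x) for b in bands], axis=0)
    return Spectrum(grid, total, {"role": "matrigel", "id": "matrigel"})


def apply_saturation(a: np.ndarray, limit: float) -> np.ndarray:
    """Stray-light compression toward the apparent-absorbance ceiling."""
    if not np.isfinite(limit):
        return np.asarray(a, dtype=float)
    return -np.log10(np.power(10.0, -np.asarray(a, dtype=float)) + 10.0 ** (-limit))


def simulate_measurement(
    cell: Spectrum,
    water: Spectrum,
    chamber: ChamberConfig,
    rng: np.random.Generator,
    c_w: float | None = None,
    c_w_pbs: float | None = None,
) -> tuple[Spectrum, Spectrum]:
    """One paired acquisition: (sample spectrum, adjacent bulk-PBS spectrum).

    The sample's local water amount ``c_w`` is drawn uniform on [0.85, 1.15]
    (local pathlength variation around the cell) and the paired PBS spot
    sees its own independent draw near 1 (uniform on [0.97, 1.03]); both
    true absorbances pass through the saturation compression and receive
    additive Gaussian noise of sd ``chamber.noise_sd``.
    """
    if cell.grid != water.grid:
        raise RangeError("cell and water spectra must share a grid")
    if c_w is None:
        c_w = float(rng.uniform(0.85, 1.15))
    if c_w_pbs is None:
        c_w_pbs = float(rng.uniform(0.97, 1.03))
    a_sample = apply_saturation(cell.intensity + c_w * water.intensity, chamber.saturation_limit)
    a_pbs = apply_saturation(c_w_pbs * water.intensity, chamber.saturation_limit)
    if chamber.noise_sd > 0:
        a_sample = a_sample + rng.normal(0.0, chamber.noise_sd, a_sample.size)
        a_pbs = a_pbs + rng.normal(0.0, chamber.noise_sd, a_pbs.size)
    sample = cell.with_intensity(a_sample, role="cell", true_c_w=c_w)
    pbs = Spectrum(cell.grid, a_pbs, {"role": "pbs", "true_c_w": c_w_pbs})
    return sample, pbs


def default_study_classes() -> list[EffectSpec]:
    """Three-class mode-of-action design: control, DNA cross-linker (phosphate
    bands up), kinase inhibitor (amide II down).

    Multipliers are calibrated so that the default study separates at the
    fivefold cross-validation accuracies typical of single-cell FTIR
    mode-of-action work (~80% per class); they are simulator constants, not
    measured values.
    """
    return [
        EffectSpec("control", {}),
        EffectSpec("crosslinker", {1217.0: 1.30, 1244.0: 1.30}),
        EffectSpec("kinase_inhibitor", {1545.0: 0.82}),
    ]


def generate_study(
    grid: WavenumberGrid | None = None,
    classes: list[EffectSpec] | None = None,
    n_per_class: int = 120,
    replicates: int = 3,
    chamber: ChamberConfig | None = None,
    profile: CellProfile | None = None,
    seed: int = 0,
    height_jitter_sd: float = 0.05,
    replicate_gain_sd: float = 0.02,
) -> SpectrumSet:
    """Full labeled study: paired cell/PBS spectra for every class.

    Per-cell biological variability is a lognormal jitter (sd 5%) on every
    band height; each replicate loading carries a small multiplicative gain
    (sd 2%) emulating loading-to-loading variation. Cells are spread over
    replicates as evenly as possible. Fully reproducible from ``seed``.
    """
    grid = grid or default_grid()
    classes = classes if classes is not None else default_study_classes()
    chamber = chamber or ChamberConfig()
    profile = profile or CellProfile()
    rng = np.random.default_rng(seed)
    water = make_water_spectrum(grid, chamber)

    spectra: list[Spectrum] = []
    pairing: dict[str, str] = {}
    for effect in classes:
        base_heights = _effect_heights(profile, effect)
        rep_sizes = _split_evenly(n_per_class, replicates)
        idx = 0
        for rep, size in enumerate(rep_sizes, start=1):
            gain = float(rng.normal(1.0, replicate_gain_sd))
            for _ in range(size):
                jitter = np.exp(rng.normal(0.0, height_jitter_sd, len(profile.bands)))
                bands = tuple(
                    replace(b, height=h * j)
                    for b, h, j in zip(profile.bands, base_heights, jitter)
                )
                cell = make_cell_spectrum(grid, CellProfile(bands, profile.intracellular_water_fraction))
                cell = cell.with_intensity(gain * cell.intensity)
                sample, pbs = simulate_measurement(cell, water, chamber, rng)
                cid = f"{effect.class_name}_r{rep}_c{idx:03d}"
                pid = f"{cid}_pbs"
                sample.meta.update(
                    id=cid, pbs_id=pid, label=effect.class_name, replicate=rep,
                    time_point_h=effect.time_point_h, spacer_um=chamber.spacer_um,
                )
                pbs.meta.update(id=pid, replicate=rep, spacer_um=chamber.spacer_um)
                spectra.extend([sample, pbs])
                pairing[cid] = pid
                idx += 1
    return SpectrumSet(spectra, pairing)


def _effect_heights(profile: CellProfile, effect: EffectSpec) -> list[float]:
    heights = []
    for band in profile.bands:
        h = band.height
        for center, mult in effect.band_multipliers.items():
            if abs(center - band.center) <= 0.5:
                h = h * mult
        heights.append(h)
    return heights


def _split_evenly(n: int, parts: int) -> list[int]:
    base, rem = divmod(n, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]
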