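"""Post-correction spectral conditioning.

Quality control, Savitzky-Golay smoothing/differentiation, vector
normalization and region cutting, applied in a configurable order. Two
presets mirror the two measurement workflows:

``spacer_eval``
    qc → smooth (9 points, quadratic) → vector normalize; used to compare
    replicate loadings at different chamber pathlengths.
``drug_study``
    qc → vector normalize → second derivative (Savitzky-Golay, 13 points,
    third order) → cut to 1100–1575 and 2750–3000 cm⁻¹; the cut removes the
    saturated water-bending/amide I region and the information-free
    1800–2750 cm⁻¹ range before classification.

Differentiation and smoothing are one Savitzky-Golay operator, and after a
region cut every subsequent filter runs per contiguous segment so that no
convolution window ever straddles the gap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .core import Spectrum, SpectrumSet, WavenumberGrid
from .errors import ConfigError, GridError, NormalizationError, WindowError

__all__ = [
    "PreprocessConfig",
    "QCReport",
    "quality_check",
    "savitzky_golay",
    "vector_normalize",
    "cut_regions",
    "run_pipeline",
    "PRESETS",
    "preset",
]

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    steps: tuple[str, ...] = ("qc", "smooth", "normalize")
    sg_window: int = 9
    sg_polyorder: int = 2
    sg_deriv: int = 0
    cut_windows: tuple[tuple[float, float], ...] = ((1100.0, 1575.0), (2750.0, 3000.0))
    min_amide_height: float = 0.05   # AU above local baseline, 1600–1700 cm⁻¹
    max_absorbance: float = 2.5      # AU, detector saturation guard
    max_noise_rms: float = 0.01      # AU, detrended 1800–2500 cm⁻¹ residual

    def __post_init__(self) -> None:
        valid = {"qc", "smooth", "derivative", "normalize", "cut"}
        unknown = set(self.steps) - valid
        if unknown:
            raise ConfigError(f"unknown steps {sorted(unknown)}")
        if list(self.steps).count("derivative") > 1:
            raise ConfigError("derivative requested twice; it is a single SG operator")
        if self.sg_window % 2 == 0:
            raise ConfigError("sg_window must be odd")
        if self.sg_window < self.sg_polyorder + 2:
            raise ConfigError("sg_window must be ≥ sg_polyorder + 2")
        if self.sg_deriv not in (0, 2):
            raise ConfigError("sg_deriv must be 0 or 2")
        if self.sg_deriv > self.sg_polyorder:
            raise ConfigError("sg_deriv must be ≤ sg_polyorder")
        wins = sorted(self.cut_windows)
        for (lo, hi) in wins:
            if lo >= hi:
                raise ConfigError(f"invalid cut window [{lo}, {hi}]")
        for (a, b), (c, d) in zip(wins, wins[1:]):
            if c <= b:
                raise ConfigError("cut windows must be disjoint")


PRESETS: dict[str, PreprocessConfig] = {
    "spacer_eval": PreprocessConfig(
        steps=("qc", "smooth", "normalize"), sg_window=9, sg_polyorder=2, sg_deriv=0
    ),
    "drug_study": PreprocessConfig(
        steps=("qc", "normalize", "derivative", "cut"),
        sg_window=13,
        sg_polyorder=3,
        sg_deriv=2,
    ),
}


def preset(name: str) -> PreprocessConfig:
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")


@dataclass
class QCReport:
    """Per-spectrum quality-control verdicts and diagnostics."""

    table: pd.DataFrame  # columns: spectrum_id, passed, failed_criteria, diagnostics

    @property
    def n_passed(self) -> int:
        return int(self.table["passed"].sum())

    @property
    def n_failed(self) -> int:
        return int((~self.table["passed"]).sum())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _amide_height(s: Spectrum) -> float:
    """Amide-region (1600–1700) peak height above the window-edge chord."""
    mask = s.grid.window_mask(1600.0, 1700.0)
    x = s.grid.values[mask]
    y = s.intensity[mask]
    chord = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
    return float(np.max(y - chord))


def _silent_noise_rms(s: Spectrum) -> float:
    mask = s.grid.window_mask(1800.0, 2500.0)
    x = s.grid.values[mask]
    y = s.intensity[mask]
    resid = y - np.polyval(np.polyfit(x, y, 1), x)
    return float(np.sqrt(np.mean(resid**2)))


def quality_check(
    sset: SpectrumSet, cfg: PreprocessConfig | None = None
) -> tuple[SpectrumSet, QCReport]:
    """Screen spectra on amide signal, saturation and silent-region noise.

    Exclusion is an outcome, not an error: the report names at least one
    failed criterion for every excluded spectrum, and pass ∪ fail equals the
    input set. Spectra are never mutated.
    """
    cfg = cfg or PreprocessConfig()
    if len(sset) and (sset.grid.lo > 1500.0 or sset.grid.hi < 2500.0):
        raise WindowError("quality control needs coverage of 1500–1800 and 1800–2500 cm⁻¹")
    rows = []
    passing = []
    for s in sset:
        amide = _amide_height(s)
        peak = float(np.max(s.intensity))
        noise = _silent_noise_rms(s)
        failed = []
        if amide < cfg.min_amide_height:
            failed.append("min_amide_height")
        if peak > cfg.max_absorbance:
            failed.append("max_absorbance")
        if noise > cfg.max_noise_rms:
            failed.append("max_noise_rms")
        if not failed:
            passing.append(s)
        rows.append(
            {
                "spectrum_id": s.meta.get("id"),
                "passed": not failed,
                "failed_criteria": ";".join(failed),
                "amide_height": amide,
                "max_absorbance": peak,
                "noise_rms": noise,
            }
        )
    report = QCReport(pd.DataFrame(rows))
    return SpectrumSet(passing, sset.pairing), report


def _segments(s: Spectrum) -> list[tuple[int, int]]:
    """Contiguous index runs; a cut spectrum carries them in meta."""
    return [tuple(seg) for seg in s.meta.get("segments", [(0, len(s.grid))])]


def savitzky_golay(s: Spectrum, window: int, polyorder: int, deriv: int = 0) -> Spectrum:
    """Savitzky-Golay filter / differentiator on a uniform grid.

    Derivative output is scaled by spacing⁻ᵈ so its units are
    AU·(cm⁻¹)⁻ᵈ. Edges are handled by polynomial fit within the one-sided
    window (no truncation). On a cut spectrum the filter is applied per
    contiguous segment.
    """
    if window % 2 == 0:
        raise ConfigError("window length must be odd")
    out = np.empty_like(s.intensity)
    for start, stop in _segments(s):
        seg_axis = s.grid.values[start:stop]
        d = np.diff(seg_axis)
        if np.any(np.abs(d - d.mean()) > 1e-6 * abs(d.mean())):
            raise GridError(
                "Savitzky-Golay requires a uniform grid (per segment); "
                "resample_to_grid first"
            )
        if window > stop - start:
            raise ConfigError("window longer than the (segment) spectrum")
        out[start:stop] = savgol_filter(
            s.intensity[start:stop],
            window_length=window,
            polyorder=polyorder,
            deriv=deriv,
            delta=float(d.mean()),
            mode="interp",
        )
    return s.with_intensity(out, sg=(window, polyorder, deriv))


def vector_normalize(s: Spectrum) -> Spectrum:
    """Scale to unit Euclidean norm over the spectrum's current grid."""
    norm = float(np.linalg.norm(s.intensity))
    if norm == 0.0:
        raise NormalizationError("cannot vector-normalize an all-zero spectrum")
    return s.with_intensity(s.intensity / norm)


def cut_regions(
    s: Spectrum, windows: tuple[tuple[float, float], ...]
) -> Spectrum:
    """Keep only the closed wavenumber windows, concatenated ascending.

    Points are never reordered or interpolated. Segment boundaries are
    recorded in ``meta["segments"]`` so later filters stay within segments.
    """
    windows = tuple(sorted(windows))
    masks = [s.grid.window_mask(lo, hi) for lo, hi in windows]
    counts = [int(m.sum()) for m in masks]
    if sum(counts) == 0:
        raise WindowError("cut windows select no grid points")
    keep = np.logical_or.reduce(masks)
    segments = []
    offset = 0
    for c in counts:
        if c:
            segments.append((offset, offset + c))
            offset += c
    return Spectrum(
        WavenumberGrid(s.grid.values[keep]),
        s.intensity[keep],
        dict(s.meta) | {"segments": segments},
    )


def run_pipeline(
    sset: SpectrumSet, cfg: PreprocessConfig | str
) -> tuple[SpectrumSet, QCReport | None]:
    """Apply the configured steps in order; returns (spectra, QC report).

    ``cfg`` may be a preset name. Each step is logged with its parameters.
    """
    if isinstance(cfg, str):
        cfg = preset(cfg)
    report: QCReport | None = None
    current = sset
    for step in cfg.steps:
        if step == "qc":
            current, report = quality_check(current, cfg)
            log.info("qc: %d passed, %d excluded", report.n_passed, report.n_failed)
        elif step == "smooth":
            log.info("smooth: SG window=%d order=%d", cfg.sg_window, cfg.sg_polyorder)
            current = SpectrumSet(
                [savitzky_golay(s, cfg.sg_window, cfg.sg_polyorder, 0) for s in current],
                current.pairing,
            )
        elif step == "derivative":
            log.info(
                "derivative: SG window=%d order=%d deriv=%d",
                cfg.sg_window, cfg.sg_polyorder, cfg.sg_deriv,
            )
            current = SpectrumSet(
                [
                    savitzky_golay(s, cfg.sg_window, cfg.sg_polyorder, cfg.sg_deriv)
                    for s in current
                ],
                current.pairing,
            )
        elif step == "normalize":
            log.info("normalize: unit Euclidean norm")
            current = SpectrumSet([vector_normalize(s) for s in current], current.pairing)
        elif step == "cut":
            log.info("cut: windows=%s", cfg.cut_windows)
            current = SpectrumSet(
                [cut_regions(s, cfg.cut_windows) for s in current], current.pairing
            )
    return current, report
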