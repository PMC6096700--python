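"""Bulk-water correction for cell spectra measured in an aqueous chamber.

The primary method fits, over a protein-dominated window (default
1500–1700 cm⁻¹), the model

    sample ≈ α · matrigel + β · pbs + baseline

by ordinary least squares, where ``matrigel`` is a protein reference
spectrum and ``pbs`` the bulk-fluid spectrum measured beside the cell.
Only the scaled water term β·pbs — the "water to be removed" — is then
subtracted from the sample over the full grid; the reference weight α and
the baseline parameters are diagnostics and are never subtracted, so no
cellular signal is removed.

Two literature alternatives are provided for comparison: a silent-region
flatness optimizer (1800–2500 cm⁻¹) and an iterative water re-addition
balancing the baseline on either side of the C–H alkyl stretch at
2900 cm⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .core import Spectrum, SpectrumSet
from .errors import DegenerateFitError, GridError, RangeError, WindowError

__all__ = [
    "FitConfig",
    "CorrectionResult",
    "fit_water_coefficient",
    "correct_set",
    "fit_by_flatness",
    "iterative_readdition",
    "flatness_metric",
]

#: silent region used for the flatness diagnostic and the flatness method
SILENT_REGION = (1800.0, 2500.0)


@dataclass
class FitConfig:
    """Configuration of the reference least-squares water fit.

    fit_lo, fit_hi : fit window in cm⁻¹ (default 1500–1700).
    baseline_order : "none", "constant" or "linear" baseline term in the fit.
    nonneg : constrain the water coefficient β ≥ 0 (clip-and-refit).
    max_condition : design-matrix condition number above which the fit is
        declared degenerate (collinear references).
    saturation_cutoff : apparent-absorbance ceiling (AU) above which fit
        points are dropped; in transmission mode the detector response is
        nonlinear well below full saturation, so points beyond ~1.5 AU are
        photometrically unreliable and would bias the water coefficient.
        ``None`` disables the mask.
    """

    fit_lo: float = 1500.0
    fit_hi: float = 1700.0
    baseline_order: str = "linear"
    nonneg: bool = True
    max_condition: float = 1e8
    saturation_cutoff: float | None = 1.5

    def __post_init__(self) -> None:
        if not self.fit_lo < self.fit_hi:
            raise WindowError("fit_lo must be < fit_hi")
        if self.baseline_order not in {"none", "constant", "linear"}:
            raise ValueError(f"unknown baseline_order {self.baseline_order!r}")


@dataclass
class CorrectionResult:
    """Outcome of one water correction.

    ``coefficient`` is the dimensionless scale applied to the water (PBS)
    spectrum; ``corrected.intensity == sample.intensity - coefficient *
    water.intensity`` pointwise on the full grid.
    """

    coefficient: float
    reference_weight: float
    baseline_params: np.ndarray
    corrected: Spectrum
    fit_residual_rms: float
    flatness_1800_2500: float
    flags: list[str] = field(default_factory=list)
    tbr: Spectrum | None = None  # the "water to be removed" spectrum, β·pbs


def _require_shared_grid(*spectra: Spectrum) -> None:
    grid = spectra[0].grid
    for s in spectra[1:]:
        if s.grid != grid:
            raise GridError("spectra must share one grid; resample references first")


def flatness_metric(s: Spectrum, lo: float = SILENT_REGION[0], hi: float = SILENT_REGION[1]) -> float:
    """RMS deviation from the best straight-line fit over [lo, hi].

    Returns NaN when the window is outside the grid range, so the diagnostic
    degrades gracefully on cut spectra.
    """
    mask = s.grid.window_mask(lo, hi)
    if mask.sum() < 3:
        return float("nan")
    x = s.grid.values[mask]
    y = s.intensity[mask]
    coeffs = np.polyfit(x, y, 1)
    return float(np.sqrt(np.mean((y - np.polyval(coeffs, x)) ** 2)))


def _baseline_columns(x: np.ndarray, order: str) -> list[np.ndarray]:
    if order == "none":
        return []
    cols = [np.ones_like(x)]
    if order == "linear":
        # centred/scaled to keep the design well conditioned
        cols.append((x - x.mean()) / (x.max() - x.min()))
    return cols


def fit_water_coefficient(
    sample: Spectrum,
    matrigel: Spectrum,
    pbs: Spectrum,
    cfg: FitConfig | None = None,
) -> CorrectionResult:
    """Primary correction: joint reference/water least squares over the fit window.

    Solves ``sample ≈ α·matrigel + β·pbs + baseline`` on [fit_lo, fit_hi] by
    OLS and subtracts β·pbs over the full grid. With ``cfg.nonneg`` a negative
    unconstrained β is clipped to zero and α/baseline refit (flag
    ``"beta_clipped"``).
    """
    cfg = cfg or FitConfig()
    _require_shared_grid(sample, matrigel, pbs)
    mask = sample.grid.window_mask(cfg.fit_lo, cfg.fit_hi)
    if not mask.any():
        raise WindowError(f"fit window [{cfg.fit_lo}, {cfg.fit_hi}] selects no grid points")

    flags: list[str] = []
    n_params = 2 + {"none": 0, "constant": 1, "linear": 2}[cfg.baseline_order]
    if cfg.saturation_cutoff is not None:
        reliable = (sample.intensity <= cfg.saturation_cutoff) & (
            pbs.intensity <= cfg.saturation_cutoff
        )
        masked = mask & reliable
        n_dropped = int(mask.sum() - masked.sum())
        if n_dropped and masked.sum() >= 5 * n_params:
            mask = masked
            flags.append(f"saturation_masked_{n_dropped}")
        elif n_dropped:
            flags.append("saturation_mask_skipped_too_few_points")

    x = sample.grid.values[mask]
    y = sample.intensity[mask]
    cols = [matrigel.intensity[mask], pbs.intensity[mask]]
    cols += _baseline_columns(x, cfg.baseline_order)
    design = np.column_stack(cols)

    # scale-invariant condition check on unit-normalized columns
    norms = np.linalg.norm(design, axis=0)
    nz = norms > 0
    scaled = design[:, nz] / norms[nz]
    if np.linalg.cond(scaled) > cfg.max_condition:
        raise DegenerateFitError(
            "matrigel and pbs are collinear over the fit window "
            f"(condition number > {cfg.max_condition:g})"
        )

    theta, *_ = np.linalg.lstsq(design, y, rcond=None)
    alpha, beta = float(theta[0]), float(theta[1])
    baseline = theta[2:]
    if cfg.nonneg and beta < 0:
        flags.append("beta_clipped")
        beta = 0.0
        reduced = np.column_stack([cols[0]] + cols[2:]) if len(cols) > 2 else design[:, :1]
        theta_r, *_ = np.linalg.lstsq(reduced, y, rcond=None)
        alpha = float(theta_r[0])
        baseline = theta_r[1:]
        fitted = reduced @ theta_r
    else:
        fitted = design @ theta

    residual_rms = float(np.sqrt(np.mean((y - fitted) ** 2)))
    tbr = pbs.with_intensity(beta * pbs.intensity, role="tbr")
    corrected = sample.with_intensity(
        sample.intensity - beta * pbs.intensity, water_coefficient=beta
    )
    return CorrectionResult(
        coefficient=beta,
        reference_weight=alpha,
        baseline_params=np.asarray(baseline, dtype=float),
        corrected=corrected,
        fit_residual_rms=residual_rms,
        flatness_1800_2500=flatness_metric(corrected),
        flags=flags,
        tbr=tbr,
    )


def correct_set(
    sset: SpectrumSet,
    matrigel: Spectrum,
    cfg: FitConfig | None = None,
) -> tuple[SpectrumSet, pd.DataFrame]:
    """Correct every cell spectrum against its own paired PBS spectrum.

    Returns the corrected cell spectra (uncorrectable cells are kept,
    flagged ``unpaired`` and left unmodified) and a per-cell report table
    with columns cell_id, coefficient, reference_weight, fit_residual_rms,
    flatness_1800_2500, flags.
    """
    cfg = cfg or FitConfig()
    rows = []
    out: list[Spectrum] = []
    for cell in sset.cells():
        cid = cell.meta.get("id")
        try:
            pbs = sset.pbs_for(cell)
        except KeyError:
            out.append(cell.with_intensity(cell.intensity, correction_flags=["unpaired"]))
            rows.append(
                {
                    "cell_id": cid,
                    "coefficient": np.nan,
                    "reference_weight": np.nan,
                    "fit_residual_rms": np.nan,
                    "flatness_1800_2500": np.nan,
                    "flags": "unpaired",
                }
            )
            continue
        res = fit_water_coefficient(cell, matrigel, pbs, cfg)
        out.append(res.corrected)
        rows.append(
            {
                "cell_id": cid,
                "coefficient": res.coefficient,
                "reference_weight": res.reference_weight,
                "fit_residual_rms": res.fit_residual_rms,
                "flatness_1800_2500": res.flatness_1800_2500,
                "flags": ";".join(res.flags),
            }
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "coefficient",
            "reference_weight",
            "fit_residual_rms",
            "flatness_1800_2500",
            "flags",
        ],
    )
    return SpectrumSet(out, sset.pairing), report


def fit_by_flatness(
    sample: Spectrum,
    water: Spectrum,
    search_lo: float = 0.0,
    search_hi: float = 3.0,
) -> CorrectionResult:
    """Alternative correction: choose β minimizing silent-region roughness.

    Minimizes the RMS deviation from a straight line of ``sample − β·water``
    over 1800–2500 cm⁻¹ (the region holding only the water combination band)
    to a tolerance of 1e-6 on β.
    """
    _require_shared_grid(sample, water)
    if sample.grid.lo > SILENT_REGION[0] or sample.grid.hi < SILENT_REGION[1]:
        raise RangeError("grid must span the 1800–2500 cm⁻¹ silent region")
    mask = sample.grid.window_mask(*SILENT_REGION)
    flags: list[str] = []

    if np.linalg.norm(water.intensity[mask]) < 1e-12:
        flags.append("degenerate_zero_water")
        beta = float(search_lo)
    else:
        def objective(b: float) -> float:
            val = flatness_metric(sample.with_intensity(sample.intensity - b * water.intensity))
            if not np.isfinite(val):
                raise FloatingPointError("flatness metric non-finite in search bracket")
            return val

        res = minimize_scalar(
            objective, bounds=(search_lo, search_hi), method="bounded",
            options={"xatol": 1e-6},
        )
        beta = float(res.x)

    corrected = sample.with_intensity(
        sample.intensity - beta * water.intensity, water_coefficient=beta
    )
    return CorrectionResult(
        coefficient=beta,
        reference_weight=float("nan"),
        baseline_params=np.empty(0),
        corrected=corrected,
        fit_residual_rms=float("nan"),
        flatness_1800_2500=flatness_metric(corrected),
        flags=flags,
        tbr=water.with_intensity(beta * water.intensity, role="tbr"),
    )


#: flank windows on either side of the C–H alkyl stretch at 2900 cm⁻¹
READD_FLANKS = ((2750.0, 2800.0), (3000.0, 3050.0))


def iterative_readdition(corrected: Spectrum, water: Spectrum) -> CorrectionResult:
    """Alternative adjustment: re-add water until the 2900 cm⁻¹ flanks balance.

    Finds γ ≥ 0 minimizing ``|mean(s + γ·w over 2750–2800) − mean(s + γ·w
    over 3000–3050)|``. The objective is |a + γ·b| with a, b the flank-mean
    differences of the spectrum and the water reference, so the global
    minimizer is computed in closed form and clipped at γ = 0; a vanishing
    water slope b is flagged as degenerate (γ = 0 returned).
    """
    _require_shared_grid(corrected, water)
    if corrected.grid.lo > READD_FLANKS[0][0] or corrected.grid.hi < READD_FLANKS[1][1]:
        raise RangeError("grid must span 2750–3050 cm⁻¹ for re-addition balancing")
    m_lo = corrected.grid.window_mask(*READD_FLANKS[0])
    m_hi = corrected.grid.window_mask(*READD_FLANKS[1])
    a = float(corrected.intensity[m_lo].mean() - corrected.intensity[m_hi].mean())
    b = float(water.intensity[m_lo].mean() - water.intensity[m_hi].mean())
    flags: list[str] = []
    if b == 0.0:
        flags.append("degenerate_flat_water")
        gamma = 0.0
    else:
        gamma = max(0.0, -a / b)
    adjusted = corrected.with_intensity(
        corrected.intensity + gamma * water.intensity, readdition_scale=gamma
    )
    return CorrectionResult(
        coefficient=gamma,
        reference_weight=float("nan"),
        baseline_params=np.empty(0),
        corrected=adjusted,
        fit_residual_rms=abs(a + gamma * b),
        flatness_1800_2500=flatness_metric(adjusted),
        flags=flags,
        tbr=water.with_intensity(gamma * water.intensity, role="readded"),
    )
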