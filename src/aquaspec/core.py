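"""Spectral data model and I/O.

Absorbance spectra live on a :class:`WavenumberGrid` (cm⁻¹, strictly
ascending). Collections of spectra sharing one grid are held in a
:class:`SpectrumSet`, which also records the pairing between each cell
spectrum and the bulk-fluid (PBS) spectrum measured beside it.

Files in descending wavenumber order — the common FTIR export convention —
are silently reversed to the ascending canonical order on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AxisError,
    GridError,
    ParseError,
    RangeError,
    WindowError,
)

__all__ = [
    "WavenumberGrid",
    "Spectrum",
    "SpectrumSet",
    "read_spectra",
    "write_spectra",
    "resample_to_grid",
    "extract_window",
]


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly ascending wavenumber axis in cm⁻¹.

    Parameters
    ----------
    values
        Wavenumbers, strictly increasing, all positive, length ≥ 2.
        Spacing may be non-uniform; see :meth:`is_uniform`.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise AxisError("wavenumber axis must be 1-D with at least 2 points")
        if not np.all(np.isfinite(values)):
            raise AxisError("wavenumber axis contains non-finite values")
        if np.any(values <= 0):
            raise AxisError("wavenumbers must be positive")
        if np.any(np.diff(values) <= 0):
            raise AxisError("wavenumber axis must be strictly ascending without duplicates")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return np.array_equal(self.values, other.values)

    def __hash__(self) -> int:
        return hash(self.values.tobytes())

    @property
    def lo(self) -> float:
        return float(self.values[0])

    @property
    def hi(self) -> float:
        return float(self.values[-1])

    def is_uniform(self, tol: float = 1e-6) -> bool:
        """True if grid spacing is constant to relative tolerance ``tol``."""
        d = np.diff(self.values)
        return bool(np.all(np.abs(d - d.mean()) <= tol * abs(d.mean())))

    @property
    def spacing(self) -> float:
        """Mean grid spacing in cm⁻¹ (exact when :meth:`is_uniform`)."""
        return float(np.diff(self.values).mean())

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of grid points in the closed interval [lo, hi]."""
        return (self.values >= lo) & (self.values <= hi)


@dataclass
class Spectrum:
    """One absorbance trace on a wavenumber grid.

    ``meta`` carries free-form per-spectrum metadata; keys used by the rest
    of the package are ``id``, ``role`` (cell / pbs / matrigel / background),
    ``pbs_id`` (pairing), ``label``, ``replicate``, ``time_point_h``,
    ``spacer_um`` and ``segments`` (contiguous-run bookkeeping after region
    cutting).
    """

    grid: WavenumberGrid
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        intensity = np.asarray(self.intensity, dtype=float)
        if intensity.shape != (len(self.grid),):
            raise GridError(
                f"intensity length {intensity.size} != grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(intensity)):
            raise ValueError("intensity contains non-finite values")
        self.intensity = intensity

    @property
    def id(self) -> str | None:
        return self.meta.get("id")

    def with_intensity(self, intensity: np.ndarray, **meta_updates) -> "Spectrum":
        """Copy of this spectrum with new intensities (same grid), meta merged."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Spectrum(self.grid, np.asarray(intensity, dtype=float), meta)

    def copy(self) -> "Spectrum":
        return Spectrum(self.grid, self.intensity.copy(), dict(self.meta))


class SpectrumSet:
    """Ordered collection of spectra sharing one grid, with cell→PBS pairing."""

    def __init__(
        self,
        spectra: Sequence[Spectrum],
        pairing: Mapping[str, str] | None = None,
    ) -> None:
        spectra = list(spectra)
        if spectra:
            grid = spectra[0].grid
            for s in spectra[1:]:
                if s.grid != grid:
                    raise GridError("all spectra in a SpectrumSet must share one grid")
        self.spectra = spectra
        if pairing is None:
            pairing = {
                s.meta["id"]: s.meta["pbs_id"]
                for s in spectra
                if s.meta.get("role") == "cell" and "pbs_id" in s.meta and "id" in s.meta
            }
        self.pairing = dict(pairing)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, key: int | str) -> Spectrum:
        if isinstance(key, str):
            for s in self.spectra:
                if s.meta.get("id") == key:
                    return s
            raise KeyError(key)
        return self.spectra[key]

    @property
    def grid(self) -> WavenumberGrid:
        if not self.spectra:
            raise GridError("empty SpectrumSet has no grid")
        return self.spectra[0].grid

    @property
    def ids(self) -> list[str | None]:
        return [s.meta.get("id") for s in self.spectra]

    def intensity_matrix(self) -> np.ndarray:
        """(n_spectra, n_points) matrix of absorbances."""
        return np.vstack([s.intensity for s in self.spectra])

    def labels(self, key: str = "label") -> list:
        return [s.meta.get(key) for s in self.spectra]

    def subset(self, predicate) -> "SpectrumSet":
        kept = [s for s in self.spectra if predicate(s)]
        pairing = {
            k: v for k, v in self.pairing.items() if k in {s.meta.get("id") for s in kept}
        }
        return SpectrumSet(kept, pairing)

    def cells(self) -> "SpectrumSet":
        return self.subset(lambda s: s.meta.get("role", "cell") == "cell")

    def pbs_for(self, cell: Spectrum) -> Spectrum:
        """Paired PBS spectrum of ``cell``; raises KeyError if unresolvable."""
        cid = cell.meta.get("id")
        pid = self.pairing.get(cid, cell.meta.get("pbs_id"))
        if pid is None:
            raise KeyError(f"no PBS pairing recorded for cell {cid!r}")
        return self[pid]


# ---------------------------------------------------------------------------
# I/O: wide table (axis column + one column per spectrum) and long table
# (spectrum_id, wavenumber, absorbance), with a key/value metadata sidecar.
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # lossless for IEEE doubles


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta")


def _write_sidecar(path: Path, sset: SpectrumSet) -> None:
    rows = []
    for s in sset:
        sid = s.meta.get("id")
        for k, v in s.meta.items():
            if k == "id":
                continue
            rows.append((sid, k, json.dumps(v)))
    if rows:
        pd.DataFrame(rows, columns=["spectrum_id", "key", "value"]).to_csv(
            _sidecar_path(path), sep="\t", index=False
        )


def _read_sidecar(path: Path) -> dict[str, dict]:
    sc = _sidecar_path(path)
    if not sc.exists():
        return {}
    df = pd.read_csv(sc, sep="\t", dtype=str, keep_default_na=False)
    meta: dict[str, dict] = {}
    for sid, key, value in df.itertuples(index=False):
        meta.setdefault(sid, {})[key] = json.loads(value)
    return meta


def _detect_sep(path: Path) -> str:
    head = path.read_text().splitlines()[0]
    return "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","


def _parse_table(path: Path) -> pd.DataFrame:
    sep = _detect_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: malformed numeric value {df[col].iloc[row]!r} "
                f"at row {row + 2}, column {col!r}"
            )
    return df.astype(float)


def read_spectra(path: str | Path, format: str = "wide") -> SpectrumSet:
    """Read a :class:`SpectrumSet` from a delimited text file.

    ``format="wide"``: first column is the wavenumber axis, remaining columns
    are spectra, header row holds spectrum ids. ``format="long"``: columns
    ``spectrum_id, wavenumber, absorbance``. Comma/tab delimiters are
    auto-detected; a ``<file>.meta`` sidecar, if present, restores metadata.
    A descending axis is normalized to ascending with intensities reversed
    in lockstep.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta_by_id = _read_sidecar(path)

    if format == "wide":
        df = _parse_table(path)
        axis = df.iloc[:, 0].to_numpy()
        columns = list(df.columns[1:])
        mat = df.iloc[:, 1:].to_numpy().T
    elif format == "long":
        sep = _detect_sep(path)
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
        expected = {"spectrum_id", "wavenumber", "absorbance"}
        if not expected.issubset(df.columns):
            raise ParseError(f"{path}: long format requires columns {sorted(expected)}")
        columns = list(dict.fromkeys(df["spectrum_id"].astype(str)))
        first = df[df["spectrum_id"].astype(str) == columns[0]]
        axis = first["wavenumber"].to_numpy(dtype=float)
        mat = np.vstack(
            [
                df[df["spectrum_id"].astype(str) == sid]["absorbance"].to_numpy(dtype=float)
                for sid in columns
            ]
        )
    else:
        raise ValueError(f"unknown format {format!r}")

    if axis.size >= 2 and np.all(np.diff(axis) < 0):
        axis = axis[::-1]
        mat = mat[:, ::-1]
    grid = WavenumberGrid(axis)

    spectra = []
    for sid, row in zip(columns, mat):
        meta = {"id": str(sid)}
        meta.update(meta_by_id.get(str(sid), {}))
        spectra.append(Spectrum(grid, row, meta))
    return SpectrumSet(spectra)


def write_spectra(sset: SpectrumSet, path: str | Path, format: str = "wide") -> None:
    """Write a non-empty :class:`SpectrumSet` as delimited text (lossless).

    Metadata, when present, goes to a ``<file>.meta`` tab-separated sidecar
    of (spectrum_id, key, value) rows; an empty metadata map omits the
    sidecar entirely.
    """
    if len(sset) == 0:
        raise ValueError("cannot write an empty SpectrumSet")
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".tab"} else ","
    ids = [s.meta.get("id", f"s{i}") for i, s in enumerate(sset)]

    if format == "wide":
        df = pd.DataFrame(
            {"wavenumber": sset.grid.values}
            | {sid: s.intensity for sid, s in zip(ids, sset)}
        )
        df.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)
    elif format == "long":
        frames = [
            pd.DataFrame(
                {
                    "spectrum_id": sid,
                    "wavenumber": sset.grid.values,
                    "absorbance": s.intensity,
                }
            )
            for sid, s in zip(ids, sset)
        ]
        pd.concat(frames).to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)
    else:
        raise ValueError(f"unknown format {format!r}")
    _write_sidecar(path, sset)


def resample_to_grid(s: Spectrum, target: WavenumberGrid) -> Spectrum:
    """Piecewise-linear resampling of ``s`` onto ``target`` (no extrapolation)."""
    if target.lo < s.grid.lo or target.hi > s.grid.hi:
        raise RangeError(
            f"target range [{target.lo}, {target.hi}] outside source "
            f"[{s.grid.lo}, {s.grid.hi}]"
        )
    if target == s.grid:
        return s.copy()
    intensity = np.interp(target.values, s.grid.values, s.intensity)
    return Spectrum(target, intensity, dict(s.meta))


def extract_window(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Sub-spectrum on the closed wavenumber interval [lo, hi]."""
    if lo >= hi:
        raise WindowError(f"window lo {lo} must be < hi {hi}")
    mask = s.grid.window_mask(lo, hi)
    if not mask.any():
        raise WindowError(f"window [{lo}, {hi}] selects no grid points")
    return Spectrum(WavenumberGrid(s.grid.values[mask]), s.intensity[mask], dict(s.meta))
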