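"""End-to-end orchestration: load or simulate → water-correct → preprocess →
classify → report.

A run is described by a :class:`RunConfig` (loadable from YAML) and leaves
behind a run directory containing the corrected spectra, the QC and
correction reports, per-class mean ± sd spectra, CVA scores, the
cross-validation report and a manifest from which the run can be replayed
bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import SpectrumSet, read_spectra, resample_to_grid, write_spectra
from .chemometrics import fit_cva, fit_pca, kfold_crossvalidate
from .errors import ConfigError, SingleClassError
from .preprocess import run_pipeline
from .simulate import (
    ChamberConfig,
    EffectSpec,
    default_grid,
    default_study_classes,
    generate_study,
    matrigel_reference,
)
from .water import FitConfig, correct_set, fit_by_flatness, iterative_readdition

__all__ = ["RunConfig", "run", "band_difference_report", "class_mean_spectra"]

log = logging.getLogger(__name__)

#: default report windows: phosphate stretch region and amide II region
DEFAULT_EFFECT_WINDOWS = ((1170.0, 1250.0), (1480.0, 1560.0))


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    Either ``spectra_path`` (+ optional ``matrigel_path``) or a synthetic
    design (``synthetic=True`` with chamber/class settings) supplies the
    input. ``correction_method`` is one of matrigel_fit / flatness /
    readdition_adjust / none.
    """

    output_dir: str = "aquaspec_run"
    seed: int = 0
    # input
    synthetic: bool = True
    spectra_path: str | None = None
    matrigel_path: str | None = None
    n_per_class: int = 120
    replicates: int = 3
    spacer_um: float = 10.0
    classes: list | None = None  # list of dicts {class_name, band_multipliers, ...}
    # stages
    correction_method: str = "matrigel_fit"
    preprocess_preset: str = "drug_study"
    variance_target: float = 0.95
    pc_cap: int = 21
    k: int = 5
    ridge: float | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**data)
        for p in (cfg.spectra_path, cfg.matrigel_path):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input file not found: {p}")
        return cfg

    def effect_specs(self) -> list[EffectSpec]:
        if self.classes is None:
            return default_study_classes()
        return [
            EffectSpec(
                c["class_name"],
                {float(k): float(v) for k, v in c.get("band_multipliers", {}).items()},
                float(c.get("time_point_h", 20.0)),
            )
            for c in self.classes
        ]


def class_mean_spectra(sset: SpectrumSet, labels) -> pd.DataFrame:
    """Per-class mean and per-point standard deviation, long format."""
    X = sset.intensity_matrix()
    y = np.asarray(labels)
    frames = []
    for c in sorted(set(y.tolist())):
        sub = X[y == c]
        frames.append(
            pd.DataFrame(
                {
                    "label": c,
                    "wavenumber": sset.grid.values,
                    "mean": sub.mean(axis=0),
                    "sd": sub.std(axis=0, ddof=1) if sub.shape[0] > 1 else 0.0,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def band_difference_report(
    sset: SpectrumSet,
    labels,
    windows: tuple[tuple[float, float], ...] = DEFAULT_EFFECT_WINDOWS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Where do two classes differ, and by how much?

    For each unordered class pair and window, computes at every grid point
    the mean difference, the pooled standard deviation and the standardized
    mean difference (Cohen's d), plus a per-window summary (mean |d|,
    max |d| and its wavenumber). Intended for spectra already converted to
    the second derivative, where band differences are sharpest.

    Returns ``(summary, pointwise)`` data frames.
    """
    X = sset.intensity_matrix()
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    point_rows = []
    summary_rows = []
    wn = sset.grid.values
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            xa, xb = X[y == a], X[y == b]
            na, nb = xa.shape[0], xb.shape[0]
            diff = xa.mean(axis=0) - xb.mean(axis=0)
            va = xa.var(axis=0, ddof=1)
            vb = xb.var(axis=0, ddof=1)
            pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
            with np.errstate(divide="ignore", invalid="ignore"):
                d = np.where(pooled > 0, diff / pooled, 0.0)
            for lo, hi in windows:
                mask = sset.grid.window_mask(lo, hi)
                if not mask.any():
                    continue
                point_rows.append(
                    pd.DataFrame(
                        {
                            "class_a": a,
                            "class_b": b,
                            "window": f"{lo:g}-{hi:g}",
                            "wavenumber": wn[mask],
                            "mean_difference": diff[mask],
                            "pooled_sd": pooled[mask],
                            "effect_size": d[mask],
                        }
                    )
                )
                k = int(np.argmax(np.abs(d[mask])))
                summary_rows.append(
                    {
                        "class_a": a,
                        "class_b": b,
                        "window": f"{lo:g}-{hi:g}",
                        "mean_abs_effect": float(np.abs(d[mask]).mean()),
                        "max_abs_effect": float(np.abs(d[mask]).max()),
                        "argmax_wavenumber": float(wn[mask][k]),
                    }
                )
    pointwise = pd.concat(point_rows, ignore_index=True) if point_rows else pd.DataFrame()
    return pd.DataFrame(summary_rows), pointwise


def _load_or_simulate(cfg: RunConfig):
    if cfg.synthetic:
        chamber = ChamberConfig(spacer_um=cfg.spacer_um)
        grid = default_grid()
        sset = generate_study(
            grid,
            classes=cfg.effect_specs(),
            n_per_class=cfg.n_per_class,
            replicates=cfg.replicates,
            chamber=chamber,
            seed=cfg.seed,
        )
        matrigel = matrigel_reference(grid)
        return sset, matrigel
    if cfg.spectra_path is None:
        raise ConfigError("non-synthetic run needs spectra_path")
    sset = read_spectra(cfg.spectra_path)
    matrigel = None
    if cfg.matrigel_path is not None:
        mset = read_spectra(cfg.matrigel_path)
        matrigel = resample_to_grid(mset[0], sset.grid)
    return sset, matrigel


def _correct(cfg: RunConfig, sset: SpectrumSet, matrigel):
    method = cfg.correction_method
    if method == "none":
        return sset.cells(), pd.DataFrame()
    if method == "matrigel_fit":
        if matrigel is None:
            raise ConfigError("matrigel_fit correction needs a Matrigel reference")
        return correct_set(sset, matrigel, FitConfig())
    rows, out = [], []
    for cell in sset.cells():
        pbs = sset.pbs_for(cell)
        if method == "flatness":
            res = fit_by_flatness(cell, pbs)
        elif method == "readdition_adjust":
            res = iterative_readdition(cell, pbs)
        else:
            raise ConfigError(f"unknown correction_method {method!r}")
        out.append(res.corrected)
        rows.append(
            {"cell_id": cell.meta.get("id"), "coefficient": res.coefficient,
             "flags": ";".join(res.flags)}
        )
    return SpectrumSet(out, sset.pairing), pd.DataFrame(rows)


def run(cfg: RunConfig) -> dict:
    """Execute the full workflow; artifacts land in ``cfg.output_dir``.

    Deterministic for a fixed config (the manifest records the config, the
    root seed and the package version, and replaying it reproduces every
    artifact bit-identically). Any stage failure aborts with the stage name.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        sset, matrigel = _load_or_simulate(cfg)
        labels_all = [s.meta.get("label") for s in sset.cells()]
        if len(set(labels_all)) < 2:
            raise SingleClassError(
                "classification requested but the input holds a single class"
            )

        stage = "correct"
        corrected, correction_report = _correct(cfg, sset, matrigel)
        write_spectra(corrected, out / "corrected.csv")
        correction_report.to_csv(out / "correction_report.csv", index=False)

        stage = "preprocess"
        processed, qc_report = run_pipeline(corrected, cfg.preprocess_preset)
        write_spectra(processed, out / "preprocessed.csv")
        if qc_report is not None:
            qc_report.to_csv(out / "qc_report.csv")

        labels = [s.meta.get("label") for s in processed]

        stage = "means"
        class_mean_spectra(processed, labels).to_csv(out / "class_means.csv", index=False)
        class_mean_spectra(corrected.cells(), [s.meta.get("label") for s in corrected.cells()]).to_csv(
            out / "class_means_raw.csv", index=False
        )

        stage = "classify"
        report = kfold_crossvalidate(
            processed, labels, k=cfg.k, seed=cfg.seed,
            variance_target=cfg.variance_target, pc_cap=cfg.pc_cap, ridge=cfg.ridge,
        )
        report.fold_class_pct.to_csv(out / "cv_report.csv")
        report.to_table().to_csv(out / "cv_table.csv")
        (out / "cv_report.json").write_text(
            json.dumps(
                {
                    "per_class_mean": report.per_class_mean.to_dict(),
                    "per_class_range": {
                        c: [float(report.fold_class_pct[c].min()),
                            float(report.fold_class_pct[c].max())]
                        for c in report.fold_class_pct.columns
                    },
                    "k": report.k,
                    "seed": report.seed,
                },
                indent=2,
            )
        )

        # whole-data CVA scores for plotting (CV1/CV2 score plot)
        pca = fit_pca(processed, variance_target=cfg.variance_target, cap=cfg.pc_cap)
        cva = fit_cva(pca.transform(processed.intensity_matrix()), labels, ridge=cfg.ridge, pca=pca)
        coords = cva.project(processed.intensity_matrix())
        scores = pd.DataFrame(
            coords, columns=[f"CV{i+1}" for i in range(coords.shape[1])]
        )
        scores.insert(0, "label", labels)
        scores.insert(0, "spectrum_id", [s.meta.get("id") for s in processed])
        scores.to_csv(out / "cva_scores.csv", index=False)

        stage = "report"
        summary, pointwise = band_difference_report(processed, labels)
        summary.to_csv(out / "band_difference_summary.csv", index=False)
        pointwise.to_csv(out / "band_difference_pointwise.csv", index=False)

        manifest = {"aquaspec_version": __version__, "config": asdict(cfg)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    return {
        "output_dir": str(out),
        "cv_report": report,
        "band_difference_summary": summary,
        "qc_report": qc_report,
        "correction_report": correction_report,
    }


def run_from_manifest(manifest_path: str | Path) -> dict:
    """Replay a previous run from its manifest."""
    manifest = json.loads(Path(manifest_path).read_text())
    return run(RunConfig(**manifest["config"]))
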