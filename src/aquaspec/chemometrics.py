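"""PCA compression, canonical variate analysis and cross-validated classification.

The classification model mirrors common chemometric practice for
vibrational spectra: spectra (typically vector-normalized second
derivatives) are compressed by principal component analysis, retaining the
smallest number of components reaching a target explained-variance fraction
(default 95%) subject to a hard cap (default 21), and the PC scores are
then rotated by canonical variate analysis (CVA) — the generalized
eigenproblem

    S_b v = λ (S_w + ridge·I) v

with S_b / S_w the between- / within-class scatter matrices — keeping at
most (classes − 1) canonical directions. Test spectra are assigned to the
nearest class centroid (Euclidean, optionally Mahalanobis) in canonical
space.

k-fold cross-validation is stratified and leakage-free: PCA and CVA are
refit on each training fold and the held-out fold is only projected in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.decomposition import PCA as _SkPCA
from sklearn.model_selection import StratifiedKFold

from .core import Spectrum, SpectrumSet
from .errors import (
    ConfigError,
    GridError,
    SingleClassError,
    SingularScatterError,
    StratificationError,
)

__all__ = [
    "PCAModel",
    "CVAModel",
    "CVReport",
    "fit_pca",
    "fit_cva",
    "classify",
    "kfold_crossvalidate",
]


@dataclass
class PCAModel:
    mean_spectrum: np.ndarray
    loadings: np.ndarray            # (n_components, n_features), orthonormal rows
    explained_fraction: np.ndarray  # per retained component, non-increasing
    n_components: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        return (X - self.mean_spectrum) @ self.loadings.T


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, SpectrumSet):
        return data.intensity_matrix()
    return np.asarray(data, dtype=float)


def fit_pca(
    data,
    variance_target: float | None = None,
    n_components: int | None = None,
    cap: int = 21,
) -> PCAModel:
    """Mean-centred PCA of spectra-as-rows.

    Exactly one of ``variance_target`` (fraction in (0, 1]; the smallest
    component count whose cumulative explained fraction reaches it is kept,
    capped at ``cap``) or ``n_components`` must be given.
    """
    X = _as_matrix(data)
    if X.shape[0] < 2:
        raise ConfigError("PCA needs at least 2 spectra")
    if (variance_target is None) == (n_components is None):
        raise ConfigError("give exactly one of variance_target or n_components")
    if variance_target is not None and not 0.0 < variance_target <= 1.0:
        raise ConfigError("variance_target must be in (0, 1]")

    full = _SkPCA(svd_solver="full").fit(X)
    ratios = full.explained_variance_ratio_
    if n_components is not None:
        m = min(n_components, ratios.size)
    else:
        cum = np.cumsum(ratios)
        # float rounding can leave cum maxing just below 1.0
        reached = np.nonzero(cum >= variance_target - 1e-12)[0]
        m = int(reached[0]) + 1 if reached.size else ratios.size
        m = min(m, cap, ratios.size)
    return PCAModel(
        mean_spectrum=full.mean_,
        loadings=full.components_[:m],
        explained_fraction=ratios[:m],
        n_components=m,
    )


@dataclass
class CVAModel:
    pca: PCAModel | None
    canonical_vectors: np.ndarray   # (n_scores_dim, n_cv), columns are directions
    eigenvalues: np.ndarray         # between/within variance ratios, decreasing
    class_centroids: dict           # class -> centroid in canonical space
    classes: list
    ridge: float
    within_cov: np.ndarray | None = None  # pooled within-class covariance (scores)
    grid: object = None              # grid of the training spectra, when known

    @property
    def n_cv(self) -> int:
        return self.canonical_vectors.shape[1]

    def project_scores(self, scores: np.ndarray) -> np.ndarray:
        return np.atleast_2d(scores) @ self.canonical_vectors

    def project(self, X: np.ndarray) -> np.ndarray:
        """Raw spectra → canonical coordinates (through PCA when attached)."""
        scores = self.pca.transform(X) if self.pca is not None else np.atleast_2d(X)
        return self.project_scores(scores)


def _scatter_matrices(scores: np.ndarray, labels: np.ndarray):
    classes = sorted(set(labels.tolist()))
    mean = scores.mean(axis=0)
    d = scores.shape[1]
    sb = np.zeros((d, d))
    sw = np.zeros((d, d))
    centroids = {}
    for c in classes:
        xc = scores[labels == c]
        mu = xc.mean(axis=0)
        centroids[c] = mu
        dm = (mu - mean)[:, None]
        sb += xc.shape[0] * (dm @ dm.T)
        r = xc - mu
        sw += r.T @ r
    return classes, sb, sw, centroids


def fit_cva(
    scores: np.ndarray,
    labels,
    ridge: float | None = None,
    pca: PCAModel | None = None,
) -> CVAModel:
    """Canonical variate analysis on PC scores.

    Solves S_b v = λ (S_w + ridge·I) v and keeps the (classes − 1) leading
    generalized eigenvectors. ``ridge`` defaults to
    1e-8 · trace(S_w)/dim for numerical stability; pass ``ridge=0`` to get a
    hard failure on singular within-class scatter.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes, sb, sw, centroids = _scatter_matrices(scores, labels)
    if len(classes) < 2:
        raise SingleClassError("CVA needs at least 2 classes; got a single class")
    for c in classes:
        if (labels == c).sum() < 2:
            raise ConfigError(f"class {c!r} has fewer than 2 members")
    d = scores.shape[1]
    if ridge is None:
        ridge = 1e-8 * np.trace(sw) / d
    sw_reg = sw + ridge * np.eye(d)
    if ridge == 0.0 and np.linalg.matrix_rank(sw) < d:
        raise SingularScatterError(
            "within-class scatter is singular; supply ridge > 0 or retain fewer PCs"
        )
    evals, evecs = linalg.eigh(sb, sw_reg)
    order = np.argsort(evals)[::-1]
    n_cv = min(len(classes) - 1, d)
    vecs = evecs[:, order[:n_cv]]
    vals = np.clip(evals[order[:n_cv]], 0.0, None)
    # sign convention: largest-magnitude loading positive, for reproducibility
    for j in range(vecs.shape[1]):
        k = np.argmax(np.abs(vecs[:, j]))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    model = CVAModel(
        pca=pca,
        canonical_vectors=vecs,
        eigenvalues=vals,
        class_centroids={},
        classes=classes,
        ridge=float(ridge),
        within_cov=sw / max(scores.shape[0] - len(classes), 1),
    )
    model.class_centroids = {
        c: model.project_scores(centroids[c])[0] for c in classes
    }
    return model


def classify(model: CVAModel, s, metric: str = "euclidean"):
    """Assign a spectrum (or score/feature vector) to the nearest centroid.

    Returns ``(label, canonical_coordinates, distances, tie)`` where
    ``distances`` maps class → distance. Ties are broken lexicographically
    by class name and flagged.
    """
    if isinstance(s, Spectrum):
        if model.grid is not None and s.grid != model.grid:
            raise GridError("spectrum grid differs from the model's training grid")
        x = s.intensity[None, :]
        coords = model.project(x)[0]
    else:
        x = np.atleast_2d(np.asarray(s, dtype=float))
        coords = model.project(x)[0]

    if metric == "mahalanobis" and model.within_cov is not None:
        w = model.canonical_vectors
        cov_c = w.T @ model.within_cov @ w
        icov = np.linalg.pinv(cov_c)
        dist = {
            c: float(np.sqrt((coords - mu) @ icov @ (coords - mu)))
            for c, mu in model.class_centroids.items()
        }
    else:
        dist = {
            c: float(np.linalg.norm(coords - mu))
            for c, mu in model.class_centroids.items()
        }
    best = min(dist.values())
    winners = sorted(c for c, v in dist.items() if np.isclose(v, best, rtol=0, atol=1e-12))
    return winners[0], coords, dist, len(winners) > 1


@dataclass
class CVReport:
    """Per-fold, per-class percent-correct table with ranges and means."""

    fold_class_pct: pd.DataFrame          # index: fold (1..k), columns: classes
    confusion_matrices: list[pd.DataFrame]
    fold_assignment: pd.DataFrame         # columns: index, fold
    seed: int
    k: int

    @property
    def per_class_mean(self) -> pd.Series:
        return self.fold_class_pct.mean(axis=0)

    @property
    def per_class_range(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"min": self.fold_class_pct.min(axis=0), "max": self.fold_class_pct.max(axis=0)}
        ).T

    @property
    def overall_mean(self) -> float:
        return float(self.fold_class_pct.to_numpy().mean())

    def to_table(self) -> pd.DataFrame:
        """Summary table: one row per fold, then Range and Mean rows."""
        body = self.fold_class_pct.copy()
        body.index = [str(i) for i in body.index]
        rng = self.per_class_range
        body.loc["Range (%)"] = [
            f"{rng.loc['min', c]:.0f}-{rng.loc['max', c]:.0f}" for c in body.columns
        ]
        body.loc["Mean (%)"] = [f"{self.per_class_mean[c]:.0f}" for c in body.columns]
        body.index.name = "k"
        return body


def kfold_crossvalidate(
    data,
    labels,
    k: int = 5,
    seed: int = 0,
    variance_target: float | None = 0.95,
    n_components: int | None = None,
    pc_cap: int = 21,
    ridge: float | None = None,
    metric: str = "euclidean",
    pca_on_all: bool = False,
) -> CVReport:
    """Stratified k-fold cross-validation of the PCA-CVA classifier.

    Fold assignment is a seeded stratified shuffle; each spectrum is tested
    exactly once. Per fold, PCA and CVA are fit on the training rows only
    and test rows are projected in, so no information leaks from the test
    fold (``pca_on_all=True`` switches to a whole-data PCA fit for
    comparison with reports that used one; it is not the default).
    """
    X = _as_matrix(data)
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise SingleClassError("cross-validation needs at least 2 classes")
    if k < 2:
        raise ConfigError("k must be ≥ 2")
    for c in classes:
        if (y == c).sum() < k:
            raise StratificationError(f"class {c!r} has fewer than k={k} members")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    shared_pca = (
        fit_pca(X, variance_target=variance_target, n_components=n_components, cap=pc_cap)
        if pca_on_all
        else None
    )

    pct_rows = []
    confusions = []
    assignment = np.empty(len(y), dtype=int)
    for fold_i, (train, test) in enumerate(skf.split(X, y), start=1):
        assignment[test] = fold_i
        pca = shared_pca or fit_pca(
            X[train], variance_target=variance_target, n_components=n_components, cap=pc_cap
        )
        model = fit_cva(pca.transform(X[train]), y[train], ridge=ridge, pca=pca)
        preds = [classify(model, X[i], metric=metric)[0] for i in test]
        cm = pd.DataFrame(0, index=classes, columns=classes)
        for true, pred in zip(y[test], preds):
            cm.loc[true, pred] += 1
        confusions.append(cm)
        pct_rows.append(
            {c: 100.0 * cm.loc[c, c] / cm.loc[c].sum() for c in classes}
        )

    fold_class_pct = pd.DataFrame(pct_rows, index=range(1, k + 1))
    fold_assignment = pd.DataFrame({"index": np.arange(len(y)), "fold": assignment})
    return CVReport(
        fold_class_pct=fold_class_pct,
        confusion_matrices=confusions,
        fold_assignment=fold_assignment,
        seed=seed,
        k=k,
    )
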