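"""Principal component regression (PCR) mapping ROI activity to psychometrics.

The decoder works in three linear steps. (1) Two principal components are
extracted from the sample subjects' ROI feature matrix (PCA on column-mean-
centered features; the stored sample mean is reused — never recomputed — when
a held-out subject is projected, so no test information leaks into the basis).
(2) Each subject's centered feature vector is regressed on the two principal
patterns, yielding a weights row (w1, w2, 1) — the two PC coefficients plus
the explicit constant column of the weights-matrix layout. (3) Stacking
sample rows into a weights matrix W and the measured
[BDI-II, AAI] pairs into Y, the model map is the minimum-norm least-squares
solution

    ModelMap = pinv(W) @ Y            (Moore-Penrose pseudoinverse)

so a held-out subject's predicted scores are simply ``row @ ModelMap``.
Predicted scores are continuous and unbounded; categorical diagnoses apply
strict cut-offs: depressed iff predicted BDI-II > 13.5 (the clinical cut of 14
adapted to continuous predictions), insecure attachment iff predicted
AAI < 4.

PC sign convention: each component's largest-magnitude loading is made
positive, making the basis deterministic (bit-identical across calls).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "PCBasis",
    "ModelMap",
    "PredictedScores",
    "ClassifierConfig",
    "extract_pcs",
    "subject_weights",
    "fit_model_map",
    "predict_scores",
    "classify_depression",
    "classify_attachment",
    "save_model_artifact",
    "load_model_artifact",
]


@dataclass
class PCBasis:
    """Top-k orthonormal principal patterns over the ROI feature space.

    ``components`` is k x features (rows orthonormal), ``mean`` the sample
    feature mean used for centering, ``explained_fraction`` the fraction of
    total sample variance carried by each component (non-increasing).
    """

    components: np.ndarray
    mean: np.ndarray
    explained_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=np.float64)
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.explained_fraction = np.asarray(self.explained_fraction, dtype=np.float64)
        if self.components.ndim != 2 or self.components.shape[1] != self.mean.size:
            raise ValueError("components and mean disagree on feature dimension")

    @property
    def k(self) -> int:
        return self.components.shape[0]


@dataclass
class ModelMap:
    """The 3x2 linear map sending a weights row (w1, w2, 1) to (BDI-II, AAI)."""

    map: np.ndarray

    def __post_init__(self) -> None:
        self.map = np.asarray(self.map, dtype=np.float64)
        if not np.all(np.isfinite(self.map)):
            raise ValueError("model map contains non-finite entries")


@dataclass(frozen=True)
class PredictedScores:
    """Continuous predicted scores; deliberately not clipped to the scales."""

    bdi_pred: float
    aai_pred: float


@dataclass(frozen=True)
class ClassifierConfig:
    """Strict diagnostic cut-offs on the predicted scores."""

    bdi_cut: float = 13.5
    aai_cut: float = 4.0

    def __post_init__(self) -> None:
        if not (0 < self.bdi_cut < 63):
            raise ValueError("bdi_cut must lie inside (0, 63)")
        if not (1 < self.aai_cut < 9):
            raise ValueError("aai_cut must lie inside (1, 9)")


def extract_pcs(features: np.ndarray, k: int = 2) -> PCBasis:
    """PCA of the sample feature matrix; returns the top-``k`` basis.

    Components are the leading right singular vectors of the column-mean-
    centered matrix, sign-fixed so each component's largest-magnitude loading
    is positive. ``explained_fraction[i]`` is that component's share of the
    total variance. Raises if ``k`` exceeds the matrix rank or the sample has
    fewer than ``k + 1`` rows.
    """
    F = np.asarray(features, dtype=np.float64)
    if F.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    if not np.all(np.isfinite(F)):
        raise ValueError("feature matrix contains non-finite entries")
    if F.shape[0] < k + 1:
        raise ValueError(f"need at least {k + 1} sample rows for {k} components, got {F.shape[0]}")
    mean = F.mean(axis=0)
    centered = F - mean
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    tol = s.max(initial=0.0) * max(centered.shape) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    if k > rank:
        raise ValueError(f"requested {k} components but centered matrix has rank {rank}")
    comps = vt[:k].copy()
    for i in range(k):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    total = float((s**2).sum())
    explained = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PCBasis(components=comps, mean=mean, explained_fraction=explained)


def subject_weights(feature_vector: np.ndarray, basis: PCBasis) -> np.ndarray:
    """One subject's weights row (w1, ..., wk, 1).

    Each wi is the least-squares coefficient of the mean-centered feature
    vector regressed on the principal patterns; with orthonormal components
    that is exactly the projection ``wi = PCi . (f - mean)``. The trailing
    entry is the constant 1 of the weights-matrix layout (the intercept
    column of the downstream model map), so a subject sitting at the sample
    mean has weights (0, ..., 0, 1).
    """
    f = np.asarray(feature_vector, dtype=np.float64).ravel()
    if f.size != basis.mean.size:
        raise ValueError(f"feature length {f.size} does not match basis dimension {basis.mean.size}")
    coef = basis.components @ (f - basis.mean)
    return np.concatenate([coef, [1.0]])


def fit_model_map(W: np.ndarray, Y: np.ndarray) -> ModelMap:
    """Solve W @ M = Y for the model map by Moore-Penrose pseudoinverse.

    ``W`` is subjects x 3 (two PC coefficients + constant 1), ``Y`` subjects x
    2 (measured BDI-II, AAI). The pseudoinverse (SVD-based; singular values
    below ``max_dim * eps`` relative to the largest are dropped) gives the
    least-squares solution of minimum Frobenius norm, which is unique even
    when W is rank-deficient.
    """
    W = np.asarray(W, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if W.ndim != 2 or Y.ndim != 2 or W.shape[0] != Y.shape[0]:
        raise ValueError("W and Y must be 2-D with aligned rows")
    if W.shape[0] < W.shape[1]:
        raise ValueError(f"need at least {W.shape[1]} sample subjects, got {W.shape[0]}")
    if not (np.all(np.isfinite(W)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite entries in weights or psychometrics")
    rcond = max(W.shape) * np.finfo(float).eps
    return ModelMap(map=np.linalg.pinv(W, rcond=rcond) @ Y)


def predict_scores(row: Sequence[float], model: ModelMap) -> PredictedScores:
    """Apply the model map to a weights row: ``[bdi, aai] = row @ M``."""
    row = np.asarray(row, dtype=np.float64).ravel()
    if row.size != model.map.shape[0]:
        raise ValueError(f"weights row length {row.size} does not match map rows {model.map.shape[0]}")
    bdi_pred, aai_pred = row @ model.map
    return PredictedScores(bdi_pred=float(bdi_pred), aai_pred=float(aai_pred))


def classify_depression(scores: PredictedScores, cfg: ClassifierConfig | None = None) -> bool:
    """True (depressed) iff predicted BDI-II strictly exceeds the cut-off."""
    cfg = cfg or ClassifierConfig()
    if not np.isfinite(scores.bdi_pred):
        raise ValueError("non-finite predicted BDI-II")
    return scores.bdi_pred > cfg.bdi_cut


def classify_attachment(scores: PredictedScores, cfg: ClassifierConfig | None = None) -> bool:
    """True (insecure attachment) iff predicted AAI is strictly below the cut-off."""
    cfg = cfg or ClassifierConfig()
    if not np.isfinite(scores.aai_pred):
        raise ValueError("non-finite predicted AAI")
    return scores.aai_pred < cfg.aai_cut


def save_model_artifact(
    path: str | Path,
    basis: PCBasis,
    model: ModelMap,
    mask_indices: Sequence[int],
    contrast_order: Sequence[str],
) -> Path:
    """Serialize a fitted fold (basis + map + feature ordering) to JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "components": basis.components.tolist(),
        "mean": basis.mean.tolist(),
        "explained_fraction": basis.explained_fraction.tolist(),
        "model_map": model.map.tolist(),
        "mask_indices": [int(i) for i in mask_indices],
        "contrast_order": list(contrast_order),
    }
    path.write_text(json.dumps(payload, sort_keys=True))
    return path


def load_model_artifact(path: str | Path) -> tuple[PCBasis, ModelMap, np.ndarray, list[str]]:
    """Inverse of :func:`save_model_artifact`; reload is bit-exact for the arrays."""
    payload = json.loads(Path(path).read_text())
    basis = PCBasis(
        components=np.array(payload["components"]),
        mean=np.array(payload["mean"]),
        explained_fraction=np.array(payload["explained_fraction"]),
    )
    model = ModelMap(map=np.array(payload["model_map"]))
    return basis, model, np.array(payload["mask_indices"], dtype=np.int64), payload["contrast_order"]
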