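"""First-level analysis: from 4-D BOLD runs to per-subject contrast maps.

The pipeline is the conventional event-related one: task regressors are event
indicators convolved with the canonical double-gamma hemodynamic response
function, the time series is spatially smoothed, each voxel is fit by ordinary
least squares, the three condition contrasts (M-F, M-S, F-S) are formed with
their variances, and runs are combined by inverse-variance (fixed-effects)
weighting.

OLS is used throughout; no prewhitening or autoregressive noise model is
applied. That is exact for white noise (the synthetic generator's model) and a
documented approximation for real scanner noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.ndimage
import scipy.stats

from .volumes_io import Volume

__all__ = [
    "CONDITIONS",
    "CONTRASTS",
    "CONTRAST_PAIRS",
    "DesignMatrix",
    "GlmFit",
    "ContrastSet",
    "canonical_hrf",
    "build_design",
    "fwhm_to_sigma",
    "gaussian_smooth",
    "fit_glm",
    "contrast_map",
    "fixed_effects_combine",
    "run_first_level",
]

logger = logging.getLogger(__name__)

#: Viewing conditions, in fixed design-column order.
CONDITIONS = ("M", "F", "S")

#: The three condition contrasts, in fixed feature-block order.
CONTRASTS = ("M-F", "M-S", "F-S")

#: Condition pairs (positive, negative) defining each contrast.
CONTRAST_PAIRS = {"M-F": ("M", "F"), "M-S": ("M", "S"), "F-S": ("F", "S")}

# Canonical double-gamma HRF parameters: response peak delay 6 s, undershoot
# delay 16 s, unit dispersions, undershoot ratio 1/6, 32-s support.
HRF_PEAK_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_PEAK_DISPERSION = 1.0
HRF_UNDERSHOOT_DISPERSION = 1.0
HRF_UNDERSHOOT_RATIO = 1.0 / 6.0
HRF_DURATION = 32.0


@dataclass
class DesignMatrix:
    """A run's design: ``columns`` is frames x regressors, ``names`` labels them."""

    columns: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=np.float64)
        if self.columns.ndim != 2 or self.columns.shape[1] != len(self.names):
            raise ValueError("design shape does not match column names")
        if self.names.count("intercept") != 1:
            raise ValueError("design must contain exactly one intercept column")

    @property
    def n_frames(self) -> int:
        return self.columns.shape[0]


@dataclass
class GlmFit:
    """Per-voxel OLS results for one run.

    ``betas`` is regressors x voxels (voxels in x-fastest linear order),
    ``sigma2`` the per-voxel residual variance, ``dof`` the residual degrees
    of freedom (frames minus design rank), and ``xtx_inv`` the shared
    ``(X'X)^-1`` needed for contrast variances.
    """

    betas: np.ndarray
    sigma2: np.ndarray
    dof: int
    design: DesignMatrix
    xtx_inv: np.ndarray
    grid_dims: tuple[int, int, int]
    voxel_dims: tuple[float, float, float]
    affine: np.ndarray


@dataclass
class ContrastSet:
    """The three contrast effect maps and their variance maps for one subject."""

    maps: dict[str, Volume]
    variances: dict[str, Volume]

    def __post_init__(self) -> None:
        if set(self.maps) != set(CONTRASTS) or set(self.variances) != set(CONTRASTS):
            raise ValueError(f"contrast keys must be exactly {CONTRASTS}")
        dims = {v.grid_dims for v in self.maps.values()} | {v.grid_dims for v in self.variances.values()}
        if len(dims) != 1:
            raise ValueError(f"contrast maps on mismatched grids: {dims}")

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.maps[CONTRASTS[0]].grid_dims


def canonical_hrf(dt: float, duration: float = HRF_DURATION) -> np.ndarray:
    """Sample the canonical double-gamma HRF at spacing ``dt`` seconds.

    Returns ``ceil(duration / dt)`` samples starting at t = 0, peak-normalized
    so the kernel maximum is exactly 1. The kernel is the standard difference
    of two gamma densities: a positive response peaking near 5 s and an
    undershoot, weighted 1/6, peaking near 15 s.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if dt > duration:
        raise ValueError(f"dt={dt} exceeds kernel duration {duration}")
    n = math.ceil(duration / dt)
    t = np.arange(n) * dt
    peak = scipy.stats.gamma.pdf(t, HRF_PEAK_DELAY / HRF_PEAK_DISPERSION, scale=HRF_PEAK_DISPERSION)
    under = scipy.stats.gamma.pdf(
        t, HRF_UNDERSHOOT_DELAY / HRF_UNDERSHOOT_DISPERSION, scale=HRF_UNDERSHOOT_DISPERSION
    )
    h = peak - HRF_UNDERSHOOT_RATIO * under
    return h / h.max()


def _event_indicator(events: Sequence[tuple[str, float, float]], condition: str, n_frames: int, tr: float) -> np.ndarray:
    """Frame-grid indicator for one condition: onsets snapped to the TR grid."""
    ind = np.zeros(n_frames)
    for cond, onset, duration in events:
        if cond != condition:
            continue
        start = int(round(onset / tr))
        n_dur = max(1, int(round(duration / tr)))
        if start < 0 or start >= n_frames:
            raise ValueError(f"event onset {onset}s outside run of {n_frames} frames")
        ind[start : min(start + n_dur, n_frames)] += 1.0
    return ind


def build_design(
    events: Sequence[tuple[str, float, float]],
    n_frames: int,
    tr: float,
    confounds: np.ndarray | None = None,
) -> DesignMatrix:
    """Build a run design matrix from an event list.

    One column per viewing condition (M, F, S) — the event indicator convolved
    with the canonical HRF sampled at the TR and truncated to the run length —
    followed by any confound columns (passed through unchanged; centering is
    the caller's responsibility) and a trailing intercept.
    """
    hrf = canonical_hrf(tr)
    cols, names = [], []
    for cond in CONDITIONS:
        ind = _event_indicator(events, cond, n_frames, tr)
        cols.append(np.convolve(ind, hrf)[:n_frames])
        names.append(cond)
    if confounds is not None:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=np.float64))
        if confounds.shape[0] != n_frames:
            raise ValueError(f"confounds have {confounds.shape[0]} rows; run has {n_frames} frames")
        for j in range(confounds.shape[1]):
            cols.append(confounds[:, j])
            names.append(f"confound{j}")
    cols.append(np.ones(n_frames))
    names.append("intercept")
    return DesignMatrix(columns=np.column_stack(cols), names=names)


def fwhm_to_sigma(fwhm_mm: float, voxel_dim_mm: float) -> float:
    """Gaussian sigma in voxel units for a smoothing kernel of given FWHM (mm)."""
    return fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / voxel_dim_mm


def gaussian_smooth(vol: Volume, fwhm_mm: float) -> Volume:
    """Spatially smooth a volume with a separable Gaussian of FWHM ``fwhm_mm``.

    4-D inputs are smoothed frame-wise. Boundary handling is reflection and
    the kernel is truncated at 4 sigma. ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm must be non-negative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return Volume(vol.data.copy(), vol.voxel_dims, vol.affine)
    sigmas = [fwhm_to_sigma(fwhm_mm, d) for d in vol.voxel_dims]
    if vol.data.ndim == 4:
        sigmas = sigmas + [0.0]  # never smooth across time
    smoothed = scipy.ndimage.gaussian_filter(vol.data, sigma=sigmas, mode="reflect", truncate=4.0)
    return Volume(smoothed, vol.voxel_dims, vol.affine)


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Name the design columns involved in a rank deficiency (via pivoted QR)."""
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    return [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]


def fit_glm(run: Volume, design: DesignMatrix) -> GlmFit:
    """Fit the design to every voxel's time series by ordinary least squares."""
    if run.data.ndim != 4:
        raise ValueError("fit_glm expects a 4-D run")
    X = design.columns
    n_frames = run.data.shape[3]
    if X.shape[0] != n_frames:
        raise ValueError(f"design has {X.shape[0]} frames; run has {n_frames}")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, design.names)
        raise ValueError(f"rank-deficient design (rank {rank} < {X.shape[1]}); collinear columns: {bad}")
    n_vox = int(np.prod(run.grid_dims))
    # x-fastest flattening of the spatial axes; time stays the second axis
    Y = run.data.reshape((n_vox, n_frames), order="F").T
    betas, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ betas
    dof = n_frames - rank
    sigma2 = (resid**2).sum(axis=0) / dof
    return GlmFit(
        betas=betas,
        sigma2=sigma2,
        dof=dof,
        design=design,
        xtx_inv=np.linalg.inv(X.T @ X),
        grid_dims=run.grid_dims,
        voxel_dims=run.voxel_dims,
        affine=run.affine,
    )


def contrast_map(fit: GlmFit, c: Sequence[float]) -> tuple[Volume, Volume]:
    """Evaluate a contrast ``c'beta`` per voxel with its OLS variance.

    ``c`` may cover only the leading task columns; it is zero-padded over
    confounds and the intercept.
    """
    c = np.asarray(c, dtype=np.float64)
    p = fit.betas.shape[0]
    if c.size < p:
        c = np.concatenate([c, np.zeros(p - c.size)])
    elif c.size > p:
        raise ValueError(f"contrast length {c.size} exceeds {p} design columns")
    effect = c @ fit.betas
    var = fit.sigma2 * float(c @ fit.xtx_inv @ c)
    shape = fit.grid_dims
    return (
        Volume(effect.reshape(shape, order="F"), fit.voxel_dims, fit.affine),
        Volume(var.reshape(shape, order="F"), fit.voxel_dims, fit.affine),
    )


def fixed_effects_combine(
    effects: Sequence[Volume], variances: Sequence[Volume]
) -> tuple[Volume, Volume]:
    """Combine per-run contrast estimates by inverse-variance weighting.

    The combined effect is the precision-weighted mean and the combined
    variance is ``1 / sum(1/v_i)``. Voxels where any run reports a
    non-positive variance fall back to the unweighted mean (with the average
    variance divided by the run count), and a warning is logged.
    """
    if len(effects) == 0:
        raise ValueError("no runs to combine")
    if len(effects) != len(variances):
        raise ValueError("effects and variances differ in length")
    dims = {v.grid_dims for v in effects} | {v.grid_dims for v in variances}
    if len(dims) != 1:
        raise ValueError(f"runs on mismatched grids: {dims}")
    E = np.stack([v.data for v in effects])
    V = np.stack([v.data for v in variances])
    degenerate = (V <= 0).any(axis=0)
    if degenerate.any():
        logger.warning(
            "fixed-effects combine: %d voxel(s) with zero variance; using unweighted mean there",
            int(degenerate.sum()),
        )
    with np.errstate(divide="ignore"):
        w = np.where(V > 0, 1.0 / np.where(V > 0, V, 1.0), 0.0)
    wsum = w.sum(axis=0)
    safe_wsum = np.where(wsum > 0, wsum, 1.0)
    eff = np.where(degenerate, E.mean(axis=0), (w * E).sum(axis=0) / safe_wsum)
    var = np.where(degenerate, V.mean(axis=0) / len(effects), 1.0 / safe_wsum)
    ref = effects[0]
    return Volume(eff, ref.voxel_dims, ref.affine), Volume(var, ref.voxel_dims, ref.affine)


def run_first_level(
    runs: Sequence[Volume],
    run_events: Sequence[Sequence[tuple[str, float, float]]],
    tr: float,
    fwhm_mm: float = 9.0,
    confounds: Sequence[np.ndarray | None] | None = None,
) -> ContrastSet:
    """Full first-level pipeline for one subject.

    Each run is smoothed, fit by OLS against its event design, and the three
    condition contrasts are estimated; runs are then combined by fixed
    effects. Returns the subject's :class:`ContrastSet`.
    """
    if len(runs) != len(run_events):
        raise ValueError("one event list per run required")
    if confounds is None:
        confounds = [None] * len(runs)
    per_contrast: dict[str, list[tuple[Volume, Volume]]] = {k: [] for k in CONTRASTS}
    for run, events, conf in zip(runs, run_events, confounds):
        smoothed = gaussian_smooth(run, fwhm_mm)
        design = build_design(events, run.data.shape[3], tr, conf)
        fit = fit_glm(smoothed, design)
        for name in CONTRASTS:
            pos, neg = CONTRAST_PAIRS[name]
            c = np.zeros(len(CONDITIONS))
            c[CONDITIONS.index(pos)] = 1.0
            c[CONDITIONS.index(neg)] = -1.0
            per_contrast[name].append(contrast_map(fit, c))
    maps, variances = {}, {}
    for name in CONTRASTS:
        eff, var = fixed_effects_combine(
            [e for e, _ in per_contrast[name]], [v for _, v in per_contrast[name]]
        )
        maps[name], variances[name] = eff, var
    return ContrastSet(maps=maps, variances=variances)
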