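"""Group-level voxelwise regression, Z-thresholded ROI selection, and feature
assembly for the principal component regression stage.

For the sample subjects of a fold, every voxel of every contrast map is
regressed on ``[intercept, BDI-II, AAI]`` by ordinary least squares. Each
regressor's t statistic (n - 3 residual degrees of freedom) is converted to a
standard normal Z by matching cumulative probabilities, giving six Z maps
(3 contrasts x 2 regressors). The ROI is the union, over all six maps, of
voxels whose |Z| exceeds the threshold (default 4.265, the upper-tail
standard-normal quantile just inside P = 1e-5). The feature matrix then
concatenates, per subject, the ROI voxel values of the three contrast maps in
fixed block order (M-F, M-S, F-S), voxels sorted by linear index within each
block — a pure re-indexing with no arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .first_level import CONTRASTS, ContrastSet
from .volumes_io import SubjectRecord, Volume, ravel3

__all__ = [
    "REGRESSORS",
    "GroupZMaps",
    "RoiMask",
    "RoiConfig",
    "t_to_z",
    "group_zmaps",
    "select_roi",
    "assemble_features",
]

logger = logging.getLogger(__name__)

#: Psychometric regressors of the group model, in design-column order.
REGRESSORS = ("BDI", "AAI")


@dataclass
class GroupZMaps:
    """Z-statistic volumes keyed ``(contrast, regressor)``; exactly 6 keys."""

    z: dict[tuple[str, str], Volume]

    def __post_init__(self) -> None:
        expected = {(c, r) for c in CONTRASTS for r in REGRESSORS}
        if set(self.z) != expected:
            raise ValueError(f"Z maps must be keyed by {sorted(expected)}")
        dims = {v.grid_dims for v in self.z.values()}
        if len(dims) != 1:
            raise ValueError("Z maps on mismatched grids")

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return next(iter(self.z.values())).grid_dims


@dataclass
class RoiMask:
    """Selected voxels as sorted unique linear indices (x fastest) on a grid."""

    indices: np.ndarray
    grid_dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.size == 0:
            raise ValueError("ROI mask is empty")
        if len(np.unique(self.indices)) != self.indices.size:
            raise ValueError("ROI indices must be unique")
        if not np.all(np.diff(self.indices) > 0):
            raise ValueError("ROI indices must be sorted")
        if self.indices.min() < 0 or self.indices.max() >= int(np.prod(self.grid_dims)):
            raise ValueError("ROI index out of grid")

    def __len__(self) -> int:
        return int(self.indices.size)

    def to_volume(self) -> Volume:
        """Binary mask volume (1 inside the ROI)."""
        flat = np.zeros(int(np.prod(self.grid_dims)))
        flat[self.indices] = 1.0
        return Volume(flat.reshape(self.grid_dims, order="F"))


@dataclass
class RoiConfig:
    """ROI selection rule: |Z| (or Z, if one-sided) must strictly exceed
    ``z_threshold``; if no voxel passes, the ``fallback_k`` strongest voxels
    are used instead."""

    z_threshold: float = 4.265
    two_sided: bool = True
    fallback_k: int = 50

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if self.fallback_k < 2:
            raise ValueError("fallback_k must be at least 2")


def t_to_z(t: np.ndarray, dof: int) -> np.ndarray:
    """Convert t statistics to standard-normal Z by matching tail probabilities.

    ``Z = Phi^-1(F_t(t))``, evaluated through the upper tail for positive t and
    the lower tail for negative t so that large statistics keep full precision.
    Strictly monotone; preserves sign; t = 0 maps to Z = 0 exactly.
    """
    t = np.asarray(t, dtype=np.float64)
    pos = t >= 0
    z = np.empty_like(t)
    z[pos] = scipy.stats.norm.isf(scipy.stats.t.sf(t[pos], dof))
    z[~pos] = -scipy.stats.norm.isf(scipy.stats.t.sf(-t[~pos], dof))
    return z


def group_zmaps(
    contrast_sets: dict[str, ContrastSet], records: list[SubjectRecord]
) -> GroupZMaps:
    """Voxelwise group regression of contrast values on [1, BDI, AAI].

    One OLS fit per voxel and contrast across the given subjects; each
    psychometric regressor's t statistic is converted to Z. Requires at least
    4 subjects (one more than the number of design columns) and non-constant
    regressors.
    """
    if len(records) < 4:
        raise ValueError(f"group model needs at least 4 subjects, got {len(records)}")
    missing = [r.subject_id for r in records if r.subject_id not in contrast_sets]
    if missing:
        raise ValueError(f"missing contrast sets for subjects: {missing}")
    bdi = np.array([r.bdi for r in records], dtype=np.float64)
    aai = np.array([r.aai for r in records], dtype=np.float64)
    for name, v in (("bdi", bdi), ("aai", aai)):
        if np.ptp(v) == 0:
            raise ValueError(f"regressor {name} is constant across subjects")
    X = np.column_stack([np.ones(len(records)), bdi, aai])
    xtx_inv = np.linalg.inv(X.T @ X)
    dof = len(records) - X.shape[1]
    ref = contrast_sets[records[0].subject_id]
    dims = ref.grid_dims
    zmaps: dict[tuple[str, str], Volume] = {}
    for contrast in CONTRASTS:
        Y = np.stack(
            [ravel3(contrast_sets[r.subject_id].maps[contrast].data) for r in records]
        )
        betas = xtx_inv @ X.T @ Y
        resid = Y - X @ betas
        sigma2 = (resid**2).sum(axis=0) / dof
        for j, reg in enumerate(REGRESSORS, start=1):
            se = np.sqrt(sigma2 * xtx_inv[j, j])
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(se > 0, betas[j] / np.where(se > 0, se, 1.0), np.inf * np.sign(betas[j]))
            t = np.where(np.isnan(t), 0.0, t)  # beta == 0 with zero residual
            ref_vol = contrast_sets[records[0].subject_id].maps[contrast]
            zmaps[(contrast, reg)] = Volume(
                t_to_z(t, dof).reshape(dims, order="F"), ref_vol.voxel_dims, ref_vol.affine
            )
    return GroupZMaps(z=zmaps)


def select_roi(zmaps: GroupZMaps, cfg: RoiConfig | None = None) -> RoiMask:
    """Union of voxels strictly exceeding the Z threshold in any of the 6 maps.

    With ``two_sided`` (default), |Z| > threshold; otherwise Z > threshold.
    If no voxel anywhere passes, the ``fallback_k`` voxels with the largest
    across-map statistic are selected and a warning is logged, so that
    downstream folds remain runnable on weak-signal data.
    """
    cfg = cfg or RoiConfig()
    stacked = np.stack([ravel3(v.data) for v in zmaps.z.values()])
    stat = np.abs(stacked) if cfg.two_sided else stacked
    best = stat.max(axis=0)
    selected = np.flatnonzero(best > cfg.z_threshold)
    if selected.size == 0:
        k = min(cfg.fallback_k, best.size)
        selected = np.sort(np.argpartition(best, -k)[-k:])
        logger.warning(
            "no voxel exceeded Z threshold %.3f; falling back to the %d strongest voxels",
            cfg.z_threshold,
            k,
        )
    return RoiMask(indices=np.sort(selected), grid_dims=zmaps.grid_dims)


def assemble_features(
    contrast_sets: dict[str, ContrastSet],
    mask: RoiMask,
    records: list[SubjectRecord],
) -> np.ndarray:
    """Stack ROI voxel values into the PCR feature matrix.

    Returns a (subjects x 3.|ROI|) array: per subject, the masked voxels of
    the M-F map, then M-S, then F-S, voxels in ascending linear-index order
    within each block.
    """
    rows = []
    for r in records:
        cset = contrast_sets[r.subject_id]
        if cset.grid_dims != mask.grid_dims:
            raise ValueError(
                f"grid mismatch for {r.subject_id}: maps {cset.grid_dims} vs mask {mask.grid_dims}"
            )
        rows.append(
            np.concatenate([ravel3(cset.maps[c].data)[mask.indices] for c in CONTRASTS])
        )
    return np.vstack(rows)
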