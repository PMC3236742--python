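"""Synthetic cohorts with a planted, psychometrics-linked activity cluster.

No scan data accompany the decoding method this package implements, so the
simulator here provides cohorts with the statistical structure the method
assumes: 14 control + 14 depressed subjects, a single contiguous ~50-voxel
cluster whose per-condition response amplitudes are linear in the subject's
depression (BDI-II) and attachment (AAI) scores, i.i.d. Gaussian observation
noise, and an event-related run structure (four 12.6-minute runs at TR 2 s
with balanced Mother/Friend/Stranger events).

Two rendering paths exist:

* :func:`render_contrast_maps` — the fast path: per-subject contrast maps
  drawn directly from the planted amplitude model plus noise, bypassing the
  BOLD simulation. This is what large-scale tests and the leave-one-out
  evaluation use.
* :func:`render_bold_run` — a full 4-D BOLD run (baseline + HRF-convolved
  event responses + white noise) for exercising the first-level pipeline
  end to end.

Everything is a pure function of ``(spec.seed, subject_id, operation)``: each
operation derives an independent random stream from the spec seed, a stable
hash of the subject id, and a per-operation salt.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd

from . import first_level
from .first_level import CONDITIONS, CONTRASTS, CONTRAST_PAIRS, ContrastSet
from .volumes_io import SubjectRecord, Volume, save_volume

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "Event",
    "EventSchedule",
    "sample_cohort_traits",
    "make_ground_truth",
    "make_event_schedule",
    "render_contrast_maps",
    "render_bold_run",
    "simulate_contrast_cohort",
    "write_cohort",
]

# salts separating the random streams of the different operations
_SALT_TRAITS = 1
_SALT_CLUSTER = 2
_SALT_SCHEDULE = 3
_SALT_CONTRAST = 4
_SALT_BOLD = 5


@dataclass
class CohortSpec:
    """Parameters of a simulated cohort.

    The cohort composition (14 + 14), run structure (four 12.6-minute runs at
    TR 2 s) and cluster size (~50 voxels) mirror the study design the method
    targets. The effect slopes are free calibration parameters — the study
    reports no effect sizes in physical units — chosen so that, at the default
    noise level, the cluster is comfortably detectable by the group Z-threshold
    rule in a 27-subject sample (see the methods note for the calibration
    argument). Amplitudes are in arbitrary BOLD units per score point.
    """

    n_control: int = 14
    n_depressed: int = 14
    grid_dims: tuple[int, int, int] = (16, 16, 10)
    voxel_dims: tuple[float, float, float] = (2.0, 2.0, 3.0)
    cluster_voxels: int = 50
    tr: float = 2.0
    run_minutes: float = 12.6
    n_runs: int = 4
    events_per_condition: int = 30
    event_duration_tr: int = 1
    #: per-condition response amplitude intercepts (arbitrary units)
    baseline_amplitude: dict[str, float] = field(default_factory=lambda: {"M": 1.0, "F": 1.0, "S": 1.0})
    #: amplitude change per BDI-II point; Mother-involving responses grow with depression
    effect_slopes: dict[str, float] = field(default_factory=lambda: {"M": 0.08, "F": 0.02, "S": 0.0})
    #: amplitude change per AAI point (weak, Mother only, by default)
    aai_slopes: dict[str, float] = field(default_factory=lambda: {"M": -0.02, "F": 0.0, "S": 0.0})
    #: magnitude of the negative BDI-AAI trait correlation, in [0, 1)
    bdi_aai_rho: float = 0.5
    noise_sd: float = 0.5
    bold_baseline: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control <= 0 or self.n_depressed <= 0:
            raise ValueError("group sizes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.cluster_voxels > int(np.prod(self.grid_dims)):
            raise ValueError("cluster_voxels exceeds grid size")
        if not (0 <= self.bdi_aai_rho < 1):
            raise ValueError("bdi_aai_rho must lie in [0, 1)")

    @property
    def n_frames(self) -> int:
        """Usable frames per run: floor(run_minutes * 60 / tr)."""
        return int(math.floor(self.run_minutes * 60.0 / self.tr))

    @property
    def n_subjects(self) -> int:
        return self.n_control + self.n_depressed


@dataclass
class GroundTruth:
    """The planted signal: cluster voxel indices (x-fastest linear order) and
    the per-condition amplitude model ``amp = intercept + b_bdi*bdi + b_aai*aai``."""

    cluster_indices: np.ndarray
    amplitude_model: dict[str, tuple[float, float, float]]

    def amplitude(self, condition: str, bdi: float, aai: float) -> float:
        intercept, b_bdi, b_aai = self.amplitude_model[condition]
        return intercept + b_bdi * bdi + b_aai * aai

    def contrast_amplitude(self, contrast: str, bdi: float, aai: float) -> float:
        pos, neg = CONTRAST_PAIRS[contrast]
        return self.amplitude(pos, bdi, aai) - self.amplitude(neg, bdi, aai)


class Event(NamedTuple):
    condition: str
    onset_s: float
    duration_s: float


@dataclass
class EventSchedule:
    """Per-run event lists: (condition, onset seconds, duration seconds)."""

    runs: list[list[Event]]


def _rng(seed: int, *salts: int | str) -> np.random.Generator:
    """Independent generator keyed by the spec seed plus operation/subject salts."""
    entropy = [seed & 0x7FFFFFFF]
    for s in salts:
        entropy.append(zlib.crc32(s.encode()) if isinstance(s, str) else int(s))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def sample_cohort_traits(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw the cohort's psychometric traits.

    Control BDI-II scores are uniform integers on [0, 12] and depressed scores
    uniform integers on [11, 54], matching the observed score ranges of the
    two groups. AAI coherence is a latent Gaussian mapped onto [1, 9] with a
    negative correlation of magnitude ``spec.bdi_aai_rho`` to the subject's
    (standardized) BDI-II score, reflecting the association between insecure
    attachment and depression.
    """
    rng = _rng(spec.seed, _SALT_TRAITS)
    records: list[SubjectRecord] = []
    groups = [("control", spec.n_control, 0, 12), ("depressed", spec.n_depressed, 11, 54)]
    bdis = {
        grp: rng.integers(lo, hi + 1, size=n)
        for grp, n, lo, hi in groups
    }
    all_bdi = np.concatenate([bdis["control"], bdis["depressed"]]).astype(float)
    mu, sd = all_bdi.mean(), max(all_bdi.std(), 1e-9)
    rho = spec.bdi_aai_rho
    for grp, n, _, _ in groups:
        for k in range(n):
            bdi = int(bdis[grp][k])
            z_bdi = (bdi - mu) / sd
            z = -rho * z_bdi + math.sqrt(1.0 - rho**2) * rng.standard_normal()
            aai = float(np.clip(round(5.0 + 1.6 * z, 1), 1.0, 9.0))
            prefix = "ctrl" if grp == "control" else "dep"
            records.append(SubjectRecord(f"{prefix}{k + 1:02d}", grp, bdi, aai))
    return records


def make_ground_truth(spec: CohortSpec) -> GroundTruth:
    """Plant a contiguous cluster (random BFS blob from an interior seed voxel)
    and attach the amplitude model from the spec's slopes."""
    rng = _rng(spec.seed, _SALT_CLUSTER)
    dims = spec.grid_dims
    start = tuple(int(rng.integers(1, d - 1)) if d > 2 else 0 for d in dims)
    chosen: list[tuple[int, int, int]] = [start]
    in_cluster = {start}
    frontier = {start}
    while len(chosen) < spec.cluster_voxels:
        candidates = set()
        for (x, y, z) in frontier:
            for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                nb = (x + dx, y + dy, z + dz)
                if all(0 <= nb[a] < dims[a] for a in range(3)) and nb not in in_cluster:
                    candidates.add(nb)
        if not candidates:
            raise ValueError("grid too small to grow the requested cluster")
        take = min(len(candidates), spec.cluster_voxels - len(chosen))
        ordered = sorted(candidates)
        picked = [ordered[j] for j in rng.choice(len(ordered), size=take, replace=False)]
        chosen.extend(picked)
        in_cluster.update(picked)
        frontier = set(picked)
    lin = np.sort(
        np.array([x + dims[0] * (y + dims[1] * z) for (x, y, z) in chosen], dtype=np.int64)
    )
    model = {
        c: (spec.baseline_amplitude[c], spec.effect_slopes[c], spec.aai_slopes[c])
        for c in CONDITIONS
    }
    return GroundTruth(cluster_indices=lin, amplitude_model=model)


def make_event_schedule(spec: CohortSpec) -> EventSchedule:
    """Randomized balanced event schedules for every run.

    Each run holds ``events_per_condition`` events of each condition, each
    lasting ``event_duration_tr`` TRs, at distinct TR-aligned onsets in random
    order. Raises if the run is too short to hold them.
    """
    n_frames = spec.n_frames
    per_run_total = 3 * spec.events_per_condition
    slots_needed = per_run_total * spec.event_duration_tr
    if slots_needed > n_frames:
        raise ValueError(
            f"run of {n_frames} frames cannot hold {per_run_total} events of {spec.event_duration_tr} TR(s)"
        )
    rng = _rng(spec.seed, _SALT_SCHEDULE)
    runs: list[list[Event]] = []
    for _ in range(spec.n_runs):
        # choose event start slots on a stride grid so events never overlap
        stride = spec.event_duration_tr
        available = np.arange(0, n_frames - stride + 1, stride)
        starts = np.sort(rng.choice(available, size=per_run_total, replace=False))
        labels = np.repeat(np.array(CONDITIONS), spec.events_per_condition)
        rng.shuffle(labels)
        runs.append(
            [
                Event(str(c), float(s * spec.tr), float(spec.event_duration_tr * spec.tr))
                for c, s in zip(labels, starts)
            ]
        )
    return EventSchedule(runs=runs)


def _affine(spec: CohortSpec) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spec.voxel_dims
    return aff


def render_contrast_maps(
    subject: SubjectRecord, truth: GroundTruth, spec: CohortSpec
) -> ContrastSet:
    """Draw a subject's three contrast maps directly from the planted model.

    Cluster voxels carry the planted contrast amplitude evaluated at the
    subject's (bdi, aai); everything else is zero; i.i.d. Gaussian noise of sd
    ``spec.noise_sd`` is added everywhere. Deterministic in
    ``(spec.seed, subject_id)``.
    """
    rng = _rng(spec.seed, subject.subject_id, _SALT_CONTRAST)
    dims = spec.grid_dims
    n_vox = int(np.prod(dims))
    maps, variances = {}, {}
    var_value = spec.noise_sd**2 if spec.noise_sd > 0 else 1.0
    for contrast in CONTRASTS:
        flat = np.zeros(n_vox)
        flat[truth.cluster_indices] = truth.contrast_amplitude(contrast, subject.bdi, subject.aai)
        flat = flat + spec.noise_sd * rng.standard_normal(n_vox)
        maps[contrast] = Volume(flat.reshape(dims, order="F"), spec.voxel_dims, _affine(spec))
        variances[contrast] = Volume(
            np.full(dims, var_value), spec.voxel_dims, _affine(spec)
        )
    return ContrastSet(maps=maps, variances=variances)


def render_bold_run(
    subject: SubjectRecord,
    schedule: EventSchedule,
    truth: GroundTruth,
    spec: CohortSpec,
    run_index: int = 0,
) -> Volume:
    """Render one 4-D BOLD run for a subject.

    Cluster voxels follow baseline + sum over conditions of the planted
    amplitude times the HRF-convolved event indicator; off-cluster voxels sit
    at baseline; white Gaussian noise of sd ``spec.noise_sd`` is added to every
    voxel and frame.
    """
    events = schedule.runs[run_index]
    n_frames = spec.n_frames
    hrf = first_level.canonical_hrf(spec.tr)
    signal = np.zeros(n_frames)
    # per-condition regressors times this subject's planted amplitudes
    for cond in CONDITIONS:
        ind = first_level._event_indicator(events, cond, n_frames, spec.tr)
        reg = np.convolve(ind, hrf)[:n_frames]
        signal = signal + truth.amplitude(cond, subject.bdi, subject.aai) * reg
    dims = spec.grid_dims
    n_vox = int(np.prod(dims))
    rng = _rng(spec.seed, subject.subject_id, _SALT_BOLD, run_index)
    flat = np.full((n_vox, n_frames), spec.bold_baseline)
    flat[truth.cluster_indices, :] += signal
    if spec.noise_sd > 0:
        flat = flat + spec.noise_sd * rng.standard_normal((n_vox, n_frames))
    data = flat.reshape(dims + (n_frames,), order="F")
    return Volume(data, spec.voxel_dims, _affine(spec))


def simulate_contrast_cohort(
    spec: CohortSpec,
) -> tuple[list[SubjectRecord], GroundTruth, dict[str, ContrastSet]]:
    """Fast-path cohort: traits, planted truth, and per-subject contrast maps."""
    records = sample_cohort_traits(spec)
    truth = make_ground_truth(spec)
    contrast_sets = {r.subject_id: render_contrast_maps(r, truth, spec) for r in records}
    return records, truth, contrast_sets


def write_cohort(
    spec: CohortSpec,
    out_dir: str | Path,
    mode: Literal["contrasts", "bold"] = "contrasts",
) -> Path:
    """Materialize a cohort on disk.

    Layout: ``<out>/participants.csv``, ``<out>/truth.json``, and per subject
    either contrast/variance maps (``con_M-F.nii.gz`` ...) or BOLD runs with
    event tables (``run-1.nii.gz`` + ``run-1_events.tsv``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = sample_cohort_traits(spec)
    truth = make_ground_truth(spec)
    pd.DataFrame(
        [{"subject_id": r.subject_id, "group": r.group, "bdi": r.bdi, "aai": r.aai} for r in records]
    ).to_csv(out / "participants.csv", index=False)
    payload = {
        "spec": asdict(spec),
        "cluster_indices": truth.cluster_indices.tolist(),
        "amplitude_model": {k: list(v) for k, v in truth.amplitude_model.items()},
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    if mode == "contrasts":
        for r in records:
            cset = render_contrast_maps(r, truth, spec)
            sdir = out / r.subject_id
            for name in CONTRASTS:
                save_volume(cset.maps[name], sdir / f"con_{name}.nii.gz")
                save_volume(cset.variances[name], sdir / f"var_{name}.nii.gz")
    elif mode == "bold":
        schedule = make_event_schedule(spec)
        for r in records:
            sdir = out / r.subject_id
            for k in range(spec.n_runs):
                save_volume(render_bold_run(r, schedule, truth, spec, k), sdir / f"run-{k + 1}.nii.gz")
                with open(sdir / f"run-{k + 1}_events.tsv", "w") as fh:
                    fh.write("condition\tonset_s\tduration_s\n")
                    for ev in schedule.runs[k]:
                        fh.write(f"{ev.condition}\t{ev.onset_s:g}\t{ev.duration_s:g}\n")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out
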