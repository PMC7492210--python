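"""Per-subject connectivity matrices and cohort-level thresholding.

A streamline connects two ROIs when its two endpoints terminate in two
distinct retained ROIs (endpoint-only rule; pass-throughs do not count).
Three weightings are built per subject: number of streamlines (NOS), binary
presence, and mean fractional anisotropy (FA) — the mean over the connecting
streamlines of each streamline's mean trilinearly-interpolated FA, so every
streamline contributes equally regardless of its length or point count.

At the cohort level, connections present in fewer than a given fraction of
subjects (default 50%, pooled over patients and controls) are discarded, and
FA and NOS weights are divided by their cohort-wide maxima so all weights
land in [0, 1] while between-subject ratios are preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .core import (
    ConnectivityMatrix,
    Group,
    LabelVolume,
    ScalarVolume,
    SubjectData,
    Weighting,
    labels_at,
)

__all__ = [
    "ConsensusMask",
    "CohortStudy",
    "assign_streamline",
    "streamline_mean_fa",
    "build_matrices",
    "consensus_threshold",
    "apply_mask_and_normalize",
    "build_cohort_study",
]

log = logging.getLogger(__name__)


@dataclass
class ConsensusMask:
    """Boolean edge mask from group-consensus thresholding."""

    mask: np.ndarray
    fraction: float
    n_subjects: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not np.array_equal(self.mask, self.mask.T):
            raise ValueError("consensus mask must be symmetric")
        if np.any(np.diag(self.mask)):
            raise ValueError("consensus mask diagonal must be False")


@dataclass
class SubjectMeta:
    subject_id: str
    group: Group
    updrs_motor: float | None = None


@dataclass
class CohortStudy:
    """Per-subject matrices plus cohort-level mask and normalization."""

    subjects: list[SubjectMeta]
    matrices: dict[str, dict[Weighting, ConnectivityMatrix]]
    node_names: list[str]
    consensus: ConsensusMask | None = None
    norm_constant: dict[Weighting, float] = field(default_factory=dict)


def _world_to_continuous_voxel(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    return np.atleast_2d(points) @ inv[:3, :3].T + inv[:3, 3]


def streamline_mean_fa(streamline: np.ndarray, fa: ScalarVolume) -> float:
    """Mean FA along a streamline, trilinearly interpolated at every point.

    Points outside the FA grid sample as 0 and still count toward the mean
    (degenerate-input policy; a debug message is logged).
    """
    vox = _world_to_continuous_voxel(fa.affine, np.asarray(streamline, dtype=float))
    shape = np.asarray(fa.data.shape)
    outside = np.any((vox < -0.5) | (vox > shape - 0.5), axis=1)
    if outside.any():
        log.debug("%d streamline point(s) outside the FA grid sampled as 0", outside.sum())
    vals = map_coordinates(fa.data, vox.T, order=1, mode="constant", cval=0.0)
    return float(vals.mean())


def assign_streamline(streamline: np.ndarray, labels: LabelVolume) -> tuple[int, int] | None:
    """Unordered ROI pair a streamline connects, or None.

    Returns the labels under the first and last points when both are
    nonzero and distinct; None when either endpoint is in background or
    outside the grid, or both endpoints share one ROI (the diagonal is zero
    by construction).
    """
    pts = np.asarray(streamline, dtype=float)
    ends = labels_at(labels, pts[[0, -1]])
    a, b = int(ends[0]), int(ends[1])
    if a == 0 or b == 0 or a == b:
        return None
    return (a, b) if a < b else (b, a)


def build_matrices(
    subject: SubjectData, node_names: list[str]
) -> dict[Weighting, ConnectivityMatrix]:
    """Build the FA, NOS and binary matrices for one subject.

    ``node_names`` fixes the row/column order and must cover every retained
    label of the subject's parcellation.  NOS counts endpoint-assigned
    streamlines per ROI pair; binary is its indicator; FA averages the
    per-streamline mean FA over the connecting streamlines (0 where no
    streamline connects).  An empty tractogram yields all-zero matrices.
    """
    lv = subject.label_volume
    name_of = lv.labels
    covered = set(node_names)
    not_covered = [n for n in name_of.values() if n not in covered]
    if not_covered:
        raise ValueError(f"node_names does not cover retained labels: {not_covered}")
    col = {name: i for i, name in enumerate(node_names)}
    n = len(node_names)

    nos = np.zeros((n, n))
    fa_sum = np.zeros((n, n))
    sl = subject.tractogram.streamlines
    if not sl:
        log.info("subject %s has an empty tractogram; matrices are all-zero",
                 subject.subject_id)
    for s in sl:
        pair = assign_streamline(s, lv)
        if pair is None:
            continue
        i, j = col[name_of[pair[0]]], col[name_of[pair[1]]]
        m = streamline_mean_fa(s, subject.fa_volume)
        nos[i, j] += 1
        nos[j, i] += 1
        fa_sum[i, j] += m
        fa_sum[j, i] += m

    binary = (nos > 0).astype(float)
    with np.errstate(invalid="ignore"):
        fa = np.where(nos > 0, fa_sum / np.maximum(nos, 1), 0.0)
    return {
        Weighting.FA: ConnectivityMatrix(fa, Weighting.FA, list(node_names)),
        Weighting.NOS: ConnectivityMatrix(nos, Weighting.NOS, list(node_names)),
        Weighting.BINARY: ConnectivityMatrix(binary, Weighting.BINARY, list(node_names)),
    }


def consensus_threshold(
    binaries: list[ConnectivityMatrix], fraction: float = 0.5
) -> ConsensusMask:
    """Retain connections present in at least ``fraction`` of all subjects.

    Pooled over the whole dataset (patients and controls together).  An edge
    present in exactly the threshold fraction is retained: only connections
    in strictly fewer subjects are discarded.
    """
    if not binaries:
        raise ValueError("need at least one subject")
    names = binaries[0].node_names
    if any(m.node_names != names for m in binaries):
        raise ValueError("all matrices must share one node set")
    stack = np.stack([m.weights > 0 for m in binaries])
    mask = stack.mean(axis=0) >= fraction
    np.fill_diagonal(mask, False)
    return ConsensusMask(mask, fraction, len(binaries))


def apply_mask_and_normalize(study: CohortStudy) -> CohortStudy:
    """Zero masked-out edges everywhere, then divide FA and NOS by cohort maxima.

    A single constant per weighting rescales every subject, so relative
    differences between subjects are preserved and the post-normalization
    maximum is exactly 1.  Raises when the consensus mask removes every edge.
    """
    if study.consensus is None:
        raise ValueError("consensus mask must be computed first")
    mask = study.consensus.mask
    if not mask.any():
        raise ValueError("all connections were masked out; no analyzable network")

    masked: dict[str, dict[Weighting, np.ndarray]] = {
        sid: {w: np.where(mask, m.weights, 0.0) for w, m in per.items()}
        for sid, per in study.matrices.items()
    }
    norm: dict[Weighting, float] = {}
    for w in (Weighting.FA, Weighting.NOS):
        cohort_max = max(float(arr[w].max()) for arr in masked.values())
        norm[w] = cohort_max
        if cohort_max > 0:
            for arr in masked.values():
                arr[w] = arr[w] / cohort_max
    norm[Weighting.BINARY] = 1.0

    matrices = {
        sid: {w: ConnectivityMatrix(arr, w, study.node_names) for w, arr in per.items()}
        for sid, per in masked.items()
    }
    return CohortStudy(
        subjects=list(study.subjects),
        matrices=matrices,
        node_names=list(study.node_names),
        consensus=study.consensus,
        norm_constant=norm,
    )


def build_cohort_study(
    subjects: list[SubjectData], node_names: list[str], fraction: float = 0.5
) -> CohortStudy:
    """Full cohort pipeline: per-subject matrices, consensus, normalization."""
    matrices = {s.subject_id: build_matrices(s, node_names) for s in subjects}
    study = CohortStudy(
        subjects=[SubjectMeta(s.subject_id, s.group, s.updrs_motor) for s in subjects],
        matrices=matrices,
        node_names=list(node_names),
    )
    study.consensus = consensus_threshold(
        [matrices[s.subject_id][Weighting.BINARY] for s in subjects], fraction
    )
    return apply_mask_and_normalize(study)
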