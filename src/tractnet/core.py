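"""Shared domain types, coordinate conventions, and validation.

Conventions used throughout the package:

* Voxel indices are 0-based; world space is RAS+ millimetres.
* A world point maps to the voxel whose index is ``floor(inv(affine) @ p + 0.5)``
  in each axis, i.e. rounding to the nearest voxel centre with the half-way
  case rounding up.  See :func:`world_to_voxel`.
* Connectivity matrices are symmetric with a zero main diagonal; the node
  order is fixed per study and recorded in every output.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Group",
    "Weighting",
    "Measure",
    "LabelVolume",
    "ScalarVolume",
    "Tractogram",
    "SubjectData",
    "ConnectivityMatrix",
    "EfficiencyResult",
    "StatResult",
    "world_to_voxel",
    "voxel_to_world",
    "validate_subject",
]


class Group(str, enum.Enum):
    """Clinical group: Parkinson's disease patient or healthy control."""

    PD = "PD"
    HC = "HC"


class Weighting(str, enum.Enum):
    """Edge weighting scheme of a connectivity matrix."""

    FA = "FA"
    NOS = "NOS"
    BINARY = "binary"


class Measure(str, enum.Enum):
    """Network efficiency measure."""

    EGLOB = "Eglob"
    ELOC = "Eloc"


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


@dataclass
class LabelVolume:
    """3-D integer label grid with a voxel->world affine and a label table.

    ``data`` holds nonnegative integer labels (0 = background); ``labels``
    maps each label integer to an ROI name.  Every nonzero value present in
    ``data`` must appear as a key of ``labels``; the table may additionally
    list labels that currently own no voxels (e.g. after a degenerate split).
    """

    data: np.ndarray
    affine: np.ndarray
    labels: dict[int, str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("label data must be a non-empty 3-D array")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label data must be integer-typed")
        self.affine = _check_affine(self.affine)
        present = set(np.unique(self.data).tolist()) - {0}
        missing = present - set(self.labels)
        if missing:
            raise ValueError(f"labels present in data but not in table: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_count(self, label: int) -> int:
        return int(np.count_nonzero(self.data == label))

    def name_to_label(self) -> dict[str, int]:
        return {name: lab for lab, name in self.labels.items()}


@dataclass
class ScalarVolume:
    """3-D real-valued volume (e.g. an FA map) with a voxel->world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("scalar data must be a non-empty 3-D array")
        self.affine = _check_affine(self.affine)


@dataclass
class Tractogram:
    """Collection of streamlines; every point is in world (RAS+ mm) space.

    Each streamline is an ``(m, 3)`` float array with ``m >= 2``, finite
    coordinates and no two consecutive points identical.
    """

    streamlines: list[np.ndarray] = field(default_factory=list)
    space: str = "world-mm"

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


def streamline_issues(points: np.ndarray) -> list[str]:
    """Return invariant violations for one streamline (empty list = valid)."""
    issues: list[str] = []
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or points.shape[0] < 2:
        return [f"streamline must be (m>=2, 3) points, got shape {points.shape}"]
    if not np.all(np.isfinite(points)):
        issues.append("streamline contains non-finite coordinates")
    else:
        steps = np.diff(points, axis=0)
        if np.any(np.all(steps == 0, axis=1)):
            issues.append("streamline has identical consecutive points")
    return issues


@dataclass
class SubjectData:
    """One subject: parcellation, FA map, tractogram and clinical metadata."""

    subject_id: str
    group: Group
    label_volume: LabelVolume
    fa_volume: ScalarVolume
    tractogram: Tractogram
    updrs_motor: float | None = None

    def __post_init__(self) -> None:
        self.group = Group(self.group)


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative adjacency matrix over named ROIs.

    The main diagonal is zero: self-connections carry no information and
    intersections without a streamline are zero by construction.
    """

    weights: np.ndarray
    weighting: Weighting
    node_names: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.weighting = Weighting(self.weighting)
        n = len(self.node_names)
        if self.weights.shape != (n, n):
            raise ValueError(
                f"weights shape {self.weights.shape} does not match {n} node names"
            )
        if np.any(self.weights < 0):
            raise ValueError("connectivity weights must be nonnegative")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("main diagonal must be zero")
        if self.weighting is Weighting.BINARY and not np.isin(self.weights, (0.0, 1.0)).all():
            raise ValueError("binary matrix entries must be 0 or 1")

    @property
    def n_nodes(self) -> int:
        return len(self.node_names)


@dataclass
class EfficiencyResult:
    """Nodal and whole-brain global/local efficiency for one matrix."""

    nodal_eglob: np.ndarray
    nodal_eloc: np.ndarray
    wholebrain_eglob: float
    wholebrain_eloc: float
    weighting: Weighting


@dataclass
class StatResult:
    """Outcome of one statistical family (measure x weighting x level)."""

    measure: Measure
    weighting: Weighting
    level: str  # "wholebrain" | "nodal"
    t_stat: np.ndarray | float | None = None
    p_group: np.ndarray | float | None = None
    r: np.ndarray | float | None = None
    p_corr: np.ndarray | float | None = None
    fdr_mask_group: np.ndarray | None = None
    fdr_mask_corr: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Coordinate mapping


def voxel_to_world(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    """Map 0-based voxel indices (…, 3) to world mm coordinates."""
    ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
    out = ijk @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]
    return out


def world_to_voxel(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Map world mm points (…, 3) to nearest voxel indices.

    The rule is ``floor(inv(affine) @ p + 0.5)`` per axis: a point maps to
    the voxel whose centre is nearest, half-way coordinates rounding toward
    the higher index.  Indices may fall outside the grid; callers check.
    """
    inv = np.linalg.inv(np.asarray(affine, dtype=float))
    points = np.atleast_2d(np.asarray(points, dtype=float))
    cont = points @ inv[:3, :3].T + inv[:3, 3]
    return np.floor(cont + 0.5).astype(np.int64)


def labels_at(volume: LabelVolume, points: np.ndarray) -> np.ndarray:
    """Label under each world point; 0 for background or outside the grid."""
    idx = world_to_voxel(volume.affine, points)
    shape = np.asarray(volume.shape)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    out = np.zeros(len(idx), dtype=volume.data.dtype)
    ii = idx[inside]
    out[inside] = volume.data[ii[:, 0], ii[:, 1], ii[:, 2]]
    return out


# ---------------------------------------------------------------------------
# Validation


def validate_subject(subject: SubjectData) -> list[str]:
    """Check all type invariants for one subject; return a list of issues.

    An empty list means the subject is well formed.  Each issue names the
    offending field and the violated rule; nothing raises, so callers can
    aggregate reports across a cohort.
    """
    issues: list[str] = []

    lv, fa = subject.label_volume, subject.fa_volume
    if fa.data.shape != lv.data.shape:
        issues.append(
            f"fa_volume: shape {fa.data.shape} does not match label volume {lv.data.shape}"
        )
    if not np.allclose(fa.affine, lv.affine):
        issues.append("fa_volume: affine does not match label volume affine")
    finite = fa.data[np.isfinite(fa.data)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        issues.append(
            f"fa_volume: FA values must lie in [0, 1], found range "
            f"[{finite.min():.3g}, {finite.max():.3g}]"
        )

    if subject.group is Group.PD:
        if subject.updrs_motor is None:
            issues.append("updrs_motor: required for PD subjects, absent")
        elif subject.updrs_motor < 0:
            issues.append("updrs_motor: must be nonnegative")
    elif subject.updrs_motor is not None:
        issues.append("updrs_motor: must be absent for HC subjects (present iff PD)")

    for k, s in enumerate(subject.tractogram):
        for msg in streamline_issues(s):
            issues.append(f"tractogram[{k}]: {msg}")

    return issues
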