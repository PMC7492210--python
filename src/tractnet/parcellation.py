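"""ROI selection and anterior-commissure-plane splitting of a region.

The analysis set comprises 85 ROIs: the 34 Desikan-Killiany cortical regions
per hemisphere, the bilateral thalamus, caudate, putamen, pallidum,
hippocampus, amygdala, accumbens area and ventral diencephalon, plus the
brainstem.  The putamen is split into an anterior and a posterior part by
the vertical plane through the anterior commissure (AC), orthogonal to the
AC-PC line: the plane is defined in AC-PC-aligned space and voxels are
classified in native space by mapping each voxel centre through the forward
transform, which is equivalent to intersecting the inverse-transformed
plane with the native grid.  Splitting both putamina brings the node count
to 87.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import LabelVolume, voxel_to_world

__all__ = [
    "AcpcTransform",
    "DESIKAN_KILLIANY_CORTICAL",
    "SUBCORTICAL_BILATERAL",
    "atlas_85",
    "canonical_node_order",
    "select_rois",
    "split_region_by_ac_plane",
]

#: The 34 cortical parcels of the Desikan-Killiany atlas (per hemisphere).
DESIKAN_KILLIANY_CORTICAL = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal", "middletemporal",
    "paracentral", "parahippocampal", "parsopercularis", "parsorbitalis",
    "parstriangularis", "pericalcarine", "postcentral", "posteriorcingulate",
    "precentral", "precuneus", "rostralanteriorcingulate",
    "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
    "superiortemporal", "supramarginal", "temporalpole", "transversetemporal",
)

#: Subcortical structures retained bilaterally.
SUBCORTICAL_BILATERAL = (
    "Thalamus-Proper", "Caudate", "Putamen", "Pallidum", "Hippocampus",
    "Amygdala", "Accumbens-area", "VentralDC",
)


def atlas_85() -> list[str]:
    """Return the 85 ROI names of the analysis set (FreeSurfer naming)."""
    names = [f"ctx-{hemi}-{roi}" for hemi in ("lh", "rh") for roi in DESIKAN_KILLIANY_CORTICAL]
    names += [f"{side}-{roi}" for side in ("Left", "Right") for roi in SUBCORTICAL_BILATERAL]
    names.append("Brainstem")
    return names


def canonical_node_order(include: list[str], split_regions: tuple[str, ...] = ()) -> list[str]:
    """Sorted node list with split-region parts inserted adjacent to the original.

    Each region in ``split_regions`` is replaced, in place in the sorted
    include-list, by ``<region>_anterior`` and ``<region>_posterior``.  The
    result is the fixed node order recorded in every matrix so that matrices
    are comparable across subjects.
    """
    order: list[str] = []
    for name in sorted(include):
        if name in split_regions:
            order += [f"{name}_anterior", f"{name}_posterior"]
        else:
            order.append(name)
    return order


@dataclass
class AcpcTransform:
    """Affine from native world coordinates to AC-PC-aligned coordinates.

    ``ac_point`` is the anterior commissure in AC-PC space; the splitting
    plane passes through it orthogonal to the AC-PC (y) axis.  +y in AC-PC
    space is anterior (RAS+ convention).
    """

    matrix: np.ndarray
    ac_point: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.ac_point = np.asarray(self.ac_point, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("AC-PC transform must be a 4x4 affine")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("AC-PC transform must be invertible")
        if self.ac_point.shape != (3,):
            raise ValueError("AC point must be a 3-vector")

    def to_acpc(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return points @ self.matrix[:3, :3].T + self.matrix[:3, 3]


def select_rois(labels: LabelVolume, include: list[str]) -> LabelVolume:
    """Restrict a parcellation to the named ROIs.

    Voxels of non-included labels become background and the label table is
    restricted.  Raises if an included ROI is missing from the table or owns
    no voxels: downstream stages need every node to be nonempty.
    """
    by_name = labels.name_to_label()
    missing = [n for n in include if n not in by_name]
    if missing:
        raise ValueError(f"ROIs not present in label table: {missing}")
    keep = {by_name[n] for n in include}
    empty = [n for n in include if labels.voxel_count(by_name[n]) == 0]
    if empty:
        raise ValueError(f"included ROIs have no voxels: {empty}")
    data = np.where(np.isin(labels.data, sorted(keep)), labels.data, 0)
    table = {lab: name for lab, name in labels.labels.items() if lab in keep}
    return LabelVolume(data, labels.affine.copy(), table)


def split_region_by_ac_plane(
    labels: LabelVolume,
    xfm: AcpcTransform,
    region: str,
    plane_thickness_mm: float = 2.0,
) -> LabelVolume:
    """Split one region into anterior/posterior parts at the AC plane.

    Every voxel centre of ``region`` is mapped to AC-PC space; voxels whose
    y-coordinate exceeds the AC point's y become ``<region>_anterior``, the
    rest (including exact ties) ``<region>_posterior``.  Classification uses
    the signed distance of the voxel centre to the plane's central surface;
    ``plane_thickness_mm`` rasterizes the plane for display only and never
    affects labelling.  The original label is removed and total voxel count
    is conserved.
    """
    by_name = labels.name_to_label()
    if region not in by_name:
        raise ValueError(f"region {region!r} not in label table")
    lab = by_name[region]
    idx = np.argwhere(labels.data == lab)
    if len(idx) == 0:
        raise ValueError(f"region {region!r} has no voxels")

    centers = voxel_to_world(labels.affine, idx)
    y_acpc = xfm.to_acpc(centers)[:, 1]
    anterior = y_acpc > xfm.ac_point[1]

    new_a = max(labels.labels) + 1
    new_p = new_a + 1
    data = labels.data.copy()
    ia, ip = idx[anterior], idx[~anterior]
    data[ia[:, 0], ia[:, 1], ia[:, 2]] = new_a
    data[ip[:, 0], ip[:, 1], ip[:, 2]] = new_p

    if len(ia) == 0 or len(ip) == 0:
        side = "anterior" if len(ia) == 0 else "posterior"
        warnings.warn(
            f"region {region!r} lies entirely on one side of the AC plane; "
            f"the {side} part is empty",
            stacklevel=2,
        )

    table = {l: n for l, n in labels.labels.items() if l != lab}
    table[new_a] = f"{region}_anterior"
    table[new_p] = f"{region}_posterior"
    return LabelVolume(data, labels.affine.copy(), table)
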