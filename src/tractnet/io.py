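"""Readers and writers for the package's external formats.

Label and scalar volumes travel as NIfTI-1 (.nii/.nii.gz); the label table
as a two-column TSV (label integer, ROI name).  Tractograms travel as TRK or
TCK; internally streamlines are always world (RAS+ mm) polylines.
Connectivity matrices travel as square CSVs with node names on both axes and
a JSON sidecar carrying the weighting, subject id and normalization constant.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import ConnectivityMatrix, LabelVolume, ScalarVolume, Tractogram, Weighting

__all__ = [
    "save_label_volume",
    "load_label_volume",
    "save_scalar_volume",
    "load_scalar_volume",
    "save_label_table",
    "load_label_table",
    "save_tractogram",
    "load_tractogram",
    "save_matrix",
    "load_matrix",
]


def save_scalar_volume(volume: ScalarVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    nib.save(img, str(path))


def load_scalar_volume(path: str | Path) -> ScalarVolume:
    img = nib.load(str(path))
    return ScalarVolume(np.asarray(img.get_fdata(), dtype=float), img.affine)


def save_label_volume(volume: LabelVolume, path: str | Path, table_path: str | Path | None = None) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.int32), volume.affine)
    nib.save(img, str(path))
    if table_path is not None:
        save_label_table(volume.labels, table_path)


def load_label_volume(path: str | Path, table_path: str | Path) -> LabelVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(np.int32)
    return LabelVolume(data, img.affine, load_label_table(table_path))


def save_label_table(labels: dict[int, str], path: str | Path) -> None:
    df = pd.DataFrame(sorted(labels.items()), columns=["label", "name"])
    df.to_csv(path, sep="\t", index=False)


def load_label_table(path: str | Path) -> dict[int, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["label"].astype(int), df["name"].astype(str)))


def save_tractogram(tractogram: Tractogram, path: str | Path, reference: LabelVolume | ScalarVolume) -> None:
    """Write streamlines as TRK or TCK (by extension), in world mm.

    TRK headers need a reference grid; ``reference`` supplies the affine and
    shape.  TCK ignores the reference.
    """
    path = Path(path)
    sl = [np.asarray(s, dtype=np.float32) for s in tractogram.streamlines]
    tg = nib.streamlines.Tractogram(sl, affine_to_rasmm=np.eye(4))
    if path.suffix == ".trk":
        header = {
            nib.streamlines.trk.Field.VOXEL_TO_RASMM: reference.affine.astype(np.float32),
            nib.streamlines.trk.Field.VOXEL_SIZES: np.asarray(
                nib.affines.voxel_sizes(reference.affine), dtype=np.float32
            ),
            nib.streamlines.trk.Field.DIMENSIONS: np.asarray(reference.data.shape, dtype=np.int16),
        }
        nib.streamlines.save(tg, str(path), header=header)
    elif path.suffix == ".tck":
        nib.streamlines.save(tg, str(path))
    else:
        raise ValueError(f"unsupported tractogram extension: {path.suffix}")


def load_tractogram(path: str | Path) -> Tractogram:
    """Read a TRK or TCK file; streamlines are returned in world mm."""
    tfile = nib.streamlines.load(str(path))
    sl = [np.asarray(s, dtype=float) for s in tfile.tractogram.streamlines]
    return Tractogram(sl)


def save_matrix(matrix: ConnectivityMatrix, path: str | Path, subject_id: str | None = None,
                norm_constant: float | None = None) -> None:
    """Write a square CSV with node names plus a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(matrix.weights, index=matrix.node_names, columns=matrix.node_names)
    df.to_csv(path)
    meta = {
        "weighting": matrix.weighting.value,
        "subject_id": subject_id,
        "norm_constant": norm_constant,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_matrix(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    meta = json.loads(path.with_suffix(".json").read_text())
    return ConnectivityMatrix(df.to_numpy(dtype=float), Weighting(meta["weighting"]),
                              list(df.columns))
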