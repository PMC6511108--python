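"""File formats: tensor and parcellation NIfTI, TCK tractograms, TSV
connectivity matrices, CSV cohort tables, YAML specs.

Tensor volumes are stored as 4-D NIfTI with the 6 unique tensor components
in lower-triangular order (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz) on the last axis.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from nibabel.streamlines import Tractogram as NibTractogram
from nibabel.streamlines.tck import TckFile

from .connectome import Connectome, Parcellation
from .tractography import Streamline, Tractogram, TrackingConfig

PathLike = Union[str, Path]


def save_tensor_nifti(volume, path: PathLike) -> None:
    img = nib.Nifti1Image(volume.to_components().astype(np.float64), volume.affine)
    nib.save(img, str(path))


def load_tensor_nifti(path: PathLike):
    from .tractography import TensorVolume

    img = nib.load(str(path))
    comps = np.asarray(img.dataobj, dtype=float)
    if comps.ndim != 4 or comps.shape[3] != 6:
        raise ValueError("tensor NIfTI must be 4-D with 6 components")
    affine = np.asarray(img.affine)
    voxel_size = np.linalg.norm(affine[:3, :3], axis=0)
    return TensorVolume.from_components(comps, voxel_size, affine)


def save_parcellation_nifti(parc: Parcellation, path: PathLike) -> None:
    img = nib.Nifti1Image(parc.labels.astype(np.int32), parc.affine)
    img.header.set_intent("label")
    nib.save(img, str(path))
    names_path = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii(.gz)
    with open(f"{names_path}_labels.tsv", "w") as fh:
        fh.write("label\tname\n")
        for lab in sorted(parc.node_names):
            fh.write(f"{lab}\t{parc.node_names[lab]}\n")


def load_parcellation_nifti(path: PathLike) -> Parcellation:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    names_path = Path(str(path)).with_suffix("").with_suffix("")
    tsv = Path(f"{names_path}_labels.tsv")
    if tsv.exists():
        df = pd.read_csv(tsv, sep="\t")
        names = dict(zip(df["label"].astype(int), df["name"].astype(str)))
    else:
        names = {int(lab): f"region{int(lab):02d}"
                 for lab in np.unique(labels) if lab != 0}
    return Parcellation(labels, names, np.asarray(img.affine))


def save_tck(tractogram: Tractogram, path: PathLike) -> None:
    nt = NibTractogram(
        [s.points for s in tractogram.streamlines], affine_to_rasmm=np.eye(4)
    )
    TckFile(nt).save(str(path))


def load_tck(path: PathLike, step: float) -> Tractogram:
    """Load a TCK file; ``step`` must be the generating step length in mm."""
    tck = TckFile.load(str(path))
    streamlines = [Streamline(np.asarray(pts), step)
                   for pts in tck.tractogram.streamlines]
    return Tractogram(streamlines, TrackingConfig(step_mm=step))


def save_connectome_tsv(conn: Connectome, path: PathLike) -> None:
    df = pd.DataFrame(conn.weights, index=conn.node_names, columns=conn.node_names)
    df.to_csv(str(path), sep="\t", index_label="node")


def load_connectome_tsv(path: PathLike) -> Connectome:
    df = pd.read_csv(str(path), sep="\t", index_col=0)
    return Connectome(df.to_numpy(dtype=float), list(df.columns))


def save_cohort_csv(table: pd.DataFrame, path: PathLike) -> None:
    table.to_csv(str(path), index=False)


def load_cohort_csv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(str(path))


def save_yaml(obj: dict, path: PathLike) -> None:
    with open(str(path), "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def load_yaml(path: PathLike) -> dict:
    with open(str(path)) as fh:
        return yaml.safe_load(fh)
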