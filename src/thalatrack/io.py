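"""Reading and writing the standard on-disk formats.

Volumes are NIfTI-1 (via nibabel) with the shared affine; label legends are
JSON sidecars, phantom truth records YAML, gradient tables FSL-style
bval/bvec text files (one row per axis), and kept streamlines a JSON-lines
point format.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .diffusion import GradientTable, OrientationField
from .grid import VolumeGrid
from .phantom import LabelVolume
from .tracking import Streamline, Termination

__all__ = [
    "save_volume",
    "load_volume",
    "save_labels",
    "load_labels",
    "save_field",
    "load_field",
    "save_truth",
    "load_truth",
    "save_gradients_fsl",
    "load_gradients_fsl",
    "save_streamlines_jsonl",
    "load_streamlines_jsonl",
]


def save_volume(data: np.ndarray, grid: VolumeGrid, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), grid.affine)
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, VolumeGrid]:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    grid = VolumeGrid(shape=tuple(data.shape[:3]), affine=np.asarray(img.affine))
    return data, grid


def save_labels(vol: LabelVolume, path: str | Path) -> Path:
    """Label volume as int NIfTI plus a JSON legend sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(vol.labels.astype(np.int16), vol.grid.affine)
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
    meta = {"legend": {str(k): v for k, v in vol.legend.items()},
            "acpc_z_mm": vol.acpc_z_mm}
    Path(str(sidecar) + ".json").write_text(json.dumps(meta, indent=2))
    return path


def load_labels(path: str | Path) -> LabelVolume:
    path = Path(path)
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int16)
    grid = VolumeGrid(shape=tuple(labels.shape), affine=np.asarray(img.affine))
    sidecar = Path(str(path.with_suffix("").with_suffix("")) + ".json")
    meta = json.loads(sidecar.read_text())
    legend = {int(k): v for k, v in meta["legend"].items()}
    return LabelVolume(grid=grid, labels=labels, legend=legend,
                       acpc_z_mm=float(meta["acpc_z_mm"]))


def save_field(field: OrientationField, stem: str | Path) -> dict[str, Path]:
    """Orientation field as a set of NIfTI volumes sharing one stem."""
    stem = Path(stem)
    paths = {}
    shape = field.grid.shape
    dirs = field.directions.reshape(shape + (6,))
    for name, data in (
        ("directions", dirs),
        ("fractions", field.fractions),
        ("kappa", np.nan_to_num(field.kappa, nan=0.0)),
        ("mask", field.mask.astype(np.uint8)),
    ):
        p = Path(f"{stem}_{name}.nii.gz")
        nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                                 field.grid.affine), str(p))
        paths[name] = p
    return paths


def load_field(stem: str | Path) -> OrientationField:
    stem = Path(stem)

    def read(name):
        img = nib.load(f"{stem}_{name}.nii.gz")
        return np.asarray(img.get_fdata()), np.asarray(img.affine)

    dirs, affine = read("directions")
    fractions, _ = read("fractions")
    kappa, _ = read("kappa")
    mask, _ = read("mask")
    shape = dirs.shape[:3]
    grid = VolumeGrid(shape=tuple(shape), affine=affine)
    kappa = np.where(mask > 0, kappa, np.nan)
    return OrientationField(
        grid=grid,
        directions=dirs.reshape(shape + (2, 3)),
        fractions=fractions,
        kappa=kappa,
        mask=mask > 0,
    )


def save_truth(truth: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(truth, sort_keys=True))
    return path


def load_truth(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def save_gradients_fsl(gradients: GradientTable, bval_path, bvec_path) -> None:
    """FSL convention: one row of b-values; bvecs as three rows (x, y, z)."""
    np.savetxt(bval_path, gradients.bvals[None, :], fmt="%.1f")
    np.savetxt(bvec_path, gradients.bvecs.T, fmt="%.6f")


def load_gradients_fsl(bval_path, bvec_path) -> GradientTable:
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    return GradientTable(bvals=bvals, bvecs=bvecs)


def save_streamlines_jsonl(streamlines: list[Streamline], path: str | Path) -> Path:
    """One JSON object per line: {"points": [[x,y,z], ...], "termination": t}."""
    path = Path(path)
    with path.open("w") as fh:
        for s in streamlines:
            fh.write(json.dumps({
                "points": np.asarray(s.points).round(4).tolist(),
                "termination": s.termination.value,
                "target": s.target,
            }) + "\n")
    return path


def load_streamlines_jsonl(path: str | Path) -> list[Streamline]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        obj = json.loads(line)
        out.append(Streamline(
            points=np.asarray(obj["points"], dtype=float),
            termination=Termination(obj["termination"]),
            target=obj.get("target"),
        ))
    return out
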