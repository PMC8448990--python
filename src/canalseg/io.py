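"""NIfTI volume I/O, case discovery and run manifests.

On disk, volumes are NIfTI (.nii.gz) with the voxel spacing in the header;
arrays are stored in the conventional (X, Y, Z) axis order and transposed
to the package's internal depth-first (D, H, W) order on read.  Cases pair
an intensity file with an optional label file by the filename convention
``<case>_img.nii.gz`` / ``<case>_lbl.nii.gz``.

Every CLI product is accompanied by a JSON run manifest (resolved configs,
seeds, package version, input checksums, output paths) sufficient to re-run
the command deterministically.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantoms import LabeledVolume

__all__ = ["read_volume", "read_labels", "write_volume", "write_labels",
           "CaseRecord", "discover_cases", "load_case", "save_dataset",
           "write_manifest"]


def read_volume(path) -> tuple[np.ndarray, tuple]:
    """Read a NIfTI volume; returns ``(grid, spacing_mm)`` with the grid in
    (D, H, W) order and spacing from the header."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    grid = np.ascontiguousarray(data.transpose(2, 1, 0)).astype(np.float32)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return grid, spacing


def read_labels(path) -> tuple[np.ndarray, tuple]:
    """Read and validate a binary label volume."""
    grid, spacing = read_volume(path)
    vals = np.unique(grid)
    bad = [float(v) for v in vals if v not in (0.0, 1.0)]
    if bad:
        raise ValueError(f"label file {path} contains non-binary values: {bad}")
    return grid.astype(np.uint8), spacing


def write_volume(path, grid: np.ndarray, spacing_mm=(1.0, 1.0, 1.0)) -> None:
    """Write a (D, H, W) grid as NIfTI with the spacing in the header."""
    sd, sh, sw = (float(s) for s in spacing_mm)
    affine = np.diag([sw, sh, sd, 1.0])
    data = np.asarray(grid).transpose(2, 1, 0)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((sw, sh, sd))
    nib.save(img, str(path))


def write_labels(path, labels: np.ndarray, spacing_mm=(1.0, 1.0, 1.0)) -> None:
    write_volume(path, np.asarray(labels).astype(np.uint8), spacing_mm)


@dataclass
class CaseRecord:
    case_id: str
    image_path: Path
    label_path: Path | None = None


def discover_cases(directory, require_labels: bool = True) -> list[CaseRecord]:
    """Find ``<case>_img.nii.gz`` (+ optional ``<case>_lbl.nii.gz``) pairs."""
    directory = Path(directory)
    records = []
    for img_path in sorted(directory.glob("*_img.nii.gz")):
        cid = img_path.name[:-len("_img.nii.gz")]
        lbl = directory / f"{cid}_lbl.nii.gz"
        if not lbl.exists():
            if require_labels:
                raise FileNotFoundError(f"no label file for case {cid}: {lbl}")
            lbl = None
        records.append(CaseRecord(cid, img_path, lbl))
    if not records:
        raise FileNotFoundError(f"no *_img.nii.gz cases found in {directory}")
    return records


def load_case(record: CaseRecord) -> LabeledVolume:
    grid, spacing = read_volume(record.image_path)
    if record.label_path is None:
        labels = np.zeros(grid.shape, dtype=np.uint8)
    else:
        labels, lbl_spacing = read_labels(record.label_path)
        if labels.shape != grid.shape:
            raise ValueError(
                f"case {record.case_id}: label shape {labels.shape} does not "
                f"match image shape {grid.shape}")
        if not np.allclose(lbl_spacing, spacing):
            raise ValueError(
                f"case {record.case_id}: label spacing {lbl_spacing} does not "
                f"match image spacing {spacing}")
    return LabeledVolume(intensities=grid, labels=labels, spacing_mm=spacing)


def save_dataset(volumes: list, directory, prefix: str) -> list[CaseRecord]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for i, vol in enumerate(volumes):
        cid = f"{prefix}{i:03d}"
        img = directory / f"{cid}_img.nii.gz"
        lbl = directory / f"{cid}_lbl.nii.gz"
        write_volume(img, vol.intensities, vol.spacing_mm)
        write_labels(lbl, vol.labels, vol.spacing_mm)
        records.append(CaseRecord(cid, img, lbl))
    return records


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, command: str, configs: dict, seed: int | None,
                   inputs: list, outputs: list) -> Path:
    from . import __version__
    manifest = {
        "command": command,
        "argv": sys.argv,
        "version": __version__,
        "seed": seed,
        "configs": configs,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).is_file()},
        "outputs": [str(p) for p in outputs],
    }
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
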