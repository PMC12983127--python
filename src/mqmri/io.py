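"""NIfTI-1 and sidecar I/O.

Every volume is written as NIfTI-1 with an affine built from the voxel size,
accompanied by a JSON sidecar recording units, stage parameters and source
hashes.  Complex volumes are stored as magnitude/phase pairs for maximal
reader compatibility; 4-D saturation stacks carry their offset list (ppm, in
acquisition order) in the sidecar.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .relaxometry import MultiEchoGRE, QuantMap

__all__ = [
    "save_volume",
    "load_volume",
    "save_quantmap",
    "load_quantmap",
    "save_gre",
    "load_gre",
    "file_hash",
]


def _affine(voxel_size) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0])
    return aff


def file_hash(path: Path | str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def save_volume(
    path: Path | str,
    data: np.ndarray,
    voxel_size=(1.0, 1.0, 1.0),
    sidecar: dict | None = None,
) -> Path:
    """Write a real-valued volume plus its JSON sidecar; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(voxel_size))
    nib.save(img, str(path))
    if sidecar is not None:
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))
    return path


def load_volume(path: Path | str) -> tuple[np.ndarray, dict]:
    path = Path(path)
    data = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    sc = path.with_suffix(".json")
    sidecar = json.loads(sc.read_text()) if sc.exists() else {}
    return data, sidecar


def save_quantmap(path: Path | str, qmap: QuantMap, voxel_size=(1.0, 1.0, 1.0)) -> Path:
    sidecar = {"units": qmap.units, "provenance": qmap.provenance}
    p = save_volume(path, qmap.values, voxel_size, sidecar)
    if qmap.valid_mask is not None:
        mask_path = Path(str(path).replace(".nii", "_mask.nii"))
        save_volume(mask_path, qmap.valid_mask.astype(np.float64), voxel_size)
    return p


def load_quantmap(path: Path | str) -> QuantMap:
    data, sidecar = load_volume(path)
    mask_path = Path(str(path).replace(".nii", "_mask.nii"))
    mask = None
    if mask_path.exists():
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0.5
    return QuantMap(data, sidecar.get("units", "a.u."), sidecar.get("provenance", {}), mask)


def save_gre(
    stem: Path | str, gre: MultiEchoGRE, voxel_size=(1.0, 1.0, 1.0)
) -> tuple[Path, Path]:
    """Write complex multiecho data as a magnitude/phase NIfTI pair.

    ``stem`` is extended to ``<stem>_mag.nii`` / ``<stem>_phase.nii``; echo
    times, flip angle and TR go to the magnitude sidecar.
    """
    stem = Path(stem)
    sidecar = {
        "echo_times_ms": list(map(float, gre.echo_times)),
        "flip_angle_deg": float(gre.flip_angle),
        "tr_ms": float(gre.tr),
    }
    mag = save_volume(
        stem.parent / (stem.name + "_mag.nii"), np.abs(gre.data), voxel_size, sidecar
    )
    phase = save_volume(
        stem.parent / (stem.name + "_phase.nii"), np.angle(gre.data), voxel_size
    )
    return mag, phase


def load_gre(stem: Path | str) -> MultiEchoGRE:
    stem = Path(stem)
    mag, sidecar = load_volume(stem.parent / (stem.name + "_mag.nii"))
    phase, _ = load_volume(stem.parent / (stem.name + "_phase.nii"))
    data = mag * np.exp(1j * phase)
    return MultiEchoGRE(
        data,
        np.asarray(sidecar["echo_times_ms"], float),
        float(sidecar["flip_angle_deg"]),
        float(sidecar["tr_ms"]),
    )
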