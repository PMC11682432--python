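"""On-disk formats: NIfTI-1 volumes, JSON b-value sidecars, CSV tables.

Synthetic studies are written one directory per patient:

    <out>/<patient_id>/dwi_te<TE>.nii.gz     4-D volume per echo time
    <out>/<patient_id>/mask_<name>.nii.gz    binary masks
    <out>/<patient_id>/sidecar.json          b-values, sample counts, TEs
    <out>/manifest.csv                       patient_id, grade_group, label, seed

Volumes are born co-registered on a shared grid, so the affine is a plain
scaling by the voxel size.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .protocols import AcquisitionProtocol
from .synthetic import SyntheticPatient
from .volumes import DWIStudy

__all__ = ["save_patient", "load_study", "save_cohort", "save_map"]


def _affine(protocol: AcquisitionProtocol) -> np.ndarray:
    return np.diag(list(protocol.voxel_size) + [1.0])


def save_map(path: str | Path, data: np.ndarray, protocol: AcquisitionProtocol) -> None:
    """Write any per-voxel map (3-D or 4-D) as NIfTI-1."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(protocol))
    nib.save(img, str(path))


def save_patient(out_dir: str | Path, patient: SyntheticPatient) -> Path:
    """Write one patient's volumes, masks and sidecar; returns the directory."""
    pdir = Path(out_dir) / patient.patient_id
    pdir.mkdir(parents=True, exist_ok=True)
    study = patient.study
    proto = study.protocol
    for te, vol in study.volumes.items():
        save_map(pdir / f"dwi_te{te:g}.nii.gz", vol, proto)
    for name, mask in study.masks.items():
        img = nib.Nifti1Image(mask.astype(np.uint8), _affine(proto))
        nib.save(img, str(pdir / f"mask_{name}.nii.gz"))
    sidecar = {
        "b_values": [[float(b), int(c)] for b, c in proto.b_values],
        "te_values": [float(t) for t in proto.te_pair],
        "voxel_size": [float(v) for v in proto.voxel_size],
        "protocol": proto.name,
        "grade_group": patient.grade_group,
        "label": int(patient.label),
        "seed": patient.seed,
    }
    (pdir / "sidecar.json").write_text(json.dumps(sidecar, indent=2))
    return pdir


def save_cohort(out_dir: str | Path, patients: list[SyntheticPatient]) -> Path:
    """Write every patient plus a cohort manifest CSV."""
    out = Path(out_dir)
    for p in patients:
        save_patient(out, p)
    manifest = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "grade_group": [p.grade_group for p in patients],
            "label": [int(p.label) for p in patients],
            "seed": [p.seed for p in patients],
        }
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    return out


def load_study(patient_dir: str | Path) -> DWIStudy:
    """Read a patient directory written by :func:`save_patient`."""
    pdir = Path(patient_dir)
    sidecar = json.loads((pdir / "sidecar.json").read_text())
    dwi_files = sorted(pdir.glob("dwi_te*.nii.gz"))
    if not dwi_files:
        raise FileNotFoundError(f"no DWI volumes under {pdir}")
    volumes = {}
    grid = None
    for f in dwi_files:
        te = float(f.name.removeprefix("dwi_te").removesuffix(".nii.gz"))
        vol = np.asarray(nib.load(str(f)).dataobj, dtype=float)
        volumes[te] = vol
        grid = vol.shape[:3]
    protocol = AcquisitionProtocol(
        name=sidecar.get("protocol", "custom"),
        b_values=tuple((float(b), int(c)) for b, c in sidecar["b_values"]),
        te_pair=tuple(sorted(volumes)),
        grid_shape=grid,
        voxel_size=tuple(sidecar.get("voxel_size", (1.7, 1.7, 3.0))),
    )
    masks = {}
    for f in sorted(pdir.glob("mask_*.nii.gz")):
        name = f.name.removeprefix("mask_").removesuffix(".nii.gz")
        masks[name] = np.asarray(nib.load(str(f)).dataobj) > 0
    return DWIStudy(
        protocol=protocol, volumes=volumes, masks=masks, patient_id=pdir.name
    )
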