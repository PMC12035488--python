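"""NIfTI and manifest I/O for phantom subjects and paired datasets."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import FlairSlice, Grade, PhantomSlice, TissueSegmentation, TumorMask
from .synthesis import MapType, TrainingExample

_PLANES = ("gm", "wm", "csf", "tumor", "flair")


def _affine(voxel_mm: tuple[float, float, float]) -> np.ndarray:
    return np.diag([voxel_mm[0], voxel_mm[1], voxel_mm[2], 1.0])


def write_nifti(path: str | Path, volume: np.ndarray,
                voxel_mm: tuple[float, float, float] = (1.71875, 1.71875, 10.0)) -> Path:
    """Write a (H, W) or (H, W, S) array as NIfTI."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), _affine(voxel_mm))
    nib.save(img, path)
    return path


def read_nifti(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(Path(path)).get_fdata(), dtype=np.float64)


def save_phantom_subject(outdir: str | Path, slices: list[PhantomSlice]) -> dict[str, Path]:
    """Write one subject's planes as per-plane 3-D NIfTI volumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seg0, tumor0, _ = slices[0]
    stacks = {
        "gm": np.stack([s[0].gm for s in slices], axis=-1),
        "wm": np.stack([s[0].wm for s in slices], axis=-1),
        "csf": np.stack([s[0].csf for s in slices], axis=-1),
        "tumor": np.stack([s[1].mask for s in slices], axis=-1),
        "flair": np.stack([s[2].intensity for s in slices], axis=-1),
    }
    paths = {}
    for name, vol in stacks.items():
        paths[name] = write_nifti(outdir / f"{seg0.subject_id}_{name}.nii.gz", vol)
    (outdir / f"{seg0.subject_id}_grade.txt").write_text(tumor0.grade.value + "\n")
    return paths


def load_phantom_subject(outdir: str | Path, subject_id: str) -> list[PhantomSlice]:
    """Read a subject saved with :func:`save_phantom_subject`."""
    outdir = Path(outdir)
    vols = {name: read_nifti(outdir / f"{subject_id}_{name}.nii.gz") for name in _PLANES}
    grade = Grade((outdir / f"{subject_id}_grade.txt").read_text().strip())
    n_slices = vols["gm"].shape[-1]
    out = []
    for s in range(n_slices):
        seg = TissueSegmentation(gm=vols["gm"][..., s], wm=vols["wm"][..., s],
                                 csf=vols["csf"][..., s], subject_id=subject_id,
                                 slice_index=s)
        tum = TumorMask(mask=(vols["tumor"][..., s] > 0.5).astype(np.uint8), grade=grade)
        fl = FlairSlice(intensity=vols["flair"][..., s], subject_id=subject_id,
                        slice_index=s)
        out.append((seg, tum, fl))
    return out


def load_segmentation_labelmap(path: str | Path, subject_id: str,
                               label_map: dict[int, str] | None = None
                               ) -> list[TissueSegmentation]:
    """Read a hard labelmap NIfTI; ``label_map`` maps label value -> tissue
    ('gm', 'wm', 'csf').  Default follows the common 1=CSF, 2=GM, 3=WM."""
    label_map = label_map or {1: "csf", 2: "gm", 3: "wm"}
    vol = read_nifti(path)
    if vol.ndim == 2:
        vol = vol[..., None]
    out = []
    for s in range(vol.shape[-1]):
        planes = {t: np.zeros(vol.shape[:2]) for t in ("gm", "wm", "csf")}
        for label, tissue in label_map.items():
            planes[tissue][vol[..., s] == label] = 1.0
        out.append(TissueSegmentation(subject_id=subject_id, slice_index=s, **planes))
    return out


def export_dataset(examples: list[TrainingExample], outdir: str | Path) -> Path:
    """Write paired LR/HR NIfTI files plus a CSV manifest; returns its path."""
    outdir = Path(outdir)
    (outdir / "maps").mkdir(parents=True, exist_ok=True)
    rows = []
    for ex in examples:
        stem = f"{ex.subject_id}_s{ex.slice_index:03d}_{ex.map_type.name}"
        lr_path = outdir / "maps" / f"{stem}_lr.nii.gz"
        hr_path = outdir / "maps" / f"{stem}_hr.nii.gz"
        write_nifti(lr_path, np.moveaxis(ex.lr_input, 0, -1), (6.875, 6.875, 10.0))
        write_nifti(hr_path, np.moveaxis(ex.hr_target, 0, -1))
        rows.append({"subject_id": ex.subject_id, "slice_index": ex.slice_index,
                     "map_type": ex.map_type.value, "grade": ex.grade.value,
                     "lr_path": lr_path.name, "hr_path": hr_path.name})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(manifest_path: str | Path) -> list[TrainingExample]:
    """Read a dataset written by :func:`export_dataset`."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path)
    required = {"subject_id", "slice_index", "map_type", "grade", "lr_path", "hr_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    maps_dir = manifest_path.parent / "maps"
    out = []
    for i, row in df.iterrows():
        try:
            lr = np.moveaxis(read_nifti(maps_dir / row["lr_path"]), -1, 0)
            hr = np.moveaxis(read_nifti(maps_dir / row["hr_path"]), -1, 0)
            out.append(TrainingExample(
                lr_input=lr.astype(np.float32), hr_target=hr.astype(np.float32),
                subject_id=str(row["subject_id"]), slice_index=int(row["slice_index"]),
                map_type=MapType(row["map_type"]), grade=Grade(row["grade"])))
        except (ValueError, KeyError, FileNotFoundError) as exc:
            raise ValueError(f"manifest row {i} is invalid: {exc}") from exc
    return out
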