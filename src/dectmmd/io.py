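"""Reading scan slices and writing fraction maps.

Supported inputs: single DICOM slices (HU, rescale applied), NIfTI
volumes/slices, NumPy ``.npy`` arrays and plain delimited numeric grids.
Fraction maps are written per material as NIfTI, 16-bit PNG (fraction x
65535) or CSV, together with the triangle-id map and out-of-hull mask.
"""

from __future__ import annotations

import pathlib

import numpy as np

__all__ = ["load_image", "save_fraction_maps"]


def load_image(path) -> np.ndarray:
    """Load a 2-D image from DICOM (.dcm), NIfTI (.nii/.nii.gz), .npy, or a
    delimited text grid (.csv/.txt/.tsv)."""
    p = pathlib.Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    suffixes = "".join(p.suffixes).lower()
    if suffixes.endswith(".dcm"):
        import pydicom

        ds = pydicom.dcmread(p)
        img = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        return img * slope + intercept
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = np.asanyarray(nib.load(str(p)).dataobj).astype(float)
        return np.squeeze(img)
    if suffixes.endswith(".npy"):
        return np.load(p).astype(float)
    if suffixes.endswith(".csv"):
        return np.loadtxt(p, delimiter=",", dtype=float)
    return np.loadtxt(p, dtype=float)


def save_fraction_maps(vfm, out_dir, fmt: str = "csv") -> list[pathlib.Path]:
    """Write one image per library material plus the triangle-id map and
    out-of-hull mask.  ``fmt``: 'csv', 'png' (16-bit, fraction x 65535) or
    'nifti'."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _write(name: str, arr: np.ndarray, integral: bool = False):
        if fmt == "csv":
            path = out / f"{name}.csv"
            np.savetxt(path, arr, delimiter=",",
                       fmt="%d" if integral else "%.6f")
        elif fmt == "png":
            from PIL import Image

            path = out / f"{name}.png"
            if integral:
                data = arr.astype(np.uint16)
            else:
                data = np.round(np.clip(arr, 0, 1) * 65535).astype(np.uint16)
            Image.fromarray(data).save(path)
        elif fmt == "nifti":
            import nibabel as nib

            path = out / f"{name}.nii.gz"
            nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), np.eye(4)),
                     str(path))
        else:
            raise ValueError(f"unknown output format {fmt!r}")
        written.append(path)

    for name in vfm.materials:
        _write(f"fraction_{name}", vfm.fraction_image(name))
    _write("triangle_id", vfm.triangle_ids, integral=True)
    _write("outside_hull", vfm.outside_hull.astype(np.uint16), integral=True)
    return written
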