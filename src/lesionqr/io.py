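"""File export/import for image batches, masks and metrics.

Images travel as 8-bit PNG directories (with a CSV manifest) or as NIfTI
stacks for volumetric layouts; metrics as CSV.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd


def save_png_dir(images: np.ndarray, outdir, prefix: str = "img") -> pd.DataFrame:
    """Write a (n, C, H, W) float batch in [0,1] as 8-bit PNGs plus manifest.

    Single-channel images become grayscale PNGs; 3-channel become RGB.
    Returns the manifest (image_id, filename) that is also written to
    ``manifest.csv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for i, img in enumerate(images):
        arr = np.clip(img, 0.0, 1.0)
        arr = (arr * 255).round().astype(np.uint8)
        if arr.shape[0] == 1:
            arr = arr[0]
        else:
            arr = np.moveaxis(arr, 0, -1)
        name = f"{prefix}_{i:04d}.png"
        iio.imwrite(outdir / name, arr)
        records.append({"image_id": i, "filename": name})
    manifest = pd.DataFrame(records)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def load_png_dir(indir) -> np.ndarray:
    """Read back a PNG directory (via its manifest) to a (n,C,H,W) float batch."""
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    out = []
    for name in manifest["filename"]:
        arr = iio.imread(indir / name).astype(float) / 255.0
        if arr.ndim == 2:
            arr = arr[None]
        else:
            arr = np.moveaxis(arr, -1, 0)
        out.append(arr)
    return np.stack(out)


def save_nifti(images: np.ndarray, path) -> None:
    """Write a (n, C, H, W) batch as a NIfTI volume (H, W, n*C)."""
    n, c, h, w = images.shape
    vol = np.moveaxis(images.reshape(n * c, h, w), 0, -1)
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4)), str(path))


def load_nifti(path, channels: int = 1) -> np.ndarray:
    vol = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
    h, w, nc = vol.shape
    return np.moveaxis(vol, -1, 0).reshape(nc // channels, channels, h, w)


def save_mask_png(mask: np.ndarray, path) -> None:
    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
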