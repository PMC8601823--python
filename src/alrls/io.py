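"""Image, mask and contour I/O.

Images are held as plain 2D float64 numpy arrays (row-major, 0-based,
pixel-centred coordinates).  PNG/TIFF are read through imageio/tifffile;
single DICOM slices through pydicom (stored values after rescale
slope/intercept).  Masks round-trip losslessly as 0/255 PNG.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["read_image", "write_image", "write_mask", "read_mask", "ImageIOError"]


class ImageIOError(IOError):
    """Raised when an image file cannot be read or written."""


def _to_grayscale(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim == 3:
        # luminance average over channels (alpha dropped)
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        arr = arr.mean(axis=2)
    if arr.ndim != 2:
        raise ImageIOError(f"expected a 2D image, got shape {arr.shape}")
    return np.asarray(arr, dtype=np.float64)


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image from PNG/TIFF/DICOM.

    Multi-channel images are collapsed by channel average.  Returns a
    float64 array in the stored intensity units (not normalised).
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such image file: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".dcm", ".dicom"):
            import pydicom

            ds = pydicom.dcmread(str(path))
            arr = ds.pixel_array.astype(np.float64)
            slope = float(getattr(ds, "RescaleSlope", 1.0))
            intercept = float(getattr(ds, "RescaleIntercept", 0.0))
            arr = arr * slope + intercept
        elif suffix in (".tif", ".tiff"):
            import tifffile

            arr = tifffile.imread(str(path))
        else:
            import imageio.v3 as iio

            arr = iio.imread(str(path))
    except ImageIOError:
        raise
    except Exception as exc:  # noqa: BLE001 - backend errors become I/O errors
        raise ImageIOError(f"cannot read image {path}: {exc}") from exc
    arr = _to_grayscale(arr)
    if arr.size == 0:
        raise ImageIOError(f"zero-area image: {path}")
    if not np.all(np.isfinite(arr)):
        raise ImageIOError(f"non-finite pixel values in {path}")
    return arr


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a float image rescaled to 8-bit PNG/TIFF (lossy in depth)."""
    import imageio.v3 as iio

    image = np.asarray(image, dtype=np.float64)
    lo, hi = float(image.min()), float(image.max())
    scale = 255.0 / (hi - lo) if hi > lo else 0.0
    data = ((image - lo) * scale).round().astype(np.uint8)
    try:
        iio.imwrite(str(path), data)
    except Exception as exc:  # noqa: BLE001
        raise ImageIOError(f"cannot write image {path}: {exc}") from exc


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as a 0/255 PNG; round-trip is bit-exact."""
    import imageio.v3 as iio

    mask = np.asarray(mask)
    if mask.dtype != bool:
        raise ValueError(f"mask must be boolean, got dtype {mask.dtype}")
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2D, got shape {mask.shape}")
    try:
        iio.imwrite(str(path), (mask.astype(np.uint8) * 255))
    except Exception as exc:  # noqa: BLE001
        raise ImageIOError(f"cannot write mask {path}: {exc}") from exc


def read_mask(path: str | Path) -> np.ndarray:
    """Read back a 0/255 PNG mask as a boolean array."""
    arr = read_image(path)
    return arr > 127.5
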