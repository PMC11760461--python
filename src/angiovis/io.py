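"""Reading and writing grayscale frames (PNG, TIFF, DICOM).

Intensities are mapped linearly to [0, 1] from the source quantisation
(e.g. a 10-bit DICOM stored value of 1023 reads as 1.0) and quantised back
only at write time.  Only lossless raster formats are written.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pydicom
import tifffile

from .errors import InputError
from .gabor import Frame

logger = logging.getLogger(__name__)

__all__ = ["read_frame", "write_frame"]

_LUMA = np.array([0.299, 0.587, 0.114])


def _normalise(array: np.ndarray, bits: int) -> np.ndarray:
    return array.astype(np.float64) / float(2 ** bits - 1)


def _to_gray(array: np.ndarray) -> np.ndarray:
    if array.ndim == 3 and array.shape[-1] in (3, 4):
        logger.warning("RGB input converted to luma")
        return array[..., :3].astype(np.float64) @ _LUMA
    return array


def _read_dicom(path: Path) -> Frame | list[Frame]:
    ds = pydicom.dcmread(path)
    bits = int(getattr(ds, "BitsStored", 16))
    pixels = ds.pixel_array.astype(np.float64)
    if getattr(ds, "PhotometricInterpretation", "MONOCHROME2") == "MONOCHROME1":
        logger.info("MONOCHROME1 DICOM inverted on read")
        pixels = (2 ** bits - 1) - pixels
    data = _normalise(pixels, bits)
    if data.ndim == 3:
        return [Frame(np.clip(f, 0, 1), bit_depth_source=bits) for f in data]
    return Frame(np.clip(data, 0, 1), bit_depth_source=bits)


def read_frame(path: str | Path) -> Frame | list[Frame]:
    """Read a PNG/TIFF/DICOM file into one Frame (or an ordered list of
    Frames for multi-frame input)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"cannot read '{path}': no such file")
    suffix = path.suffix.lower()
    try:
        if suffix in (".dcm", ".dicom", ""):
            return _read_dicom(path)
        if suffix in (".tif", ".tiff"):
            raw = tifffile.imread(path)
        else:
            raw = iio.imread(path)
    except Exception as exc:
        raise InputError(f"cannot read '{path}': {exc}") from exc
    gray = _to_gray(raw)
    bits = 8 if raw.dtype == np.uint8 else 16
    if gray.ndim == 3:  # multi-page TIFF
        return [Frame(np.clip(_normalise(f, bits), 0, 1), bit_depth_source=bits)
                for f in gray]
    return Frame(np.clip(_normalise(gray, bits), 0, 1), bit_depth_source=bits)


def write_frame(frame: Frame | np.ndarray, path: str | Path,
                bit_depth: int = 16) -> Path:
    """Quantise a [0, 1] frame to ``bit_depth`` and write it losslessly."""
    path = Path(path)
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame, dtype=np.float64)
    if pixels.min() < 0 or pixels.max() > 1 or not np.all(np.isfinite(pixels)):
        raise InputError("write_frame expects intensities in [0, 1]")
    if bit_depth not in (8, 16):
        raise InputError("bit_depth must be 8 or 16")
    peak = 2 ** bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    quantised = np.round(pixels * peak).astype(dtype)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, quantised)
    elif suffix == ".png":
        iio.imwrite(path, quantised)
    else:
        raise InputError(f"unsupported output format '{suffix}' (PNG/TIFF only)")
    return path
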