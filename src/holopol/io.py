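"""File formats: TIFF images/fields, PNG label masks, CSV tables, JSON.

All writers are atomic (write to a temporary sibling, then rename), so
a crashed run never leaves a truncated output in place.  Mosaics are
stored as 16-bit grayscale TIFF with a fixed integer gain; feature maps
and reconstructions as 32-bit float TIFF; label masks as 16-bit PNG
with pixel value = particle id.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import FormatError

__all__ = [
    "MOSAIC_GAIN",
    "atomic_write_bytes",
    "write_tiff",
    "read_tiff",
    "write_mosaic_tiff",
    "read_mosaic_tiff",
    "write_label_png",
    "read_label_png",
    "write_json",
    "read_json",
    "read_mosaic_video",
    "write_complex_field",
    "read_complex_field",
]

#: Counts per unit intensity when quantizing mosaics to 16-bit.
MOSAIC_GAIN = 10000.0


def atomic_write_bytes(path, data: bytes) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_tiff(path, array: np.ndarray) -> None:
    """Write an array as TIFF atomically (dtype preserved)."""
    import io as _io

    buf = _io.BytesIO()
    tifffile.imwrite(buf, array)
    atomic_write_bytes(path, buf.getvalue())


def read_tiff(path) -> np.ndarray:
    try:
        return tifffile.imread(path)
    except Exception as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc


def write_mosaic_tiff(path, mosaic: np.ndarray, gain: float = MOSAIC_GAIN) -> None:
    """Quantize a normalized-intensity mosaic to 16-bit and write it."""
    counts = np.clip(np.round(mosaic * gain), 0, 65535).astype(np.uint16)
    write_tiff(path, counts)


def read_mosaic_tiff(path, gain: float = MOSAIC_GAIN) -> np.ndarray:
    raw = read_tiff(path)
    return raw.astype(float) / gain


def write_label_png(path, labels: np.ndarray) -> None:
    """Label mask as 16-bit PNG, pixel value = particle id."""
    if labels.max() > 65535:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit PNG")
    buf = iio.imwrite("<bytes>", labels.astype(np.uint16), extension=".png")
    atomic_write_bytes(path, buf)


def read_label_png(path) -> np.ndarray:
    try:
        return iio.imread(path).astype(np.int32)
    except Exception as exc:
        raise FormatError(f"cannot read PNG {path}: {exc}") from exc


def write_json(path, obj) -> None:
    atomic_write_bytes(path, json.dumps(obj, indent=2, sort_keys=True).encode())


def read_json(path):
    try:
        with open(path) as fh:
            return json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read JSON {path}: {exc}") from exc


def read_mosaic_video(path, gain: float = MOSAIC_GAIN) -> list[np.ndarray]:
    """Load a mosaic video from a multi-page TIFF or a directory of TIFFs.

    Directory frames are taken in sorted filename order.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")
        )
        if not files:
            raise FormatError(f"no TIFF frames found in directory {path}")
        return [read_mosaic_tiff(p, gain) for p in files]
    stack = read_tiff(path)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise FormatError(f"{path}: expected a 2-D frame or 3-D stack")
    return [frame.astype(float) / gain for frame in stack]


def write_complex_field(path_real, path_imag, field) -> None:
    """Store a complex field as paired 32-bit float TIFFs."""
    write_tiff(path_real, field.data.real.astype(np.float32))
    write_tiff(path_imag, field.data.imag.astype(np.float32))


def read_complex_field(path_real, path_imag, pitch: float, wavelength: float):
    from .holography import ComplexField

    re = read_tiff(path_real).astype(float)
    im = read_tiff(path_imag).astype(float)
    if re.shape != im.shape:
        raise FormatError("real/imaginary parts have different shapes")
    return ComplexField(re + 1j * im, pitch, wavelength)
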