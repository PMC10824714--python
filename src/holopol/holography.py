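"""In-line hologram formation and angular-spectrum reconstruction.

An in-line (Gabor) hologram is the intensity of the superposition of a
reference wave and the wave scattered by the object,

    I = |U_R + U_O|^2 = |U_R|^2 + |U_O|^2 + U_O* U_R + U_O U_R*.

The first two terms form the DC background and are suppressed either by
mean subtraction or by a Gaussian notch at zero frequency.  The complex
field at any depth ``z`` is obtained with the angular-spectrum method:
the 2-D spectrum is multiplied by the free-space transfer function

    H(f_x, f_y) = exp(-i 2 pi z / lambda * sqrt(1 - lambda^2 (f_x^2 + f_y^2)))

with evanescent components (negative argument of the square root)
hard-zeroed.  Back-propagation uses the same kernel with ``-z``; the
sign convention is fixed in :mod:`holopol.constants`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import FORWARD_KERNEL_SIGN
from .errors import ShapeError

__all__ = [
    "ComplexField",
    "ReconstructionResult",
    "form_hologram",
    "suppress_dc",
    "angular_spectrum_propagate",
    "reconstruct",
    "focus_metric",
    "focus_search",
]


@dataclass
class ComplexField:
    """A sampled 2-D complex optical field.

    Parameters
    ----------
    data
        Complex samples on a regular grid, shape ``(ny, nx)``.
    pitch
        Sample spacing in metres (isotropic).
    wavelength
        Illumination wavelength in metres.
    """

    data: np.ndarray
    pitch: float
    wavelength: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 2:
            raise ShapeError("field must be a 2-D array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("field contains non-finite samples")
        if self.pitch <= 0 or self.wavelength <= 0:
            raise ValueError("pitch and wavelength must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.data) ** 2


@dataclass
class ReconstructionResult:
    """Complex wavefront reconstructed at one depth, with derived images."""

    field: ComplexField
    z: float
    amplitude: np.ndarray
    phase: np.ndarray
    focus_value: float


def form_hologram(u_obj: ComplexField, u_ref: ComplexField) -> np.ndarray:
    """Intensity of the superposed object and reference waves.

    Returns the real, non-negative image ``|U_R + U_O|^2``.
    """
    if u_obj.shape != u_ref.shape:
        raise ShapeError(f"field grids differ: {u_obj.shape} vs {u_ref.shape}")
    if u_obj.pitch != u_ref.pitch or u_obj.wavelength != u_ref.wavelength:
        raise ShapeError("fields must share pitch and wavelength")
    total = u_ref.data + u_obj.data
    return (total.real**2 + total.imag**2).astype(float)


def suppress_dc(
    hologram: np.ndarray, method: str = "mean_subtract", notch_radius: float = 3.0
) -> np.ndarray:
    """Remove the DC (undiffracted background) term from a hologram.

    ``mean_subtract`` subtracts the global mean; ``freq_notch`` applies a
    Gaussian notch of 1/e half-width ``notch_radius`` (in frequency
    samples) centred on zero frequency.
    """
    h = np.asarray(hologram, dtype=float)
    if h.ndim != 2:
        raise ShapeError("hologram must be 2-D")
    if method == "mean_subtract":
        return h - h.mean()
    if method == "freq_notch":
        ny, nx = h.shape
        fy = np.fft.fftfreq(ny)[:, None] * ny
        fx = np.fft.fftfreq(nx)[None, :] * nx
        notch = 1.0 - np.exp(-(fx**2 + fy**2) / (2.0 * notch_radius**2))
        return np.fft.ifft2(np.fft.fft2(h) * notch).real
    from .errors import ConfigError

    raise ConfigError(f"unknown DC suppression method: {method!r}")


def _asm_kernel(shape, pitch, wavelength, z):
    ny, nx = shape
    fx = np.fft.fftfreq(nx, d=pitch)[None, :]
    fy = np.fft.fftfreq(ny, d=pitch)[:, None]
    arg = 1.0 - wavelength**2 * (fx**2 + fy**2)
    propagating = arg > 0
    kz = np.sqrt(np.where(propagating, arg, 0.0))
    kernel = np.exp(FORWARD_KERNEL_SIGN * 1j * 2.0 * np.pi * z / wavelength * kz)
    return np.where(propagating, kernel, 0.0)


def angular_spectrum_propagate(
    field: ComplexField, z: float, pad: bool = False
) -> ComplexField:
    """Propagate a field over distance ``z`` with the angular-spectrum kernel.

    Positive ``z`` is forward (towards the detector), negative ``z`` is
    back-propagation.  Evanescent components are zeroed, so the operator
    is unitary on band-limited fields.  ``pad=True`` embeds the field in
    a 2x zero-padded grid to reduce wrap-around for large ``z``.
    """
    if not np.isfinite(z):
        raise ValueError("propagation distance must be finite")
    ny, nx = field.shape
    if ny < 16 or nx < 16:
        raise ShapeError("field grid must be at least 16x16")
    data = field.data
    if pad:
        padded = np.zeros((2 * ny, 2 * nx), dtype=complex)
        padded[ny // 2 : ny // 2 + ny, nx // 2 : nx // 2 + nx] = data
        data = padded
    kernel = _asm_kernel(data.shape, field.pitch, field.wavelength, z)
    out = np.fft.ifft2(np.fft.fft2(data) * kernel)
    if pad:
        out = out[ny // 2 : ny // 2 + ny, nx // 2 : nx // 2 + nx]
    return ComplexField(out, field.pitch, field.wavelength)


def focus_metric(amplitude: np.ndarray) -> float:
    """Gradient-energy (Tenengrad-style) sharpness of an amplitude image.

    Mean squared gradient magnitude: maximal when edges are sharp,
    exactly zero for a uniform image.  For in-line holograms of
    absorbing particles this peaks at the recording depth, provided the
    amplitude retains the undiffracted reference (see
    :func:`reconstruct`): suppressing the DC term rotates the object
    wave against the reference phase and flattens the focus response.
    """
    a = np.asarray(amplitude, dtype=float)
    gy, gx = np.gradient(a)
    return float(np.mean(gy**2 + gx**2))


def reconstruct(
    hologram: np.ndarray,
    cfg,
    z: float,
    dc_method: str = "mean_subtract",
    pad: bool = False,
) -> ReconstructionResult:
    """Reconstruct the complex wavefront at depth ``z`` from a hologram.

    The DC-suppressed hologram, multiplied by the conjugate of the
    (unit, on-axis) reference wave, is treated as a field at the detector
    plane and back-propagated by ``-z``.

    Parameters
    ----------
    hologram
        Real detector-plane intensity image at channel resolution.
    cfg
        An :class:`~holopol.scene.OpticalConfig` (supplies wavelength and
        the object-plane pixel pitch).
    z
        Recording distance in metres; the field is propagated by ``-z``.
    """
    h_raw = np.asarray(hologram, dtype=float)
    h = suppress_dc(h_raw, dc_method)
    pitch = cfg.object_pixel_pitch
    gamma = angular_spectrum_propagate(ComplexField(h.astype(complex), pitch, cfg.wavelength), -z, pad=pad)
    amplitude = np.abs(gamma.data)
    phase = np.angle(gamma.data)
    # Focus is judged on the reference-retained field: back-propagating the
    # raw hologram keeps the undiffracted background phase-aligned with the
    # real image, which the DC-suppressed field does not.
    with_ref = angular_spectrum_propagate(
        ComplexField(h_raw.astype(complex), pitch, cfg.wavelength), -z, pad=pad
    )
    return ReconstructionResult(gamma, z, amplitude, phase, focus_metric(np.abs(with_ref.data)))


def focus_search(
    hologram: np.ndarray,
    cfg,
    z_range: tuple[float, float],
    n_steps: int,
    dc_method: str = "mean_subtract",
) -> tuple[float, np.ndarray, np.ndarray]:
    """Autofocus: maximise the focus metric over a uniform depth scan.

    Returns ``(best_z, z_grid, metric_values)``.  Ties (including a
    completely flat metric, e.g. an empty hologram) resolve to the
    smallest ``z``.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be at least 2")
    lo, hi = z_range
    if not hi > lo:
        raise ValueError("z_range must be non-degenerate (lo < hi)")
    zs = np.linspace(lo, hi, n_steps)
    vals = np.array([reconstruct(hologram, cfg, z, dc_method).focus_value for z in zs])
    return float(zs[int(np.argmax(vals))]), zs, vals
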