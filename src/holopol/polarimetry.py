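"""Stokes, DoLP, AoP and SSD feature maps from four-angle captures.

A division-of-focal-plane polarization camera records the four analyzer
channels 0/45/90/135 degrees interleaved in 2x2 pixel groups.  After
demosaicing, the linear Stokes parameters are

    I = I0 + I90,   Q = I0 - I90,   U = I45 - I135,

from which the degree of linear polarization DoLP = sqrt(Q^2+U^2)/I and
the angle of polarization AoP = 1/2 arctan(U/Q) follow.  The stack
standard deviation (SSD) is the per-pixel population standard deviation
over the four channels; for a uniform retarder of retardance delta under
circular illumination it equals |sin delta| / (2 sqrt(2)) times the
total intensity, making it a direct birefringence-contrast feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ShapeError

__all__ = [
    "PolarizationStack",
    "StokesMaps",
    "FeatureMap",
    "MosaicLayout",
    "DEFAULT_LAYOUT",
    "split_mosaic",
    "stokes_maps",
    "dolp_map",
    "aop_map",
    "ssd_map",
]


@dataclass
class PolarizationStack:
    """Four co-registered non-negative intensity images."""

    I0: np.ndarray
    I45: np.ndarray
    I90: np.ndarray
    I135: np.ndarray
    pitch: float = 1.0

    def __post_init__(self):
        arrs = [np.asarray(a, dtype=float) for a in (self.I0, self.I45, self.I90, self.I135)]
        shapes = {a.shape for a in arrs}
        if len(shapes) != 1:
            raise ShapeError(f"channel shapes differ: {shapes}")
        self.I0, self.I45, self.I90, self.I135 = arrs

    @property
    def shape(self) -> tuple[int, int]:
        return self.I0.shape

    def channels(self) -> np.ndarray:
        """Stack the four channels along a leading axis (0,45,90,135)."""
        return np.stack([self.I0, self.I45, self.I90, self.I135])

    def scaled(self, factor: float) -> "PolarizationStack":
        return PolarizationStack(
            self.I0 * factor, self.I45 * factor, self.I90 * factor,
            self.I135 * factor, self.pitch,
        )


@dataclass
class StokesMaps:
    """Linear Stokes parameter images I, Q, U on a common grid."""

    I: np.ndarray
    Q: np.ndarray
    U: np.ndarray
    pitch: float = 1.0

    def __post_init__(self):
        if not (self.I.shape == self.Q.shape == self.U.shape):
            raise ShapeError("I, Q, U must share one shape")


@dataclass
class FeatureMap:
    """A derived per-pixel feature image with a validity mask."""

    kind: str  # "DoLP" | "AoP" | "SSD"
    values: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    pitch: float = 1.0

    def __post_init__(self):
        if self.valid is None:
            self.valid = np.ones(self.values.shape, dtype=bool)
        if self.valid.shape != self.values.shape:
            raise ShapeError("valid mask must match values shape")


@dataclass(frozen=True)
class MosaicLayout:
    """Assignment of analyzer angles to positions in each 2x2 pixel group.

    ``angles[i][j]`` is the analyzer angle (degrees) of the pixel at row
    offset ``i``, column offset ``j`` within the group.  The default
    follows the common commercial sensor arrangement::

        90  45
        135   0
    """

    angles: tuple[tuple[int, int], tuple[int, int]] = ((90, 45), (135, 0))

    def __post_init__(self):
        flat = [a for row in self.angles for a in row]
        if sorted(flat) != [0, 45, 90, 135]:
            raise ConfigError(
                f"layout must contain each of 0/45/90/135 exactly once, got {flat}"
            )

    @classmethod
    def from_code(cls, code: str) -> "MosaicLayout":
        """Parse a layout code like ``"90-45-135-0"`` (row-major)."""
        try:
            a, b, c, d = (int(x) for x in code.split("-"))
        except ValueError as exc:
            raise ConfigError(f"cannot parse layout code {code!r}") from exc
        return cls(((a, b), (c, d)))

    def code(self) -> str:
        return "-".join(str(a) for row in self.angles for a in row)

    def position_of(self, angle: int) -> tuple[int, int]:
        for i in range(2):
            for j in range(2):
                if self.angles[i][j] == angle:
                    return i, j
        raise ConfigError(f"angle {angle} not in layout")


DEFAULT_LAYOUT = MosaicLayout()


def split_mosaic(mosaic: np.ndarray, layout: MosaicLayout = DEFAULT_LAYOUT,
                 pitch: float = 1.0) -> PolarizationStack:
    """Demosaic a 2x2-interleaved capture into the four angle channels.

    Channels are extracted by position sampling (no interpolation), so
    each has half the mosaic resolution; ``pitch`` is the resulting
    channel pitch.
    """
    m = np.asarray(mosaic, dtype=float)
    if m.ndim != 2:
        raise ShapeError("mosaic must be 2-D")
    if m.shape[0] % 2 or m.shape[1] % 2:
        raise ShapeError(f"mosaic dimensions must be even, got {m.shape}")
    chans = {}
    for angle in (0, 45, 90, 135):
        i, j = layout.position_of(angle)
        chans[angle] = m[i::2, j::2]
    return PolarizationStack(chans[0], chans[45], chans[90], chans[135], pitch)


def stokes_maps(stack: PolarizationStack) -> StokesMaps:
    """Pixelwise linear Stokes parameters from a four-angle stack."""
    return StokesMaps(
        I=stack.I0 + stack.I90,
        Q=stack.I0 - stack.I90,
        U=stack.I45 - stack.I135,
        pitch=stack.pitch,
    )


def dolp_map(s: StokesMaps, intensity_floor: float = 1e-3) -> FeatureMap:
    """Degree of linear polarization, sqrt(Q^2 + U^2) / I, in [0, 1].

    Pixels whose total intensity falls below ``intensity_floor`` times
    the frame maximum are set to 0 and flagged invalid rather than
    producing unstable ratios.  Values are clipped at 1: for ideal
    stacks sqrt(Q^2+U^2) <= I holds exactly, so clipping only absorbs
    noise excursions.
    """
    thresh = intensity_floor * float(np.max(s.I)) if s.I.size else 0.0
    valid = s.I > thresh
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.hypot(s.Q, s.U) / s.I
    values = np.where(valid, np.minimum(raw, 1.0), 0.0)
    return FeatureMap("DoLP", values, valid, s.pitch)


def aop_map(s: StokesMaps) -> FeatureMap:
    """Angle of polarization, 1/2 arctan(U/Q), restricted to [-pi/4, pi/4].

    Uses the single-argument arctangent, so the angle is defined modulo
    pi/2.  Pixels with Q = 0 map to sign(U) * pi/4; pixels with
    Q = U = 0 carry no orientation and are flagged invalid (value 0).
    """
    q, u = s.Q, s.U
    with np.errstate(divide="ignore", invalid="ignore"):
        values = 0.5 * np.arctan(np.true_divide(u, q))
    values = np.where(q == 0, np.sign(u) * np.pi / 4.0, values)
    undefined = (q == 0) & (u == 0)
    values = np.where(undefined, 0.0, values)
    return FeatureMap("AoP", values, ~undefined, s.pitch)


def ssd_map(stack: PolarizationStack) -> FeatureMap:
    """Per-pixel population standard deviation over the four channels.

    The divisor is N = 4 (population form); with a fixed channel count
    the sample/population choice only rescales the feature.
    """
    values = np.std(stack.channels(), axis=0, ddof=0)
    return FeatureMap("SSD", values, np.ones_like(values, dtype=bool), stack.pitch)
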