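"""Physically based synthetic polarization holograms of flowing particles.

This module emulates the acquisition geometry of an in-line polarization
holographic flow imager: coherent 632.8 nm illumination is circularly
polarized, passes through transparent birefringent particles suspended
in a water-filled flow channel, propagates to a division-of-focal-plane
polarization camera (2x2 groups of 0/45/90/135 degree analyzers,
3.45 um pixels, 2464x2056 mosaic), and is recorded as an intensity
mosaic.  Each particle acts as a uniform linear retarder: a scalar
amplitude transmittance times the Jones matrix of a wave plate with a
per-particle retardance delta (drawn once, clipped to [0, pi]) and fast
axis theta.  The two Cartesian field components are propagated
independently with the angular-spectrum operator (water and glass are
treated as isotropic), and the analyzer projection happens at the
detector plane.  No separate reference beam exists: the undiffracted
background is the reference (Gabor geometry), so the twin image is
accepted.

Every render is accompanied by a :class:`GroundTruth` (label masks,
per-particle records, counts, trajectories), so all downstream stages
are testable without any external data.

The default material retardances are *synthetic placeholders*: the real
birefringence magnitudes of the six plastics are not tabulated anywhere
in this toolkit's sources; the defaults are chosen only to create
distinct, orderable birefringence classes (glass = 0 is the
non-birefringent control).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from skimage import draw as skdraw

from .constants import ILLUMINATION_JONES
from .errors import GeometryError, SamplingError
from .holography import ComplexField, angular_spectrum_propagate
from .polarimetry import DEFAULT_LAYOUT, MosaicLayout, PolarizationStack

__all__ = [
    "OpticalConfig",
    "MaterialSpec",
    "ParticleSpec",
    "NoiseSpec",
    "SceneSpec",
    "FlowSpec",
    "ParticleTruth",
    "GroundTruth",
    "DEFAULT_MATERIALS",
    "SHAPE_KINDS",
    "mean_flow_speed",
    "make_particle_fields",
    "render_polarized_hologram",
    "render_uniform_retarder",
    "mosaic_sample",
    "render_video",
]

SHAPE_KINDS = ("fragment", "pellet", "fiber", "film", "foam", "bead")

MATERIAL_NAMES = ("PC", "PET", "PVC", "PP", "PS", "PMMA", "glass", "lens_paper", "algae")


@dataclass(frozen=True)
class OpticalConfig:
    """Acquisition geometry of the polarization holographic imager.

    ``mosaic_shape`` is (rows, cols) of the raw detector mosaic; the
    demosaiced channels have half that resolution and twice the pixel
    pitch (``channel_pitch``).  ``magnification`` defaults to 1
    (lensless in-line assumption), so the object-plane pixel size equals
    the channel pitch.
    """

    wavelength: float = 632.8e-9
    physical_pixel_pitch: float = 3.45e-6
    mosaic_shape: tuple[int, int] = (2056, 2464)
    propagation_distance: float = 5e-3
    magnification: float = 1.0

    def __post_init__(self):
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.physical_pixel_pitch <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.mosaic_shape[0] % 2 or self.mosaic_shape[1] % 2:
            raise ValueError("mosaic dimensions must be even")
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")

    @property
    def channel_pitch(self) -> float:
        """Pitch of one demosaiced channel: exactly 2x the physical pitch."""
        return 2.0 * self.physical_pixel_pitch

    @property
    def channel_shape(self) -> tuple[int, int]:
        return (self.mosaic_shape[0] // 2, self.mosaic_shape[1] // 2)

    @property
    def object_pixel_pitch(self) -> float:
        return self.channel_pitch / self.magnification


@dataclass(frozen=True)
class MaterialSpec:
    """A material's synthetic birefringence model.

    ``retardance_mean``/``retardance_sd`` parameterize the per-particle
    retardance draw (radians); ``amplitude_transmittance`` scales the
    transmitted field amplitude.
    """

    name: str
    retardance_mean: float
    retardance_sd: float = 0.05
    amplitude_transmittance: float = 0.9

    def __post_init__(self):
        if self.name not in MATERIAL_NAMES:
            raise ValueError(f"unknown material {self.name!r}")
        if self.retardance_sd < 0:
            raise ValueError("retardance_sd must be >= 0")
        if not 0.0 <= self.amplitude_transmittance <= 1.0:
            raise ValueError("amplitude_transmittance must lie in [0, 1]")
        if self.name == "glass" and self.retardance_mean != 0.0:
            raise ValueError("glass is the non-birefringent reference (mean 0)")


#: Synthetic per-material defaults.  Retardance magnitudes are placeholders
#: chosen to create orderable birefringence classes, not measured physics;
#: glass is the zero-retardance control.
DEFAULT_MATERIALS: dict[str, MaterialSpec] = {
    "glass": MaterialSpec("glass", 0.0, 0.0, 0.95),
    "PMMA": MaterialSpec("PMMA", 0.15),
    "PS": MaterialSpec("PS", 0.35),
    "PVC": MaterialSpec("PVC", 0.45),
    "PC": MaterialSpec("PC", 0.60),
    "PP": MaterialSpec("PP", 0.90),
    "PET": MaterialSpec("PET", 1.30),
    "lens_paper": MaterialSpec("lens_paper", 0.05, 0.02, 0.75),
    "algae": MaterialSpec("algae", 0.03, 0.01, 0.60),
}


@dataclass(frozen=True)
class ParticleSpec:
    """One particle: shape, physical size, position, fast axis, material.

    ``centroid`` is (x, y) in metres in the object plane, with x along
    the flow axis (image columns) and y along rows.  ``fast_axis_angle``
    must lie in [0, pi).
    """

    shape_kind: str
    characteristic_size: float
    centroid: tuple[float, float]
    fast_axis_angle: float
    material: MaterialSpec

    def __post_init__(self):
        if self.shape_kind not in SHAPE_KINDS:
            raise ValueError(f"unknown shape kind {self.shape_kind!r}")
        if self.characteristic_size <= 0:
            raise ValueError("characteristic_size must be positive")
        if not 0.0 <= self.fast_axis_angle < np.pi:
            raise ValueError("fast_axis_angle must lie in [0, pi)")


@dataclass(frozen=True)
class NoiseSpec:
    """Detector and medium noise levels.

    ``background_scatter_sd`` — additive Gaussian intensity noise from
    suspended-matter scattering, relative to the mean illumination level
    (applied to the channel stack).  ``shot_noise_scale`` — expected
    photon count at unit intensity for Poisson shot noise on the mosaic
    (0 disables).  ``read_noise_sd`` — Gaussian read noise on the
    mosaic, in the same normalized intensity units.  All zeros give a
    bit-reproducible noiseless render.
    """

    background_scatter_sd: float = 0.0
    shot_noise_scale: float = 0.0
    read_noise_sd: float = 0.0

    def __post_init__(self):
        if min(self.background_scatter_sd, self.shot_noise_scale, self.read_noise_sd) < 0:
            raise ValueError("noise levels must be >= 0")

    @property
    def is_noiseless(self) -> bool:
        return (
            self.background_scatter_sd == 0
            and self.shot_noise_scale == 0
            and self.read_noise_sd == 0
        )

    @classmethod
    def mild(cls) -> "NoiseSpec":
        """Mild noise: visible but far from masking mm-scale fringes."""
        return cls(background_scatter_sd=0.02, shot_noise_scale=2e4, read_noise_sd=0.002)


@dataclass(frozen=True)
class SceneSpec:
    """A declarative synthetic scene; ``seed`` fully determines output."""

    particles: tuple[ParticleSpec, ...]
    field_of_view: tuple[int, int]  # channel-resolution (rows, cols)
    noise: NoiseSpec = NoiseSpec()
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "particles", tuple(self.particles))


@dataclass(frozen=True)
class FlowSpec:
    """Pump and flow-cell geometry; defaults follow the 8 ml/min regime."""

    volume_flow_rate: float = 8.0  # ml/min
    channel_inner_thickness: float = 5.0  # mm
    channel_width: float = 10.0  # mm
    frames_per_second: float = 60.0

    PUMP_RANGE = (2.0, 15.0)  # ml/min

    def __post_init__(self):
        if self.volume_flow_rate < 0:
            raise ValueError("flow rate must be >= 0")
        if self.frames_per_second <= 0:
            raise ValueError("frames_per_second must be positive")

    def validate_pump_range(self) -> None:
        lo, hi = self.PUMP_RANGE
        if not lo <= self.volume_flow_rate <= hi:
            raise ValueError(
                f"flow rate {self.volume_flow_rate} ml/min outside pump range [{lo}, {hi}]"
            )


@dataclass
class ParticleTruth:
    """Ground-truth record for one simulated particle."""

    id: int
    material: str
    shape_kind: str
    retardance: float
    area_px: int
    mfd_px: float
    centroid_px: tuple[float, float]  # (row, col) at first appearance


@dataclass
class GroundTruth:
    """Per-frame truth for a render: label masks, records, trajectories.

    ``label_masks[f]`` assigns each pixel of frame ``f`` the id of the
    particle covering it (0 = background).  ``trajectories[pid]`` lists
    ``(frame, row, col)`` centroids for the frames in which particle
    ``pid`` is visible.  ``count`` is the number of distinct particle
    identities that appear in at least one frame.
    """

    label_masks: list[np.ndarray]
    records: list[ParticleTruth]
    count: int
    trajectories: dict[int, list[tuple[int, float, float]]]


# ---------------------------------------------------------------------------
# flow kinematics


def mean_flow_speed(flow: FlowSpec) -> float:
    """Mean flow speed in mm/s from the volume flow rate and cross-section.

    speed = Q / (thickness * width); 8 ml/min in a 5 x 10 mm channel
    gives 2.667 mm/s.
    """
    area_mm2 = flow.channel_inner_thickness * flow.channel_width
    if area_mm2 <= 0:
        raise GeometryError("channel cross-section must be positive")
    q_mm3_per_s = flow.volume_flow_rate * 1000.0 / 60.0
    return q_mm3_per_s / area_mm2


# ---------------------------------------------------------------------------
# particle rasterization


def _raster_shape(kind, center_rc, r_px, orientation, rng, fov):
    """Boolean support mask of one particle, clipped to the field of view."""
    mask = np.zeros(fov, dtype=bool)
    cr, cc = center_rc
    if kind == "bead":
        rr, cc_ = skdraw.disk((cr, cc), r_px, shape=fov)
        mask[rr, cc_] = True
    elif kind == "pellet":
        ratio = 1.35
        rr, cc_ = skdraw.ellipse(
            cr, cc, r_px * np.sqrt(ratio), r_px / np.sqrt(ratio),
            shape=fov, rotation=orientation,
        )
        mask[rr, cc_] = True
    elif kind == "fiber":
        half_len = r_px
        half_w = max(1.0, r_px / 8.0)
        dr, dc = np.sin(orientation), np.cos(orientation)
        pr, pc = -dc, dr  # perpendicular
        corners_r = [cr + s * half_len * dr + t * half_w * pr for s, t in
                     ((-1, -1), (-1, 1), (1, 1), (1, -1))]
        corners_c = [cc + s * half_len * dc + t * half_w * pc for s, t in
                     ((-1, -1), (-1, 1), (1, 1), (1, -1))]
        rr, cc_ = skdraw.polygon(corners_r, corners_c, shape=fov)
        mask[rr, cc_] = True
    elif kind == "film":
        # large, slightly irregular quadrilateral sheet
        ang = orientation + np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
        rad = r_px * (1.0 + 0.15 * rng.uniform(-1, 1, 4))
        aspect = 1.3
        rr, cc_ = skdraw.polygon(
            cr + rad * np.sin(ang) / np.sqrt(aspect),
            cc + rad * np.cos(ang) * np.sqrt(aspect), shape=fov)
        mask[rr, cc_] = True
    elif kind == "fragment":
        # irregular radial polygon: rough outline, moderate elongation
        n_v = 12
        ang = np.sort(rng.uniform(0, 2 * np.pi, n_v))
        rad = r_px * rng.uniform(0.55, 1.0, n_v)
        rr, cc_ = skdraw.polygon(cr + rad * np.sin(ang), cc + rad * np.cos(ang), shape=fov)
        mask[rr, cc_] = True
    elif kind == "foam":
        # cluster of lobes with deep concavities (low solidity)
        n_lobes = 3
        base = rng.uniform(0, 2 * np.pi)
        for k in range(n_lobes):
            a = base + 2 * np.pi * k / n_lobes
            lr = cr + 0.62 * r_px * np.sin(a)
            lc = cc + 0.62 * r_px * np.cos(a)
            rr, cc_ = skdraw.disk((lr, lc), 0.42 * r_px, shape=fov)
            mask[rr, cc_] = True
    else:  # pragma: no cover - guarded by ParticleSpec
        raise ValueError(kind)
    return mask


def make_particle_fields(
    p: ParticleSpec,
    fov: tuple[int, int],
    pitch: float,
    seed: int,
    allow_partial: bool = False,
):
    """Rasterize one particle into support, retardance, fast-axis and
    transmittance maps.

    The retardance is drawn once for the whole particle from
    ``Normal(mean, sd)`` clipped to [0, pi]; outside the support the
    retardance is 0 and the transmittance 1.  The same seed reproduces
    identical maps (shape irregularity included), so a moving particle
    keeps its shape between frames.
    """
    rng = np.random.default_rng(seed)
    r_px = 0.5 * p.characteristic_size / pitch
    cx, cy = p.centroid
    cc, cr = cx / pitch, cy / pitch
    if 2 * r_px >= min(fov):
        raise GeometryError(
            f"particle size {p.characteristic_size} exceeds the field of view"
        )
    if not allow_partial and not (
        r_px <= cr <= fov[0] - r_px and r_px <= cc <= fov[1] - r_px
    ):
        raise GeometryError("particle support extends outside the field of view")
    orientation = rng.uniform(0, np.pi)
    delta = float(np.clip(rng.normal(p.material.retardance_mean,
                                     p.material.retardance_sd), 0.0, np.pi))
    if p.material.retardance_mean == 0 and p.material.retardance_sd == 0:
        delta = 0.0
    mask = _raster_shape(p.shape_kind, (cr, cc), r_px, orientation, rng, fov)
    delta_map = np.where(mask, delta, 0.0)
    theta_map = np.where(mask, p.fast_axis_angle, 0.0)
    trans_map = np.where(mask, p.material.amplitude_transmittance, 1.0)
    return mask, delta_map, theta_map, trans_map


# ---------------------------------------------------------------------------
# vector Gabor rendering


def _jones_components(delta_map, theta_map, trans_map):
    """Object-plane field components for circular illumination through a
    pixelwise linear retarder of retardance delta and fast axis theta."""
    c, s = np.cos(theta_map), np.sin(theta_map)
    a = np.exp(-0.5j * delta_map)
    b = np.exp(0.5j * delta_map)
    j11 = a * c * c + b * s * s
    j12 = (a - b) * c * s
    j22 = a * s * s + b * c * c
    ex0, ey0 = ILLUMINATION_JONES
    ex = trans_map * (j11 * ex0 + j12 * ey0)
    ey = trans_map * (j12 * ex0 + j22 * ey0)
    return ex, ey


def _analyzer_channels(ex, ey):
    out = {}
    for adeg in (0, 45, 90, 135):
        a = np.deg2rad(adeg)
        e = np.cos(a) * ex + np.sin(a) * ey
        out[adeg] = e.real**2 + e.imag**2
    return out


def _asm_z_limit(fov, pitch, wavelength):
    """Largest |z| for which the angular-spectrum kernel is adequately
    sampled on this grid (beyond it, kernel fringes alias): N * pitch^2 / lambda."""
    return min(fov) * pitch**2 / wavelength


def _stack_from_maps(delta_map, theta_map, trans_map, cfg, z, fov):
    pitch = cfg.object_pixel_pitch
    ex, ey = _jones_components(delta_map, theta_map, trans_map)
    if z != 0.0:
        z_max = _asm_z_limit(fov, pitch, cfg.wavelength)
        if abs(z) > z_max:
            raise SamplingError(
                f"|z|={abs(z):.3g} m exceeds the alias-free propagation limit "
                f"{z_max:.3g} m for this grid/pitch"
            )
        # Split off the uniform illumination: the background plane wave
        # propagates analytically (a global phase), while the compactly
        # supported scattered component is propagated on a 2x zero-padded
        # grid so its fringes do not wrap around the periodic FFT domain.
        phase = np.exp(-1j * 2.0 * np.pi * z / cfg.wavelength)
        ex0, ey0 = ILLUMINATION_JONES
        ex = ex0 * phase + angular_spectrum_propagate(
            ComplexField(ex - ex0, pitch, cfg.wavelength), z, pad=True
        ).data
        ey = ey0 * phase + angular_spectrum_propagate(
            ComplexField(ey - ey0, pitch, cfg.wavelength), z, pad=True
        ).data
    ch = _analyzer_channels(ex, ey)
    return PolarizationStack(ch[0], ch[45], ch[90], ch[135], pitch)


def render_uniform_retarder(
    delta: float, theta: float, shape: tuple[int, int] = (32, 32),
    cfg: OpticalConfig | None = None, z: float = 0.0, transmittance: float = 1.0,
) -> PolarizationStack:
    """Render a frame filled by one uniform retarder (calibration aid).

    At z = 0 the analytic channel intensities are
    ``1/2 (1 - sin(delta) sin(2 alpha - 2 theta)) * t^2``.
    """
    cfg = cfg or OpticalConfig()
    delta_map = np.full(shape, float(delta))
    theta_map = np.full(shape, float(theta))
    trans_map = np.full(shape, float(transmittance))
    return _stack_from_maps(delta_map, theta_map, trans_map, cfg, z, shape)


def _scene_maps(scene: SceneSpec, pitch: float, allow_partial: bool):
    fov = scene.field_of_view
    label = np.zeros(fov, dtype=np.int32)
    delta_map = np.zeros(fov)
    theta_map = np.zeros(fov)
    trans_map = np.ones(fov)
    deltas = {}
    root = np.random.SeedSequence(scene.seed)
    part_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(len(scene.particles) + 1)]
    for idx, p in enumerate(scene.particles):
        mask, dmap, tmap_theta, tmap = make_particle_fields(
            p, fov, pitch, part_seeds[idx], allow_partial=allow_partial
        )
        pid = idx + 1
        label[mask] = pid
        delta_map[mask] = dmap[mask]
        theta_map[mask] = tmap_theta[mask]
        trans_map[mask] = tmap[mask]
        deltas[pid] = float(dmap[mask].max()) if mask.any() else 0.0
    return label, delta_map, theta_map, trans_map, deltas, part_seeds[-1]


def _truth_from_label(label, deltas, scene):
    from .morphometry import max_feret  # deferred: avoids import cycle at load

    records = []
    trajectories = {}
    for idx, p in enumerate(scene.particles):
        pid = idx + 1
        mask = label == pid
        if not mask.any():
            continue
        rr, cc = np.nonzero(mask)
        centroid = (float(rr.mean()), float(cc.mean()))
        records.append(
            ParticleTruth(
                id=pid,
                material=p.material.name,
                shape_kind=p.shape_kind,
                retardance=deltas.get(pid, 0.0),
                area_px=int(mask.sum()),
                mfd_px=float(max_feret(mask, pitch=1.0)),
                centroid_px=centroid,
            )
        )
        trajectories[pid] = [(0, centroid[0], centroid[1])]
    return GroundTruth([label], records, len(records), trajectories)


def render_polarized_hologram(
    scene: SceneSpec,
    cfg: OpticalConfig | None = None,
    z: float | None = None,
    allow_partial: bool = False,
) -> tuple[PolarizationStack, GroundTruth]:
    """Render the four analyzer channels of one in-line hologram frame.

    The illumination has unit intensity, so an empty noiseless scene
    yields every channel uniform at 1/2.  ``z`` defaults to the config's
    propagation distance; background-scatter noise from the scene's
    :class:`NoiseSpec` is applied last (detector shot/read noise belongs
    to :func:`mosaic_sample`).
    """
    cfg = cfg or OpticalConfig()
    if z is None:
        z = cfg.propagation_distance
    pitch = cfg.object_pixel_pitch
    label, delta_map, theta_map, trans_map, deltas, noise_seed = _scene_maps(
        scene, pitch, allow_partial
    )
    stack = _stack_from_maps(delta_map, theta_map, trans_map, cfg, z, scene.field_of_view)
    if scene.noise.background_scatter_sd > 0:
        rng = np.random.default_rng(noise_seed)
        sd = scene.noise.background_scatter_sd * 0.5  # relative to mean channel level
        chans = [
            np.clip(c + rng.normal(0.0, sd, c.shape), 0.0, None)
            for c in (stack.I0, stack.I45, stack.I90, stack.I135)
        ]
        stack = PolarizationStack(*chans, pitch)
    return stack, _truth_from_label(label, deltas, scene)


# ---------------------------------------------------------------------------
# detector mosaic


def mosaic_sample(
    stack: PolarizationStack,
    layout: MosaicLayout = DEFAULT_LAYOUT,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
) -> np.ndarray:
    """Interleave the four channels into a 2x2-mosaic detector image.

    Poisson shot noise (photon count ``shot_noise_scale`` per unit
    intensity) and Gaussian read noise are applied to the mosaic under
    ``seed``; with a noiseless spec the operation is the exact inverse
    of :func:`~holopol.polarimetry.split_mosaic`.
    """
    ny, nx = stack.shape
    mosaic = np.empty((2 * ny, 2 * nx), dtype=float)
    chans = {0: stack.I0, 45: stack.I45, 90: stack.I90, 135: stack.I135}
    for angle, img in chans.items():
        i, j = layout.position_of(angle)
        mosaic[i::2, j::2] = img
    rng = np.random.default_rng(seed)
    if noise.shot_noise_scale > 0:
        mosaic = rng.poisson(np.clip(mosaic, 0, None) * noise.shot_noise_scale) / noise.shot_noise_scale
    if noise.read_noise_sd > 0:
        mosaic = mosaic + rng.normal(0.0, noise.read_noise_sd, mosaic.shape)
    return np.clip(mosaic, 0.0, None) if not noise.is_noiseless else mosaic


# ---------------------------------------------------------------------------
# flowing video


def render_video(
    scene: SceneSpec,
    flow: FlowSpec,
    n_frames: int,
    cfg: OpticalConfig | None = None,
    z: float | None = None,
    layout: MosaicLayout = DEFAULT_LAYOUT,
) -> tuple[list[np.ndarray], GroundTruth]:
    """Render a mosaic video of the scene's particles advected by the flow.

    Particles translate along the flow axis (image columns) by
    ``mean_flow_speed / fps / object_pixel_pitch`` pixels per frame;
    initial positions may start upstream of the field of view, and
    particles are retired once they exit.  The ground truth records the
    per-frame label masks and centroid trajectories of every particle
    that appears in at least one frame.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    cfg = cfg or OpticalConfig()
    if z is None:
        z = cfg.propagation_distance
    pitch = cfg.object_pixel_pitch
    fov = scene.field_of_view
    speed_m_s = mean_flow_speed(flow) * 1e-3
    disp_px = speed_m_s / flow.frames_per_second / pitch
    if disp_px > fov[1]:
        warnings.warn(
            f"per-frame displacement {disp_px:.1f} px exceeds the field of view; "
            "clamping (tracking across such gaps is impossible)"
        )
        disp_px = float(fov[1])

    root = np.random.SeedSequence(scene.seed)
    children = root.spawn(len(scene.particles) + n_frames)
    part_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in children[: len(scene.particles)]]
    frame_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in children[len(scene.particles):]]

    from .morphometry import max_feret  # deferred import (cycle at module load)

    mosaics: list[np.ndarray] = []
    label_masks: list[np.ndarray] = []
    trajectories: dict[int, list[tuple[int, float, float]]] = {}
    records: dict[int, ParticleTruth] = {}

    for f in range(n_frames):
        shift_m = f * disp_px * pitch
        label = np.zeros(fov, dtype=np.int32)
        delta_map = np.zeros(fov)
        theta_map = np.zeros(fov)
        trans_map = np.ones(fov)
        for idx, p0 in enumerate(scene.particles):
            p = replace(p0, centroid=(p0.centroid[0] + shift_m, p0.centroid[1]))
            cx_px = p.centroid[0] / pitch
            r_px = 0.5 * p.characteristic_size / pitch
            if cx_px - r_px > fov[1]:  # retired: fully past the exit edge
                continue
            if cx_px + r_px < 0:  # not yet entered
                continue
            mask, dmap, thmap, tmap = make_particle_fields(
                p, fov, pitch, part_seeds[idx], allow_partial=True
            )
            if not mask.any():
                continue
            pid = idx + 1
            label[mask] = pid
            delta_map[mask] = dmap[mask]
            theta_map[mask] = thmap[mask]
            trans_map[mask] = tmap[mask]
            rr, cc = np.nonzero(mask)
            cen = (float(rr.mean()), float(cc.mean()))
            trajectories.setdefault(pid, []).append((f, cen[0], cen[1]))
            # keep the record from the frame of fullest visibility, so
            # edge-clipped entry frames do not understate area/MFD
            if pid not in records or int(mask.sum()) > records[pid].area_px:
                records[pid] = ParticleTruth(
                    id=pid,
                    material=p.material.name,
                    shape_kind=p.shape_kind,
                    retardance=float(dmap[mask].max()),
                    area_px=int(mask.sum()),
                    mfd_px=float(max_feret(mask, pitch=1.0)),
                    centroid_px=cen,
                )
        stack = _stack_from_maps(delta_map, theta_map, trans_map, cfg, z, fov)
        if scene.noise.background_scatter_sd > 0:
            rng = np.random.default_rng(frame_seeds[f])
            sd = scene.noise.background_scatter_sd * 0.5
            chans = [
                np.clip(c + rng.normal(0.0, sd, c.shape), 0.0, None)
                for c in (stack.I0, stack.I45, stack.I90, stack.I135)
            ]
            stack = PolarizationStack(*chans, pitch)
        mosaics.append(mosaic_sample(stack, layout, scene.noise, seed=frame_seeds[f] ^ 0x5A5A))
        label_masks.append(label)

    truth = GroundTruth(
        label_masks=label_masks,
        records=[records[k] for k in sorted(records)],
        count=len(records),
        trajectories=trajectories,
    )
    return mosaics, truth
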