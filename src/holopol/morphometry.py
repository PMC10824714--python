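"""Particle segmentation and morphological descriptors.

Measures follow the conventions of commercial particle analyzers:

* **Max Feret diameter (MFD)** — the largest distance between two
  parallel supporting lines of the particle outline ("length").
* **Min Feret diameter** — the smallest such caliper width ("width").
* **Circularity** — perimeter-equivalence form ``2 sqrt(pi A) / P``
  (1 for a perfect circle, approaching 0 for elongated objects).
* **SE volume** — sphere-equivalent volume ``(pi/6) CED^3`` with the
  circular-equivalent diameter ``CED = 2 sqrt(A / pi)``.

All caliper measures use the *pixel-corner* (outer boundary)
convention: the convex hull is built from the corner points of the
particle's pixels, so a single pixel has MFD sqrt(2) and a 1 x n pixel
line has width exactly 1.  Feret diameters are computed by rotating
calipers on that hull; a brute-force hull-vertex pairwise scan gives
identical values and serves as the independent oracle in the tests.

The perimeter is the length of the traced half-level boundary polygon
after one vertex-averaging pass, which removes the staircase bias of
the raw marching-squares contour (a rasterized disk then measures
within ~1% of ``2 pi r``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from skimage import filters, measure, morphology

from .errors import EmptyRegionError, ConfigError

__all__ = [
    "ParticleRecord",
    "SegmentationParams",
    "ShapeRules",
    "segment_particles",
    "hull_corner_points",
    "max_feret",
    "min_feret",
    "perimeter_length",
    "circularity",
    "se_volume",
    "solidity",
    "measure_particle",
    "classify_shape",
    "size_material_heatmap",
    "records_to_dataframe",
    "PARTICLE_CSV_COLUMNS",
]


@dataclass
class ParticleRecord:
    """Morphometric and polarimetric descriptors of one segmented particle."""

    id: int
    mask: np.ndarray
    frame: int = 0
    centroid_px: tuple[float, float] = (0.0, 0.0)  # (row, col)
    area_um2: float = 0.0
    perimeter_um: float = 0.0
    mfd_um: float = 0.0
    width_um: float = 0.0
    circularity: float = 0.0
    se_volume_um3: float = 0.0
    solidity: float = 1.0
    shape_class: str | None = None
    material_class: str | None = None
    ssd_mean: float = float("nan")
    ssd_p90: float = float("nan")
    dolp_mean: float = float("nan")
    transmittance_mean: float | None = None

    @property
    def aspect(self) -> float:
        return self.mfd_um / self.width_um if self.width_um > 0 else float("inf")


@dataclass
class SegmentationParams:
    """Classical threshold-based segmentation settings.

    ``source`` documents which image the params are meant for
    (amplitude, SSD or raw intensity); ``polarity`` selects whether
    particles are brighter or darker than background ("auto" picks the
    minority side after thresholding).
    """

    source: str = "amplitude"
    threshold_method: str = "otsu"  # "otsu" | "fixed"
    threshold_value: float | None = None
    polarity: str = "auto"  # "bright" | "dark" | "auto"
    min_area: int = 20
    closing_radius: int = 1
    smoothing_sigma: float = 0.0

    def __post_init__(self):
        if self.min_area < 1:
            raise ConfigError("min_area must be >= 1")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ConfigError(f"unknown threshold method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.threshold_value is None:
            raise ConfigError("fixed thresholding requires threshold_value")
        if self.polarity not in ("bright", "dark", "auto"):
            raise ConfigError(f"unknown polarity {self.polarity!r}")


def segment_particles(image: np.ndarray, params: SegmentationParams) -> list[np.ndarray]:
    """Threshold, clean and label an image into disjoint particle masks.

    Pipeline: optional Gaussian smoothing -> global threshold (Otsu by
    default) -> morphological closing -> 8-connected components ->
    discard components below ``min_area``.  A blank (constant) image
    yields an empty list rather than an error.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("segmentation expects a single-channel image")
    if params.smoothing_sigma > 0:
        img = filters.gaussian(img, sigma=params.smoothing_sigma, preserve_range=True)
    if img.size == 0 or img.max() == img.min():
        return []
    if params.threshold_method == "fixed":
        thr = float(params.threshold_value)
    else:
        thr = float(filters.threshold_otsu(img))
    if params.polarity == "bright":
        fg = img > thr
    elif params.polarity == "dark":
        fg = img < thr
    else:
        above = img > thr
        fg = above if above.sum() <= (~above).sum() else ~above
    if params.closing_radius > 0:
        fg = morphology.closing(fg, morphology.disk(params.closing_radius))
    labels = measure.label(fg, connectivity=2)
    masks = []
    for lbl in range(1, labels.max() + 1):
        m = labels == lbl
        if m.sum() >= params.min_area:
            masks.append(m)
    return masks


# ---------------------------------------------------------------------------
# caliper geometry


def hull_corner_points(mask: np.ndarray) -> np.ndarray:
    """Convex-hull vertices (x, y) of the pixel-corner point cloud, CCW.

    Only boundary pixels contribute corners, which keeps the hull cheap
    on large masks without changing it.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRegionError("mask has no pixels")
    interior = morphology.erosion(mask, morphology.footprint_rectangle((3, 3)))
    boundary = mask & ~interior
    rr, cc = np.nonzero(boundary)
    corners = np.concatenate(
        [np.stack([cc + dx, rr + dy], axis=1) for dx in (0, 1) for dy in (0, 1)]
    ).astype(float)
    corners = np.unique(corners, axis=0)
    hull = ConvexHull(corners)
    return corners[hull.vertices]  # scipy returns CCW order in 2-D


def _caliper_max(pts: np.ndarray) -> float:
    """Diameter of a convex polygon via rotating calipers (antipodal pairs)."""
    m = len(pts)
    if m == 2:
        return float(np.hypot(*(pts[1] - pts[0])))

    def cross_area(i, j, k):
        a = pts[j] - pts[i]
        b = pts[k] - pts[i]
        return a[0] * b[1] - a[1] * b[0]

    best = 0.0
    k = 1
    for i in range(m):
        j = (i + 1) % m
        while cross_area(i, j, (k + 1) % m) > cross_area(i, j, k):
            k = (k + 1) % m
        for cand in (k, (k + 1) % m):
            for base in (i, j):
                d = float(np.hypot(*(pts[cand] - pts[base])))
                if d > best:
                    best = d
    return best


def _caliper_min_width(pts: np.ndarray) -> float:
    """Minimum width of a convex polygon: for each edge, the farthest
    vertex distance to the edge's supporting line; take the minimum."""
    m = len(pts)
    if m == 2:
        return 0.0
    best = np.inf
    for i in range(m):
        p = pts[i]
        e = pts[(i + 1) % m] - p
        norm = np.hypot(*e)
        if norm == 0:
            continue
        d = np.abs(e[0] * (pts[:, 1] - p[1]) - e[1] * (pts[:, 0] - p[0])) / norm
        best = min(best, float(d.max()))
    return best


def max_feret(mask: np.ndarray, pitch: float = 1.0) -> float:
    """Maximum Feret diameter (length) in physical units (``pitch`` per px)."""
    return _caliper_max(hull_corner_points(mask)) * pitch


def min_feret(mask: np.ndarray, pitch: float = 1.0) -> float:
    """Minimum Feret diameter (width) in physical units."""
    return _caliper_min_width(hull_corner_points(mask)) * pitch


# ---------------------------------------------------------------------------
# boundary, area and derived scalars


def perimeter_length(mask: np.ndarray, pitch: float = 1.0) -> float:
    """Length of the traced boundary polygon (all contours, holes included).

    One circular vertex-averaging pass removes the marching-squares
    staircase bias before the polygon length is summed.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRegionError("mask has no pixels")
    padded = np.pad(mask, 1).astype(float)
    total = 0.0
    for contour in measure.find_contours(padded, 0.5):
        closed = np.allclose(contour[0], contour[-1])
        pts = contour[:-1] if closed else contour
        if len(pts) >= 3:
            pts = (np.roll(pts, 1, axis=0) + pts + np.roll(pts, -1, axis=0)) / 3.0
        loop = np.vstack([pts, pts[:1]]) if closed else pts
        total += float(np.sum(np.hypot(*np.diff(loop, axis=0).T)))
    return total * pitch


def circularity(mask: np.ndarray, pitch: float = 1.0, form: str = "perimeter_equivalent") -> float:
    """Shape circularity in (0, 1].

    ``perimeter_equivalent`` (default) is ``2 sqrt(pi A) / P``, the
    convention of Morphologi-style particle analyzers; ``iso`` is the
    squared form ``4 pi A / P^2``.
    """
    a = float(np.asarray(mask, dtype=bool).sum()) * pitch**2
    p = perimeter_length(mask, pitch)
    if p <= 0:
        raise EmptyRegionError("degenerate boundary (zero perimeter)")
    if form == "perimeter_equivalent":
        return 2.0 * np.sqrt(np.pi * a) / p
    if form == "iso":
        return 4.0 * np.pi * a / p**2
    raise ConfigError(f"unknown circularity form {form!r}")


def se_volume(mask: np.ndarray, pitch: float = 1.0) -> float:
    """Sphere-equivalent volume from the circular-equivalent diameter."""
    n = int(np.asarray(mask, dtype=bool).sum())
    if n == 0:
        raise EmptyRegionError("mask has no pixels")
    ced = 2.0 * np.sqrt(n / np.pi) * pitch
    return np.pi / 6.0 * ced**3


def solidity(mask: np.ndarray) -> float:
    """Pixel area divided by the area of the pixel-corner convex hull."""
    mask = np.asarray(mask, dtype=bool)
    pts = hull_corner_points(mask)
    hull_area = ConvexHull(pts).volume  # 2-D: "volume" is the area
    return float(mask.sum()) / hull_area if hull_area > 0 else 1.0


# ---------------------------------------------------------------------------
# records and classification


def measure_particle(
    mask: np.ndarray,
    pitch: float,
    pid: int = 0,
    frame: int = 0,
    ssd=None,
    dolp=None,
    transmittance: np.ndarray | None = None,
) -> ParticleRecord:
    """Fill a :class:`ParticleRecord` from a mask and optional feature maps.

    ``pitch`` is the object-plane pixel size in metres; outputs are in
    micrometres.  ``ssd``/``dolp`` accept :class:`~holopol.polarimetry.FeatureMap`
    instances; statistics respect their validity masks.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRegionError("mask has no pixels")
    um = pitch * 1e6
    rr, cc = np.nonzero(mask)
    rec = ParticleRecord(
        id=pid,
        mask=mask,
        frame=frame,
        centroid_px=(float(rr.mean()), float(cc.mean())),
        area_um2=float(mask.sum()) * um**2,
        perimeter_um=perimeter_length(mask, um),
        mfd_um=max_feret(mask, um),
        width_um=min_feret(mask, um),
        circularity=circularity(mask),
        se_volume_um3=se_volume(mask, um),
        solidity=solidity(mask),
    )
    for attr_mean, attr_p90, fmap in (("ssd_mean", "ssd_p90", ssd), ("dolp_mean", None, dolp)):
        if fmap is not None:
            sel = mask & fmap.valid
            if sel.any():
                vals = fmap.values[sel]
                setattr(rec, attr_mean, float(vals.mean()))
                if attr_p90:
                    setattr(rec, attr_p90, float(np.percentile(vals, 90)))
    if transmittance is not None:
        rec.transmittance_mean = float(np.asarray(transmittance, dtype=float)[mask].mean())
    return rec


@dataclass(frozen=True)
class ShapeRules:
    """Thresholds for the rule-cascade shape classifier (applied in order:
    fiber, bead, pellet, foam, film, else fragment)."""

    fiber_min_aspect: float = 5.0
    bead_min_circularity: float = 0.92
    bead_max_aspect: float = 1.2
    pellet_min_circularity: float = 0.85
    pellet_max_aspect: float = 1.5
    foam_max_solidity: float = 0.85
    film_min_transmittance: float = 0.9
    film_min_area_um2: float = 5e5


def classify_shape(record: ParticleRecord, rules: ShapeRules = ShapeRules()) -> str:
    """Assign one of the six shape classes from morphometric descriptors."""
    aspect = record.aspect
    if aspect >= rules.fiber_min_aspect:
        return "fiber"
    if record.circularity >= rules.bead_min_circularity and aspect <= rules.bead_max_aspect:
        return "bead"
    if record.circularity >= rules.pellet_min_circularity and aspect <= rules.pellet_max_aspect:
        return "pellet"
    if record.solidity < rules.foam_max_solidity:
        return "foam"
    if (
        record.transmittance_mean is not None
        and record.transmittance_mean >= rules.film_min_transmittance
        and record.area_um2 >= rules.film_min_area_um2
    ):
        return "film"
    return "fragment"


def size_material_heatmap(
    records: list[ParticleRecord], size_bin_edges_mm: list[float]
) -> pd.DataFrame:
    """Count labelled records per (material, MFD size bin).

    Bins are half-open ``[lo, hi)`` in millimetres.  Rows are sorted
    material labels; records without a material label are skipped.
    """
    edges = np.asarray(size_bin_edges_mm, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("size_bin_edges_mm must be increasing with >= 2 entries")
    labelled = [r for r in records if r.material_class is not None]
    materials = sorted({r.material_class for r in labelled})
    cols = [f"[{lo:g},{hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
    counts = pd.DataFrame(0, index=materials, columns=cols, dtype=int)
    for r in labelled:
        mm = r.mfd_um / 1000.0
        idx = np.searchsorted(edges, mm, side="right") - 1
        if 0 <= idx < len(cols) and mm < edges[-1]:
            counts.loc[r.material_class, cols[idx]] += 1
    return counts


PARTICLE_CSV_COLUMNS = [
    "id", "frame", "cx_px", "cy_px", "area_um2", "mfd_um", "width_um",
    "circularity", "se_volume_um3", "shape", "material", "ssd_mean", "dolp_mean",
]


def records_to_dataframe(records: list[ParticleRecord]) -> pd.DataFrame:
    """Flatten records to the fixed-column particle table."""
    rows = []
    for r in records:
        rows.append({
            "id": r.id,
            "frame": r.frame,
            "cx_px": r.centroid_px[1],
            "cy_px": r.centroid_px[0],
            "area_um2": r.area_um2,
            "mfd_um": r.mfd_um,
            "width_um": r.width_um,
            "circularity": r.circularity,
            "se_volume_um3": r.se_volume_um3,
            "shape": r.shape_class,
            "material": r.material_class,
            "ssd_mean": r.ssd_mean,
            "dolp_mean": r.dolp_mean,
        })
    return pd.DataFrame(rows, columns=PARTICLE_CSV_COLUMNS)
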