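"""End-to-end processing: mosaics -> features -> detect -> track -> classify.

The per-frame chain demosaics the capture, computes Stokes/DoLP/SSD
maps, detects particles on the SSD image (birefringent particles stand
out on a near-zero background there), links detections into tracks,
and classifies each confirmed track's material from its pooled
polarimetric features.  :func:`run_pipeline` wraps the chain with file
I/O, logging and a JSON summary for the command line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import classification as clf
from .errors import StageError
from .morphometry import SegmentationParams, records_to_dataframe, measure_particle, classify_shape
from .polarimetry import MosaicLayout, DEFAULT_LAYOUT, split_mosaic, stokes_maps, dolp_map, ssd_map
from .scene import OpticalConfig
from .tracking import TrackParams, detect_frame, link_tracks, count_and_score

logger = logging.getLogger("holopol")

__all__ = ["FrameFeatures", "compute_frame_features", "process_video", "run_pipeline"]


@dataclass
class FrameFeatures:
    """Feature maps derived from one mosaic frame.

    ``raw_ssd`` is always computed from the as-recorded channels (used
    for detection); ``stokes``/``dolp``/``ssd``/``transmittance`` are
    the maps used for particle feature statistics and come from the
    refocused channels when a refocus depth was given.
    """

    raw_ssd: object
    stokes: object
    dolp: object
    ssd: object
    transmittance: np.ndarray


def _refocus_channel(channel: np.ndarray, pitch: float, wavelength: float, z: float):
    """Channel intensity back-propagated to the object plane.

    The raw channel (DC retained, so the undiffracted reference stays
    phase-aligned with the real image) is treated as a complex field
    and back-propagated; its squared modulus approximates the channel
    intensity at the particle plane, restoring the interior
    birefringence plateau that diffraction smears at the detector.
    """
    from .holography import ComplexField, angular_spectrum_propagate

    f = angular_spectrum_propagate(
        ComplexField(channel.astype(complex), pitch, wavelength), -z
    )
    return np.abs(f.data) ** 2


def compute_frame_features(
    mosaic: np.ndarray,
    layout: MosaicLayout = DEFAULT_LAYOUT,
    pitch: float = 1.0,
    refocus_z: float | None = None,
    wavelength: float = 632.8e-9,
) -> FrameFeatures:
    """Demosaic and derive Stokes, DoLP, SSD and a transmittance image.

    With ``refocus_z`` set, the four channels are numerically refocused
    to the particle plane before the statistics maps are computed
    (detection keeps using the raw-hologram SSD, which is cheap and
    robust).  The amplitude-transmittance image is ``sqrt(I /
    median(I))``: with near-unit illumination the background median of
    the total intensity is the reference level, so particle pixels read
    their amplitude transmittance.
    """
    stack = split_mosaic(mosaic, layout, pitch)
    raw_ssd = ssd_map(stack)
    if refocus_z is not None:
        stack = type(stack)(
            *[
                _refocus_channel(c, pitch, wavelength, refocus_z)
                for c in (stack.I0, stack.I45, stack.I90, stack.I135)
            ],
            pitch,
        )
    s = stokes_maps(stack)
    ref = float(np.median(s.I))
    trans = np.sqrt(np.clip(s.I / ref, 0.0, None)) if ref > 0 else np.ones_like(s.I)
    return FrameFeatures(raw_ssd, s, dolp_map(s), ssd_map(stack), trans)


def process_video(
    mosaics: list[np.ndarray],
    layout: MosaicLayout = DEFAULT_LAYOUT,
    seg_params: SegmentationParams | None = None,
    track_params: TrackParams | None = None,
    cfg: OpticalConfig | None = None,
    model: clf.CentroidModel | None = None,
    erode_px: int = 2,
    refocus_z: float | None = None,
    truth=None,
) -> dict:
    """Run detection, tracking, counting and (optionally) classification.

    Returns a dict with per-frame detections, tracks, the
    :class:`~holopol.tracking.CountReport`, per-track feature vectors
    and, when a model is given, per-track material predictions.
    """
    cfg = cfg or OpticalConfig()
    seg_params = seg_params or SegmentationParams(
        source="SSD", threshold_method="fixed", threshold_value=0.02,
        polarity="bright", min_area=25, closing_radius=2, smoothing_sigma=1.5,
    )
    track_params = track_params or TrackParams()

    frames: list[FrameFeatures] = []
    detections_by_frame = []
    for f, mosaic in enumerate(mosaics):
        feats = compute_frame_features(
            mosaic, layout, cfg.channel_pitch, refocus_z, cfg.wavelength
        )
        frames.append(feats)
        detections_by_frame.append(detect_frame(feats.raw_ssd.values, seg_params, frame=f))

    tracks = link_tracks(detections_by_frame, track_params)
    report = count_and_score(tracks, truth)

    confirmed = [t for t in tracks if t.ever_confirmed]
    track_features = {}
    for t in confirmed:
        vecs = []
        for d in t.detections:
            if d.mask is None:
                continue
            ff = frames[d.frame]
            try:
                vecs.append(
                    clf.extract_features(
                        d.mask, ff.ssd, ff.dolp, ff.transmittance, erode_px=erode_px
                    )
                )
            except Exception:
                continue
        if vecs:
            track_features[t.id] = np.mean(vecs, axis=0)

    predictions = {}
    if model is not None and track_features:
        tids = sorted(track_features)
        labels, margins = clf.predict(model, np.stack([track_features[i] for i in tids]))
        predictions = {tid: lab for tid, lab in zip(tids, labels)}

    return {
        "frames": frames,
        "detections_by_frame": detections_by_frame,
        "tracks": tracks,
        "report": report,
        "track_features": track_features,
        "predictions": predictions,
    }


def _tracks_dataframe(tracks):
    import pandas as pd

    rows = [
        {"track_id": t.id, "frame": d.frame, "cx": d.centroid[1], "cy": d.centroid[0],
         "state": t.state}
        for t in tracks
        for d in t.detections
    ]
    return pd.DataFrame(rows, columns=["track_id", "frame", "cx", "cy", "state"])


def run_pipeline(config, input_path) -> dict:
    """File-level pipeline: read a mosaic video, process, write a report bundle.

    Outputs under ``config.output_dir``: per-first-frame feature maps
    (float32 TIFF), ``particles.csv``, ``tracks.csv`` and
    ``summary.json``.  Deterministic given identical inputs and config;
    a failing stage raises a :class:`~holopol.errors.StageError` naming
    the stage, leaving earlier outputs in place.
    """
    from . import io as hio

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    logger.info("run_pipeline: input=%s seed=%d", input_path, config.seed)
    logger.info("segmentation=%s tracking=%s", config.segmentation, config.tracking)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        mosaics = hio.read_mosaic_video(input_path)
    except Exception as exc:
        raise StageError("read", str(exc)) from exc

    model = None
    if config.model_path:
        try:
            model = clf.CentroidModel.from_json(Path(config.model_path).read_text())
        except Exception as exc:
            raise StageError("classify", f"cannot load model: {exc}") from exc

    try:
        result = process_video(
            mosaics,
            layout=config.layout,
            seg_params=config.segmentation,
            track_params=config.tracking,
            cfg=config.optical,
            model=model,
            erode_px=config.erode_px,
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("process", str(exc)) from exc

    try:
        ff = result["frames"][0]
        hio.write_tiff(out / "ssd_frame0.tiff", ff.ssd.values.astype(np.float32))
        hio.write_tiff(out / "dolp_frame0.tiff", ff.dolp.values.astype(np.float32))
        pitch = config.optical.object_pixel_pitch
        records = []
        for f, dets in enumerate(result["detections_by_frame"]):
            feats = result["frames"][f]
            for i, d in enumerate(dets):
                rec = measure_particle(
                    d.mask, pitch, pid=i, frame=f, ssd=feats.ssd, dolp=feats.dolp,
                    transmittance=feats.transmittance,
                )
                rec.shape_class = classify_shape(rec)
                records.append(rec)
        records_to_dataframe(records).to_csv(out / "particles.csv", index=False)
        _tracks_dataframe(result["tracks"]).to_csv(out / "tracks.csv", index=False)
        report = result["report"]
        summary = {
            "n_frames": len(mosaics),
            "estimated_count": report.estimated_count,
            "n_tracks_total": report.n_tracks_total,
            "n_detections": sum(len(d) for d in result["detections_by_frame"]),
            "predictions": {str(k): v for k, v in result["predictions"].items()},
            "seed": config.seed,
        }
        hio.write_json(out / "summary.json", summary)
    except Exception as exc:
        raise StageError("write", str(exc)) from exc
    logger.info("estimated count: %d", report.estimated_count)
    return summary
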