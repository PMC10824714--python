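"""Frame-to-frame particle linking and counting for flowing video.

A deliberately transparent multi-object tracker: detections come from
classical threshold segmentation, and links are made by a
constant-velocity greedy nearest-neighbour assignment with a distance
gate.  Tracks are confirmed after ``m_confirm`` consecutive hits
(filtering transient noise blobs) and terminated after ``k_miss``
consecutive misses; the particle count is the number of tracks that
were ever confirmed.  There is no appearance model — at the low number
densities of a flow cell, gating on predicted position is sufficient
and keeps the whole stage deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .morphometry import SegmentationParams, segment_particles

__all__ = [
    "Detection",
    "Track",
    "TrackParams",
    "CountReport",
    "detect_frame",
    "link_tracks",
    "count_and_score",
]


@dataclass
class Detection:
    """One segmented particle in one frame."""

    frame: int
    centroid: tuple[float, float]  # (row, col) px
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    mask: np.ndarray | None = None
    area_px: int = 0
    mfd_px: float = 0.0


@dataclass
class Track:
    """An identity linked over frames."""

    id: int
    detections: list[Detection] = field(default_factory=list)
    state: str = "tentative"  # tentative | confirmed | terminated
    ever_confirmed: bool = False
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(2))
    consecutive_hits: int = 0
    consecutive_misses: int = 0

    @property
    def last(self) -> Detection:
        return self.detections[-1]

    def frames(self) -> list[int]:
        return [d.frame for d in self.detections]


@dataclass
class TrackParams:
    gate_px: float = 30.0
    m_confirm: int = 3
    k_miss: int = 5

    def __post_init__(self):
        if self.gate_px < 0:
            raise ValueError("gate_px must be >= 0")
        if self.m_confirm < 1 or self.k_miss < 1:
            raise ValueError("m_confirm and k_miss must be >= 1")


@dataclass
class CountReport:
    """Counting result and (when ground truth is known) its accuracy."""

    estimated_count: int
    n_tracks_total: int
    counting_accuracy: float | None = None
    per_particle_matched: dict[int, int] | None = None  # truth id -> track id
    per_particle_correct_rate: float | None = None


def detect_frame(
    image: np.ndarray, params: SegmentationParams, frame: int = 0
) -> list[Detection]:
    """Segment one feature image into detections (one per mask)."""
    detections = []
    for mask in segment_particles(image, params):
        rr, cc = np.nonzero(mask)
        detections.append(
            Detection(
                frame=frame,
                centroid=(float(rr.mean()), float(cc.mean())),
                bbox=(int(rr.min()), int(cc.min()), int(rr.max()) + 1, int(cc.max()) + 1),
                mask=mask,
                area_px=int(mask.sum()),
            )
        )
    return detections


def link_tracks(
    detections_by_frame: list[list[Detection]], params: TrackParams = TrackParams()
) -> list[Track]:
    """Greedy constant-velocity linking of per-frame detections.

    Per frame: each live track predicts its position by extrapolating
    its last matched position with its velocity estimate; (track,
    detection) pairs within the gate are assigned greedily in order of
    increasing distance (ties favour the lower track id).  Unmatched
    detections spawn tentative tracks; the velocity estimate is the
    displacement between the last two matched positions per frame (zero
    for single-detection tracks).
    """
    tracks: list[Track] = []
    next_id = 0
    for f, dets in enumerate(detections_by_frame):
        live = [t for t in tracks if t.state != "terminated"]
        # predictions
        preds = {}
        for t in live:
            gap = f - t.last.frame
            preds[t.id] = np.asarray(t.last.centroid) + t.velocity * gap
        # candidate pairs within the gate, sorted by (distance, track id)
        pairs = []
        for t in live:
            for di, d in enumerate(dets):
                dist = float(np.hypot(*(preds[t.id] - np.asarray(d.centroid))))
                if dist <= params.gate_px:
                    pairs.append((dist, t.id, di))
        pairs.sort()
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        by_id = {t.id: t for t in live}
        for dist, tid, di in pairs:
            if tid in used_tracks or di in used_dets:
                continue
            used_tracks.add(tid)
            used_dets.add(di)
            t = by_id[tid]
            d = dets[di]
            gap = d.frame - t.last.frame
            t.velocity = (np.asarray(d.centroid) - np.asarray(t.last.centroid)) / max(gap, 1)
            t.detections.append(d)
            t.consecutive_hits += 1
            t.consecutive_misses = 0
            if t.state == "tentative" and t.consecutive_hits >= params.m_confirm:
                t.state = "confirmed"
                t.ever_confirmed = True
        # misses
        for t in live:
            if t.id not in used_tracks:
                t.consecutive_hits = 0
                t.consecutive_misses += 1
                if t.consecutive_misses >= params.k_miss:
                    t.state = "terminated"
        # births
        for di, d in enumerate(dets):
            if di not in used_dets:
                t = Track(id=next_id, detections=[d], consecutive_hits=1)
                next_id += 1
                if params.m_confirm <= 1:
                    t.state = "confirmed"
                    t.ever_confirmed = True
                tracks.append(t)
    return tracks


def count_and_score(
    tracks: list[Track],
    truth=None,
    match_radius_px: float = 12.0,
    min_overlap: float = 0.5,
) -> CountReport:
    """Count confirmed tracks; score against ground truth when available.

    Counting accuracy is ``1 - |count - true| / true``.  Each confirmed
    track is matched to the ground-truth particle whose trajectory it
    overlaps most (a frame overlaps when both are present and the
    centroids are within ``match_radius_px``); the match requires at
    least ``min_overlap`` of the track's frames.  A truth particle is
    correctly counted when at least one track matches it.
    """
    confirmed = [t for t in tracks if t.ever_confirmed]
    report = CountReport(estimated_count=len(confirmed), n_tracks_total=len(tracks))
    if truth is None:
        return report
    true_count = truth.count
    if true_count > 0:
        report.counting_accuracy = max(0.0, 1.0 - abs(len(confirmed) - true_count) / true_count)
    matched: dict[int, int] = {}
    for t in confirmed:
        track_pos = {d.frame: np.asarray(d.centroid) for d in t.detections}
        best_pid, best_frac = None, 0.0
        for pid, traj in truth.trajectories.items():
            n_hit = sum(
                1
                for (fr, r, c) in traj
                if fr in track_pos
                and float(np.hypot(*(track_pos[fr] - np.array([r, c])))) <= match_radius_px
            )
            frac = n_hit / len(t.detections)
            if frac > best_frac:
                best_pid, best_frac = pid, frac
        if best_pid is not None and best_frac >= min_overlap and best_pid not in matched:
            matched[best_pid] = t.id
    report.per_particle_matched = matched
    if true_count > 0:
        report.per_particle_correct_rate = len(matched) / true_count
    return report
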