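"""Per-track Kalman filtering, IoU-gated optimal assignment, and track
lifecycle management.

The track state is the 8-vector ``[u, v, s, r, du, dv, ds, dr]``: box center,
box area, width/height aspect ratio, and their per-frame rates. All four
measured components — including the aspect ratio — evolve under a discrete
constant-velocity model (dt = 1 frame), so a box whose shape drifts from
frame to frame (leaf motion, viewing angle) is still trackable.

Detections are associated to predicted track boxes by a maximum-total-IoU
one-to-one assignment (Hungarian method); assigned pairs below the IoU gate
are demoted to unmatched on both sides. An unmatched track coasts on its
prediction and is deleted once it has gone more than ``max_age`` consecutive
frames without an update.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import Box, Measurement, box_to_measurement, iou, measurement_to_box

__all__ = [
    "TrackerConfig",
    "Track",
    "AssociationResult",
    "kf_predict",
    "kf_update",
    "init_track",
    "associate",
    "step_tracks",
    "MultiObjectTracker",
]

_DIM_X = 8
_DIM_Z = 4

# Transition: constant velocity on (u, v, s, r); rates persist.
_F = np.eye(_DIM_X)
_F[:_DIM_Z, _DIM_Z:] = np.eye(_DIM_Z)

# Observation: the detector reports (u, v, s, r) only.
_H = np.zeros((_DIM_Z, _DIM_X))
_H[:, :_DIM_Z] = np.eye(_DIM_Z)

# Floor applied to predicted s and r before conversion back to a box; the
# filter state itself is never clamped.
_EPS_POSITIVE = 1e-6


@dataclass(frozen=True)
class TrackerConfig:
    """Tunable parameters of the tracker.

    The gate and the noise scales are deliberately exposed: the state model
    fixes only the structure of F and H, not the magnitudes.
    """

    iou_threshold: float = 0.3
    max_age: int = 2
    process_noise_position: float = 1.0  # Q diagonal on u, v, s, r
    process_noise_rate: float = 0.01  # Q diagonal on the four rates
    measurement_noise_center: float = 1.0  # R diagonal on u, v (px^2)
    measurement_noise_area: float = 10.0  # R diagonal on s
    measurement_noise_aspect: float = 0.01  # R diagonal on r
    initial_rate_variance_multiplier: float = 1000.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.iou_threshold <= 1.0:
            raise ValueError("iou_threshold must lie in [0, 1]")
        if self.max_age < 0:
            raise ValueError("max_age must be nonnegative")

    def process_noise(self) -> np.ndarray:
        q = np.empty(_DIM_X)
        q[:_DIM_Z] = self.process_noise_position
        q[_DIM_Z:] = self.process_noise_rate
        return np.diag(q)

    def measurement_noise(self) -> np.ndarray:
        return np.diag(
            [
                self.measurement_noise_center,
                self.measurement_noise_center,
                self.measurement_noise_area,
                self.measurement_noise_aspect,
            ]
        )

    def initial_covariance(self) -> np.ndarray:
        p = np.empty(_DIM_X)
        p[:_DIM_Z] = np.diag(self.measurement_noise())
        p[_DIM_Z:] = p[:_DIM_Z] * self.initial_rate_variance_multiplier
        return np.diag(p)


@dataclass
class Track:
    """One tracked object: identity, filter state, and lifecycle counters."""

    id: int
    state: np.ndarray  # shape (8,)
    covariance: np.ndarray  # shape (8, 8)
    time_since_update: int = 0
    hits: int = 1
    counted: bool = False
    prev_center: Optional[Tuple[float, float]] = None
    curr_center: Optional[Tuple[float, float]] = None

    def predicted_box(self) -> Box:
        """Current state as a box, with s and r floored to stay valid."""
        u, v, s, r = self.state[:_DIM_Z]
        s = max(s, _EPS_POSITIVE)
        r = max(r, _EPS_POSITIVE)
        return measurement_to_box(Measurement(u=u, v=v, s=s, r=r))


@dataclass(frozen=True)
class AssociationResult:
    """Partition of tracks and detections produced by one association step."""

    matches: Tuple[Tuple[int, int], ...]  # (track id, detection index)
    unmatched_detections: Tuple[int, ...]
    unmatched_tracks: Tuple[int, ...]


def _symmetrize(p: np.ndarray) -> np.ndarray:
    return (p + p.T) / 2.0


def kf_predict(
    state: np.ndarray, cov: np.ndarray, process_noise: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Time update: propagate one frame under constant velocity.

    Returns the prior state and covariance; the covariance is re-symmetrized
    to keep round-off from accumulating.
    """
    state = np.asarray(state, dtype=float)
    cov = np.asarray(cov, dtype=float)
    x = _F @ state
    p = _F @ cov @ _F.T + process_noise
    return x, _symmetrize(p)


def kf_update(
    state: np.ndarray,
    cov: np.ndarray,
    z: Measurement,
    measurement_noise: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """Measurement update against an observed (u, v, s, r).

    Uses the Joseph-form covariance update, which preserves symmetry and
    positive semidefiniteness even with a zero measurement-noise matrix.

    Raises
    ------
    np.linalg.LinAlgError
        If the innovation covariance is singular.
    """
    state = np.asarray(state, dtype=float)
    cov = np.asarray(cov, dtype=float)
    zv = np.array([z.u, z.v, z.s, z.r], dtype=float)

    y = zv - _H @ state
    s_innov = _H @ cov @ _H.T + measurement_noise
    k = cov @ _H.T @ np.linalg.inv(s_innov)
    x = state + k @ y
    ikh = np.eye(_DIM_X) - k @ _H
    p = ikh @ cov @ ikh.T + k @ measurement_noise @ k.T
    return x, _symmetrize(p)


def init_track(det: Box, next_id: int, config: Optional[TrackerConfig] = None) -> Track:
    """Start a new track from an unmatched detection.

    The measured components come from the box; the rates start at zero with
    large variance, since a single observation says nothing about velocity.
    """
    if config is None:
        config = TrackerConfig()
    m = box_to_measurement(det)
    state = np.zeros(_DIM_X)
    state[:_DIM_Z] = (m.u, m.v, m.s, m.r)
    track = Track(id=next_id, state=state, covariance=config.initial_covariance())
    track.curr_center = (m.u, m.v)
    return track


def associate(
    detections: Sequence[Box],
    predicted_tracks: Sequence[Tuple[int, Box]],
    iou_threshold: float,
) -> AssociationResult:
    """Assign detections to predicted track boxes.

    The assignment maximizes total IoU over one-to-one pairings; any chosen
    pair whose IoU falls below ``iou_threshold`` is then rejected, leaving
    both sides unmatched. Every track and every detection appears exactly
    once across the three result sets.
    """
    if not 0.0 <= iou_threshold <= 1.0:
        raise ValueError("iou_threshold must lie in [0, 1]")

    n_det = len(detections)
    n_trk = len(predicted_tracks)
    if n_det == 0 or n_trk == 0:
        return AssociationResult(
            matches=(),
            unmatched_detections=tuple(range(n_det)),
            unmatched_tracks=tuple(tid for tid, _ in predicted_tracks),
        )

    iou_matrix = np.zeros((n_trk, n_det))
    for i, (_, tbox) in enumerate(predicted_tracks):
        for j, det in enumerate(detections):
            iou_matrix[i, j] = iou(tbox, det)

    rows, cols = linear_sum_assignment(-iou_matrix)

    matches: List[Tuple[int, int]] = []
    matched_tracks = set()
    matched_dets = set()
    for i, j in zip(rows, cols):
        if iou_matrix[i, j] >= iou_threshold and iou_matrix[i, j] > 0.0:
            matches.append((predicted_tracks[i][0], j))
            matched_tracks.add(i)
            matched_dets.add(j)
    matches.sort()

    return AssociationResult(
        matches=tuple(matches),
        unmatched_detections=tuple(
            j for j in range(n_det) if j not in matched_dets
        ),
        unmatched_tracks=tuple(
            predicted_tracks[i][0] for i in range(n_trk) if i not in matched_tracks
        ),
    )


def step_tracks(
    tracks: List[Track],
    detections: Sequence[Box],
    config: TrackerConfig,
    next_id: Optional[int] = None,
) -> Tuple[List[Track], AssociationResult]:
    """Advance the tracker by one frame.

    Predict every track, associate the predictions with the detections,
    update matched tracks, age unmatched ones, spawn tracks for unmatched
    detections, and drop tracks older than ``max_age``. Centers before and
    after the step are recorded on each surviving track so the caller can
    test the inter-frame trace against a finish line.

    ``next_id`` is the first id to hand to a newly spawned track; when None
    it defaults to one past the largest live id (callers that must guarantee
    no id reuse across total track extinction should pass it explicitly —
    see :class:`MultiObjectTracker`).
    """
    if next_id is None:
        next_id = max((t.id for t in tracks), default=0) + 1

    q = config.process_noise()
    r = config.measurement_noise()

    for track in tracks:
        track.prev_center = track.curr_center
        track.state, track.covariance = kf_predict(track.state, track.covariance, q)
        track.curr_center = (track.state[0], track.state[1])

    result = associate(
        detections,
        [(t.id, t.predicted_box()) for t in tracks],
        config.iou_threshold,
    )

    by_id = {t.id: t for t in tracks}
    for track_id, det_idx in result.matches:
        track = by_id[track_id]
        z = box_to_measurement(detections[det_idx])
        track.state, track.covariance = kf_update(track.state, track.covariance, z, r)
        track.time_since_update = 0
        track.hits += 1
        track.curr_center = (track.state[0], track.state[1])
    for track_id in result.unmatched_tracks:
        by_id[track_id].time_since_update += 1

    for det_idx in result.unmatched_detections:
        tracks.append(init_track(detections[det_idx], next_id, config))
        next_id += 1

    survivors = [t for t in tracks if t.time_since_update <= config.max_age]
    return survivors, result


class MultiObjectTracker:
    """Stateful wrapper around :func:`step_tracks` guaranteeing id uniqueness.

    Keeps the live track list and a monotone id counter, so track ids are
    never reused within a run even if every track dies.
    """

    def __init__(self, config: Optional[TrackerConfig] = None) -> None:
        self.config = config if config is not None else TrackerConfig()
        self.tracks: List[Track] = []
        self._next_id = 1
        self.created = 0
        self.deleted = 0

    def step(self, detections: Sequence[Box]) -> AssociationResult:
        before_ids = {t.id for t in self.tracks}
        self.tracks, result = step_tracks(
            self.tracks, detections, self.config, next_id=self._next_id
        )
        after_ids = {t.id for t in self.tracks}
        self.created += len(after_ids - before_ids)
        self.deleted += len(before_ids - after_ids)
        if after_ids:
            self._next_id = max(self._next_id, max(after_ids) + 1)
        return result
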