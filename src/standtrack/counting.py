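"""Finish-line crossing counter and the per-frame orchestration loop.

A fixed image segment (the finish line) is the counting trigger: each frame,
every live track's inter-frame center trace — the segment from its previous
center to its current one — is tested for intersection with the line, and a
track is counted exactly once, the first time its trace touches the line.
Counting by crossings rather than by the number of track ids makes the total
robust to identity churn: a re-detected plant that received a fresh id still
crosses the line only once per physical pass, and a short-lived false track
usually dies before ever reaching it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

from .geometry import Segment, segments_intersect
from .tracking import MultiObjectTracker, Track, TrackerConfig

__all__ = [
    "FinishLine",
    "CountEvent",
    "CountResult",
    "default_finish_line",
    "check_crossing",
    "run_pipeline",
]


@dataclass(frozen=True)
class FinishLine:
    """Fixed segment in image coordinates that triggers count events."""

    segment: Segment

    @classmethod
    def horizontal(cls, y: float, x_min: float, x_max: float) -> "FinishLine":
        return cls(Segment((x_min, y), (x_max, y)))


def default_finish_line(frame_width: float, frame_height: float) -> FinishLine:
    """Full-width horizontal line at 90% of the frame height."""
    return FinishLine.horizontal(0.9 * frame_height, 0.0, frame_width)


@dataclass(frozen=True)
class CountEvent:
    frame: int
    track_id: int
    crossing_point: Tuple[float, float]


@dataclass
class CountResult:
    """Outcome of a pipeline run: the count, its event log, and run stats."""

    total: int = 0
    events: List[CountEvent] = field(default_factory=list)
    frames_processed: int = 0
    tracks_created: int = 0
    tracks_deleted: int = 0
    live_tracks: int = 0

    def record(self, event: CountEvent) -> None:
        self.events.append(event)
        self.total += 1


def check_crossing(
    track: Track, line: FinishLine, frame: int = 0
) -> Optional[CountEvent]:
    """Emit a count event if the track's center trace crosses the line.

    The trace is the closed segment between the previous and current center,
    so an endpoint landing exactly on the line counts. Tracks without two
    distinct centers yet, or already-counted tracks, never emit. On emission
    the track's ``counted`` flag is set, making the per-track count final.
    """
    if track.counted:
        return None
    if track.prev_center is None or track.curr_center is None:
        return None
    if tuple(track.prev_center) == tuple(track.curr_center):
        return None
    trace = Segment(track.prev_center, track.curr_center)
    if not segments_intersect(trace, line.segment):
        return None
    track.counted = True
    return CountEvent(frame=frame, track_id=track.id, crossing_point=track.curr_center)


def run_pipeline(
    detection_stream: Iterable[Tuple[int, Sequence[Box]]],
    line: FinishLine,
    config: Optional[TrackerConfig] = None,
    verbose: bool = False,
) -> CountResult:
    """Run the full track-and-count loop over a detection stream.

    Parameters
    ----------
    detection_stream
        Iterable of ``(frame_index, boxes)`` with strictly increasing frame
        indices. Gaps are treated as frames with zero detections: the
        tracker still predicts through them, so tracks coast and may cross
        the line while undetected.
    line
        The finish line.
    config
        Tracker parameters; defaults to :class:`TrackerConfig`.

    Returns
    -------
    CountResult
        Total count (== number of events), the event log, and statistics.
    """
    tracker = MultiObjectTracker(config)
    result = CountResult()

    last_frame = -1
    for frame_index, boxes in detection_stream:
        if frame_index <= last_frame:
            raise ValueError(
                f"detection stream frames must be strictly increasing: "
                f"frame {frame_index} after {last_frame}"
            )
        # Step through any skipped frames with empty detections.
        for fidx in range(last_frame + 1, frame_index + 1):
            frame_boxes = boxes if fidx == frame_index else []
            tracker.step(frame_boxes)
            for track in tracker.tracks:
                event = check_crossing(track, line, frame=fidx)
                if event is not None:
                    result.record(event)
            result.frames_processed += 1
            if verbose:
                print(
                    f"frame {fidx}: {len(frame_boxes)} detections, "
                    f"{len(tracker.tracks)} live tracks, count {result.total}"
                )
        last_frame = frame_index

    result.tracks_created = tracker.created
    result.tracks_deleted = tracker.deleted
    result.live_tracks = len(tracker.tracks)
    return result
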