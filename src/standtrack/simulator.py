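"""Synthetic row-scene generator standing in for field video plus detector.

A single crop row of plants streams through the frame under a constant
camera velocity (cart pushed along the row at roughly constant speed, camera
looking straight down), entering at the top edge and exiting past the bottom
where the finish line sits. Ground-truth trajectories are exactly constant
velocity; the detection channel then corrupts them with the documented
failure taxonomy:

* center-position jitter (cart vibration),
* a bounded aspect-ratio random walk at constant box area (leaf motion and
  view-angle change),
* missed detections,
* short-lived (1-2 frame) false-positive boxes (weeds, soil clutter),
* split detections, where one plant is reported as 2-3 overlapping
  fragments.

All randomness flows from the config seed, so a scene is bit-reproducible.
The noise magnitudes in the presets are this package's own benchmark
settings, not measurements of any particular detector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np

from .counting import default_finish_line
from .detector_io import DetectionRecord
from .geometry import Box, Segment, segments_intersect

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "generate_scene",
    "scene_presets",
    "noise_free",
    "benchmark_config",
    "BENCHMARK_NOISE",
]

_ASPECT_BOUNDS = (0.3, 3.0)


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic scene; see module docstring for semantics."""

    frame_width: int = 1024
    frame_height: int = 1024
    n_plants: int = 10
    spacing_mean: float = 120.0  # px between consecutive plants along the row
    spacing_jitter: float = 20.0
    camera_speed: float = 16.0  # px/frame scene translation toward the bottom
    box_width: float = 60.0
    box_height: float = 60.0
    position_noise: float = 0.0  # sigma of detection center jitter (px)
    aspect_drift: float = 0.0  # sigma of per-frame aspect-ratio walk
    miss_probability: float = 0.0
    false_positive_rate: float = 0.0  # expected FP boxes born per frame
    split_probability: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("miss_probability", "split_probability"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.false_positive_rate < 0:
            raise ValueError("false_positive_rate must be nonnegative")
        for name in (
            "frame_width",
            "frame_height",
            "spacing_mean",
            "camera_speed",
            "box_width",
            "box_height",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_plants < 0:
            raise ValueError("n_plants must be nonnegative")
        if self.position_noise < 0 or self.aspect_drift < 0 or self.spacing_jitter < 0:
            raise ValueError("noise sigmas must be nonnegative")


@dataclass
class SyntheticScene:
    """Ground truth plus corrupted detections for one simulated row pass."""

    config: SceneConfig
    n_frames: int
    # per frame: list of (plant id, box)
    ground_truth: List[List[Tuple[int, Box]]] = field(default_factory=list)
    # per frame: list of (box, confidence)
    detections: List[List[Tuple[Box, float]]] = field(default_factory=list)
    true_count: int = 0

    def detection_stream(self) -> List[Tuple[int, List[Box]]]:
        """Frame-indexed box lists for :func:`standtrack.counting.run_pipeline`."""
        return [
            (frame, [box for box, _ in dets])
            for frame, dets in enumerate(self.detections)
        ]

    def detection_records(self) -> List[DetectionRecord]:
        records = []
        for frame, dets in enumerate(self.detections):
            for box, conf in dets:
                x, y, w, h = box.to_xywh()
                records.append(
                    DetectionRecord(frame=frame, x=x, y=y, w=w, h=h, confidence=conf)
                )
        return records

    def ground_truth_records(self) -> List[DetectionRecord]:
        records = []
        for frame, entries in enumerate(self.ground_truth):
            for plant_id, box in entries:
                x, y, w, h = box.to_xywh()
                records.append(
                    DetectionRecord(
                        frame=frame, x=x, y=y, w=w, h=h,
                        confidence=1.0, object_id=plant_id,
                    )
                )
        return records


def _split_box(box: Box, n_parts: int, rng: np.random.Generator) -> List[Box]:
    """Partition a box into side-by-side fragments with ~10% mutual overlap."""
    w = box.width
    part_w = w / n_parts
    overlap = 0.10 * part_w
    parts = []
    for k in range(n_parts):
        x1 = box.x1 + k * part_w - (overlap if k > 0 else 0.0)
        x2 = box.x1 + (k + 1) * part_w + (overlap if k < n_parts - 1 else 0.0)
        parts.append(Box(x1, box.y1, x2, box.y2))
    return parts


def generate_scene(cfg: SceneConfig) -> SyntheticScene:
    """Generate a fully reproducible synthetic scene from its config.

    Plants are laid out along the row with jittered spacing, start above the
    top edge, and translate by ``camera_speed`` px/frame until every plant
    has left the frame. Ground truth contains each plant's (unclipped) box
    in every frame where it overlaps the frame rectangle.
    """
    rng = np.random.default_rng(cfg.seed)
    w0, h0 = cfg.box_width, cfg.box_height

    # Row layout: plant 0 starts just above the top edge, the rest behind it.
    y_positions = []
    y = -h0  # center of first plant, one box above the frame
    for _ in range(cfg.n_plants):
        y_positions.append(y)
        y -= cfg.spacing_mean + rng.normal(0.0, cfg.spacing_jitter)
    x_positions = [
        cfg.frame_width / 2.0 + rng.uniform(-0.1, 0.1) * cfg.frame_width
        for _ in range(cfg.n_plants)
    ]

    if cfg.n_plants:
        span = -min(y_positions)  # distance from first to last plant center
    else:
        span = 0.0
    travel = span + cfg.frame_height + 2 * h0
    n_frames = max(1, int(math.ceil(travel / cfg.camera_speed)) + 1)

    aspect = np.full(cfg.n_plants, w0 / h0)
    ground_truth: List[List[Tuple[int, Box]]] = []
    detections: List[List[Tuple[Box, float]]] = []
    live_fps: List[Tuple[int, Box]] = []  # (frames remaining, box)

    for frame in range(n_frames):
        gt_frame: List[Tuple[int, Box]] = []
        det_frame: List[Tuple[Box, float]] = []

        # advance the bounded aspect-ratio random walk (detection-side noise)
        if cfg.aspect_drift > 0:
            aspect = aspect + rng.normal(0.0, cfg.aspect_drift, size=cfg.n_plants)
            lo, hi = _ASPECT_BOUNDS
            # reflect at the bounds
            aspect = np.where(aspect < lo, 2 * lo - aspect, aspect)
            aspect = np.where(aspect > hi, 2 * hi - aspect, aspect)
            aspect = np.clip(aspect, lo, hi)

        for pid in range(cfg.n_plants):
            cy = y_positions[pid] + frame * cfg.camera_speed
            cx = x_positions[pid]
            gt_box = Box(cx - w0 / 2, cy - h0 / 2, cx + w0 / 2, cy + h0 / 2)
            if (
                gt_box.x2 <= 0
                or gt_box.x1 >= cfg.frame_width
                or gt_box.y2 <= 0
                or gt_box.y1 >= cfg.frame_height
            ):
                continue
            gt_frame.append((pid + 1, gt_box))

            if rng.random() < cfg.miss_probability:
                continue

            # constant-area aspect perturbation, then center jitter
            s = w0 * h0
            r = float(aspect[pid])
            dw = math.sqrt(s * r)
            dh = math.sqrt(s / r)
            du, dv = rng.normal(0.0, cfg.position_noise, size=2) if cfg.position_noise else (0.0, 0.0)
            det_box = Box(
                cx + du - dw / 2, cy + dv - dh / 2, cx + du + dw / 2, cy + dv + dh / 2
            )

            if rng.random() < cfg.split_probability:
                n_parts = int(rng.integers(2, 4))
                for part in _split_box(det_box, n_parts, rng):
                    det_frame.append((part, float(rng.uniform(0.5, 0.9))))
            else:
                det_frame.append((det_box, float(rng.uniform(0.7, 1.0))))

        # false positives: born ~Poisson(rate), each living 1-2 frames
        n_new_fp = rng.poisson(cfg.false_positive_rate) if cfg.false_positive_rate else 0
        for _ in range(n_new_fp):
            fw = w0 * rng.uniform(0.4, 1.2)
            fh = h0 * rng.uniform(0.4, 1.2)
            fx = rng.uniform(0, cfg.frame_width - fw)
            fy = rng.uniform(0, cfg.frame_height - fh)
            lifetime = int(rng.integers(1, 3))
            live_fps.append((lifetime, Box(fx, fy, fx + fw, fy + fh)))

        next_fps = []
        for remaining, fp_box in live_fps:
            det_frame.append((fp_box, float(rng.uniform(0.3, 0.7))))
            if remaining > 1:
                next_fps.append((remaining - 1, fp_box))
        live_fps = next_fps

        ground_truth.append(gt_frame)
        detections.append(det_frame)

    true_count = _count_line_crossings(cfg, ground_truth)
    return SyntheticScene(
        config=cfg,
        n_frames=n_frames,
        ground_truth=ground_truth,
        detections=detections,
        true_count=true_count,
    )


def _count_line_crossings(
    cfg: SceneConfig, ground_truth: List[List[Tuple[int, Box]]]
) -> int:
    """Plants whose center trace crosses the default finish line."""
    line = default_finish_line(cfg.frame_width, cfg.frame_height)
    centers: Dict[int, List[Tuple[float, float]]] = {}
    for frame_entries in ground_truth:
        for pid, box in frame_entries:
            centers.setdefault(pid, []).append(box.center)
    count = 0
    for trace in centers.values():
        for a, b in zip(trace, trace[1:]):
            if a == b:
                continue
            if segments_intersect(Segment(a, b), line.segment):
                count += 1
                break
    return count


_PRESETS: Dict[str, SceneConfig] = {
    # Small seedlings: tiny boxes, proportionally strong position jitter.
    "V1": SceneConfig(
        box_width=30.0,
        box_height=30.0,
        position_noise=3.0,
        aspect_drift=0.02,
        miss_probability=0.05,
        false_positive_rate=0.02,
        split_probability=0.0,
    ),
    # Mid vegetative stages: clean detections, mild shape drift.
    "V2": SceneConfig(
        box_width=60.0,
        box_height=60.0,
        position_noise=1.5,
        aspect_drift=0.03,
        miss_probability=0.02,
        false_positive_rate=0.02,
        split_probability=0.01,
    ),
    "V3": SceneConfig(
        box_width=80.0,
        box_height=80.0,
        position_noise=1.5,
        aspect_drift=0.04,
        miss_probability=0.02,
        false_positive_rate=0.02,
        split_probability=0.01,
    ),
    # Large overlapping canopies: strong shape drift and frequent splits.
    "V4": SceneConfig(
        box_width=120.0,
        box_height=120.0,
        position_noise=2.0,
        aspect_drift=0.06,
        miss_probability=0.03,
        false_positive_rate=0.03,
        split_probability=0.05,
    ),
}


def scene_presets(stage: str) -> SceneConfig:
    """Named growth-stage presets V1-V4 (this package's own settings).

    Box size grows with stage; V1 carries the highest relative position
    noise and V4 the highest split probability.
    """
    try:
        return _PRESETS[stage.upper()]
    except KeyError:
        raise ValueError(
            f"unknown stage {stage!r}; expected one of {sorted(_PRESETS)}"
        ) from None


# Default noise benchmark for the robust-count check: this package's own
# setting (position jitter 2 px, 10% misses, 0.05 FP births/frame, 2% splits),
# not a measured detector profile.
BENCHMARK_NOISE = {
    "position_noise": 2.0,
    "aspect_drift": 0.03,
    "miss_probability": 0.10,
    "false_positive_rate": 0.05,
    "split_probability": 0.02,
}


def benchmark_config(n_plants: int = 30, seed: int = 0) -> SceneConfig:
    """Scene config for the documented default-noise counting benchmark."""
    return SceneConfig(n_plants=n_plants, seed=seed, **BENCHMARK_NOISE)


def noise_free(cfg: SceneConfig) -> SceneConfig:
    """Copy of a config with every detection corruption switched off."""
    return replace(
        cfg,
        position_noise=0.0,
        aspect_drift=0.0,
        miss_probability=0.0,
        false_positive_rate=0.0,
        split_probability=0.0,
    )
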