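# standtrack

Plant stand counting from per-frame bounding-box detections by
tracking-by-detection: a Kalman filter with a constant-velocity state over
box center, area, and a *time-varying* aspect ratio links detections across
frames; an IoU-gated Hungarian assignment associates detections with
predicted tracks; and a plant is counted exactly once when the trace of its
track center between consecutive frames crosses a fixed finish line near
the bottom of the image. Counting by line crossings (rather than by track
ids) makes the total robust to identity churn from missed detections and
short-lived false positives.

No detector is bundled: the detector contract is "anything that yields
per-frame box lists" — either an MOT-style detection text file or the
built-in seeded scene simulator, which generates ground-truth constant
velocity trajectories and corrupts the detection channel with position
jitter, aspect-ratio drift, misses, short-lived false positives, and split
detections.

## Modules

| module | contents |
|---|---|
| `standtrack.geometry` | `Box`, `Measurement`, `Segment`; IoU; box ↔ (u, v, s, r) conversion; segment intersection |
| `standtrack.tracking` | 8-state Kalman predict/update, IoU-gated optimal assignment, `max_age` lifecycle, `MultiObjectTracker` |
| `standtrack.counting` | `FinishLine`, crossing detection, `run_pipeline` orchestration |
| `standtrack.detector_io` | MOT-style detection file read/write; detector grid-geometry helpers (`kernel_depth`, `grid_sizes`) |
| `standtrack.simulator` | seeded synthetic row scenes, growth-stage presets V1–V4, benchmark noise profile |
| `standtrack.evaluation` | counting accuracy, TP/FP/FN matching, average precision at IoU 0.5 |

The numeric values in the V1–V4 presets and in the default noise benchmark
(`simulator.BENCHMARK_NOISE`: position σ 2 px, 10% misses, 0.05 false
positives born per frame, 2% splits) are this package's own settings for
testing and benchmarking, not measurements of any particular detector.

## CLI

```sh
# generate a synthetic scene (detections + ground truth with plant ids)
standtrack simulate --preset V2 --plants 30 --seed 1 --out dets.txt --gt gt.txt

# track and count; the default finish line spans the frame at 90% height
standtrack count --detections dets.txt --frame-size 1024x1024 \
    --iou-threshold 0.3 --max-age 2 --out report.txt

# explicit finish line as x1,y1,x2,y2
standtrack count --detections dets.txt --line 0,900,1024,900

# detection quality against ground truth (TP/FP/FN and AP@IoU0.5)
standtrack evaluate --pred dets.txt --gt gt.txt --iou 0.5

# counting accuracy from two totals
standtrack evaluate-count --counted 98 --truth 100
```

Detection files are comma-separated `frame,id,x,y,w,h,conf` with 0-based
frames and top-left + width/height boxes; the id field is `-1` for raw
detections and the real plant id in ground-truth files.

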