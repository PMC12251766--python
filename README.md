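# fishcurtain

Detection and morphometric-estimation pipeline for infrared beam-break
fish counters, with a physics-grounded passage simulator so the whole
chain can be developed, validated and regression-tested without
hardware.

## Who this is for

Fishway monitoring relies increasingly on IR "light curtains": two
vertical arrays of infrared beams mounted a few centimetres apart
across a passage channel. A fish crossing the curtain breaks beams; the
receiver reports the full matrix of beam states (`0` = interrupted,
`1` = intact) at a fixed sampling rate. From that binary stream alone a
counter must decide *that* a fish passed, *which way*, *how fast*, and
*how big* it was. `fishcurtain` implements that decision chain for
ecologists and instrument developers: it reads plain-text beam-state
logs, segments them into candidate events, strips spurious
interruptions, estimates kinematics and morphometrics, reconstructs the
body silhouette, applies a three-criterion validity filter, and scores
detections against ground truth.

## The method

With arrays A and B separated by a gap `D` (default 6 cm) and sampled
at `f` (default 50 Hz):

- **Direction** follows from which array is activated first (entry) and
  cleared last (exit); `+1` means A→B travel.
- **Speed** is `V = D / Δt`, where `Δt` is the frame delay between the
  first activations of the two arrays; the same applied to the last
  clearings gives a second, independent estimate. The event velocity is
  the mean of the defined estimates.
- **Length** uses the occlusion time of each array: a body of length
  `L` occludes one array for `L / V` seconds, so `L_X = V · T_X` per
  array, averaged.
- **Height** is the vertical extent of the union of interrupted beams
  (`(j_max − j_min) ·` pitch) plus a half-pitch correction for the body
  overhang beyond the outermost beams, so a single interrupted beam
  reads half a pitch instead of zero.
- **Silhouette**: stacking each frame's interrupted-beam profile at
  horizontal steps `Δx = V / f` reconstructs a 2-D outline — a
  species-independent size estimate that needs no allometric prior.
- **Validity filter**: an event is a fish only if (1) entry and exit
  directions sum to non-zero, (2) its mean velocity is defined and
  positive, and (3) its height is at least a plausibility threshold
  (default 1.5 cm). Everything else (turnarounds, stationary debris,
  noise slivers) is rejected with an audit reason.

The default geometry is a 40-beam curtain at 1.5 cm pitch (60 cm
detection span), 6 cm array gap, 50 Hz. Geometry fixes the detection
limits: a body must be ≥ 3 cm high to guarantee two interrupted beams
at any vertical offset, and ≥ 6 cm long to bridge the gap as one
contiguous event.

The simulator moves rigid 2-D silhouettes (ellipses or rectangles)
through the modelled curtain and reproduces the field failure modes of
a partially submerged unit: surface-distortion bands masking one fish
(case I) or a following fish (case II), overlapping passages
(case III), and self-cancelling turnarounds (case IV), plus seeded
Poisson beam flickers. The evaluation harness matches detections to
ground truth, computes detection rates, tabulates the error taxonomy
and runs the allometric consistency check `L = b·H` (b ∈ [2.5, 3.0]
for cultivated carp).

## Worked example

Simulate a single 16.5 cm × 6.4 cm fish crossing at 30 cm/s, classify
the resulting log, and score it against the simulator's ground truth:

```bash
$ cat scenario.yaml
stream_length_s: 8.0
start_time: "2025-07-01T00:00:00+00:00"
fishes:
  - {length: 16.5, height: 6.4, depth_center: 29.25, speed: 30.0,
     direction: 1, shape: ellipse, entry_time: 2.0, tag: clean}

$ fishcurtain simulate scenario.yaml --out hour.log
simulated 1 truth record(s) -> hour.log
$ fishcurtain classify hour.log --out run
candidates=1 accepted=1 rejected=0 (by reason: none)
$ cat run/event_log.txt
2025-07-01T00:00:02.020000+0000	downstream	30.00	15.60	5.25	classifiedEvents/event_20250701T000002_020000.log
$ fishcurtain evaluate run/event_log.txt hour.log.truth.tsv
hits	1
misses	0
false_positives	0
detection_rate	100.00%
```

Reading the event-log line: the passage started 2.02 s into the stream,
travelled A→B (labelled `downstream` under the default mounting), at
30.00 cm/s — exact, because the 6 cm gap at 30 cm/s is a whole number
of frame delays. The length estimate 15.60 cm sits within the frame
quantization of the true 16.5 cm (the nose and tail are each seen at
most one frame late), and the height 5.25 cm is the 4-beam vertical
extent plus the half-pitch correction, inside the expected
[5.25, 6.75] cm band for a 6.4 cm body. `fishcurtain render` turns the
saved clip into a silhouette PNG with axes in cm;
`fishcurtain summarize` prints per-direction counts and mean sizes of
an event log.

The same chain is available as a library:

```python
from fishcurtain import FishSpec, SensorConfig, simulate_passage, classify_stream

fish = FishSpec(length=16.5, height=6.4, depth_center=29.25, speed=30.0, entry_time=2.0)
stream, truth = simulate_passage(fish, SensorConfig(), 8.0)
result = classify_stream(stream)
event = result.accepted[0]
print(event.direction, event.velocity.mean, event.morphometrics.length)
# 1 30.0 15.6
```

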