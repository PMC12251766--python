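# Methods

## The measurement model

A beam-break curtain observes a crossing body only through the binary
occupancy matrix it leaves behind: per frame (`1/f` seconds apart) and
per beam (one pitch `s` apart vertically), on each of two arrays a
horizontal gap `D` apart. All estimation in `fishcurtain` is therefore
frame-index arithmetic:

- An array is *activated* at the first frame in which any of its beams
  is interrupted, and *cleared* at the last. Matching arrays per-array
  rather than per-beam makes direction and velocity estimates robust to
  vertical drift of the body between the two arrays.
- Entry velocity is `D / (Δk_entry / f)` with `Δk_entry` the activation
  delay in frames; exit velocity uses the clearing delay. A zero-frame
  delay is propagated as *undefined* rather than clamped: the validity
  filter then rejects the event as velocity-implausible, which keeps
  "no measurable transit" distinct from "slow transit".
- Occupancy duration per array uses the open span `(last − first)/f`
  rather than the inclusive frame count, avoiding a systematic
  `+1`-frame (one `Δx`) inflation of length estimates.
- Height uses the union of interrupted beams across both arrays (the
  two arrays sample the body at different phases; the union maximizes
  vertical evidence) with an additive half-pitch correction: a body
  shorter than one pitch interrupts a single beam, which without the
  correction would read as zero height. Under the correction, an
  estimate for a body of height `h` always falls in
  `[(⌊h/s⌋ − 1)·s + s/2, h + s/2]` — the bound the property tests
  enforce.
- The silhouette stacks the reference array's per-frame interrupted
  profile at steps `Δx = V/f`, with column order reversed for B→A
  travel so the nose is always drawn first. Array A is the reference
  purely by convention, falling back to B when A was never touched.

Quantization is the dominant error source everywhere: delays and spans
are integers in frames, so speed errors scale as `D·f/(d(d−1))` for a
true delay of `d` frames, and length errors combine one `Δx` at each
body end with the propagated speed error. At the default geometry and a
typical 30 cm/s crossing these amount to a few percent — the mean
length of the 16.5 cm validation replica is recovered at ≈ 15.5 cm
(−6%).

## Detection chain

1. **Segmentation** — frames with any interrupted beam on either array
   are active; maximal active runs separated by at most `gap_frames`
   intact frames (default 5, i.e. 0.1 s at 50 Hz) merge into one
   candidate. The merge tolerance exists because a fish shorter than
   the array gap plus one frame of travel can momentarily leave the
   whole curtain intact mid-passage; 0.1 s re-joins such flickers while
   genuinely separate fish (seconds apart) stay separate. Candidates
   with fewer than `min_active_frames` (default 2) active frames are
   dropped — one frame cannot yield direction or velocity.
2. **Spurious-line removal** — 4-connected blobs of interrupted cells
   (per array, in the frame × beam grid) are reset to intact when they
   are at most 2 frames wide and 1 beam tall *and* the other array
   shows no interruption within ±2 frames. Real bodies mark both
   arrays within roughly the gap-transit time; electrical noise and
   glancing debris do not. All removal decisions are taken
   simultaneously on the input state, which makes the operation
   idempotent and order-free; the event is re-trimmed afterwards and
   dropped if emptied. The three limits are deliberately conservative
   and config-exposed, since the boundary between debris and small fish
   is site-specific.
3. **Estimation** — as above.
4. **Validity filter** — in fixed order: direction (entry + exit ≠ 0),
   velocity (defined and > 0; an optional cap exists but is off by
   default, since only the zero case is a principled rejection),
   height (≥ 1.5 cm). The first failed criterion is the audit reason.
   The final direction of an accepted event is `sign(entry + exit)`,
   so an event with one indeterminate component still resolves.

Upstream/downstream words are mounting metadata: the pipeline works in
signed A→B coordinates and maps to labels only at reporting time.

## Simulator

Fish are rigid 2-D silhouettes (ellipse or rectangle) translating
horizontally at constant speed, entering with their leading edge at the
first array at `entry_time`. This mirrors the estimator's own
assumptions on purpose: it makes recovery bounds exact and attributable
to quantization alone. What it deliberately does **not** emulate:
variable swimming speed, oblique crossing angles, body flexion,
turbulence-induced partial occlusions, bubbles, or multi-species
mixtures. Passing tests therefore demonstrate correctness of the
*algorithmic chain* under the stated geometry, not field accuracy —
field performance is dominated by surface distortion and fish
behaviour, which the error scenarios below only caricature.

The four failure modes are modelled mechanistically but minimally:

- **case I/II** — a *surface band*: persistent interruption of the top
  `k` beams of both arrays over a time window. Overlapping a fish's
  crossing, it merges with the fish into one direction-less candidate
  (case I); triggered behind a leading fish and covering a follower, it
  masks the follower entirely (case II, marked not-expected-detectable
  in ground truth). Band extent and duration are placeholders for
  sensitivity studies, not calibrated claims — the real phenomenon is
  unquantified.
- **case III** — two fish with overlapping crossing intervals at
  different depths merge into one candidate; exactly one can be
  matched, the other becomes an overlap miss.
- **case IV** — a triangular trajectory: the fish advances a set
  distance past its entry array, then reverses. Entry and exit
  direction estimates cancel and the filter rejects with reason
  "direction".

Spurious blips are single-beam, single-frame interruptions at Poisson
times from a mandatory seed; noise only ever accumulates interruptions
(logical OR), never removes them.

## Evaluation

Matching is greedy nearest-timestamp within a tolerance (default 2 s),
one-to-one, invariant under common time translation. Unmatched truths
expected to be detectable are misses (tabulated by scenario tag, with
percentages of all misses); unmatched detections are false positives;
truths marked not-expected-detectable count as neither. Detection rate
is `100 · hits / detectable truths`.

The allometric check bins events by estimated height (1.5 cm bins),
takes per-bin medians of height and length, and fits an ordinary
least-squares line to the medians (medians and IQR error bars resist
the long tails that overlap events produce). Individual events are also
flagged inside/outside their predicted band `[2.5·H, 3.0·H]`. Because
per-event height errors reach about one pitch, a fit over a height span
`R` can be attenuated by roughly `(1 − s/R)`; the recovery tests bound
the slope error by `b·s/R` accordingly.

## Problem sizes and numerics

The test and acceptance workloads are deliberately small — 4–12 s
streams at 50 Hz (200–600 frames × 40 beams), 20-passage replica
batches, 60-fish allometric populations — which keeps every recovery
property exact to its quantization bound while the full suite runs in
seconds. Geometry uses closed coordinate comparisons with a 1e-9
tolerance so that bodies exactly touching a beam line interrupt it
deterministically. The detection-limit sweep works on an integer
hundredth-of-a-centimetre grid (offsets at 0.01 cm over one pitch,
candidate heights at 0.1 cm), making interval/beam intersection counts
exact rather than float-dependent. Log files round-trip bit-exactly:
states as fixed-width 0/1 text, timestamps as ISO-8601 with timezone,
event-log values at 0.01 precision.

## Design choices where the design was open

- **Calibration criterion**: a beam is healthy when intact in ≥ 99% of
  a fish-free window; the check's goal (all beams transmitting and
  receiving) admits any threshold, and 99% flags both stuck and
  flickering beams while tolerating rare dropouts.
- **Length combination**: the two per-array lengths are averaged, and
  the velocity used is the mean of entry/exit estimates — the mean
  halves quantization noise and no asymmetric choice is better
  justified.
- **Detection span** is quoted as `n·s` (40 × 1.5 = 60 cm), the
  occupancy-band convention of the instrument, not the `(n−1)·s`
  distance between outermost beam centres.
- **Per-event cleaning**: spurious-line removal runs on segmented
  candidates (with re-trimming) rather than whole streams, keeping the
  operation local and order-free.
- **Two co-linear arrays**: each side is modelled as a single vertical
  beam line; any half-pitch stagger of the physical double-row layout
  is not modelled.

## Known limitations

- Overlapping fish are not de-overlapped: case III inherently costs a
  miss, as in comparable commercial counters.
- No species discrimination and no debris model beyond the geometric
  noise rules.
- Velocity/length estimates assume constant, perpendicular travel;
  angled or accelerating passages bias both (unquantified here, as in
  the field).
- The surface-band mechanism is a stand-in with free parameters; its
  realism is untested against field data.
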