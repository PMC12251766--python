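"""Per-event kinematic and morphometric estimation.

The two-array geometry yields all passage metrics from frame indices
alone.  With arrays A and B a distance ``D`` apart and sampled at
``f`` Hz:

* **direction** — the array activated first is the near side; the array
  cleared last is the far side.  +1 denotes A-to-B travel.
* **velocity** — ``V = D / dt`` where ``dt`` is the delay between the
  first activations (entry estimate) or the last clearings (exit
  estimate) of the two arrays; the mean of the defined estimates is the
  event velocity.
* **length** — each array is occluded for the time the body takes to
  pass it, so ``L_X = V * (last_X - first_X) / f`` per array; the event
  length is the mean over the arrays that were interrupted.
* **height** — vertical extent of the union of interrupted beams across
  both arrays, plus a half-pitch correction for the body overhang
  beyond the outermost beams.
* **silhouette** — stacking the per-frame interrupted-beam profile of
  one array at horizontal steps ``dx = V / f`` reconstructs the body
  outline, the basis of the species-independent size estimate.

"Activation" of an array means any interrupted beam on that array:
per-array (not per-beam) matching is robust to vertical drift of the
body between the two arrays.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np

from .event_detection import CandidateEvent
from .sensor_model import BeamStream, SensorConfig

__all__ = [
    "DirectionEstimate",
    "VelocityEstimate",
    "MorphometricEstimate",
    "Silhouette",
    "EventEstimates",
    "PassageEvent",
    "estimate_directions",
    "estimate_velocities",
    "estimate_length",
    "estimate_height",
    "reconstruct_silhouette",
    "assign_timestamp",
    "analyze_candidate",
]


@dataclass(frozen=True)
class DirectionEstimate:
    """Entry/exit travel direction: +1 = A-to-B, -1 = B-to-A, 0 = tie."""

    entry: int
    exit: int

    def __post_init__(self) -> None:
        if self.entry not in (-1, 0, 1) or self.exit not in (-1, 0, 1):
            raise ValueError("direction components must be -1, 0 or +1")


@dataclass(frozen=True)
class VelocityEstimate:
    """Entry/exit gap-transit speeds (cm/s); ``None`` = undefined.

    A zero-frame delay between the arrays leaves that estimate
    undefined rather than infinite; ``mean`` averages the defined
    components and is ``None`` when neither is defined.
    """

    entry: float | None
    exit: float | None

    def __post_init__(self) -> None:
        for v in (self.entry, self.exit):
            if v is not None and v <= 0:
                raise ValueError("defined velocity components must be > 0")

    @property
    def mean(self) -> float | None:
        defined = [v for v in (self.entry, self.exit) if v is not None]
        return sum(defined) / len(defined) if defined else None


@dataclass(frozen=True)
class MorphometricEstimate:
    """Body size estimates in cm; per-array lengths may be undefined."""

    length_a: float | None
    length_b: float | None
    height: float

    def __post_init__(self) -> None:
        for v in (self.length_a, self.length_b):
            if v is not None and v < 0:
                raise ValueError("lengths must be >= 0")
        if self.height < 0:
            raise ValueError("height must be >= 0")

    @property
    def length(self) -> float | None:
        defined = [v for v in (self.length_a, self.length_b) if v is not None]
        return sum(defined) / len(defined) if defined else None


@dataclass(frozen=True)
class Silhouette:
    """Reconstructed 2-D body outline.

    ``occupancy`` is a (columns x beams) binary matrix; column spacing
    is ``dx = V/f`` cm, rows are ordered nose-first regardless of the
    travel direction.  ``extent`` is (length, height) in cm.
    """

    dx: float
    occupancy: np.ndarray
    extent: tuple[float, float]

    def __post_init__(self) -> None:
        if self.dx <= 0:
            raise ValueError("dx must be > 0")


@dataclass(frozen=True)
class EventEstimates:
    """All per-event estimates prior to validity filtering."""

    direction: DirectionEstimate
    velocity: VelocityEstimate
    morphometrics: MorphometricEstimate
    silhouette: Silhouette | None
    timestamp: _dt.datetime


@dataclass(frozen=True)
class PassageEvent:
    """A candidate that passed the validity filter, with its estimates."""

    candidate: CandidateEvent
    direction: int
    direction_estimate: DirectionEstimate
    velocity: VelocityEstimate
    morphometrics: MorphometricEstimate
    silhouette: Silhouette | None
    timestamp: _dt.datetime


def _first_last_active(interrupted: np.ndarray) -> tuple[int | None, int | None]:
    active = np.nonzero(interrupted.any(axis=1))[0]
    if active.size == 0:
        return None, None
    return int(active[0]), int(active[-1])


def estimate_directions(event: CandidateEvent, config: SensorConfig | None = None) -> DirectionEstimate:
    """Entry/exit direction from first-activation and last-clearing order.

    Entry: the array activated first is the near side (A first => +1).
    Exit: the array cleared last is the far side (B last => +1).  A
    same-frame tie, or an array never interrupted, gives 0 for both the
    affected components.
    """
    fa, la = _first_last_active(event.interrupted_a())
    fb, lb = _first_last_active(event.interrupted_b())
    if fa is None or fb is None:
        return DirectionEstimate(0, 0)
    entry = int(np.sign(fb - fa))
    exit_ = int(np.sign(lb - la))
    return DirectionEstimate(entry, exit_)


def estimate_velocities(event: CandidateEvent, config: SensorConfig | None = None) -> VelocityEstimate:
    """Gap-transit speed estimates from inter-array frame delays."""
    config = config or event.config
    fa, la = _first_last_active(event.interrupted_a())
    fb, lb = _first_last_active(event.interrupted_b())
    if fa is None or fb is None:
        return VelocityEstimate(None, None)

    def _speed(delay_frames: int) -> float | None:
        if delay_frames == 0:
            return None
        return config.array_gap * config.sampling_rate / abs(delay_frames)

    return VelocityEstimate(_speed(fb - fa), _speed(lb - la))


def estimate_length(
    event: CandidateEvent,
    velocity: VelocityEstimate,
    config: SensorConfig | None = None,
) -> tuple[float | None, float | None, float | None]:
    """Per-array and combined body length, cm.

    The occupancy duration of array X is ``(last_X - first_X)/f`` (the
    open span, which avoids the one-frame bias of inclusive counting);
    length_X = mean velocity x duration.  Returns
    ``(length_a, length_b, length)`` with ``None`` for undefined values.
    """
    config = config or event.config
    v = velocity.mean
    if v is None:
        return None, None, None

    def _length(interrupted: np.ndarray) -> float | None:
        first, last = _first_last_active(interrupted)
        if first is None:
            return None
        return v * (last - first) / config.sampling_rate

    la = _length(event.interrupted_a())
    lb = _length(event.interrupted_b())
    defined = [x for x in (la, lb) if x is not None]
    mean = sum(defined) / len(defined) if defined else None
    return la, lb, mean


def estimate_height(event: CandidateEvent, config: SensorConfig | None = None) -> float:
    """Body height from the union of interrupted beams, cm.

    ``(j_max - j_min) * beam_spacing + height_correction`` over both
    arrays and all frames.  The half-pitch correction compensates the
    average body overhang beyond the outermost interrupted beams, so a
    single interrupted beam reads as half a pitch rather than zero.
    """
    config = config or event.config
    beams = np.nonzero(event.interrupted_a().any(axis=0) | event.interrupted_b().any(axis=0))[0]
    if beams.size == 0:
        raise ValueError("event has no interrupted beams")
    span = (int(beams[-1]) - int(beams[0])) * config.beam_spacing
    return span + config.height_correction


def estimate_morphometrics(
    event: CandidateEvent,
    velocity: VelocityEstimate,
    config: SensorConfig | None = None,
) -> MorphometricEstimate:
    la, lb, _ = estimate_length(event, velocity, config)
    return MorphometricEstimate(la, lb, estimate_height(event, config))


def reconstruct_silhouette(
    event: CandidateEvent,
    velocity: VelocityEstimate,
    config: SensorConfig | None = None,
    direction: int = 1,
) -> Silhouette | None:
    """Map per-frame beam profiles onto a 2-D outline at steps dx = V/f.

    Array A is the reference (B if A was never touched).  For B-to-A
    travel the column order is reversed so the nose is always drawn
    first.  Returns ``None`` when the velocity is undefined.
    """
    config = config or event.config
    v = velocity.mean
    if v is None:
        return None
    ref = event.interrupted_a()
    if not ref.any():
        ref = event.interrupted_b()
        if not ref.any():
            return None
    first, last = _first_last_active(ref)
    occupancy = ref[first : last + 1].astype(np.uint8)
    if direction == -1:
        occupancy = occupancy[::-1].copy()
    dx = v / config.sampling_rate
    beams = np.nonzero(occupancy.any(axis=0))[0]
    height = (int(beams[-1]) - int(beams[0])) * config.beam_spacing + config.height_correction
    length = (occupancy.shape[0] - 1) * dx
    return Silhouette(dx=dx, occupancy=occupancy, extent=(length, height))


def assign_timestamp(event: CandidateEvent, stream: BeamStream) -> _dt.datetime:
    """Wall-clock time of the event's first frame."""
    if not (0 <= event.start_frame <= event.end_frame < stream.n_frames):
        raise IndexError("event lies outside the stream bounds")
    return stream.time_of(event.start_frame)


def analyze_candidate(
    event: CandidateEvent,
    stream: BeamStream | None = None,
    config: SensorConfig | None = None,
    start_time: _dt.datetime | None = None,
) -> EventEstimates:
    """Compute the full estimate bundle for one cleaned candidate.

    The timestamp comes from ``stream`` when given, else from
    ``start_time`` (time of stream frame 0), else from epoch zero.
    """
    config = config or event.config
    direction = estimate_directions(event, config)
    velocity = estimate_velocities(event, config)
    morpho = estimate_morphometrics(event, velocity, config)
    sil_dir = int(np.sign(direction.entry + direction.exit)) or 1
    silhouette = reconstruct_silhouette(event, velocity, config, direction=sil_dir)
    if stream is not None:
        ts = assign_timestamp(event, stream)
    else:
        base = start_time or _dt.datetime(1970, 1, 1, tzinfo=_dt.timezone.utc)
        ts = base + _dt.timedelta(seconds=event.start_frame / config.sampling_rate)
    return EventEstimates(direction, velocity, morpho, silhouette, ts)
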