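"""Curtain geometry and the in-memory beam-state data model.

An infrared beam-break curtain consists of two vertical arrays of beams
(here labelled A and B along the travel axis) separated by a horizontal
gap ``D``.  Each array holds ``n_beams`` beams at a constant vertical
pitch; the receiver samples the full matrix of beam states at a fixed
rate ``f``.  Beam index 0 is the bottom-most beam and the vertical
coordinate of beam ``j`` is ``j * beam_spacing`` (cm).

A beam state of 0 means the beam is interrupted (broken by a body); 1
means intact.  This is the convention of the acquisition hardware and is
kept throughout the package.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "SensorConfig",
    "BeamFrame",
    "BeamStream",
    "beam_positions",
    "detection_span",
    "min_guaranteed_height",
]


@dataclass(frozen=True)
class SensorConfig:
    """Geometry and timing constants of a two-array IR curtain.

    Parameters
    ----------
    n_beams : int
        Beams per array (>= 2).
    beam_spacing : float
        Vertical pitch between adjacent beams, cm.
    array_gap : float
        Horizontal distance D between the two arrays, cm.
    sampling_rate : float
        Sampling frequency f of the full beam-state matrix, Hz.
    height_filter_threshold : float
        Minimum biologically plausible body height, cm; events with a
        smaller estimated height are rejected by the validity filter.
    height_correction : float or None
        Additive correction applied to the raw vertical beam extent when
        estimating body height, cm.  ``None`` selects the default of
        half the beam spacing, which compensates the half-pitch that a
        body extends, on average, beyond the outermost interrupted beams.
    array_labels : tuple of str
        Identifiers of the first and second array along the positive
        travel axis.
    upstream_label : str
        Which of the two labels faces upstream; purely a reporting
        convention that depends on how the curtain is mounted.
    """

    n_beams: int = 40
    beam_spacing: float = 1.5
    array_gap: float = 6.0
    sampling_rate: float = 50.0
    height_filter_threshold: float = 1.5
    height_correction: float | None = None
    array_labels: tuple[str, str] = ("A", "B")
    upstream_label: str = "A"

    def __post_init__(self) -> None:
        if self.n_beams < 2:
            raise ValueError(f"n_beams must be >= 2, got {self.n_beams}")
        if self.beam_spacing <= 0:
            raise ValueError("beam_spacing must be > 0")
        if self.array_gap <= 0:
            raise ValueError("array_gap must be > 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.height_correction is None:
            object.__setattr__(self, "height_correction", self.beam_spacing / 2.0)
        if len(self.array_labels) != 2 or self.array_labels[0] == self.array_labels[1]:
            raise ValueError("array_labels must be two distinct identifiers")
        if self.upstream_label not in self.array_labels:
            raise ValueError("upstream_label must be one of array_labels")

    @property
    def frame_dt(self) -> float:
        """Time between consecutive frames, seconds."""
        return 1.0 / self.sampling_rate

    @property
    def downstream_label(self) -> str:
        a, b = self.array_labels
        return b if self.upstream_label == a else a

    def direction_label(self, direction: int) -> str:
        """Map a signed travel direction (+1 = A-to-B) onto the
        upstream/downstream vocabulary of the mounted instrument."""
        if direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        towards = self.array_labels[1] if direction == 1 else self.array_labels[0]
        return "upstream" if towards == self.upstream_label else "downstream"

    @classmethod
    def full_scale(cls, **overrides) -> "SensorConfig":
        """The 40-beam production curtain (1.5 cm pitch, 6 cm gap, 50 Hz)."""
        return cls(**overrides)

    @classmethod
    def mini(cls, **overrides) -> "SensorConfig":
        """The 8-beam bench prototype; identical except for beam count."""
        overrides.setdefault("n_beams", 8)
        return cls(**overrides)

    def to_dict(self) -> dict:
        return {
            "n_beams": self.n_beams,
            "beam_spacing_cm": self.beam_spacing,
            "array_gap_cm": self.array_gap,
            "sampling_rate_hz": self.sampling_rate,
            "height_filter_threshold_cm": self.height_filter_threshold,
            "height_correction_cm": self.height_correction,
            "array_labels": list(self.array_labels),
            "upstream_label": self.upstream_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensorConfig":
        kwargs = {}
        mapping = {
            "n_beams": "n_beams",
            "beam_spacing_cm": "beam_spacing",
            "array_gap_cm": "array_gap",
            "sampling_rate_hz": "sampling_rate",
            "height_filter_threshold_cm": "height_filter_threshold",
            "height_correction_cm": "height_correction",
            "upstream_label": "upstream_label",
        }
        for key, attr in mapping.items():
            if key in d and d[key] is not None:
                kwargs[attr] = d[key]
        if "array_labels" in d:
            kwargs["array_labels"] = tuple(d["array_labels"])
        if "n_beams" in kwargs:
            kwargs["n_beams"] = int(kwargs["n_beams"])
        return cls(**kwargs)


@dataclass(frozen=True)
class BeamFrame:
    """One sample instant: the binary state of both arrays.

    0 = interrupted, 1 = intact; element ``j`` is beam ``j`` counted
    from the bottom.
    """

    frame_index: int
    state_a: np.ndarray
    state_b: np.ndarray

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        if len(self.state_a) != len(self.state_b):
            raise ValueError("state_a and state_b must have equal length")


class BeamStream:
    """Time-ordered sequence of beam-state frames from one curtain.

    States are held as two ``(n_frames, n_beams)`` uint8 matrices (one
    per array).  Frame ``k`` occurs at ``start_time + k / sampling_rate``.
    """

    def __init__(
        self,
        config: SensorConfig,
        start_time: _dt.datetime,
        states_a: np.ndarray,
        states_b: np.ndarray,
    ) -> None:
        states_a = np.asarray(states_a, dtype=np.uint8)
        states_b = np.asarray(states_b, dtype=np.uint8)
        if states_a.ndim != 2 or states_b.ndim != 2:
            raise ValueError("state matrices must be 2-D (frames x beams)")
        if states_a.shape != states_b.shape:
            raise ValueError("state matrices for the two arrays must match in shape")
        if states_a.shape[1] != config.n_beams:
            raise ValueError(
                f"state width {states_a.shape[1]} != n_beams {config.n_beams}"
            )
        for name, m in (("A", states_a), ("B", states_b)):
            if m.size and not np.isin(m, (0, 1)).all():
                raise ValueError(f"array {name} states must be binary 0/1")
        self.config = config
        self.start_time = start_time
        self.states_a = states_a
        self.states_b = states_b

    @classmethod
    def empty(cls, config: SensorConfig, start_time: _dt.datetime) -> "BeamStream":
        z = np.zeros((0, config.n_beams), dtype=np.uint8)
        return cls(config, start_time, z.copy(), z.copy())

    @classmethod
    def from_frames(
        cls,
        config: SensorConfig,
        start_time: _dt.datetime,
        frames: Sequence[BeamFrame],
    ) -> "BeamStream":
        if not frames:
            return cls.empty(config, start_time)
        idx = [f.frame_index for f in frames]
        if idx != list(range(idx[0], idx[0] + len(frames))):
            raise ValueError("frame_index must increase strictly by 1")
        if idx[0] != 0:
            raise ValueError("frame_index of the first frame must be 0")
        a = np.stack([np.asarray(f.state_a, dtype=np.uint8) for f in frames])
        b = np.stack([np.asarray(f.state_b, dtype=np.uint8) for f in frames])
        return cls(config, start_time, a, b)

    @property
    def n_frames(self) -> int:
        return self.states_a.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def frames(self) -> Iterator[BeamFrame]:
        for k in range(self.n_frames):
            yield BeamFrame(k, self.states_a[k], self.states_b[k])

    def time_of(self, frame_index: int) -> _dt.datetime:
        return self.start_time + _dt.timedelta(
            seconds=frame_index / self.config.sampling_rate
        )

    def interrupted_a(self) -> np.ndarray:
        """Boolean (frames x beams) matrix of interruptions on array A."""
        return self.states_a == 0

    def interrupted_b(self) -> np.ndarray:
        return self.states_b == 0

    def activity(self) -> np.ndarray:
        """Per-frame boolean: any beam interrupted on either array."""
        if self.n_frames == 0:
            return np.zeros(0, dtype=bool)
        return self.interrupted_a().any(axis=1) | self.interrupted_b().any(axis=1)

    def slice(self, start_frame: int, end_frame: int) -> "BeamStream":
        """Sub-stream over inclusive frame bounds, re-anchored in time."""
        if not (0 <= start_frame <= end_frame < self.n_frames):
            raise IndexError("slice bounds outside stream")
        return BeamStream(
            self.config,
            self.time_of(start_frame),
            self.states_a[start_frame : end_frame + 1].copy(),
            self.states_b[start_frame : end_frame + 1].copy(),
        )

    def reversed(self) -> "BeamStream":
        """Time-reversed copy (used for mirror-symmetry checks)."""
        return BeamStream(
            self.config,
            self.start_time,
            self.states_a[::-1].copy(),
            self.states_b[::-1].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BeamStream):
            return NotImplemented
        return (
            self.config == other.config
            and self.start_time == other.start_time
            and np.array_equal(self.states_a, other.states_a)
            and np.array_equal(self.states_b, other.states_b)
        )


def beam_positions(config: SensorConfig) -> np.ndarray:
    """Vertical coordinates of the beams, bottom to top, cm."""
    return np.arange(config.n_beams) * config.beam_spacing


def detection_span(config: SensorConfig) -> float:
    """Advertised total detection height: ``n_beams * beam_spacing`` cm.

    This is the occupancy band covered at the stated element pitch (the
    convention under which 40 beams at 1.5 cm span 60 cm), not the
    distance between the outermost beam centres.
    """
    return config.n_beams * config.beam_spacing


def min_guaranteed_height(
    config: SensorConfig,
    min_beams: int,
    offset_step: float = 0.01,
    height_step: float = 0.1,
) -> float:
    """Smallest body height guaranteed to intersect ``min_beams`` beams.

    A vertical body segment of height ``h`` placed at an arbitrary
    vertical offset intersects a beam when the closed interval
    ``[offset, offset + h]`` contains the beam's coordinate.  The
    smallest ``h`` for which *every* offset yields at least
    ``min_beams`` intersections is found by brute force: candidate
    heights are swept in ``height_step`` increments and, for each, all
    offsets across one beam pitch in ``offset_step`` increments.

    The closed-form answer is ``min_beams * beam_spacing``; the sweep is
    kept as the package's deliberately independent geometric argument
    and agrees with the closed form to within the sweep resolution.
    """
    if min_beams < 1:
        raise ValueError("min_beams must be >= 1")
    if min_beams > config.n_beams:
        raise ValueError(
            f"cannot guarantee {min_beams} beams with only {config.n_beams} in the array"
        )
    # Work on an integer grid (units of offset_step) so interval/beam
    # intersection counting is exact.
    scale = 1.0 / offset_step
    s = int(round(config.beam_spacing * scale))
    h_step = int(round(height_step * scale))
    if s <= 0 or h_step <= 0:
        raise ValueError("offset_step/height_step too coarse for this geometry")

    def worst_case_count(h: int) -> int:
        worst = np.inf
        for off in range(0, s):
            # beams at multiples of s hit by [off, off + h]
            count = (off + h) // s - (-(-off // s)) + 1
            if count < worst:
                worst = count
        return int(worst)

    h = h_step
    h_max = (min_beams + 1) * s
    while h <= h_max:
        if worst_case_count(h) >= min_beams:
            return h / scale
        h += h_step
    raise RuntimeError("sweep failed to find a guaranteeing height")  # pragma: no cover
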