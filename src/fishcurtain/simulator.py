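"""Physics-grounded simulator of fish passages through the IR curtain.

Fish are rigid 2-D silhouettes (ellipse or rectangle) moving
horizontally at constant speed, perpendicular to the curtain — the same
idealization the estimation pipeline itself assumes.  Beam ``j`` of the
array at horizontal position ``x`` is interrupted at frame ``k``
whenever the body region covers the point ``(x, j * beam_spacing)`` at
time ``k / f``.  Arrays A and B sit at ``x = 0`` and ``x = array_gap``.

On top of clean passages the simulator reproduces the field failure
modes of a partially submerged curtain:

* **case I** — a surface-distortion band (persistent interruption of
  the top beams on both arrays) overlapping a single fish's crossing;
* **case II** — a second fish fully masked by the band kicked up by a
  preceding fish;
* **case III** — two fish with overlapping crossing intervals at
  different depths, merged into one candidate;
* **case IV** — a fish that enters, then reverses before clearing the
  far array, self-cancelling its direction estimates;

plus seeded Poisson "blips": single-beam, single-frame spurious
interruptions.  Every stream is deterministic given its specs and seed.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .sensor_model import BeamStream, SensorConfig, beam_positions

__all__ = [
    "FishSpec",
    "NoiseSpec",
    "TruthRecord",
    "DEFAULT_START_TIME",
    "simulate_passage",
    "simulate_scenario",
    "scenario_case",
    "scenario_from_dict",
    "write_truth",
    "read_truth",
]

DEFAULT_START_TIME = _dt.datetime(2025, 7, 1, 0, 0, 0, tzinfo=_dt.timezone.utc)

SCENARIO_TAGS = ("clean", "case_I", "case_II", "case_III", "case_IV", "noise_only")

_GEOM_EPS = 1e-9  # closed-boundary tolerance for coverage tests


@dataclass(frozen=True)
class FishSpec:
    """A rigid fish crossing the curtain.

    ``entry_time`` is the instant (seconds from stream start) at which
    the leading edge reaches the first array on its path.  ``direction``
    +1 travels A-to-B.  ``turn_after`` (cm), when set, makes the fish
    reverse after its leading edge has advanced that far past its entry
    array — the self-cancelling case-IV trajectory.
    """

    length: float
    height: float
    depth_center: float
    speed: float
    direction: int = 1
    shape: str = "ellipse"
    entry_time: float = 0.0
    turn_after: float | None = None

    def __post_init__(self) -> None:
        if self.length <= 0 or self.height <= 0 or self.speed <= 0:
            raise ValueError("length, height and speed must be > 0")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")
        if self.shape not in ("ellipse", "rectangle"):
            raise ValueError("shape must be 'ellipse' or 'rectangle'")
        if self.turn_after is not None and self.turn_after <= 0:
            raise ValueError("turn_after must be > 0 when set")


@dataclass(frozen=True)
class NoiseSpec:
    """Stochastic disturbances; the seed is mandatory for reproducibility.

    ``spurious_rate`` is the expected number of single-beam one-frame
    blips per second (Poisson).  A surface band interrupts the top
    ``surface_band_beams`` beams of both arrays for
    ``surface_band_duration`` seconds starting at ``surface_band_start``.
    """

    seed: int
    spurious_rate: float = 0.0
    surface_band_beams: int = 0
    surface_band_start: float = 0.0
    surface_band_duration: float = 0.0

    def __post_init__(self) -> None:
        if self.spurious_rate < 0 or self.surface_band_beams < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.surface_band_duration < 0 or self.surface_band_start < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated fish (or pure-noise stream)."""

    fish: FishSpec | None
    scenario_tag: str
    expected_detectable: bool
    timestamp: _dt.datetime

    def __post_init__(self) -> None:
        if self.scenario_tag not in SCENARIO_TAGS:
            raise ValueError(f"unknown scenario tag {self.scenario_tag!r}")


def _half_widths(fish: FishSpec, config: SensorConfig) -> np.ndarray:
    """Horizontal half-width of the body at each beam height; NaN where
    the beam lies outside the body's vertical band."""
    dy = beam_positions(config) - fish.depth_center
    half_h = fish.height / 2.0
    inside = np.abs(dy) <= half_h + _GEOM_EPS
    hw = np.full(config.n_beams, np.nan)
    if fish.shape == "rectangle":
        hw[inside] = fish.length / 2.0
    else:  # ellipse
        frac = np.clip(1.0 - (dy[inside] / half_h) ** 2, 0.0, None)
        hw[inside] = (fish.length / 2.0) * np.sqrt(frac)
    return hw


def _center_positions(fish: FishSpec, times: np.ndarray, config: SensorConfig) -> np.ndarray:
    """Body-center x(t).  The leading edge reaches the entry array at
    ``entry_time``; a ``turn_after`` trajectory is triangular in time."""
    half_l = fish.length / 2.0
    if fish.direction == 1:
        x0, sgn = -half_l, 1.0
    else:
        x0, sgn = config.array_gap + half_l, -1.0
    travel = fish.speed * (times - fish.entry_time)
    if fish.turn_after is not None:
        t_turn = fish.turn_after / fish.speed
        travel = np.where(
            times - fish.entry_time <= t_turn,
            travel,
            2 * fish.turn_after - travel,
        )
    return x0 + sgn * travel


def _occupancy(fish: FishSpec, n_frames: int, config: SensorConfig) -> tuple[np.ndarray, np.ndarray]:
    """(frames x beams) boolean interruption masks for arrays A and B."""
    times = np.arange(n_frames) / config.sampling_rate
    xc = _center_positions(fish, times, config)
    hw = _half_widths(fish, config)  # (beams,)
    with np.errstate(invalid="ignore"):
        int_a = np.abs(0.0 - xc)[:, None] <= hw[None, :] + _GEOM_EPS
        int_b = np.abs(config.array_gap - xc)[:, None] <= hw[None, :] + _GEOM_EPS
    return np.nan_to_num(int_a, nan=0).astype(bool), np.nan_to_num(int_b, nan=0).astype(bool)


def _vertically_detectable(fish: FishSpec, config: SensorConfig) -> bool:
    pos = beam_positions(config)
    lo = fish.depth_center - fish.height / 2.0 - _GEOM_EPS
    hi = fish.depth_center + fish.height / 2.0 + _GEOM_EPS
    return bool(((pos >= lo) & (pos <= hi)).any())


def simulate_passage(
    fish: FishSpec,
    config: SensorConfig | None = None,
    stream_length_s: float = 10.0,
    start_time: _dt.datetime = DEFAULT_START_TIME,
) -> tuple[BeamStream, TruthRecord]:
    """Simulate a single fish crossing an otherwise quiet curtain.

    Deterministic given its inputs.  A fish whose body lies entirely
    between/outside the beam lines produces a stream with no
    interruptions and ``expected_detectable=False``.
    """
    config = config or SensorConfig()
    n_frames = int(round(stream_length_s * config.sampling_rate))
    int_a, int_b = _occupancy(fish, n_frames, config)
    states_a = np.where(int_a, 0, 1).astype(np.uint8)
    states_b = np.where(int_b, 0, 1).astype(np.uint8)
    stream = BeamStream(config, start_time, states_a, states_b)
    truth = TruthRecord(
        fish=fish,
        scenario_tag="clean",
        expected_detectable=_vertically_detectable(fish, config),
        timestamp=start_time + _dt.timedelta(seconds=fish.entry_time),
    )
    return stream, truth


def simulate_scenario(
    fishes: Sequence[FishSpec],
    noise: NoiseSpec | None = None,
    config: SensorConfig | None = None,
    tags: Sequence[str] | None = None,
    detectable_overrides: Sequence[bool | None] | None = None,
    stream_length_s: float = 10.0,
    start_time: _dt.datetime = DEFAULT_START_TIME,
) -> tuple[BeamStream, list[TruthRecord]]:
    """Superimpose passages and noise into one stream with ground truth.

    Interruptions accumulate (logical OR); noise never turns an
    interrupted cell intact.  ``tags`` assigns a scenario tag per fish
    (default ``clean``); ``detectable_overrides`` lets a scenario mark a
    fish as not expected to be detectable (e.g. a case-II masked fish).
    """
    config = config or SensorConfig()
    n_frames = int(round(stream_length_s * config.sampling_rate))
    int_a = np.zeros((n_frames, config.n_beams), dtype=bool)
    int_b = np.zeros_like(int_a)
    truths: list[TruthRecord] = []
    tags = list(tags) if tags is not None else ["clean"] * len(fishes)
    overrides = (
        list(detectable_overrides)
        if detectable_overrides is not None
        else [None] * len(fishes)
    )
    if len(tags) != len(fishes) or len(overrides) != len(fishes):
        raise ValueError("tags/overrides must align with fishes")
    for fish, tag, override in zip(fishes, tags, overrides):
        fa, fb = _occupancy(fish, n_frames, config)
        int_a |= fa
        int_b |= fb
        detectable = (
            override if override is not None else _vertically_detectable(fish, config)
        )
        truths.append(
            TruthRecord(
                fish=fish,
                scenario_tag=tag,
                expected_detectable=detectable,
                timestamp=start_time + _dt.timedelta(seconds=fish.entry_time),
            )
        )
    if noise is not None:
        rng = np.random.default_rng(noise.seed)
        if noise.surface_band_beams > 0 and noise.surface_band_duration > 0:
            k0 = int(math.floor(noise.surface_band_start * config.sampling_rate))
            k1 = int(
                math.ceil(
                    (noise.surface_band_start + noise.surface_band_duration)
                    * config.sampling_rate
                )
            )
            k0, k1 = max(0, k0), min(n_frames, k1)
            top = slice(config.n_beams - noise.surface_band_beams, config.n_beams)
            int_a[k0:k1, top] = True
            int_b[k0:k1, top] = True
        if noise.spurious_rate > 0:
            n_blips = rng.poisson(noise.spurious_rate * stream_length_s)
            for _ in range(n_blips):
                k = int(rng.integers(0, n_frames))
                j = int(rng.integers(0, config.n_beams))
                side = rng.integers(0, 2)
                (int_a if side == 0 else int_b)[k, j] = True
        if not fishes:
            truths.append(
                TruthRecord(
                    fish=None,
                    scenario_tag="noise_only",
                    expected_detectable=False,
                    timestamp=start_time,
                )
            )
    states_a = np.where(int_a, 0, 1).astype(np.uint8)
    states_b = np.where(int_b, 0, 1).astype(np.uint8)
    return BeamStream(config, start_time, states_a, states_b), truths


def _centered_depth(config: SensorConfig) -> float:
    return (config.n_beams - 1) * config.beam_spacing / 2.0


def scenario_case(
    case: str,
    config: SensorConfig | None = None,
    seed: int = 0,
    stream_length_s: float = 12.0,
    start_time: _dt.datetime = DEFAULT_START_TIME,
) -> tuple[BeamStream, list[TruthRecord]]:
    """Canned scenario for each error category (and clean/noise-only).

    Fish parameters follow the larger validation replica (16.5 cm long,
    6.4 cm high) at a typical 30 cm/s cruise unless the mechanism
    requires otherwise.
    """
    config = config or SensorConfig()
    depth_mid = _centered_depth(config)
    span_top = config.n_beams * config.beam_spacing
    base = FishSpec(
        length=16.5, height=6.4, depth_center=depth_mid, speed=30.0,
        direction=1, shape="ellipse", entry_time=2.0,
    )
    crossing_s = (base.length + config.array_gap) / base.speed

    if case == "clean":
        return simulate_scenario(
            [base], None, config, ["clean"], None, stream_length_s, start_time
        )
    if case == "case_I":
        # band overlaps the single fish's crossing and merges with it
        fish = replace(base, depth_center=span_top - 6.0)
        noise = NoiseSpec(
            seed=seed, surface_band_beams=6,
            surface_band_start=max(0.0, fish.entry_time - 1.0),
            surface_band_duration=crossing_s + 2.0,
        )
        return simulate_scenario(
            [fish], noise, config, ["case_I"], None, stream_length_s, start_time
        )
    if case == "case_II":
        fish1 = base
        fish2 = replace(base, entry_time=7.0, depth_center=span_top - 4.0)
        band_start = fish1.entry_time + crossing_s + 0.5
        noise = NoiseSpec(
            seed=seed, surface_band_beams=8,
            surface_band_start=band_start,
            surface_band_duration=stream_length_s - band_start,
        )
        return simulate_scenario(
            [fish1, fish2], noise, config, ["clean", "case_II"],
            [None, False], stream_length_s, start_time,
        )
    if case == "case_III":
        fish1 = base
        fish2 = replace(base, entry_time=2.25, depth_center=depth_mid + 12.0)
        return simulate_scenario(
            [fish1, fish2], None, config, ["case_III", "case_III"],
            None, stream_length_s, start_time,
        )
    if case == "case_IV":
        fish = replace(base, turn_after=config.array_gap + 2.0)
        return simulate_scenario(
            [fish], None, config, ["case_IV"], None, stream_length_s, start_time
        )
    if case == "noise_only":
        noise = NoiseSpec(seed=seed, spurious_rate=2.0)
        return simulate_scenario(
            [], noise, config, [], None, stream_length_s, start_time
        )
    raise ValueError(f"unknown case {case!r}")


def scenario_from_dict(
    spec: dict,
    config: SensorConfig | None = None,
    seed: int | None = None,
) -> tuple[BeamStream, list[TruthRecord]]:
    """Build a scenario from a parsed YAML/JSON mapping.

    Recognized keys: ``stream_length_s``, ``start_time`` (ISO-8601),
    ``config`` (sensor overrides), ``fishes`` (list of FishSpec fields
    plus optional ``tag`` and ``expected_detectable``), ``noise``
    (NoiseSpec fields; its seed may come from the ``seed`` argument).
    """
    if config is None and "config" in spec:
        config = SensorConfig.from_dict(spec["config"])
    config = config or SensorConfig()
    stream_length_s = float(spec.get("stream_length_s", 10.0))
    start_time = DEFAULT_START_TIME
    if "start_time" in spec:
        start_time = _dt.datetime.fromisoformat(spec["start_time"])
        if start_time.tzinfo is None:
            start_time = start_time.replace(tzinfo=_dt.timezone.utc)
    fishes, tags, overrides = [], [], []
    for f in spec.get("fishes", []):
        f = dict(f)
        tags.append(f.pop("tag", "clean"))
        overrides.append(f.pop("expected_detectable", None))
        fishes.append(FishSpec(**f))
    noise = None
    if "noise" in spec and spec["noise"]:
        n = dict(spec["noise"])
        if "seed" not in n:
            if seed is None:
                raise ValueError("noise requested but no seed provided")
            n["seed"] = seed
        noise = NoiseSpec(**n)
    return simulate_scenario(
        fishes, noise, config, tags, overrides, stream_length_s, start_time
    )


_TRUTH_COLUMNS = (
    "timestamp",
    "scenario_tag",
    "expected_detectable",
    "length_cm",
    "height_cm",
    "speed_cm_s",
    "direction",
)


def write_truth(truths: Sequence[TruthRecord], path) -> Path:
    """Ground-truth sidecar as TSV (one row per simulated fish)."""
    path = Path(path)
    lines = ["\t".join(_TRUTH_COLUMNS)]
    for t in truths:
        fish = t.fish
        lines.append(
            "\t".join(
                [
                    t.timestamp.strftime("%Y-%m-%dT%H:%M:%S.%f%z"),
                    t.scenario_tag,
                    str(int(t.expected_detectable)),
                    f"{fish.length:.2f}" if fish else "",
                    f"{fish.height:.2f}" if fish else "",
                    f"{fish.speed:.2f}" if fish else "",
                    str(fish.direction) if fish else "",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_truth(path) -> list[TruthRecord]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != list(_TRUTH_COLUMNS):
        raise ValueError("not a truth TSV")
    records = []
    for line in lines[1:]:
        if not line.strip():
            continue
        ts_s, tag, det, length, height, speed, direction = line.split("\t")
        fish = None
        if length:
            fish = FishSpec(
                length=float(length),
                height=float(height),
                depth_center=0.0,
                speed=float(speed),
                direction=int(direction),
            )
        records.append(
            TruthRecord(
                fish=fish,
                scenario_tag=tag,
                expected_detectable=bool(int(det)),
                timestamp=_dt.datetime.strptime(ts_s, "%Y-%m-%dT%H:%M:%S.%f%z"),
            )
        )
    return records
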