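"""Plain-text log files: hourly streams, per-event clips, the event log.

The logging side of the instrument stores the raw beam-state matrix in
hourly text files; the classification side reads them back, writes one
clip file per validated event and appends a one-line summary per event
to a central tab-separated event log.  The dialect here is fixed so
that write/read round-trips are bit-exact:

* line 1 — header: ``# fishcurtain-log v1`` followed by ``key=value``
  pairs carrying the sensor configuration and the ISO-8601 start time;
* one line per frame — ``frame_index<TAB>A-states<TAB>B-states`` where
  each state block is ``n_beams`` characters of ``0`` (interrupted) or
  ``1`` (intact), beam 0 first.
"""

from __future__ import annotations

import datetime as _dt
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .sensor_model import BeamStream, SensorConfig

__all__ = [
    "StreamFormatError",
    "EventLogRecord",
    "write_log",
    "read_log",
    "check_calibration",
    "CalibrationReport",
    "write_event_clip",
    "append_event_log",
    "read_event_log",
]

_HEADER_MAGIC = "# fishcurtain-log v1"
_TIMESTAMP_FMT = "%Y-%m-%dT%H:%M:%S.%f%z"


class StreamFormatError(ValueError):
    """Malformed stream log; carries the 1-based offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


def _format_time(t: _dt.datetime) -> str:
    if t.tzinfo is None:
        t = t.replace(tzinfo=_dt.timezone.utc)
    return t.strftime(_TIMESTAMP_FMT)


def _parse_time(s: str) -> _dt.datetime:
    return _dt.datetime.strptime(s, _TIMESTAMP_FMT)


def _header_line(stream: BeamStream) -> str:
    c = stream.config
    pairs = [
        f"n_beams={c.n_beams}",
        f"beam_spacing_cm={c.beam_spacing!r}",
        f"array_gap_cm={c.array_gap!r}",
        f"sampling_rate_hz={c.sampling_rate!r}",
        f"height_filter_threshold_cm={c.height_filter_threshold!r}",
        f"height_correction_cm={c.height_correction!r}",
        f"labels={c.array_labels[0]},{c.array_labels[1]}",
        f"upstream={c.upstream_label}",
        f"start={_format_time(stream.start_time)}",
    ]
    return _HEADER_MAGIC + " " + " ".join(pairs)


def write_log(stream: BeamStream, path: str | os.PathLike) -> Path:
    """Write a stream to a log file in the fixed-width text dialect."""
    path = Path(path)
    lines = [_header_line(stream)]
    for k in range(stream.n_frames):
        a = "".join("1" if v else "0" for v in stream.states_a[k])
        b = "".join("1" if v else "0" for v in stream.states_b[k])
        lines.append(f"{k}\t{a}\t{b}")
    path.write_text("\n".join(lines) + "\n")
    return path


def _parse_header(line: str) -> tuple[SensorConfig, _dt.datetime]:
    if not line.startswith(_HEADER_MAGIC):
        raise StreamFormatError("missing log header", 1)
    fields = dict(
        kv.split("=", 1) for kv in line[len(_HEADER_MAGIC) :].split() if "=" in kv
    )
    try:
        labels = tuple(fields.get("labels", "A,B").split(","))
        config = SensorConfig(
            n_beams=int(fields["n_beams"]),
            beam_spacing=float(fields["beam_spacing_cm"]),
            array_gap=float(fields["array_gap_cm"]),
            sampling_rate=float(fields["sampling_rate_hz"]),
            height_filter_threshold=float(fields["height_filter_threshold_cm"]),
            height_correction=float(fields["height_correction_cm"]),
            array_labels=labels,  # type: ignore[arg-type]
            upstream_label=fields.get("upstream", labels[0]),
        )
        start = _parse_time(fields["start"])
    except (KeyError, ValueError) as exc:
        raise StreamFormatError(f"bad header: {exc}", 1) from exc
    return config, start


def _parse_states(block: str, n_beams: int, line_no: int) -> np.ndarray:
    if len(block) != n_beams:
        raise StreamFormatError(
            f"expected {n_beams} state characters, got {len(block)}", line_no
        )
    if set(block) - {"0", "1"}:
        raise StreamFormatError("non-binary state character", line_no)
    return np.frombuffer(block.encode("ascii"), dtype=np.uint8) - ord("0")


def read_log(path: str | os.PathLike) -> BeamStream:
    """Read a stream log written by :func:`write_log`."""
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines:
        raise StreamFormatError("empty file", 1)
    config, start = _parse_header(lines[0])
    rows_a, rows_b = [], []
    expected_index = 0
    for line_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise StreamFormatError(
                f"expected 3 tab-separated fields, got {len(parts)}", line_no
            )
        try:
            idx = int(parts[0])
        except ValueError:
            raise StreamFormatError("non-integer frame index", line_no) from None
        if idx != expected_index:
            raise StreamFormatError(
                f"non-monotonic frame index {idx} (expected {expected_index})", line_no
            )
        rows_a.append(_parse_states(parts[1], config.n_beams, line_no))
        rows_b.append(_parse_states(parts[2], config.n_beams, line_no))
        expected_index += 1
    if rows_a:
        states_a = np.stack(rows_a)
        states_b = np.stack(rows_b)
    else:
        states_a = np.zeros((0, config.n_beams), dtype=np.uint8)
        states_b = states_a.copy()
    return BeamStream(config, start, states_a, states_b)


@dataclass(frozen=True)
class CalibrationReport:
    """Per-beam health summary over a fish-free window."""

    window_frames: int
    intact_fraction_a: np.ndarray
    intact_fraction_b: np.ndarray
    flagged: tuple[tuple[str, int], ...]

    @property
    def ok(self) -> bool:
        return not self.flagged


def check_calibration(
    stream: BeamStream, window_frames: int, intact_threshold: float = 0.99
) -> CalibrationReport:
    """Flag beams that are not reliably intact under fish-free conditions.

    A healthy beam reads intact in at least ``intact_threshold`` of the
    window's frames; anything below (stuck-interrupted or flickering)
    is flagged as ``(array_label, beam_index)``.
    """
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    if stream.n_frames == 0:
        raise ValueError("cannot calibrate from an empty stream")
    if stream.n_frames < window_frames:
        raise ValueError(
            f"stream has {stream.n_frames} frames; window needs {window_frames}"
        )
    frac_a = stream.states_a[:window_frames].mean(axis=0)
    frac_b = stream.states_b[:window_frames].mean(axis=0)
    label_a, label_b = stream.config.array_labels
    flagged = []
    for label, frac in ((label_a, frac_a), (label_b, frac_b)):
        for j in np.nonzero(frac < intact_threshold)[0]:
            flagged.append((label, int(j)))
    return CalibrationReport(window_frames, frac_a, frac_b, tuple(flagged))


@dataclass(frozen=True)
class EventLogRecord:
    """One line of the central event log.

    ``direction`` is the signed travel direction (+1 = first-to-second
    array); ``direction_label`` the upstream/downstream word derived
    from the mounting configuration.  Velocity, length and height are in
    cm/s and cm, formatted at 0.01 precision on disk.
    """

    timestamp: _dt.datetime
    direction: int
    direction_label: str
    velocity: float
    length: float
    height: float
    event_id: str
    source_clip: str

    def approx_equal(self, other: "EventLogRecord", tol: float = 0.01) -> bool:
        return (
            self.timestamp == other.timestamp
            and self.direction == other.direction
            and self.direction_label == other.direction_label
            and abs(self.velocity - other.velocity) <= tol
            and abs(self.length - other.length) <= tol
            and abs(self.height - other.height) <= tol
            and self.event_id == other.event_id
        )


def event_id_for(timestamp: _dt.datetime) -> str:
    return timestamp.strftime("event_%Y%m%dT%H%M%S_%f")


def write_event_clip(event, clip_dir: str | os.PathLike) -> Path:
    """Write the raw frame slice of a validated event as a clip file.

    The clip is a stand-alone stream log whose start time is the event
    timestamp, so it can be re-read and re-analyzed in isolation.
    """
    clip_dir = Path(clip_dir)
    clip_dir.mkdir(parents=True, exist_ok=True)
    candidate = event.candidate
    sub = BeamStream(
        candidate.config, event.timestamp, candidate.states_a, candidate.states_b
    )
    path = clip_dir / (event_id_for(event.timestamp) + ".log")
    return write_log(sub, path)


def append_event_log(record: EventLogRecord, path: str | os.PathLike) -> str:
    """Append one tab-separated summary line; returns the line written."""
    line = "\t".join(
        [
            _format_time(record.timestamp),
            record.direction_label,
            f"{record.velocity:.2f}",
            f"{record.length:.2f}",
            f"{record.height:.2f}",
            record.source_clip,
        ]
    )
    with open(path, "a") as fh:
        fh.write(line + "\n")
    return line


def read_event_log(
    path: str | os.PathLike, config: SensorConfig | None = None
) -> list[EventLogRecord]:
    """Parse the central event log back into records.

    ``config`` resolves the upstream/downstream label back to a signed
    direction; with no config the default A-upstream mapping is used.
    """
    if config is None:
        config = SensorConfig()
    records = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        ts_s, dir_label, vel_s, len_s, hgt_s, clip = line.split("\t")
        ts = _parse_time(ts_s)
        direction = 1 if config.direction_label(1) == dir_label else -1
        records.append(
            EventLogRecord(
                timestamp=ts,
                direction=direction,
                direction_label=dir_label,
                velocity=float(vel_s),
                length=float(len_s),
                height=float(hgt_s),
                event_id=event_id_for(ts),
                source_clip=clip,
            )
        )
    return records
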