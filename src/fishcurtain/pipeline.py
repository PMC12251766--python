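"""The hourly classification chain: read, segment, clean, estimate, filter.

This is the batch routine that turns one closed stream log into
validated passage events, per-event clip files, appended event-log
lines, and a rejection audit sidecar.  Hourly scheduling itself is
deployment glue and is not modelled; any closed log file can be
processed at any time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from . import stream_io
from .event_detection import CandidateEvent, remove_random_lines, segment_events
from .event_filter import RejectedEvent, filter_events
from .kinematics import PassageEvent, analyze_candidate
from .sensor_model import BeamStream
from .stream_io import EventLogRecord

__all__ = ["PipelineParams", "ClassifyResult", "classify_stream", "classify_log"]


@dataclass(frozen=True)
class PipelineParams:
    """Tunable thresholds of the detection chain (all config-exposed)."""

    gap_frames: int = 5
    min_active_frames: int = 2
    noise_max_width_frames: int = 2
    noise_max_height_beams: int = 1
    require_cross_array: bool = True
    max_velocity: float | None = None


@dataclass(frozen=True)
class ClassifyResult:
    n_candidates: int
    accepted: tuple[PassageEvent, ...]
    rejected: tuple[RejectedEvent, ...]

    def summary(self) -> str:
        reasons: dict[str, int] = {}
        for r in self.rejected:
            reasons[r.reason] = reasons.get(r.reason, 0) + 1
        reason_s = ", ".join(f"{k}={v}" for k, v in sorted(reasons.items())) or "none"
        return (
            f"candidates={self.n_candidates} accepted={len(self.accepted)} "
            f"rejected={len(self.rejected)} (by reason: {reason_s})"
        )


def classify_stream(
    stream: BeamStream, params: PipelineParams | None = None
) -> ClassifyResult:
    """Run segmentation, noise removal, estimation and filtering."""
    params = params or PipelineParams()
    candidates = segment_events(
        stream,
        gap_frames=params.gap_frames,
        min_active_frames=params.min_active_frames,
    )
    n_candidates = len(candidates)
    cleaned: list[CandidateEvent] = []
    for cand in candidates:
        c = remove_random_lines(
            cand,
            max_width_frames=params.noise_max_width_frames,
            max_height_beams=params.noise_max_height_beams,
            require_cross_array=params.require_cross_array,
        )
        if c is not None and c.n_active_frames() >= params.min_active_frames:
            cleaned.append(c)
    analyzed = [(c, analyze_candidate(c, stream=stream)) for c in cleaned]
    accepted, rejected = filter_events(
        analyzed, stream.config, max_velocity=params.max_velocity
    )
    return ClassifyResult(n_candidates, tuple(accepted), tuple(rejected))


def classify_log(
    log_path: str | Path,
    out_dir: str | Path,
    params: PipelineParams | None = None,
    keep_rejected: bool = True,
) -> ClassifyResult:
    """Classify one stream log file and write all output artifacts.

    Writes per-event clips under ``<out_dir>/classifiedEvents/``,
    appends summaries to ``<out_dir>/event_log.txt`` and, when
    ``keep_rejected``, a rejection audit to ``<out_dir>/rejected.tsv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stream = stream_io.read_log(log_path)
    result = classify_stream(stream, params)
    clip_dir = out_dir / "classifiedEvents"
    event_log = out_dir / "event_log.txt"
    for ev in result.accepted:
        clip_path = stream_io.write_event_clip(ev, clip_dir)
        record = EventLogRecord(
            timestamp=ev.timestamp,
            direction=ev.direction,
            direction_label=stream.config.direction_label(ev.direction),
            velocity=ev.velocity.mean,
            length=ev.morphometrics.length,
            height=ev.morphometrics.height,
            event_id=stream_io.event_id_for(ev.timestamp),
            source_clip=str(clip_path.relative_to(out_dir)),
        )
        stream_io.append_event_log(record, event_log)
    if not event_log.exists():
        event_log.touch()
    if keep_rejected:
        audit = out_dir / "rejected.tsv"
        with open(audit, "a") as fh:
            for r in result.rejected:
                v = r.estimates.velocity.mean
                fh.write(
                    "\t".join(
                        [
                            r.estimates.timestamp.strftime("%Y-%m-%dT%H:%M:%S.%f%z"),
                            r.reason,
                            f"{v:.2f}" if v is not None else "NA",
                            f"{r.estimates.morphometrics.height:.2f}",
                        ]
                    )
                    + "\n"
                )
    return result
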