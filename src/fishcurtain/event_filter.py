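"""Three-criterion validity filter for candidate events.

A candidate becomes a validated passage only if it shows

1. **directional consistency** — the entry and exit direction estimates
   sum to a non-zero value (a turnaround or an oscillating body sums to
   zero and is rejected);
2. **velocity plausibility** — a defined, strictly positive mean
   gap-transit speed (stationary debris gives none);
3. **morphological coherence** — an estimated height at or above the
   biologically plausible threshold (default 1.5 cm).

Criteria are evaluated in this order and the first failure becomes the
rejection reason, giving deterministic reason codes for the audit
sidecar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .event_detection import CandidateEvent
from .kinematics import EventEstimates, PassageEvent
from .sensor_model import SensorConfig

__all__ = ["RejectedEvent", "filter_events"]

REASON_DIRECTION = "direction"
REASON_VELOCITY = "velocity"
REASON_HEIGHT = "height"


@dataclass(frozen=True)
class RejectedEvent:
    candidate: CandidateEvent
    estimates: EventEstimates
    reason: str


def _rejection_reason(
    est: EventEstimates, config: SensorConfig, max_velocity: float | None
) -> str | None:
    if est.direction.entry + est.direction.exit == 0:
        return REASON_DIRECTION
    v = est.velocity.mean
    if v is None or v <= 0:
        return REASON_VELOCITY
    if max_velocity is not None and v > max_velocity:
        return REASON_VELOCITY
    if est.morphometrics.height < config.height_filter_threshold:
        return REASON_HEIGHT
    return None


def filter_events(
    candidates: list[tuple[CandidateEvent, EventEstimates]],
    config: SensorConfig | None = None,
    max_velocity: float | None = None,
) -> tuple[list[PassageEvent], list[RejectedEvent]]:
    """Partition candidates into accepted passages and rejections.

    The filter is a pure per-event predicate: accepted and rejected
    lists partition the input and preserve its order.  The final
    direction of an accepted event is ``sign(entry + exit)``, so an
    event with one indeterminate component (for example entry +1,
    exit 0) still resolves to a direction.  ``max_velocity`` optionally
    caps the plausible speed; by default only the zero/undefined case
    is rejected.
    """
    accepted: list[PassageEvent] = []
    rejected: list[RejectedEvent] = []
    for candidate, est in candidates:
        cfg = config or candidate.config
        reason = _rejection_reason(est, cfg, max_velocity)
        if reason is not None:
            rejected.append(RejectedEvent(candidate, est, reason))
            continue
        direction = int(np.sign(est.direction.entry + est.direction.exit))
        accepted.append(
            PassageEvent(
                candidate=candidate,
                direction=direction,
                direction_estimate=est.direction,
                velocity=est.velocity,
                morphometrics=est.morphometrics,
                silhouette=est.silhouette,
                timestamp=est.timestamp,
            )
        )
    return accepted, rejected
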