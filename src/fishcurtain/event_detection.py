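"""Segmentation of a beam stream into candidate passage events.

A frame is *active* when any beam of either array is interrupted.
Maximal runs of active frames become candidate events; runs separated
by a short fully-intact gap are merged, since a fish whose body briefly
clears the curtain (or whose mid-body is narrower than the array gap)
should not be split into two events.  A second pass removes spurious
"random lines": short, vertically thin interruptions with no
counterpart on the other array, typical of electrical noise or debris
glancing a single beam.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .sensor_model import BeamStream, SensorConfig

__all__ = ["CandidateEvent", "segment_events", "remove_random_lines"]

#: 4-connectivity structuring element for blob grouping in the
#: (frame x beam) grid; diagonal contacts are separate blobs.
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class CandidateEvent:
    """A contiguous stream slice hypothesized to contain one passage.

    ``start_frame``/``end_frame`` are inclusive indices into the source
    stream; ``states_a``/``states_b`` are the corresponding state
    slices (0 = interrupted, 1 = intact).
    """

    config: SensorConfig
    start_frame: int
    end_frame: int
    states_a: np.ndarray
    states_b: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame:
            raise ValueError("end_frame must be >= start_frame")
        n = self.end_frame - self.start_frame + 1
        if self.states_a.shape[0] != n or self.states_b.shape[0] != n:
            raise ValueError("state slices inconsistent with frame bounds")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def interrupted_a(self) -> np.ndarray:
        return self.states_a == 0

    def interrupted_b(self) -> np.ndarray:
        return self.states_b == 0

    def activity(self) -> np.ndarray:
        return self.interrupted_a().any(axis=1) | self.interrupted_b().any(axis=1)

    def n_active_frames(self) -> int:
        return int(self.activity().sum())


def _active_runs(activity: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, end) bounds of maximal runs of True."""
    runs = []
    in_run = False
    start = 0
    for k, a in enumerate(activity):
        if a and not in_run:
            in_run, start = True, k
        elif not a and in_run:
            runs.append((start, k - 1))
            in_run = False
    if in_run:
        runs.append((start, len(activity) - 1))
    return runs


def segment_events(
    stream: BeamStream,
    gap_frames: int = 5,
    min_active_frames: int = 2,
    provenance: str = "",
) -> list[CandidateEvent]:
    """Split a stream into disjoint, ordered candidate events.

    Runs of active frames separated by at most ``gap_frames``
    fully-intact frames are merged into one candidate; candidates with
    fewer than ``min_active_frames`` active frames are dropped (a
    single-frame event can yield neither direction nor velocity).
    """
    if gap_frames < 0 or min_active_frames < 1:
        raise ValueError("gap_frames must be >= 0 and min_active_frames >= 1")
    activity = stream.activity()
    runs = _active_runs(activity)
    if not runs:
        return []
    merged: list[list[int]] = [list(runs[0])]
    for start, end in runs[1:]:
        if start - merged[-1][1] - 1 <= gap_frames:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    events = []
    for start, end in merged:
        n_active = int(activity[start : end + 1].sum())
        if n_active < min_active_frames:
            continue
        events.append(
            CandidateEvent(
                config=stream.config,
                start_frame=start,
                end_frame=end,
                states_a=stream.states_a[start : end + 1].copy(),
                states_b=stream.states_b[start : end + 1].copy(),
                provenance=provenance,
            )
        )
    return events


def _spurious_mask(
    interrupted: np.ndarray,
    other_interrupted: np.ndarray,
    max_width_frames: int,
    max_height_beams: int,
    require_cross_array: bool,
    cross_array_tol_frames: int,
) -> np.ndarray:
    """Boolean mask of interrupted cells belonging to spurious blobs."""
    mask = np.zeros_like(interrupted, dtype=bool)
    labels, n = ndimage.label(interrupted, structure=_CROSS)
    if n == 0:
        return mask
    other_active = other_interrupted.any(axis=1)
    n_frames = interrupted.shape[0]
    for label_id, (sl_f, sl_b) in enumerate(ndimage.find_objects(labels), start=1):
        width = sl_f.stop - sl_f.start
        height = sl_b.stop - sl_b.start
        if width > max_width_frames or height > max_height_beams:
            continue
        if require_cross_array:
            lo = max(0, sl_f.start - cross_array_tol_frames)
            hi = min(n_frames, sl_f.stop + cross_array_tol_frames)
            if other_active[lo:hi].any():
                continue  # a counterpart exists on the other array
        mask[sl_f, sl_b] |= labels[sl_f, sl_b] == label_id
    return mask


def remove_random_lines(
    event: CandidateEvent,
    max_width_frames: int = 2,
    max_height_beams: int = 1,
    require_cross_array: bool = True,
    cross_array_tol_frames: int | None = None,
) -> CandidateEvent | None:
    """Reset spurious interruptions to intact; drop an emptied event.

    A 4-connected blob of interrupted cells is spurious when its
    temporal width is at most ``max_width_frames`` frames, its vertical
    extent at most ``max_height_beams`` beams, and (when
    ``require_cross_array``) the other array shows no interruption
    within ``cross_array_tol_frames`` of the blob — a real body crossing
    the curtain marks both arrays within roughly the gap-transit time,
    noise does not.  Decisions are taken simultaneously on the input
    state, which makes the operation idempotent.  After cleaning, the
    event is re-trimmed to its active bounds; if nothing remains the
    event is dropped (``None``).
    """
    if cross_array_tol_frames is None:
        cross_array_tol_frames = max_width_frames
    int_a = event.interrupted_a()
    int_b = event.interrupted_b()
    bad_a = _spurious_mask(
        int_a, int_b, max_width_frames, max_height_beams,
        require_cross_array, cross_array_tol_frames,
    )
    bad_b = _spurious_mask(
        int_b, int_a, max_width_frames, max_height_beams,
        require_cross_array, cross_array_tol_frames,
    )
    states_a = event.states_a.copy()
    states_b = event.states_b.copy()
    states_a[bad_a] = 1
    states_b[bad_b] = 1
    activity = ((states_a == 0).any(axis=1)) | ((states_b == 0).any(axis=1))
    active = np.nonzero(activity)[0]
    if active.size == 0:
        return None
    lo, hi = int(active[0]), int(active[-1])
    return CandidateEvent(
        config=event.config,
        start_frame=event.start_frame + lo,
        end_frame=event.start_frame + hi,
        states_a=states_a[lo : hi + 1],
        states_b=states_b[lo : hi + 1],
        provenance=event.provenance,
    )
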