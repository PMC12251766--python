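"""Detection scoring against ground truth and morphometric validation.

Detections are matched one-to-one to truth records by nearest
timestamp; unmatched detectable truths are misses, unmatched detections
false positives.  Misses carry their simulated scenario tag, so the
error taxonomy (surface distortion, masking, overlap, self-cancelling)
can be tabulated exactly as in a field hit/miss protocol.

The allometric comparison checks internal consistency of the two
independent size channels: directly estimated length L versus length
predicted from height H through ``L = b * H`` with the cultivated-carp
band ``b`` in [2.5, 3.0].  Events are binned by height (1.5 cm bins),
bin medians computed, and a least-squares line fitted to the medians.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kinematics import PassageEvent
from .simulator import TruthRecord

__all__ = [
    "MatchResult",
    "match_events",
    "detection_rate",
    "categorize_errors",
    "AllometricReport",
    "allometric_compare",
]

ERROR_TAGS = ("case_I", "case_II", "case_III", "case_IV")


@dataclass(frozen=True)
class MatchResult:
    """One-to-one matching of detections to truth records.

    ``undetectable_unmatched`` holds unmatched truths that were never
    expected to be detectable (e.g. a fully masked fish); they count
    neither as hits nor misses.
    """

    hits: tuple[tuple[object, TruthRecord], ...]
    misses: tuple[TruthRecord, ...]
    false_positives: tuple[object, ...]
    undetectable_unmatched: tuple[TruthRecord, ...]


def _timestamp(obj) -> _dt.datetime:
    return obj.timestamp if hasattr(obj, "timestamp") else obj


def match_events(
    detected: Sequence,
    truth: Sequence[TruthRecord],
    time_tol_s: float = 2.0,
) -> MatchResult:
    """Greedy nearest-timestamp matching within ``time_tol_s`` seconds.

    Candidate pairs are ordered by absolute time difference and matched
    greedily one-to-one, which is invariant under a common time
    translation of both lists.
    """
    pairs = []
    for i, det in enumerate(detected):
        td = _timestamp(det)
        for j, tr in enumerate(truth):
            dt = abs((td - tr.timestamp).total_seconds())
            if dt <= time_tol_s:
                pairs.append((dt, i, j))
    pairs.sort(key=lambda p: (p[0], p[1], p[2]))
    used_det: set[int] = set()
    used_truth: set[int] = set()
    hits = []
    for _, i, j in pairs:
        if i in used_det or j in used_truth:
            continue
        used_det.add(i)
        used_truth.add(j)
        hits.append((detected[i], truth[j]))
    misses = []
    undetectable = []
    for j, tr in enumerate(truth):
        if j in used_truth:
            continue
        (misses if tr.expected_detectable else undetectable).append(tr)
    false_positives = [d for i, d in enumerate(detected) if i not in used_det]
    return MatchResult(tuple(hits), tuple(misses), tuple(false_positives), tuple(undetectable))


def detection_rate(hits, truths: Sequence[TruthRecord]) -> float:
    """Percentage of detectable truths that were hit: 100 * hits / truths."""
    n_hits = hits if isinstance(hits, int) else len(hits)
    n_truths = sum(1 for t in truths if t.expected_detectable)
    if n_truths == 0:
        raise ValueError("no detectable truths to score against")
    return 100.0 * n_hits / n_truths


def categorize_errors(misses: Sequence[TruthRecord]) -> pd.DataFrame:
    """Count misses per error category with percentages of all misses.

    Returns a DataFrame indexed by scenario tag with ``count`` and
    ``percentage`` columns; empty when there are no misses.
    Percentages sum to 100 whenever at least one miss exists.
    """
    tags = [m.scenario_tag for m in misses]
    if not tags:
        return pd.DataFrame(columns=["count", "percentage"])
    counts = pd.Series(tags).value_counts()
    order = [t for t in ERROR_TAGS if t in counts.index]
    order += [t for t in counts.index if t not in order]
    counts = counts.reindex(order)
    return pd.DataFrame(
        {"count": counts, "percentage": 100.0 * counts / counts.sum()}
    )


@dataclass(frozen=True)
class AllometricReport:
    """Outcome of the length-vs-height consistency check.

    ``events`` has one row per event (height, length, predicted band,
    inside flag); ``bins`` one row per non-empty height bin (medians and
    interquartile ranges); the regression fields are ``None`` when
    fewer than two bins exist.
    """

    events: pd.DataFrame
    bins: pd.DataFrame
    b_low: float
    b_high: float
    slope: float | None
    intercept: float | None
    rvalue: float | None

    @property
    def fraction_inside(self) -> float:
        if len(self.events) == 0:
            return float("nan")
        return float(self.events["inside"].mean())


def _lengths_heights(events) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(events, pd.DataFrame):
        return events["length"].to_numpy(float), events["height"].to_numpy(float)
    lengths, heights = [], []
    for e in events:
        if isinstance(e, PassageEvent):
            lengths.append(e.morphometrics.length)
            heights.append(e.morphometrics.height)
        else:
            length, height = e
            lengths.append(length)
            heights.append(height)
    return np.asarray(lengths, float), np.asarray(heights, float)


def allometric_compare(
    events,
    b_low: float = 2.5,
    b_high: float = 3.0,
    bin_width_cm: float = 1.5,
) -> AllometricReport:
    """Compare direct length estimates against the allometric band.

    ``events`` may be PassageEvents, ``(length, height)`` pairs, or a
    DataFrame with ``length``/``height`` columns.  Each event is
    flagged inside/outside its predicted band ``[b_low*H, b_high*H]``;
    bin medians per ``bin_width_cm`` height bin get a least-squares
    line (only when at least two bins are populated).
    """
    lengths, heights = _lengths_heights(events)
    if np.isnan(lengths).any() or np.isnan(heights).any():
        raise ValueError("all events must have defined length and height")
    pred_low = b_low * heights
    pred_high = b_high * heights
    inside = (lengths >= pred_low) & (lengths <= pred_high)
    bin_index = np.floor(heights / bin_width_cm).astype(int)
    ev = pd.DataFrame(
        {
            "height": heights,
            "length": lengths,
            "pred_low": pred_low,
            "pred_high": pred_high,
            "inside": inside,
            "bin": bin_index,
        }
    )
    rows = []
    for b, grp in ev.groupby("bin", sort=True):
        q1_l, med_l, q3_l = np.percentile(grp["length"], [25, 50, 75])
        rows.append(
            {
                "bin": b,
                "bin_center": (b + 0.5) * bin_width_cm,
                "n": len(grp),
                "median_height": float(np.median(grp["height"])),
                "median_length": float(med_l),
                "iqr_length": float(q3_l - q1_l),
            }
        )
    bins = pd.DataFrame(rows)
    slope = intercept = rvalue = None
    if len(bins) >= 2:
        fit = stats.linregress(bins["median_height"], bins["median_length"])
        slope, intercept, rvalue = float(fit.slope), float(fit.intercept), float(fit.rvalue)
    return AllometricReport(
        events=ev.drop(columns="bin"),
        bins=bins,
        b_low=b_low,
        b_high=b_high,
        slope=slope,
        intercept=intercept,
        rvalue=rvalue,
    )
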