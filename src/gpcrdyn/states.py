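"""Threshold-box state classifiers and occupancy statistics.

Two classifiers operate on the collective-variable pairs:

* ECL2 gating: the loop is *closed* when delta lies strictly inside
  (24, 33) Angstrom AND beta strictly inside (29, 48) degrees; *open*
  otherwise. Strict inequalities mean boundary values count as open, which
  is conservative with respect to claiming loop closure.
* Activation: *active* when the TM5-TM7 distance d < 19 Angstrom AND the
  TM6 angle theta > 45 degrees; *inactive* when d >= 19 AND theta <= 45;
  *intermediate* when the two criteria disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .geometry import CVSeries

__all__ = [
    "StateThresholds",
    "OccupancyResult",
    "classify_ecl2",
    "classify_activation",
    "occupancy",
    "scatter_table",
]


@dataclass(frozen=True)
class StateThresholds:
    """Classifier boxes for loop gating and receptor activation."""

    delta_min: float = 24.0
    delta_max: float = 33.0
    beta_min: float = 29.0
    beta_max: float = 48.0
    d_active_max: float = 19.0
    theta_active_min: float = 45.0
    # width of the diagnostic border zone flagged (not classified) around
    # the closed box, in the same units as each axis
    border_delta: float = 1.0
    border_beta: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.delta_min < self.delta_max):
            raise ValueError("delta thresholds must satisfy 0 < min < max")
        if not (0 < self.beta_min < self.beta_max):
            raise ValueError("beta thresholds must satisfy 0 < min < max")
        if self.d_active_max <= 0 or self.theta_active_min <= 0:
            raise ValueError("activation thresholds must be positive")


DEFAULT_THRESHOLDS = StateThresholds()


def classify_ecl2(delta, beta, thresholds: StateThresholds = DEFAULT_THRESHOLDS):
    """Classify ECL2 state(s): ``"closed"`` or ``"open"``.

    Accepts scalars or arrays; strict inequalities at the box edges.
    """
    delta = np.asarray(delta, dtype=float)
    beta = np.asarray(beta, dtype=float)
    closed = (
        (delta > thresholds.delta_min)
        & (delta < thresholds.delta_max)
        & (beta > thresholds.beta_min)
        & (beta < thresholds.beta_max)
    )
    labels = np.where(closed, "closed", "open")
    return labels.item() if labels.ndim == 0 else labels


def in_border_zone(delta, beta, thresholds: StateThresholds = DEFAULT_THRESHOLDS):
    """Diagnostic flag: point is open but within the border margin of the
    closed box (the scatter-plot 'border' band). Not a third class."""
    delta = np.asarray(delta, dtype=float)
    beta = np.asarray(beta, dtype=float)
    t = thresholds
    in_outer = (
        (delta > t.delta_min - t.border_delta)
        & (delta < t.delta_max + t.border_delta)
        & (beta > t.beta_min - t.border_beta)
        & (beta < t.beta_max + t.border_beta)
    )
    closed = np.asarray(classify_ecl2(delta, beta, t)) == "closed"
    flag = in_outer & ~closed
    return flag.item() if flag.ndim == 0 else flag


def classify_activation(d, theta, thresholds: StateThresholds = DEFAULT_THRESHOLDS):
    """Classify activation state(s): ``"active"``, ``"inactive"`` or
    ``"intermediate"`` (the two criteria disagree)."""
    d = np.asarray(d, dtype=float)
    theta = np.asarray(theta, dtype=float)
    dist_active = d < thresholds.d_active_max
    angle_active = theta > thresholds.theta_active_min
    labels = np.where(
        dist_active & angle_active,
        "active",
        np.where(~dist_active & ~angle_active, "inactive", "intermediate"),
    )
    return labels.item() if labels.ndim == 0 else labels


@dataclass
class OccupancyResult:
    """Per-replica and pooled state occupancies."""

    states: tuple[str, ...]
    per_replica_counts: dict[int, dict[str, int]]
    total_frames: int

    @property
    def pooled_counts(self) -> dict[str, int]:
        out = {s: 0 for s in self.states}
        for counts in self.per_replica_counts.values():
            for s, c in counts.items():
                out[s] += c
        return out

    @property
    def pooled_percent(self) -> dict[str, float]:
        return {s: 100.0 * c / self.total_frames for s, c in self.pooled_counts.items()}

    def replica_percent(self, replica: int) -> dict[str, float]:
        counts = self.per_replica_counts[replica]
        n = sum(counts.values())
        return {s: 100.0 * c / n for s, c in counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rep, counts in self.per_replica_counts.items():
            n = sum(counts.values())
            for s in self.states:
                rows.append((rep, s, counts[s], 100.0 * counts[s] / n))
        for s in self.states:
            rows.append(("pooled", s, self.pooled_counts[s], self.pooled_percent[s]))
        return pd.DataFrame(rows, columns=["replica", "state", "count", "percent"])


def occupancy(
    series_pairs: Sequence[tuple[CVSeries, CVSeries]],
    classifier: Callable = classify_ecl2,
    thresholds: StateThresholds = DEFAULT_THRESHOLDS,
) -> OccupancyResult:
    """State occupancies from paired CV series, one pair per replica.

    Percentages are 100 x state frames / total frames, reported per
    replica and pooled; the pooled value is exactly the frame-count-
    weighted mean of per-replica values.
    """
    if not series_pairs:
        raise ValueError("occupancy needs at least one replica's CV pair")
    per_replica: dict[int, dict[str, int]] = {}
    all_states: set[str] = set()
    total = 0
    for i, (a, b) in enumerate(series_pairs):
        if len(a) != len(b):
            raise ValueError(f"replica {i}: paired series have unequal lengths")
        if len(a) == 0:
            raise ValueError(f"replica {i}: empty series")
        labels = np.asarray(classifier(a.values, b.values, thresholds))
        uniq, counts = np.unique(labels, return_counts=True)
        rep = a.replica_id if a.replica_id not in per_replica else i
        per_replica[rep] = {str(u): int(c) for u, c in zip(uniq, counts)}
        all_states.update(per_replica[rep])
        total += len(a)
    if classifier is classify_ecl2:
        states: tuple[str, ...] = ("closed", "open")
    elif classifier is classify_activation:
        states = ("active", "intermediate", "inactive")
    else:
        states = tuple(sorted(all_states))
    per_replica = {r: {s: c.get(s, 0) for s in states} for r, c in per_replica.items()}
    return OccupancyResult(states=states, per_replica_counts=per_replica, total_frames=total)


def scatter_table(
    system: str,
    series_pairs: Sequence[tuple[CVSeries, CVSeries]],
    classifier: Callable = classify_ecl2,
    thresholds: StateThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-frame scatter export (system, replica, frame, the two CVs and
    the label), suitable for re-plotting the CV-plane figures.

    For the ECL2 classifier a ``border`` column flags frames in the
    diagnostic band around the closed box.
    """
    frames = []
    for a, b in series_pairs:
        labels = np.asarray(classifier(a.values, b.values, thresholds))
        df = pd.DataFrame(
            {
                "system": system,
                "replica": a.replica_id,
                "frame": a.frame_indices,
                a.name: a.values,
                b.name: b.values,
                "label": labels,
            }
        )
        if classifier is classify_ecl2:
            df["border"] = np.asarray(in_border_zone(a.values, b.values, thresholds))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
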