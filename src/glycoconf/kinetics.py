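"""Conformational exchange kinetics by hysteresis-based transition counting.

Frames are assigned to states only when the trajectory enters a state's
*core* region; between cores the previous label persists.  This
hysteresis suppresses rapid recrossings at basin boundaries, so counted
transitions correspond to genuine core-to-core exchange events.  Rates
are reported per μs with exact Poisson 95% confidence intervals.

Default pucker cores follow the θ region bands: chair cores θ < 30° and
θ > 150°, a boat/skew core 60° ≤ θ ≤ 120°, with the envelope/half-chair
bands acting as unassigned buffer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .torsions import wrap_angles

__all__ = [
    "IntervalCore",
    "TorusCore",
    "StateTrajectory",
    "RateEstimate",
    "DEFAULT_PUCKER_CORES",
    "assign_states",
    "count_transitions",
    "exchange_rate",
    "dwell_times",
    "poisson_ci",
]

UNASSIGNED = -1


@dataclass(frozen=True)
class IntervalCore:
    """A core on a linear angular coordinate (e.g. the pucker θ)."""

    label: str
    lo: float
    hi: float  # inclusive bounds

    def contains(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if v.ndim == 2:
            v = v[:, 0]
        return (v >= self.lo) & (v <= self.hi)

    def overlaps(self, other: "IntervalCore") -> bool:
        return self.lo <= other.hi and other.lo <= self.hi


@dataclass(frozen=True)
class TorusCore:
    """A circular window of ±radius around a centre on the (φ, ψ) torus."""

    label: str
    center: tuple[float, ...]
    radius: float = 30.0

    def contains(self, values: np.ndarray) -> np.ndarray:
        v = np.atleast_2d(np.asarray(values, dtype=float))
        if v.shape[1] != len(self.center):
            raise ValueError(
                f"core {self.label!r} has {len(self.center)} dims but "
                f"values have {v.shape[1]}"
            )
        d = np.abs(wrap_angles(v - np.asarray(self.center)))
        return np.all(d <= self.radius, axis=1)

    def overlaps(self, other: "TorusCore") -> bool:
        d = np.abs(wrap_angles(
            np.asarray(self.center) - np.asarray(other.center)
        ))
        return bool(np.all(d <= self.radius + other.radius))


DEFAULT_PUCKER_CORES = (
    IntervalCore("C(north)", 0.0, 30.0 - 1e-12),
    IntervalCore("B/SB", 60.0, 120.0),
    IntervalCore("C(south)", 150.0 + 1e-12, 180.0),
)


@dataclass
class StateTrajectory:
    """Per-frame state labels from hysteresis assignment."""

    labels: np.ndarray  # int core index per frame; -1 before first entry
    cores: tuple  # core definitions, in label-index order
    frame_interval_ps: float

    @property
    def core_labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.cores)

    @property
    def total_time_us(self) -> float:
        return self.labels.size * self.frame_interval_ps * 1e-6

    def label_names(self) -> np.ndarray:
        names = np.asarray(self.core_labels + ("",), dtype=object)
        return names[self.labels]


def assign_states(
    series,
    cores: Sequence = DEFAULT_PUCKER_CORES,
    frame_interval_ps: float = 10.0,
) -> StateTrajectory:
    """Transition-based (hysteresis) state assignment.

    A frame's label is the core most recently entered; frames before the
    first core entry stay unassigned.  Cores must be pairwise disjoint.
    """
    cores = tuple(cores)
    for i, a in enumerate(cores):
        for b in cores[i + 1:]:
            if type(a) is type(b) and a.overlaps(b):
                raise ValueError(
                    f"cores {a.label!r} and {b.label!r} overlap"
                )
    v = np.asarray(series, dtype=float)
    n = v.shape[0]
    current = np.full(n, UNASSIGNED, dtype=np.intp)
    for k, core in enumerate(cores):
        current[core.contains(v)] = k
    # forward-fill: label persists until another core is entered
    seen = current != UNASSIGNED
    idx = np.where(seen, np.arange(n), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, current[np.maximum(idx, 0)], UNASSIGNED)
    return StateTrajectory(
        labels=filled, cores=cores, frame_interval_ps=frame_interval_ps
    )


def count_transitions(state_traj: StateTrajectory) -> dict[tuple[str, str], int]:
    """Ordered-pair counts of label changes; unassigned frames are bridged."""
    labels = state_traj.labels[state_traj.labels != UNASSIGNED]
    if labels.size < 2:
        return {}
    a, b = labels[:-1], labels[1:]
    changed = a != b
    names = state_traj.core_labels
    out: dict[tuple[str, str], int] = {}
    for i, j in zip(a[changed], b[changed]):
        key = (names[i], names[j])
        out[key] = out.get(key, 0) + 1
    return out


def poisson_ci(n_events: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) Poisson confidence interval for an event count."""
    alpha = 1.0 - confidence
    lo = 0.0 if n_events == 0 else stats.chi2.ppf(alpha / 2, 2 * n_events) / 2
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * n_events + 2) / 2
    return float(lo), float(hi)


@dataclass(frozen=True)
class RateEstimate:
    """Exchange rate with exact Poisson 95% confidence interval."""

    n_transitions: int
    total_time_us: float
    rate_per_us: float
    ci95_per_us: tuple[float, float]


def exchange_rate(
    n_transitions: int | dict, total_time_us: float
) -> RateEstimate:
    """Transitions per μs with the exact Poisson 95% interval.

    ``n_transitions`` may be a pairwise count dict (summed) or a count.
    """
    if isinstance(n_transitions, dict):
        n_transitions = sum(n_transitions.values())
    if total_time_us <= 0:
        raise ValueError("total_time_us must be positive")
    lo, hi = poisson_ci(int(n_transitions))
    return RateEstimate(
        n_transitions=int(n_transitions),
        total_time_us=float(total_time_us),
        rate_per_us=n_transitions / total_time_us,
        ci95_per_us=(lo / total_time_us, hi / total_time_us),
    )


@dataclass(frozen=True)
class DwellRecord:
    state: str
    duration_us: float
    censored: bool  # first/last segments do not see both boundaries


def dwell_times(state_traj: StateTrajectory) -> dict[str, list[DwellRecord]]:
    """Contiguous residence durations per state.

    Unassigned frames are bridged (attributed to the persisting label);
    the first and last segments are flagged censored.
    """
    labels = state_traj.labels
    dt_us = state_traj.frame_interval_ps * 1e-6
    names = state_traj.core_labels
    out: dict[str, list[DwellRecord]] = {n: [] for n in names}
    assigned = labels != UNASSIGNED
    if not np.any(assigned):
        return out
    lab = labels[assigned]
    change = np.nonzero(lab[1:] != lab[:-1])[0] + 1
    bounds = np.concatenate([[0], change, [lab.size]])
    n_seg = bounds.size - 1
    for s in range(n_seg):
        start, stop = bounds[s], bounds[s + 1]
        out[names[lab[start]]].append(
            DwellRecord(
                state=names[lab[start]],
                duration_us=(stop - start) * dt_us,
                censored=(s == 0 or s == n_seg - 1),
            )
        )
    return out
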