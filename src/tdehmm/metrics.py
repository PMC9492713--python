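"""Chronnectome metrics: how the brain moves between states.

Five summaries per subject are computed from the state time courses:
fractional occupancy (mean posterior probability of each state), state
lifetimes (durations of uninterrupted visits), interval times (gaps between
consecutive visits of the same state), the switching rate (state changes
per second) and the transition-probability matrix with the persistence
(diagonal) removed and rows renormalized.  Lifetimes and intervals need a
hard state sequence; the Viterbi path is used because it respects the
Markov prior and avoids single-sample flicker.

Runs touching the record edges have unknown true duration; by default they
are still counted (matching the hand-countable bookkeeping below), and
``censor_edges=True`` drops them from the lifetime distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["fractional_occupancy", "max_fractional_occupancy",
           "hard_path_metrics", "HardPathMetrics", "TemporalMetrics",
           "cohort_temporal_metrics"]


def fractional_occupancy(gamma: np.ndarray) -> np.ndarray:
    """Column means of a (T x K) state time course; sums to 1."""
    gamma = np.asarray(gamma, dtype=np.float64)
    return gamma.mean(axis=0)


def max_fractional_occupancy(fo: np.ndarray) -> np.ndarray:
    """Row-wise maximum of a (subjects x K) fractional-occupancy matrix;
    low values mean a mixture of states with no single dominant state."""
    return np.asarray(fo).max(axis=-1)


@dataclass
class HardPathMetrics:
    """Metrics of one subject's hard state path (durations in ms)."""
    K: int
    fs: float
    lifetimes: dict                    # state (1..K) -> array of ms
    interval_times: dict               # state -> array of ms
    switching_rate: float              # state changes per second
    transition_probabilities: np.ndarray   # K x K, zero diagonal
    n_visits: dict = field(default_factory=dict)

    def mean_lifetime(self) -> float:
        all_lt = np.concatenate(
            [v for v in self.lifetimes.values() if v.size] or [np.empty(0)])
        return float(all_lt.mean()) if all_lt.size else np.nan


def hard_path_metrics(path: np.ndarray, fs: float, K: int | None = None,
                      censor_edges: bool = False) -> HardPathMetrics:
    """Lifetimes, intervals, switching rate and off-diagonal transition
    probabilities of a hard state path (values 1..K).

    A run of ``n`` samples lasts ``n * 1000/fs`` ms; an interval is the gap
    between two consecutive runs of the same state.  The switching rate is
    (number of state changes) / (record duration in seconds).  Transition
    probabilities count consecutive pairs, zero the diagonal ("without the
    persistence probabilities") and renormalize rows; rows of states that
    are never left are NaN.
    """
    path = np.asarray(path)
    if path.size == 0:
        raise ValueError("empty state path")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if K is None:
        K = int(path.max())
    ms = 1000.0 / fs

    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [path.size]))
    states = path[starts]

    lifetimes = {k: [] for k in range(1, K + 1)}
    intervals = {k: [] for k in range(1, K + 1)}
    n_visits = {k: 0 for k in range(1, K + 1)}
    last_stop = {}
    n_runs = starts.size
    for r, (a, b, s) in enumerate(zip(starts, stops, states)):
        s = int(s)
        n_visits[s] += 1
        edge = (r == 0) or (r == n_runs - 1)
        if not (censor_edges and edge):
            lifetimes[s].append((b - a) * ms)
        if s in last_stop:
            intervals[s].append((a - last_stop[s]) * ms)
        last_stop[s] = b

    counts = np.zeros((K, K))
    np.add.at(counts, (path[:-1] - 1, path[1:] - 1), 1.0)
    np.fill_diagonal(counts, 0.0)
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        trans = np.where(row > 0, counts / np.where(row > 0, row, 1.0),
                         np.nan)

    n_changes = change.size
    duration_s = path.size / fs
    return HardPathMetrics(
        K=K, fs=fs,
        lifetimes={k: np.asarray(v) for k, v in lifetimes.items()},
        interval_times={k: np.asarray(v) for k, v in intervals.items()},
        switching_rate=n_changes / duration_s,
        transition_probabilities=trans,
        n_visits=n_visits)


@dataclass
class TemporalMetrics:
    """Cohort-level chronnectome table."""
    subject_ids: list
    groups: dict                       # subject -> group label
    fractional_occupancy: np.ndarray   # subjects x K (from gamma)
    per_subject: list                  # HardPathMetrics per subject
    fs: float

    @property
    def K(self) -> int:
        return self.fractional_occupancy.shape[1]

    def max_fractional_occupancy(self) -> np.ndarray:
        return max_fractional_occupancy(self.fractional_occupancy)

    def switching_rates(self) -> np.ndarray:
        return np.asarray([m.switching_rate for m in self.per_subject])

    def mean_lifetimes(self) -> np.ndarray:
        """Subjects x K mean lifetime (ms); NaN where a state is unvisited."""
        out = np.full((len(self.per_subject), self.K), np.nan)
        for i, m in enumerate(self.per_subject):
            for k in range(1, self.K + 1):
                if m.lifetimes[k].size:
                    out[i, k - 1] = m.lifetimes[k].mean()
        return out

    def mean_intervals(self) -> np.ndarray:
        out = np.full((len(self.per_subject), self.K), np.nan)
        for i, m in enumerate(self.per_subject):
            for k in range(1, self.K + 1):
                if m.interval_times[k].size:
                    out[i, k - 1] = m.interval_times[k].mean()
        return out

    def pooled_lifetimes(self, state: int) -> np.ndarray:
        """All lifetimes of one state pooled over subjects (ms)."""
        return np.concatenate([m.lifetimes[state] for m in self.per_subject])

    def pooled_intervals(self, state: int) -> np.ndarray:
        return np.concatenate(
            [m.interval_times[state] for m in self.per_subject])

    def group_transition_matrix(self) -> np.ndarray:
        """Pooled (subject-averaged) off-diagonal transition matrix."""
        mats = np.stack([m.transition_probabilities
                         for m in self.per_subject])
        with np.errstate(invalid="ignore"):
            return np.nanmean(mats, axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: subject, group, state, metric, value."""
        rows = []
        lt = self.mean_lifetimes()
        iv = self.mean_intervals()
        for i, sid in enumerate(self.subject_ids):
            g = self.groups.get(sid)
            for k in range(self.K):
                rows.append((sid, g, k + 1, "fractional_occupancy",
                             self.fractional_occupancy[i, k]))
                rows.append((sid, g, k + 1, "mean_lifetime_ms", lt[i, k]))
                rows.append((sid, g, k + 1, "mean_interval_ms", iv[i, k]))
            rows.append((sid, g, 0, "switching_rate",
                         self.per_subject[i].switching_rate))
            rows.append((sid, g, 0, "max_fractional_occupancy",
                         float(self.fractional_occupancy[i].max())))
        return pd.DataFrame(
            rows, columns=["subject", "group", "state", "metric", "value"])


def cohort_temporal_metrics(paths: dict, fo: np.ndarray, subject_ids: list,
                            fs: float, groups: dict | None = None,
                            censor_edges: bool = False) -> TemporalMetrics:
    """Build the cohort metrics table from hard paths and a gamma-based
    fractional-occupancy matrix."""
    K = fo.shape[1]
    per_subject = [hard_path_metrics(paths[sid], fs, K=K,
                                     censor_edges=censor_edges)
                   for sid in subject_ids]
    return TemporalMetrics(subject_ids=subject_ids, groups=groups or {},
                           fractional_occupancy=np.asarray(fo),
                           per_subject=per_subject, fs=fs)
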