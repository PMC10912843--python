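"""Per-subject temporal dynamics of decoded brain-state sequences.

Five properties summarise how a subject moves through the K states:

* fractional occupancy — proportion of timepoints spent in each state;
* lifetime (s) — mean duration of uninterrupted visits to a state;
* interval time (s) — mean time between consecutive visits to a state;
* switching rate (Hz) — frequency of state changes per second;
* transition probability matrix — row-normalized counts of consecutive
  state pairs (self-transitions included; an off-diagonal view with the
  diagonal zeroed and rows renormalized is derived for between-state
  switching analyses).

States are labelled 1..K.  A state never visited gets NaN lifetime; a
state visited at most once gets NaN interval time (an interval requires
two visits; censored head/tail gaps are excluded).  A visit's lifetime
counts its full sample span, (end - start + 1) x TR, mapping each sample
to one TR of dwell time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Visit",
    "SubjectDynamics",
    "run_length_encode",
    "fractional_occupancy",
    "lifetimes",
    "interval_times",
    "switching_rate",
    "subject_transition_matrix",
    "offdiagonal_view",
    "compute_dynamics",
    "soft_fractional_occupancy",
]


@dataclass
class Visit:
    """A maximal run of consecutive timepoints in one state (0-based, inclusive)."""

    state: int
    start_index: int
    end_index: int
    duration_seconds: float

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass
class SubjectDynamics:
    """The five temporal-dynamics metrics for one subject."""

    subject_id: str
    n_states: int
    tr_seconds: float
    fractional_occupancy: np.ndarray   # (K,), sums to 1
    mean_lifetime: np.ndarray          # (K,) seconds, NaN if never visited
    mean_interval: np.ndarray          # (K,) seconds, NaN if < 2 visits
    switching_rate: float              # Hz
    transition_counts: np.ndarray      # (K, K) ints, total T-1
    transition_probs: np.ndarray       # (K, K), NaN rows for unvisited states
    soft_fractional_occupancy: np.ndarray | None = None
    group: str = ""
    moca: float | None = None
    covariates: dict = field(default_factory=dict)


def run_length_encode(path: Sequence[int], tr_seconds: float = 2.0) -> list[Visit]:
    """Segment a state sequence into maximal constant runs (visits).

    Visits tile ``0..T-1`` with no gaps and consecutive visits differ in
    state.
    """
    p = np.asarray(path, dtype=int)
    if p.size == 0:
        raise ValueError("path must be nonempty")
    change = np.flatnonzero(np.diff(p) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [p.size - 1]])
    return [Visit(int(p[a]), int(a), int(b), (b - a + 1) * tr_seconds)
            for a, b in zip(starts, ends)]


def fractional_occupancy(path: Sequence[int], K: int) -> np.ndarray:
    """Proportion of timepoints spent in each of states 1..K."""
    p = np.asarray(path, dtype=int)
    counts = np.bincount(p - 1, minlength=K)
    return counts / p.size


def soft_fractional_occupancy(posterior: np.ndarray) -> np.ndarray:
    """Gamma-weighted occupancy: mean posterior probability per state."""
    return np.asarray(posterior).mean(axis=0)


def lifetimes(visits: Sequence[Visit], K: int, tr_seconds: float) -> np.ndarray:
    """Mean visit duration (s) per state; NaN where a state is never visited."""
    out = np.full(K, np.nan)
    for k in range(1, K + 1):
        durs = [v.duration_seconds for v in visits if v.state == k]
        if durs:
            out[k - 1] = float(np.mean(durs))
    return out


def interval_times(visits: Sequence[Visit], K: int, tr_seconds: float) -> np.ndarray:
    """Mean gap (s) between consecutive visits to each state.

    A gap is the number of timepoints strictly between the end of one visit
    and the start of the next, times TR.  States with fewer than two visits
    get NaN; time before the first and after the last visit is censored and
    excluded.
    """
    out = np.full(K, np.nan)
    for k in range(1, K + 1):
        vk = [v for v in visits if v.state == k]
        if len(vk) >= 2:
            gaps = [nxt.start_index - prev.end_index - 1 for prev, nxt in zip(vk, vk[1:])]
            out[k - 1] = float(np.mean(gaps)) * tr_seconds
    return out


def switching_rate(path: Sequence[int], tr_seconds: float) -> float:
    """State changes per second: (# adjacent differing pairs) / ((T-1) x TR)."""
    p = np.asarray(path, dtype=int)
    if p.size < 2:
        raise ValueError("switching rate needs T >= 2")
    n_switch = int((np.diff(p) != 0).sum())
    return n_switch / ((p.size - 1) * tr_seconds)


def subject_transition_matrix(path: Sequence[int], K: int) -> tuple[np.ndarray, np.ndarray]:
    """Counts and row-normalized probabilities of consecutive state pairs.

    Self-transitions are included; rows of states never departed from
    (zero counts) are NaN in the probability matrix.
    """
    p = np.asarray(path, dtype=int)
    if p.size < 2:
        raise ValueError("transition matrix needs T >= 2")
    counts = np.zeros((K, K), dtype=int)
    np.add.at(counts, (p[:-1] - 1, p[1:] - 1), 1)
    row = counts.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(row > 0, counts / np.where(row == 0, np.nan, row), np.nan)
    return counts, probs


def offdiagonal_view(probs: np.ndarray) -> np.ndarray:
    """Zero the diagonal and renormalize rows: between-state switching only.

    Rows whose off-diagonal mass is zero (or that were NaN) become NaN.
    """
    out = np.array(probs, dtype=float)
    np.fill_diagonal(out, 0.0)
    row = np.nansum(out, axis=1, keepdims=True)
    all_nan = np.isnan(probs).all(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(row > 0, out / np.where(row == 0, np.nan, row), np.nan)
    out[np.broadcast_to(all_nan, out.shape)] = np.nan
    return out


def compute_dynamics(subject_id: str, path: Sequence[int], K: int, tr_seconds: float,
                     posterior: np.ndarray | None = None) -> SubjectDynamics:
    """All five metrics for one decoded path (plus soft FO if gamma given)."""
    p = np.asarray(path, dtype=int)
    if p.min() < 1 or p.max() > K:
        raise ValueError(f"{subject_id}: states must lie in 1..{K}")
    visits = run_length_encode(p, tr_seconds)
    counts, probs = subject_transition_matrix(p, K)
    return SubjectDynamics(
        subject_id=subject_id,
        n_states=K,
        tr_seconds=tr_seconds,
        fractional_occupancy=fractional_occupancy(p, K),
        mean_lifetime=lifetimes(visits, K, tr_seconds),
        mean_interval=interval_times(visits, K, tr_seconds),
        switching_rate=switching_rate(p, tr_seconds),
        transition_counts=counts,
        transition_probs=probs,
        soft_fractional_occupancy=(soft_fractional_occupancy(posterior)
                                   if posterior is not None else None),
    )
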