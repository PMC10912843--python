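"""Ground-truth simulator: two-group cohorts of ROI time series from a known HMM.

Every downstream stage (fitting, decoding, dynamics metrics, group
statistics) is exercised against cohorts drawn from a fully specified
generative model: a K-state Markov chain with state-specific Gaussian
emissions, per-subject transition-matrix jitter on the row-wise logit
scale, and group effects expressed as multiplicative factors on targeted
transition entries (rows renormalized).  True state paths and true
subject-level transition matrices are retained so recovery can be scored.

The default specification mirrors the study design this package targets:
12 states, 116 regions x 220 timepoints at TR = 2 s, cohorts of 71
patients and 57 controls, all scalable down for desk-size runs, with a
planted patient effect suppressing occupancy of state 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Cohort, ROITimeSeries, SubjectMeta, save_cohort

__all__ = [
    "GroundTruthSpec",
    "SyntheticCohort",
    "simulate_cohort",
    "default_study_spec",
    "sample_state_path",
    "subject_transition_from_spec",
    "write_synthetic_cohort",
    "DESIGNATED_EFFECT_STATE",
    "DESIGNATED_POWER_ENTRY",
]

# state whose occupancy the default patient effect suppresses, and the
# directed transition used for planted-effect power studies (1-based)
DESIGNATED_EFFECT_STATE = 3
DESIGNATED_POWER_ENTRY = (7, 1)


@dataclass
class GroundTruthSpec:
    """Complete generative description of a synthetic two-group cohort.

    ``group_effects`` entries are ``(group, from_state, to_state, factor)``
    with 1-based states: the targeted transition probability is multiplied
    by ``factor`` for subjects of ``group`` and the row renormalized.
    ``subject_jitter_sd`` is the SD of iid Gaussian noise added to each
    row's log-probabilities before renormalization (between-subject
    variability).  Demographics are scenery: age ~ N(44, 10) truncated to
    [18, 80] years and education ~ N(12, 3) truncated at 0 years; MoCA is
    drawn per group and can optionally be coupled to the subject's true
    value of one transition entry for correlation studies.
    """

    n_states: int
    n_regions: int
    n_timepoints: int
    tr_seconds: float
    base_transition: np.ndarray          # (K, K) row-stochastic
    initial_dist: np.ndarray             # (K,)
    state_means: np.ndarray              # (K, d)
    state_covs: np.ndarray               # (K, d, d) SPD
    n_per_group: dict[str, int]
    group_effects: list[tuple[str, int, int, float]] = field(default_factory=list)
    subject_jitter_sd: float = 0.0
    seed: int = 0
    moca_mean: dict[str, float] = field(default_factory=lambda: {"patient": 24.5, "control": 27.4})
    moca_sd: float = 2.5
    moca_coupling: tuple[int, int, float] | None = None   # (from, to, slope per unit prob)

    def __post_init__(self) -> None:
        self.base_transition = np.asarray(self.base_transition, dtype=float)
        self.initial_dist = np.asarray(self.initial_dist, dtype=float)
        self.state_means = np.asarray(self.state_means, dtype=float)
        self.state_covs = np.asarray(self.state_covs, dtype=float)
        K, d = self.n_states, self.n_regions
        if self.base_transition.shape != (K, K):
            raise ValueError("base_transition shape mismatch")
        if (self.base_transition < 0).any():
            raise ValueError("base_transition entries must be nonnegative")
        if np.abs(self.base_transition.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValueError("base_transition rows must sum to 1 within 1e-12")
        if abs(self.initial_dist.sum() - 1.0) > 1e-12 or (self.initial_dist < 0).any():
            raise ValueError("initial_dist must be a probability simplex")
        if self.state_means.shape != (K, d):
            raise ValueError("state_means shape mismatch")
        if self.state_covs.shape != (K, d, d):
            raise ValueError("state_covs shape mismatch")
        for k in range(K):
            C = self.state_covs[k]
            if not np.allclose(C, C.T, atol=1e-10):
                raise ValueError(f"state {k + 1} covariance is not symmetric")
            try:
                np.linalg.cholesky(C)
            except np.linalg.LinAlgError:
                raise ValueError(f"state {k + 1} covariance is not positive definite") from None
        if self.subject_jitter_sd < 0:
            raise ValueError("subject_jitter_sd must be nonnegative")
        for g, i, j, f in self.group_effects:
            if g not in self.n_per_group:
                raise ValueError(f"group effect references unknown group {g!r}")
            if not (1 <= i <= K and 1 <= j <= K):
                raise ValueError(f"group effect states ({i},{j}) outside 1..{K}")
            if f < 0:
                raise ValueError("group effect factor must be nonnegative")


@dataclass
class SyntheticCohort:
    """A simulated cohort plus its generative ground truth."""

    cohort: Cohort
    true_paths: dict[str, np.ndarray]        # subject_id -> (T,) states 1..K
    true_models: dict[str, np.ndarray]       # subject_id -> (K, K) transition
    spec: GroundTruthSpec


def sample_state_path(transition: np.ndarray, initial_dist: np.ndarray,
                      n_timepoints: int, rng: np.random.Generator) -> np.ndarray:
    """Draw one Markov-chain path (1-based states) of the given length."""
    cum_init = np.cumsum(initial_dist)
    cum_trans = np.cumsum(transition, axis=1)
    u = rng.random(n_timepoints)
    path = np.empty(n_timepoints, dtype=int)
    path[0] = int(np.searchsorted(cum_init, u[0], side="right"))
    for t in range(1, n_timepoints):
        path[t] = int(np.searchsorted(cum_trans[path[t - 1]], u[t], side="right"))
    return path + 1


def subject_transition_from_spec(spec: GroundTruthSpec, group: str,
                                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Base matrix -> group effects -> logit-scale jitter -> renormalized rows."""
    A = spec.base_transition.copy()
    for g, i, j, f in spec.group_effects:
        if g == group:
            A[i - 1, j - 1] *= f
    if (A.sum(axis=1) == 0).any():
        bad = int(np.flatnonzero(A.sum(axis=1) == 0)[0]) + 1
        raise ValueError(f"group effects zeroed out row {bad} of the transition matrix")
    A /= A.sum(axis=1, keepdims=True)
    if rng is not None and spec.subject_jitter_sd > 0:
        with np.errstate(divide="ignore"):
            logits = np.log(A)
        logits += rng.normal(0.0, spec.subject_jitter_sd, size=A.shape)
        A = np.exp(logits - logits.max(axis=1, keepdims=True))
        A /= A.sum(axis=1, keepdims=True)
    return A


def _truncated_normal(rng, mean, sd, low, high):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if low <= x <= high:
            return x
    return float(np.clip(mean, low, high))


def simulate_cohort(spec: GroundTruthSpec) -> SyntheticCohort:
    """Generate a cohort deterministically from the specification.

    Each subject gets an independent random substream derived from
    ``(spec.seed, group index, subject index)``, so a subject's data are
    invariant to cohort ordering.  Per subject: build the subject
    transition matrix, sample the hidden chain, then draw each observation
    from the active state's Gaussian; finally draw demographics.
    """
    K, d, T = spec.n_states, spec.n_regions, spec.n_timepoints
    chols = np.linalg.cholesky(spec.state_covs)
    series, meta = [], []
    true_paths: dict[str, np.ndarray] = {}
    true_models: dict[str, np.ndarray] = {}
    labels = [f"R{i + 1:03d}" for i in range(d)]
    for g_idx, (group, n_sub) in enumerate(sorted(spec.n_per_group.items())):
        for s_idx in range(n_sub):
            sid = f"{group}{s_idx + 1:03d}"
            rng = np.random.default_rng([spec.seed, g_idx, s_idx])
            A = subject_transition_from_spec(spec, group, rng)
            path = sample_state_path(A, spec.initial_dist, T, rng)
            z = rng.standard_normal((T, d))
            X = np.empty((T, d))
            for k in range(1, K + 1):
                idx = np.flatnonzero(path == k)
                if idx.size:
                    X[idx] = spec.state_means[k - 1] + z[idx] @ chols[k - 1].T
            age = _truncated_normal(rng, 44.0, 10.0, 18.0, 80.0)
            education = _truncated_normal(rng, 12.0, 3.0, 0.0, 30.0)
            sex = "M" if rng.random() < 0.5 else "F"
            moca = rng.normal(spec.moca_mean.get(group, 26.0), spec.moca_sd)
            if spec.moca_coupling is not None:
                i, j, slope = spec.moca_coupling
                moca += slope * (A[i - 1, j - 1] - spec.base_transition[i - 1, j - 1])
            moca = float(np.clip(round(moca), 0, 30))
            series.append(ROITimeSeries(sid, X.T, spec.tr_seconds, list(labels)))
            meta.append(SubjectMeta(sid, group, age=age, sex=sex,
                                    education=education, moca=moca))
            true_paths[sid] = path
            true_models[sid] = A
    return SyntheticCohort(Cohort(series, meta), true_paths, true_models, spec)


# ---------------------------------------------------------------------------
# default study-like specification
# ---------------------------------------------------------------------------

def _default_means(K: int, d: int, rng: np.random.Generator) -> np.ndarray:
    """Distinct sparse activation patterns: ~d/3 regions at +/-1 per state."""
    means = np.zeros((K, d))
    n_active = max(2, d // 3)
    for k in range(K):
        idx = rng.choice(d, size=n_active, replace=False)
        means[k, idx] = rng.choice([-1.0, 1.0], size=n_active)
    return means


def _default_covs(K: int, d: int, rng: np.random.Generator) -> np.ndarray:
    """Unit diagonal plus a rank-one component; condition number ~3."""
    covs = np.empty((K, d, d))
    eye = np.eye(d)
    for k in range(K):
        u = rng.standard_normal(d)
        u /= np.linalg.norm(u)
        covs[k] = eye + 0.5 * np.outer(u, u)
    return covs


def _stationary(A: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(A.T)
    v = np.real(vecs[:, np.argmin(np.abs(vals - 1.0))])
    v = np.abs(v)
    return v / v.sum()


def default_study_spec(scale: float = 1.0, seed: int = 12345,
                            subject_jitter_sd: float = 0.2) -> GroundTruthSpec:
    """Study-dimensioned ground truth, scalable down.

    At ``scale=1``: 12 states, 116 regions, 220 timepoints at TR = 2 s,
    71 patients / 57 controls.  ``n_regions`` and group sizes shrink with
    ``scale`` (clamped at 8 regions and 5 subjects per group).  Transitions
    are sticky (diagonal 0.85).  Two structural choices support testing:
    the directed transition 7->1 carries most of row 7's off-diagonal mass
    and state 7 receives elevated inflow (raising its occupancy), so that
    planted effects on that entry are estimable from T=220 samples; and the
    default patient effect multiplies every transition into state 3 by 0.6,
    suppressing that state's occupancy in patients.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    K = 12
    d = max(8, round(116 * scale))
    n_patient = max(5, round(71 * scale))
    n_control = max(5, round(57 * scale))

    A = np.zeros((K, K))
    hub_from, hub_to = DESIGNATED_POWER_ENTRY   # 7 -> 1
    for i in range(K):
        A[i, i] = 0.85
        if i == hub_from - 1:
            A[i, hub_to - 1] = 0.14
            rest = [j for j in range(K) if j not in (i, hub_to - 1)]
            A[i, rest] = 0.01 / len(rest)
        else:
            A[i, hub_from - 1] = 0.09
            rest = [j for j in range(K) if j not in (i, hub_from - 1)]
            A[i, rest] = 0.06 / len(rest)
    A /= A.sum(axis=1, keepdims=True)

    rng = np.random.default_rng(116)   # fixed: the pattern is part of the spec
    means = _default_means(K, d, rng)
    covs = _default_covs(K, d, rng)
    effects = [("patient", j, DESIGNATED_EFFECT_STATE, 0.6)
               for j in range(1, K + 1) if j != DESIGNATED_EFFECT_STATE]
    return GroundTruthSpec(
        n_states=K, n_regions=d, n_timepoints=220, tr_seconds=2.0,
        base_transition=A, initial_dist=_stationary(A),
        state_means=means, state_covs=covs,
        n_per_group={"patient": n_patient, "control": n_control},
        group_effects=effects, subject_jitter_sd=subject_jitter_sd, seed=seed,
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_synthetic_cohort(syn: SyntheticCohort, out_dir: str | Path) -> Path:
    """Cohort TSVs plus a ``truth/`` sidecar (paths + subject transitions)."""
    out_dir = Path(out_dir)
    save_cohort(syn.cohort, out_dir)
    truth = out_dir / "truth"
    truth.mkdir(parents=True, exist_ok=True)
    T = syn.spec.n_timepoints
    paths_df = pd.DataFrame(
        {sid: p for sid, p in syn.true_paths.items()},
        index=pd.Index(range(T), name="timepoint"),
    ).T
    paths_df.index.name = "subject_id"
    paths_df.to_csv(truth / "paths.tsv", sep="\t")
    rows = []
    for sid, A in syn.true_models.items():
        for i in range(syn.spec.n_states):
            for j in range(syn.spec.n_states):
                rows.append({"subject_id": sid, "from_state": i + 1,
                             "to_state": j + 1, "prob": A[i, j]})
    pd.DataFrame(rows).to_csv(truth / "transitions.tsv", sep="\t", index=False,
                              float_format="%.17g")
    return out_dir
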