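"""Self-validation harnesses: oracles, recovery, calibration and power.

Every function here runs the package end-to-end against an independent
reference — exhaustive path enumeration for the forward-backward/Viterbi
recursions, simulator ground truth for parameter recovery and model-order
selection, hand-computed values for the dynamics metrics on a worked toy
path, and Monte-Carlo replication for type-I error and power of the group
statistics.  They return plain dictionaries of numbers so the same checks
can back both the test suite and the reproduction script.

Problem sizes are scaled for a single-CPU desk run: recovery uses 20
subjects of 220 timepoints in 8 regions, calibration uses a 4-state
10-region null design, and the power study uses the study-like generator
at scale 0.3 with dynamics taken from the simulator's true state paths
(isolating the statistical layer; decoding fidelity is scored separately
by the recovery harness).
"""

from __future__ import annotations

import itertools
import tempfile
from pathlib import Path

import numpy as np

from .hmm import (HMMModel, _gaussian_logpdf, fit_hmm, log_forward_backward,
                  match_states, select_model_order, viterbi)
from .metrics import compute_dynamics
from .report import PipelineConfig, run_pipeline
from .simulate import (GroundTruthSpec, default_study_spec, sample_state_path,
                       simulate_cohort, subject_transition_from_spec,
                       write_synthetic_cohort, DESIGNATED_POWER_ENTRY)
from .stats import compare_metric, permutation_test_transitions

__all__ = [
    "enumerate_log_evidence", "enumerate_best_path", "oracle_check",
    "k3_recovery_spec", "transition_recovery", "order_selection_check",
    "toy_path_metrics", "TOY_PATH",
    "ttest_type1", "null_spec", "permutation_calibration",
    "null_pipeline_calibration", "planted_power", "study_scale_constants",
]


# ---------------------------------------------------------------------------
# exhaustive-enumeration oracle (independent of the recursive implementation)
# ---------------------------------------------------------------------------

def _enumerate(model: HMMModel, X: np.ndarray) -> tuple[float, np.ndarray]:
    """Brute force over all K^T paths: (log evidence, best joint path).

    Ties in the best path go to the lexicographically smallest path,
    matching the recursions' documented lower-state-index tie-break.
    """
    from scipy.special import logsumexp

    logB = _gaussian_logpdf(np.asarray(X, float), model.means, model.covariances)
    with np.errstate(divide="ignore"):
        logA = np.log(model.transition)
        logpi = np.log(model.initial_dist)
    T, K = logB.shape
    terms = []
    best_lp, best_path = -np.inf, None
    for path in itertools.product(range(K), repeat=T):
        lp = logpi[path[0]] + logB[0, path[0]]
        for t in range(1, T):
            lp += logA[path[t - 1], path[t]] + logB[t, path[t]]
        terms.append(lp)
        if lp > best_lp + 1e-12:
            best_lp, best_path = lp, path
    return float(logsumexp(terms)), np.asarray(best_path) + 1


def enumerate_log_evidence(model: HMMModel, X: np.ndarray) -> float:
    """log p(X | model) by brute-force summation over all K^T state paths."""
    return _enumerate(model, X)[0]


def enumerate_best_path(model: HMMModel, X: np.ndarray) -> np.ndarray:
    """argmax joint path by exhaustive enumeration."""
    return _enumerate(model, X)[1]


def _random_instance(rng: np.random.Generator, K_max: int = 3, T_max: int = 8):
    K = int(rng.integers(1, K_max + 1))
    d = int(rng.integers(1, 4))
    T = int(rng.integers(2, T_max + 1))
    A = rng.dirichlet(np.ones(K) * 2.0, size=K)
    pi = rng.dirichlet(np.ones(K))
    means = rng.normal(0.0, 1.5, (K, d))
    covs = np.empty((K, d, d))
    for k in range(K):
        u = rng.normal(0.0, 1.0, d)
        covs[k] = np.eye(d) * rng.uniform(0.5, 2.0) + 0.3 * np.outer(u, u) / max(d, 1)
    model = HMMModel(K, means, covs, A, pi)
    X = rng.normal(0.0, 1.5, (T, d))
    return model, X


def oracle_check(n_instances: int = 100, seed: int = 0) -> dict:
    """Forward-backward evidence and Viterbi path vs exhaustive enumeration."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    vit_match = 0
    for _ in range(n_instances):
        model, X = _random_instance(rng)
        lz, gamma, xi = log_forward_backward(model, X)
        ref_lz, ref_path = _enumerate(model, X)
        max_err = max(max_err, abs(lz - ref_lz))
        if np.array_equal(viterbi(model, X), ref_path):
            vit_match += 1
        assert np.abs(gamma.sum(axis=1) - 1.0).max() < 1e-10
    return {"n": n_instances, "max_log_evidence_abs_err": max_err,
            "viterbi_match_fraction": vit_match / n_instances}


# ---------------------------------------------------------------------------
# parameter recovery and order selection (simulator ground truth as oracle)
# ---------------------------------------------------------------------------

def k3_recovery_spec(seed: int, n_subjects: int = 20, amp: float = 1.2) -> GroundTruthSpec:
    """Well-separated 3-state, 8-region ground truth, T=220 at TR=2 s."""
    d = 8
    A = np.array([[0.85, 0.10, 0.05],
                  [0.08, 0.85, 0.07],
                  [0.06, 0.09, 0.85]])
    base = np.zeros((3, d))
    base[0, : d // 2] = 1.0
    base[1, d // 2:] = 1.0
    base[2, :2] = -1.0
    base[2, -2:] = -1.0
    return GroundTruthSpec(
        n_states=3, n_regions=d, n_timepoints=220, tr_seconds=2.0,
        base_transition=A, initial_dist=np.full(3, 1 / 3),
        state_means=amp * base, state_covs=np.array([np.eye(d)] * 3),
        n_per_group={"patient": n_subjects // 2,
                     "control": n_subjects - n_subjects // 2},
        subject_jitter_sd=0.0, seed=seed)


def transition_recovery(n_seeds: int = 10, seed0: int = 0, n_restarts: int = 2,
                        trans_tol: float = 0.05, mean_tol: float = 0.10) -> dict:
    """Fit K=3 to simulated cohorts; score transition / mean recovery.

    Mean recovery is the per-state L2 relative error ||mu_hat - mu||/||mu||
    after Hungarian matching of states on their mean vectors.
    """
    trans_errs, mean_errs, passes = [], [], 0
    for i in range(n_seeds):
        spec = k3_recovery_spec(seed0 + i)
        syn = simulate_cohort(spec)
        model, _ = fit_hmm(syn.cohort, 3, n_restarts=n_restarts, seed=seed0 + i,
                           tol=1e-6, max_iter=300)
        ref = HMMModel(3, spec.state_means, spec.state_covs,
                       spec.base_transition, spec.initial_dist)
        perm = match_states(ref, model)
        t_err = float(np.abs(model.transition[np.ix_(perm, perm)]
                             - spec.base_transition).max())
        m_err = float(max(np.linalg.norm(model.means[perm[k]] - spec.state_means[k])
                          / np.linalg.norm(spec.state_means[k]) for k in range(3)))
        trans_errs.append(t_err)
        mean_errs.append(m_err)
        passes += (t_err < trans_tol) and (m_err < mean_tol)
    return {"n": n_seeds, "n_pass": passes,
            "transition_max_abs_err": trans_errs,
            "median_transition_err": float(np.median(trans_errs)),
            "mean_rel_err": mean_errs,
            "median_mean_rel_err": float(np.median(mean_errs))}


def order_selection_check(seed: int = 42, candidates=(2, 3, 4, 5, 6),
                          n_restarts: int = 2) -> dict:
    """Model-order selection on K=3 data over the candidate grid."""
    syn = simulate_cohort(k3_recovery_spec(seed, amp=1.5))
    report, _ = select_model_order(syn.cohort, list(candidates),
                                   n_restarts=n_restarts, seed=0,
                                   tol=1e-6, max_iter=300)
    return {"chosen_K": report.chosen_K,
            "bics": {k: report.bics[k] for k in report.candidates},
            "n_near_empty_at_max_K": report.n_near_empty[max(candidates)],
            "n": len(candidates)}


# ---------------------------------------------------------------------------
# worked toy path: all five metrics by hand
# ---------------------------------------------------------------------------

TOY_PATH = [1, 1, 2, 2, 2, 1, 3, 3, 1, 1]


def toy_path_metrics(tr_seconds: float = 2.0) -> dict:
    """The five dynamics metrics of the worked 10-point, 3-state path."""
    d = compute_dynamics("toy", TOY_PATH, 3, tr_seconds)
    return {
        "fractional_occupancy": d.fractional_occupancy.tolist(),
        "mean_lifetime_s": d.mean_lifetime.tolist(),
        "mean_interval_s": d.mean_interval.tolist(),
        "switching_rate_hz": d.switching_rate,
        "transition_counts": d.transition_counts.tolist(),
        "transition_probs_row1": d.transition_probs[0].tolist(),
    }


# ---------------------------------------------------------------------------
# statistical calibration and power
# ---------------------------------------------------------------------------

def _dyn_with_lifetime(values: np.ndarray, sid: str) -> "object":
    from .metrics import SubjectDynamics

    K = values.size
    return SubjectDynamics(
        subject_id=sid, n_states=K, tr_seconds=2.0,
        fractional_occupancy=np.full(K, 1.0 / K), mean_lifetime=values,
        mean_interval=np.full(K, np.nan), switching_rate=0.0,
        transition_counts=np.zeros((K, K), int),
        transition_probs=np.full((K, K), np.nan))


def ttest_type1(n_rep: int = 500, n_per_group: int = 1000, K: int = 4,
                alpha: float = 0.05, seed: int = 0) -> dict:
    """Type-I error of the per-state t test on null normal data.

    Both groups draw from the same normal distribution; the rejection rate
    of the raw two-tailed test at ``alpha`` is returned pooled over states
    and replicates (and per state).
    """
    rng = np.random.default_rng(seed)
    rej = np.zeros(K)
    for _ in range(n_rep):
        A = [_dyn_with_lifetime(rng.normal(5.0, 1.0, K), f"a{i}") for i in range(n_per_group)]
        B = [_dyn_with_lifetime(rng.normal(5.0, 1.0, K), f"b{i}") for i in range(n_per_group)]
        comps = compare_metric(A, B, "lifetime")
        for k, c in enumerate(comps):
            rej[k] += c.p_raw < alpha
    per_state = rej / n_rep
    return {"n": n_rep * K, "type1_rate": float(rej.sum() / (n_rep * K)),
            "per_state_rates": per_state.tolist()}


def null_spec(seed: int, n_per_group: int = 12) -> GroundTruthSpec:
    """4-state, 10-region two-group design with no group effect."""
    K, d = 4, 10
    A = np.full((K, K), 0.15 / (K - 1))
    np.fill_diagonal(A, 0.85)
    rng = np.random.default_rng(7)
    base = np.zeros((K, d))
    for k in range(K):
        idx = rng.choice(d, 3, replace=False)
        base[k, idx] = rng.choice([-1.5, 1.5], 3)
    return GroundTruthSpec(
        n_states=K, n_regions=d, n_timepoints=220, tr_seconds=2.0,
        base_transition=A, initial_dist=np.full(K, 1.0 / K),
        state_means=base, state_covs=np.array([np.eye(d)] * K),
        n_per_group={"patient": n_per_group, "control": n_per_group},
        subject_jitter_sd=0.2, seed=seed)


def _true_path_dynamics(spec: GroundTruthSpec) -> tuple[list, list]:
    """Per-subject dynamics from simulator-sampled true paths (no fitting)."""
    dynA, dynB = [], []
    for g_idx, (group, n_sub) in enumerate(sorted(spec.n_per_group.items())):
        for s_idx in range(n_sub):
            rng = np.random.default_rng([spec.seed, g_idx, s_idx])
            A = subject_transition_from_spec(spec, group, rng)
            path = sample_state_path(A, spec.initial_dist, spec.n_timepoints, rng)
            d = compute_dynamics(f"{group}{s_idx:03d}", path, spec.n_states,
                                 spec.tr_seconds)
            (dynA if group == "patient" else dynB).append(d)
    return dynA, dynB


def permutation_calibration(n_cohorts: int = 200, n_permutations: int = 999,
                            alpha: float = 0.05, seed: int = 0,
                            n_per_group: int = 15) -> dict:
    """Rejection rate of the transition permutation test under the null."""
    K = 4
    rej = np.zeros((K, K))
    n_tested = np.zeros((K, K))
    for rep in range(n_cohorts):
        spec = null_spec((seed * 100_003 + rep) % (2**31 - 1), n_per_group=n_per_group)
        dynA, dynB = _true_path_dynamics(spec)
        res = permutation_test_transitions(dynA, dynB, n_permutations=n_permutations,
                                           seed=seed + rep)
        for c in res:
            rej[c.from_state - 1, c.to_state - 1] += c.p_perm < alpha
            n_tested[c.from_state - 1, c.to_state - 1] += 1
    per_entry = rej / n_tested
    return {"n": int(n_tested.sum()),
            "rejection_rate": float(rej.sum() / n_tested.sum()),
            "per_entry_rates": per_entry.tolist()}


def null_pipeline_calibration(n_runs: int = 20, seed: int = 0) -> dict:
    """Full simulate -> write -> load -> fit -> metrics -> stats pipeline
    under a no-effect design; counts runs with zero FDR-significant metric
    comparisons in the patient-vs-control contrast (single pooled FDR
    family across the four metric families)."""
    clean = 0
    sig_counts = []
    for rep in range(n_runs):
        spec = null_spec((seed * 100_003 + rep) % (2**31 - 1))
        syn = simulate_cohort(spec)
        with tempfile.TemporaryDirectory() as tmp:
            data_dir = Path(tmp) / "cohort"
            write_synthetic_cohort(syn, data_dir)
            config = PipelineConfig(
                seed=seed + rep, out_dir=str(Path(tmp) / "out"),
                input={"matrix_dir": str(data_dir / "matrices"),
                       "meta_table": str(data_dir / "meta.tsv"),
                       "tr_seconds": 2.0},
                n_states=4, n_restarts=2, tol=1e-5, max_iter=150,
                n_permutations=199, fdr_family="pooled")
            result = run_pipeline(config)
        n_sig = result.n_significant.get("patient_vs_control_metrics", 0)
        sig_counts.append(n_sig)
        clean += n_sig == 0
    return {"n": n_runs, "clean_fraction": clean / n_runs,
            "sig_counts": sig_counts}


def planted_power(n_rep: int = 50, seed: int = 0, factor: float = 1.6,
                  scale: float = 0.3, n_permutations: int = 999,
                  alpha: float = 0.05) -> dict:
    """Detection rate of a planted multiplicative transition effect.

    The study-like generator at the given scale plants ``factor`` on the
    designated transition (7 -> 1) in patients; per-subject dynamics come
    from the true simulated paths and the permutation test must flag that
    entry at ``alpha``.
    """
    i, j = DESIGNATED_POWER_ENTRY
    detect = 0
    pvals = []
    for rep in range(n_rep):
        spec = default_study_spec(scale=scale, seed=(seed * 100_003 + rep) % (2**31 - 1))
        spec.group_effects = [("patient", i, j, factor)]
        dynA, dynB = _true_path_dynamics(spec)
        res = permutation_test_transitions(dynA, dynB, n_permutations=n_permutations,
                                           seed=seed + rep)
        p = next(c.p_perm for c in res if c.from_state == i and c.to_state == j)
        pvals.append(p)
        detect += p < alpha
    return {"n": n_rep, "power": detect / n_rep, "median_p": float(np.median(pvals))}


def study_scale_constants() -> dict:
    """Dimensions of the full-scale default specification."""
    spec = default_study_spec(scale=1.0)
    return {"n_states": spec.n_states, "n_regions": spec.n_regions,
            "n_timepoints": spec.n_timepoints, "tr_seconds": spec.tr_seconds,
            "n_patients": spec.n_per_group["patient"],
            "n_controls": spec.n_per_group["control"]}
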