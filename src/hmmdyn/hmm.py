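"""Gaussian-emission hidden Markov model: inference, fitting, order selection.

One model is fitted to the pooled cohort (every subject is an independent
observation sequence sharing the same K states), matching the group-level
design in which states are subsequently compared across groups.  Each state
is a multivariate normal over regions (mean activity vector + covariance
matrix); hidden dynamics are a first-order Markov chain.

Inference is maximum-likelihood EM (Baum-Welch) with log-space
forward-backward and Cholesky-based Gaussian log-densities, k-means
initialized means, a shared pooled covariance and sticky transitions per
restart.  Model order is chosen by BIC plus a near-empty-state check
(states whose median fractional occupancy collapses flag overfitting).
Ties in decoding are broken toward the lower state index.  State labels are
arbitrary; `match_states` aligns two models by optimal assignment on their
mean vectors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .io import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "HMMModel",
    "StatePath",
    "OrderSelectionReport",
    "log_forward_backward",
    "viterbi",
    "fit_hmm",
    "select_model_order",
    "match_states",
    "n_hmm_params",
]


def n_hmm_params(K: int, n_regions: int) -> int:
    """Free parameters: initial dist + transitions + means + covariances."""
    d = n_regions
    return (K - 1) + K * (K - 1) + K * d + K * d * (d + 1) // 2


@dataclass
class HMMModel:
    """A fitted K-state Gaussian-emission HMM.

    ``means[k]`` is state k's mean activity over regions, ``covariances[k]``
    its region-by-region covariance; ``transition`` is row-stochastic and
    ``initial_dist`` a probability simplex.  State indices in the arrays are
    0-based; user-facing state labels are 1..K.
    """

    n_states: int
    means: np.ndarray                # (K, d)
    covariances: np.ndarray          # (K, d, d)
    transition: np.ndarray           # (K, K)
    initial_dist: np.ndarray         # (K,)
    log_likelihood: float = np.nan
    n_params: int = 0
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial_dist = np.asarray(self.initial_dist, dtype=float)
        K = self.n_states
        if self.means.shape[0] != K or self.covariances.shape[0] != K:
            raise ValueError("means/covariances first dimension must equal n_states")
        if self.transition.shape != (K, K):
            raise ValueError(f"transition must be {K}x{K}")
        if np.abs(self.transition.sum(axis=1) - 1.0).max() > 1e-10:
            raise ValueError("transition rows must sum to 1 (tolerance 1e-10)")
        if (self.transition < 0).any():
            raise ValueError("transition entries must be nonnegative")
        if abs(self.initial_dist.sum() - 1.0) > 1e-10 or (self.initial_dist < 0).any():
            raise ValueError("initial_dist must be a probability simplex")
        if not self.n_params:
            self.n_params = n_hmm_params(K, self.means.shape[1])

    @property
    def n_regions(self) -> int:
        return self.means.shape[1]

    def bic(self, n_total_timepoints: int) -> float:
        return -2.0 * self.log_likelihood + self.n_params * np.log(n_total_timepoints)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_states": self.n_states,
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "transition": self.transition.tolist(),
            "initial_dist": self.initial_dist.tolist(),
            "log_likelihood": self.log_likelihood,
            "n_params": self.n_params,
            "fit_meta": _jsonable(self.fit_meta),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "HMMModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            n_states=payload["n_states"],
            means=np.array(payload["means"]),
            covariances=np.array(payload["covariances"]),
            transition=np.array(payload["transition"]),
            initial_dist=np.array(payload["initial_dist"]),
            log_likelihood=payload["log_likelihood"],
            n_params=payload["n_params"],
            fit_meta=payload.get("fit_meta", {}),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


@dataclass
class StatePath:
    """Decoded state trajectory for one subject.

    ``posterior`` holds the per-timepoint marginal state probabilities
    (gamma); ``decoded_path`` is its argmax (the default decoding) and
    ``viterbi_path`` the jointly most probable sequence.  Paths are 1-based.
    """

    subject_id: str
    viterbi_path: np.ndarray     # (T,) ints in 1..K
    posterior: np.ndarray        # (T, K)
    decoded_path: np.ndarray     # (T,) ints in 1..K

    def __post_init__(self) -> None:
        if np.abs(self.posterior.sum(axis=1) - 1.0).max() > 1e-10:
            raise ValueError("posterior rows must sum to 1")
        K = self.posterior.shape[1]
        for name, p in (("viterbi_path", self.viterbi_path), ("decoded_path", self.decoded_path)):
            p = np.asarray(p)
            if p.min() < 1 or p.max() > K:
                raise ValueError(f"{name} states must lie in 1..{K}")


# ---------------------------------------------------------------------------
# Gaussian log-densities
# ---------------------------------------------------------------------------

def _gaussian_logpdf(X: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Per-state multivariate-normal log density, shape (N, K)."""
    N, d = X.shape
    K = means.shape[0]
    out = np.empty((N, K))
    const = -0.5 * d * np.log(2.0 * np.pi)
    for k in range(K):
        try:
            L = cholesky(covs[k], lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
            raise np.linalg.LinAlgError(f"covariance of state {k + 1} is not SPD") from exc
        dev = solve_triangular(L, (X - means[k]).T, lower=True)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        out[:, k] = const - 0.5 * logdet - 0.5 * (dev * dev).sum(axis=0)
    return out


def _log_params(model: HMMModel) -> tuple[np.ndarray, np.ndarray]:
    with np.errstate(divide="ignore"):
        return np.log(model.transition), np.log(model.initial_dist)


# ---------------------------------------------------------------------------
# forward-backward / Viterbi
# ---------------------------------------------------------------------------

def _forward_backward_logb(logB: np.ndarray, A: np.ndarray, pi: np.ndarray):
    """Scaled forward-backward given emission log-densities.

    Emission densities are rescaled per timepoint (dividing by their max)
    and the forward variables renormalized at every step, so arbitrarily
    long high-dimensional sequences are stable; the log evidence is
    recovered from the accumulated scaling constants.  Returns
    ``(log_evidence, gamma, xi)`` where ``gamma[t, k]`` is p(z_t = k | X)
    and ``xi[t, i, j]`` is p(z_t = i, z_{t+1} = j | X) (each slice sums
    to 1).
    """
    T, K = logB.shape
    bmax = logB.max(axis=1)
    Bs = np.exp(logB - bmax[:, None])          # in (0, 1], max 1 per row
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = pi * Bs[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * Bs[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    log_evidence = float(np.log(c).sum() + bmax.sum())
    betahat = np.empty((T, K))
    betahat[-1] = 1.0
    for t in range(T - 2, -1, -1):
        betahat[t] = (A @ (Bs[t + 1] * betahat[t + 1])) / c[t + 1]
    gamma = alpha * betahat
    gamma /= gamma.sum(axis=1, keepdims=True)
    if T > 1:
        xi = (alpha[:-1, :, None] * A[None, :, :]
              * (Bs[1:] * betahat[1:])[:, None, :] / c[1:, None, None])
        xi /= xi.sum(axis=(1, 2), keepdims=True)
    else:
        xi = np.zeros((0, K, K))
    return log_evidence, gamma, xi


def log_forward_backward(model: HMMModel, observations: np.ndarray):
    """Evidence and posteriors for one subject's (T, n_regions) matrix.

    Returns ``(log_evidence, posterior, pairwise_posteriors)``.
    """
    X = np.asarray(observations, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("observations contain non-finite values")
    logB = _gaussian_logpdf(X, model.means, model.covariances)
    return _forward_backward_logb(logB, model.transition, model.initial_dist)


def viterbi(model: HMMModel, observations: np.ndarray) -> np.ndarray:
    """Most probable joint state path (1-based); ties go to the lower index."""
    X = np.asarray(observations, dtype=float)
    logB = _gaussian_logpdf(X, model.means, model.covariances)
    logA, logpi = _log_params(model)
    T, K = logB.shape
    delta = logpi + logB[0]
    psi = np.empty((T, K), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + logA
        psi[t] = np.argmax(scores, axis=0)          # argmax takes the first (lowest) index
        delta = scores[psi[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path + 1


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

_RIDGE = 1e-6  # fraction of the mean covariance diagonal added each M-step


def _run_em(X: np.ndarray, bounds: list[tuple[int, int]], means: np.ndarray,
            covs: np.ndarray, A: np.ndarray, pi: np.ndarray,
            tol: float, max_iter: int):
    """Baum-Welch from the given initialization.

    ``X`` is the (N, d) concatenation of all subjects; ``bounds`` the
    per-subject slices.  Returns the model arrays, per-subject final
    log-evidences, gamma over all frames, and the log-likelihood history.
    """
    N, d = X.shape
    K = means.shape[0]
    means, covs, A, pi = (a.copy() for a in (means, covs, A, pi))
    pooled_cov = np.cov(X.T, ddof=1).reshape(d, d)
    pooled_cov += _RIDGE * np.mean(np.diag(pooled_cov)) * np.eye(d)
    ll_history: list[float] = []
    converged = False
    subject_ll = np.zeros(len(bounds))
    gamma_all = np.empty((N, K))
    for it in range(max_iter):
        logB = _gaussian_logpdf(X, means, covs)
        xi_sum = np.zeros((K, K))
        pi_sum = np.zeros(K)
        total_ll = 0.0
        for s, (a, b) in enumerate(bounds):
            ll_s, gamma, xi = _forward_backward_logb(logB[a:b], A, pi)
            gamma_all[a:b] = gamma
            xi_sum += xi.sum(axis=0)
            pi_sum += gamma[0]
            subject_ll[s] = ll_s
            total_ll += ll_s
        ll_history.append(total_ll)
        if len(ll_history) > 1:
            prev = ll_history[-2]
            if abs(total_ll - prev) < tol * abs(prev):
                converged = True
                break
        # M-step
        Nk = gamma_all.sum(axis=0)
        starved = set(np.flatnonzero(Nk < d + 1).tolist())
        pi = pi_sum / pi_sum.sum()
        row = xi_sum.sum(axis=1, keepdims=True)
        A = np.where(row > 0, xi_sum / np.where(row == 0, 1.0, row), 1.0 / K)
        worst = np.argsort(logB.max(axis=1))[: 2 * (d + 1)] if starved else None
        for k in range(K):
            if k in starved:
                # re-seed from the worst-explained frames with the pooled covariance
                means[k] = X[worst].mean(axis=0)
                covs[k] = pooled_cov
                logger.warning("state %d starved (weight %.2f); re-seeded from %d worst-fit frames",
                               k + 1, Nk[k], worst.size)
                continue
            means[k] = gamma_all[:, k] @ X / Nk[k]
            dev = X - means[k]
            cov = (dev * gamma_all[:, k:k + 1]).T @ dev / Nk[k]
            cov += _RIDGE * np.mean(np.diag(cov)) * np.eye(d)
            covs[k] = cov
    return means, covs, A, pi, subject_ll, gamma_all, ll_history, converged


def _initial_params(X: np.ndarray, K: int, rng_seed: int):
    """K-means means, shared pooled covariance, sticky transitions."""
    d = X.shape[1]
    if K == 1:
        means = X.mean(axis=0, keepdims=True)
    else:
        km = KMeans(n_clusters=K, n_init=3, random_state=rng_seed)
        km.fit(X)
        means = km.cluster_centers_
        # stable state ordering of the initialization: sort by first coordinate
        means = means[np.lexsort(means.T[::-1])]
    pooled = np.cov(X.T, ddof=1).reshape(d, d)
    pooled += _RIDGE * np.mean(np.diag(pooled)) * np.eye(d)
    covs = np.repeat(pooled[None], K, axis=0)
    A = np.full((K, K), 0.2 / max(K - 1, 1))
    np.fill_diagonal(A, 0.8 if K > 1 else 1.0)
    pi = np.full(K, 1.0 / K)
    return means, covs, A, pi


def _pool_cohort(cohort: Cohort) -> tuple[np.ndarray, list[tuple[int, int]]]:
    X = np.concatenate([ts.data.T for ts in cohort.series], axis=0)
    bounds, start = [], 0
    for ts in cohort.series:
        bounds.append((start, start + ts.n_timepoints))
        start += ts.n_timepoints
    return X, bounds


def fit_hmm(cohort: Cohort, K: int, n_restarts: int = 10, seed: int = 0,
            tol: float = 1e-6, max_iter: int = 500,
            decoder: str = "gamma") -> tuple[HMMModel, list[StatePath]]:
    """Fit one K-state model to all subjects and decode each subject's path.

    Subjects are independent sequences sharing the model (group-level fit).
    Each restart draws its own k-means initialization; the restart with the
    best final log-likelihood wins.  Deterministic given ``seed``.

    Parameters
    ----------
    decoder : {"gamma", "viterbi"}
        ``decoded_path`` source: argmax of the marginal posterior (default)
        or the Viterbi path.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if decoder not in ("gamma", "viterbi"):
        raise ValueError(f"unknown decoder {decoder!r}")
    X, bounds = _pool_cohort(cohort)
    N, d = X.shape
    n_params = n_hmm_params(K, d)
    if N <= n_params:
        logger.warning("only %d timepoints for %d parameters (K=%d, d=%d); fit may be unstable",
                       N, n_params, K, d)
    restart_seeds = np.random.SeedSequence(seed).generate_state(max(n_restarts, 1)) % (2**31 - 1)
    best = None
    for r in range(max(n_restarts, 1)):
        init = _initial_params(X, K, int(restart_seeds[r]))
        result = _run_em(X, bounds, *init, tol=tol, max_iter=max_iter)
        if best is None or result[6][-1] > best[1][6][-1]:
            best = (r, result)
    r_best, (means, covs, A, pi, subject_ll, _gamma, ll_history, converged) = best
    model = HMMModel(
        n_states=K, means=means, covariances=covs, transition=A, initial_dist=pi,
        log_likelihood=ll_history[-1], n_params=n_params,
        fit_meta={
            "seed": seed, "restarts": max(n_restarts, 1), "winning_restart": r_best,
            "iterations": len(ll_history), "converged": converged,
            "tol": tol, "max_iter": max_iter, "decoder": decoder,
            "ll_history": [float(v) for v in ll_history],
            "subject_log_likelihoods": [float(v) for v in subject_ll],
        },
    )
    paths = decode_cohort(model, cohort, decoder=decoder)
    return model, paths


def decode_cohort(model: HMMModel, cohort: Cohort, decoder: str = "gamma") -> list[StatePath]:
    """Posterior + Viterbi decoding for every subject under a fitted model."""
    paths = []
    for ts in cohort.series:
        X = ts.data.T
        _, gamma, _ = log_forward_backward(model, X)
        vit = viterbi(model, X)
        decoded = np.argmax(gamma, axis=1) + 1 if decoder == "gamma" else vit
        paths.append(StatePath(ts.subject_id, vit, gamma, decoded))
    return paths


# ---------------------------------------------------------------------------
# model-order selection
# ---------------------------------------------------------------------------

@dataclass
class OrderSelectionReport:
    """Per-candidate fit summaries and the chosen number of states.

    ``chosen_K`` is the smallest candidate within one BIC standard error of
    the minimum BIC that has no near-empty state (median fractional
    occupancy < 1/(10K)); if no candidate is clean, the minimum-BIC
    candidate is chosen.  The full table is kept so users can override.
    """

    candidates: list[int]
    log_likelihoods: dict[int, float]
    bics: dict[int, float]
    median_fo: dict[int, np.ndarray]
    n_near_empty: dict[int, int]
    chosen_K: int
    bic_se: float

    def as_table(self):
        import pandas as pd
        return pd.DataFrame({
            "K": self.candidates,
            "log_likelihood": [self.log_likelihoods[k] for k in self.candidates],
            "bic": [self.bics[k] for k in self.candidates],
            "n_near_empty_states": [self.n_near_empty[k] for k in self.candidates],
            "chosen": [k == self.chosen_K for k in self.candidates],
        })


def select_model_order(cohort: Cohort, candidate_Ks: Sequence[int], n_restarts: int = 5,
                       seed: int = 0, tol: float = 1e-6, max_iter: int = 500,
                       ) -> tuple[OrderSelectionReport, dict[int, tuple[HMMModel, list[StatePath]]]]:
    """Fit every candidate K and choose an order by BIC + degeneracy check."""
    from .metrics import fractional_occupancy

    if not candidate_Ks:
        raise ValueError("candidate_Ks must be nonempty")
    candidates = sorted(set(int(k) for k in candidate_Ks))
    fits, lls, bics, med_fo, n_empty = {}, {}, {}, {}, {}
    n_total = sum(ts.n_timepoints for ts in cohort.series)
    for K in candidates:
        model, paths = fit_hmm(cohort, K, n_restarts=n_restarts, seed=seed,
                               tol=tol, max_iter=max_iter)
        fits[K] = (model, paths)
        lls[K] = model.log_likelihood
        bics[K] = model.bic(n_total)
        fo = np.array([fractional_occupancy(p.decoded_path, K) for p in paths])
        med = np.median(fo, axis=0)
        med_fo[K] = med
        n_empty[K] = int((med < 1.0 / (10 * K)).sum())
    k_min = min(candidates, key=lambda k: bics[k])
    subj_ll = np.asarray(fits[k_min][0].fit_meta["subject_log_likelihoods"])
    bic_se = 2.0 * float(np.std(subj_ll, ddof=1) * np.sqrt(len(subj_ll))) if len(subj_ll) > 1 else 0.0
    eligible = [k for k in candidates if bics[k] <= bics[k_min] + bic_se and n_empty[k] == 0]
    chosen = min(eligible) if eligible else k_min
    report = OrderSelectionReport(candidates, lls, bics, med_fo, n_empty, chosen, bic_se)
    return report, fits


# ---------------------------------------------------------------------------
# state matching
# ---------------------------------------------------------------------------

def match_states(reference: HMMModel, other: HMMModel) -> np.ndarray:
    """Optimal assignment of ``other``'s states onto ``reference``'s.

    Returns a 0-based index array ``perm`` such that ``other`` state
    ``perm[i]`` corresponds to reference state ``i``, minimizing the total
    Euclidean distance between matched mean vectors (Hungarian algorithm).
    """
    if reference.n_states != other.n_states:
        raise ValueError("models must have equal K")
    if reference.n_regions != other.n_regions:
        raise ValueError("models must have equal n_regions")
    diff = reference.means[:, None, :] - other.means[None, :, :]
    cost = np.sqrt((diff ** 2).sum(axis=2))
    _, cols = linear_sum_assignment(cost)
    return cols
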