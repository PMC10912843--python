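"""Group-level inference on state dynamics.

Three procedures mirror the analysis layer of HMM brain-state studies:

* two-tailed two-sample t tests per state on fractional occupancy,
  lifetime, interval time (and one global test on switching rate), with
  Benjamini-Hochberg FDR within each metric family;
* label-permutation tests on every directed transition probability, with
  a single joint shuffle per permutation so the matrix's dependence
  structure is preserved in the null;
* covariate-adjusted Spearman correlation (rank both variables,
  residualize on covariates, correlate residuals) between a dynamics
  metric and a cognitive score.

NaN metric values (unvisited states) are excluded pairwise with recorded
per-group sample sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .metrics import SubjectDynamics

logger = logging.getLogger(__name__)

__all__ = [
    "MetricComparison",
    "TransitionComparison",
    "CorrelationResult",
    "compare_metric",
    "fdr_adjust",
    "permutation_test_transitions",
    "partial_spearman",
    "assign_cognitive_groups",
    "METRIC_FIELDS",
]

# metric name -> SubjectDynamics attribute; per-state vectors except switching_rate
METRIC_FIELDS = {
    "fractional_occupancy": "fractional_occupancy",
    "lifetime": "mean_lifetime",
    "interval": "mean_interval",
    "switching_rate": "switching_rate",
}


@dataclass
class MetricComparison:
    """One state's (or the global) two-sample comparison for one metric."""

    metric: str
    state: int | str                    # 1..K or "global"
    group_means: tuple[float, float]
    group_sds: tuple[float, float]
    t_statistic: float
    df: float
    p_raw: float
    q_fdr: float
    n_per_group: tuple[int, int]


@dataclass
class TransitionComparison:
    """Permutation test of one directed transition probability."""

    from_state: int
    to_state: int
    observed_diff: float                # mean(group A) - mean(group B)
    p_perm: float
    n_permutations: int
    direction: str                      # "increase" | "decrease"


@dataclass
class CorrelationResult:
    """Partial Spearman correlation of a dynamics metric with a score."""

    x_metric: tuple[str, int | str]
    y: str
    rho: float
    p: float
    covariates: list[str] = field(default_factory=list)
    n: int = 0


def _metric_values(dyns: Sequence[SubjectDynamics], metric: str) -> np.ndarray:
    """(n_subjects, K) array, or (n_subjects, 1) for switching_rate."""
    if metric not in METRIC_FIELDS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRIC_FIELDS)}")
    attr = METRIC_FIELDS[metric]
    vals = [np.atleast_1d(np.asarray(getattr(d, attr), dtype=float)) for d in dyns]
    return np.vstack(vals)


def compare_metric(groupA: Sequence[SubjectDynamics], groupB: Sequence[SubjectDynamics],
                   metric: str, variant: str = "student") -> list[MetricComparison]:
    """Two-tailed two-sample t tests per state, FDR-adjusted within the metric.

    ``variant="student"`` uses the classical pooled-variance test (default);
    ``"welch"`` does not assume equal variances.  States with fewer than two
    finite values in either group get NaN statistics and are excluded from
    the FDR family.
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    va, vb = _metric_values(groupA, metric), _metric_values(groupB, metric)
    n_cols = va.shape[1]
    results: list[MetricComparison] = []
    for k in range(n_cols):
        a = va[:, k][np.isfinite(va[:, k])]
        b = vb[:, k][np.isfinite(vb[:, k])]
        state: int | str = "global" if metric == "switching_rate" else k + 1
        if a.size < 2 or b.size < 2:
            logger.warning("%s state %s: insufficient data (n=%d, %d); excluded from FDR",
                           metric, state, a.size, b.size)
            results.append(MetricComparison(metric, state,
                                            (float(np.mean(a)) if a.size else np.nan,
                                             float(np.mean(b)) if b.size else np.nan),
                                            (np.nan, np.nan), np.nan, np.nan, np.nan,
                                            np.nan, (a.size, b.size)))
            continue
        res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
        results.append(MetricComparison(
            metric=metric, state=state,
            group_means=(float(a.mean()), float(b.mean())),
            group_sds=(float(a.std(ddof=1)), float(b.std(ddof=1))),
            t_statistic=float(res.statistic), df=float(res.df),
            p_raw=float(res.pvalue), q_fdr=np.nan,
            n_per_group=(a.size, b.size),
        ))
    valid = [r for r in results if np.isfinite(r.p_raw)]
    if valid:
        qs = fdr_adjust([r.p_raw for r in valid])
        for r, q in zip(valid, qs):
            r.q_fdr = float(q)
    return results


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q values (capped at 1, monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def transition_prob_stack(dyns: Sequence[SubjectDynamics], use_offdiagonal: bool = False
                          ) -> np.ndarray:
    """(n_subjects, K, K) stack of per-subject transition probabilities."""
    from .metrics import offdiagonal_view

    mats = [d.transition_probs for d in dyns]
    if use_offdiagonal:
        mats = [offdiagonal_view(m) for m in mats]
    return np.stack(mats)


def permutation_test_transitions(groupA: Sequence[SubjectDynamics],
                                 groupB: Sequence[SubjectDynamics],
                                 n_permutations: int = 5000, seed: int = 0,
                                 include_diagonal: bool = True,
                                 statistic: str = "mean_diff",
                                 use_offdiagonal_view: bool = False,
                                 ) -> list[TransitionComparison]:
    """Label-permutation test of group differences in transition probability.

    The observed statistic for each ordered state pair (i, j) is the
    difference of group means (group A minus group B); ``statistic="t"``
    uses the Welch t statistic instead.  Each permutation applies one joint
    shuffle of the group labels to every entry, and two-sided p values use
    add-one smoothing: p = (1 + #{|null| >= |observed|}) / (n_permutations
    + 1), so p is never exactly zero.  NaN entries (unvisited source
    states) are excluded pairwise via NaN-aware means.
    """
    if not groupA or not groupB:
        raise ValueError("both groups must be nonempty")
    if statistic not in ("mean_diff", "t"):
        raise ValueError(f"unknown statistic {statistic!r}")
    VA = transition_prob_stack(groupA, use_offdiagonal_view)
    VB = transition_prob_stack(groupB, use_offdiagonal_view)
    K = VA.shape[1]
    V = np.concatenate([VA, VB]).reshape(len(groupA) + len(groupB), K * K)
    nA = len(groupA)
    n = V.shape[0]
    finite = np.isfinite(V)
    Vz = np.where(finite, V, 0.0)

    def stat(mask_a: np.ndarray) -> np.ndarray:
        # mask_a: (reps, n) boolean of group-A membership
        cA = mask_a.astype(float) @ finite
        cB = (~mask_a).astype(float) @ finite
        sA = mask_a.astype(float) @ Vz
        sB = (~mask_a).astype(float) @ Vz
        with np.errstate(invalid="ignore", divide="ignore"):
            mA = sA / cA
            mB = sB / cB
            diff = mA - mB
            if statistic == "mean_diff":
                return diff
            qA = mask_a.astype(float) @ (Vz * Vz)
            qB = (~mask_a).astype(float) @ (Vz * Vz)
            varA = (qA - cA * mA * mA) / np.maximum(cA - 1, 1)
            varB = (qB - cB * mB * mB) / np.maximum(cB - 1, 1)
            se = np.sqrt(varA / cA + varB / cB)
            return diff / se

    observed = stat(np.arange(n)[None, :] < nA)[0]
    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, K * K))
    labels = np.zeros(n, dtype=bool)
    labels[:nA] = True
    batch = 250
    for start in range(0, n_permutations, batch):
        stop = min(start + batch, n_permutations)
        masks = np.stack([rng.permutation(labels) for _ in range(stop - start)])
        null[start:stop] = stat(masks)
    exceed = np.abs(null) >= np.abs(observed)[None, :]
    p = (1 + np.nansum(np.where(np.isfinite(null), exceed, False), axis=0)) / (n_permutations + 1)

    results = []
    for i in range(K):
        for j in range(K):
            if not include_diagonal and i == j:
                continue
            obs = observed[i * K + j]
            results.append(TransitionComparison(
                from_state=i + 1, to_state=j + 1,
                observed_diff=float(obs),
                p_perm=float(p[i * K + j]),
                n_permutations=n_permutations,
                direction="increase" if obs >= 0 else "decrease",
            ))
    return results


def partial_spearman(x: Sequence[float], y: Sequence[float],
                     covariates: np.ndarray | None = None,
                     covariate_names: Sequence[str] = (),
                     x_name: tuple[str, int | str] = ("metric", "global"),
                     y_name: str = "score",
                     rank_covariates: bool = True) -> CorrelationResult:
    """Spearman correlation of x and y adjusted for covariates.

    Both variables are rank-transformed, residualized on the covariates
    (with intercept; continuous covariates are rank-transformed too by
    default), and the Pearson correlation of the residuals is reported
    with a t-approximation p value at df = n - 2 - n_covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        covariates = np.empty((x.size, 0))
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(covariates).all(axis=1)
    x, y, covariates = x[keep], y[keep], covariates[keep]
    n, n_cov = x.size, covariates.shape[1]
    if n < n_cov + 3:
        raise ValueError(f"need n >= {n_cov + 3} complete observations, got {n}")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    Z = np.column_stack([np.ones(n)] +
                        [sps.rankdata(c) if rank_covariates else c for c in covariates.T])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    coef_x, *_ = np.linalg.lstsq(Z, rx, rcond=None)
    coef_y, *_ = np.linalg.lstsq(Z, ry, rcond=None)
    ex, ey = rx - Z @ coef_x, ry - Z @ coef_y
    denom = np.sqrt((ex * ex).sum() * (ey * ey).sum())
    rho = float((ex * ey).sum() / denom) if denom > 0 else np.nan
    df = n - 2 - n_cov
    if np.isfinite(rho) and abs(rho) < 1:
        t = rho * np.sqrt(df / (1.0 - rho * rho))
        p = float(2 * sps.t.sf(abs(t), df))
    else:
        p = 0.0 if np.isfinite(rho) else np.nan
    return CorrelationResult(x_metric=tuple(x_name), y=y_name, rho=rho, p=p,
                             covariates=list(covariate_names), n=n)


def assign_cognitive_groups(moca_scores: Sequence[float], cutoff: float = 26.0
                            ) -> tuple[np.ndarray, int]:
    """Impairment labels from MoCA: score < cutoff -> impaired.

    Scores exactly at the cutoff join the unimpaired group; their count is
    returned (and logged) as a boundary report.
    """
    s = np.asarray(moca_scores, dtype=float)
    impaired = s < cutoff
    n_boundary = int((s == cutoff).sum())
    if n_boundary:
        logger.info("%d subject(s) score exactly %.0f on MoCA; assigned to the "
                    "unimpaired group", n_boundary, cutoff)
    return impaired, n_boundary
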