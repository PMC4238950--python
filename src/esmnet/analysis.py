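"""Arrival times, distance/degree relationships, cross-validation and nulls.

Given simulated deposition trajectories, a region's arrival time is the
first day its deposition probability reaches a threshold.  The analyses here
quantify how well effective anatomical distance to the outbreak set predicts
arrival time and deposition (the radial-propagation signature), how regional
connectivity degree relates to arrival time (hub vulnerability), whether the
real connectome explains a cohort better than degree/weight-preserving
randomizations, and how group-level parameters generalize across random
cohort splits.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .connectome import Connectome, randomize_connectome, weighted_degree
from .fitting import SearchConfig, fit_cohort
from .model import Trajectory, simulate

__all__ = [
    "ArrivalTimes",
    "arrival_times",
    "distance_time_regression",
    "explained_variance",
    "null_model_contrast",
    "split_half_cv",
    "degree_time_correlation",
]


@dataclasses.dataclass
class ArrivalTimes:
    """First-passage days to a deposition-probability threshold."""

    threshold: float
    t_arrive: np.ndarray


def arrival_times(traj: Trajectory, threshold: float) -> ArrivalTimes:
    """First day each region's deposition reaches ``threshold`` (inf if never)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    reached = traj.p >= threshold
    first = np.argmax(reached, axis=0)
    ever = reached.any(axis=0)
    out = np.where(ever, traj.time_days[first], np.inf)
    return ArrivalTimes(threshold=float(threshold), t_arrive=out)


def distance_time_regression(dist, times) -> tuple[float, float, float, float]:
    """OLS of arrival times on effective distances.

    Pairs with non-finite entries (unreached regions) are excluded pairwise.
    Returns (slope, intercept, r, two-sided p-value for the slope).
    """
    dist = np.asarray(dist, dtype=float)
    times = np.asarray(times, dtype=float)
    mask = np.isfinite(dist) & np.isfinite(times)
    if mask.sum() < 3:
        raise ValueError("need at least 3 finite (distance, time) pairs")
    res = stats.linregress(dist[mask], times[mask])
    return float(res.slope), float(res.intercept), float(res.rvalue), float(res.pvalue)


def explained_variance(estimated, reference) -> float:
    """Percentage of variance explained: 100 * (Pearson r)^2."""
    est = np.asarray(estimated, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape or est.size < 3:
        raise ValueError("inputs must have equal length >= 3")
    if np.ptp(est) == 0 or np.ptp(ref) == 0:
        raise ValueError("zero-variance input")
    r = stats.pearsonr(est, ref).statistic
    return float(100.0 * r * r)


def _cohort_explained_variance(patterns, conn, seeds, cfg) -> float:
    fits = fit_cohort(patterns, conn, seeds, cfg)
    scores = []
    for fit, pat in zip(fits, patterns):
        try:
            scores.append(explained_variance(fit.predicted, pat))
        except ValueError:  # flat prediction carries no explanatory power
            scores.append(0.0)
    return float(np.mean(scores))


def null_model_contrast(
    patterns,
    conn: Connectome,
    seeds,
    n_random: int,
    rng_seed: int,
    search_cfg: SearchConfig | None = None,
) -> tuple[float, np.ndarray, float]:
    """Contrast model fit on the true connectome against rewired nulls.

    Scores are cohort-mean explained variances of trajectory-matching fits.
    The empirical p-value uses the add-one permutation convention
    (1 + #{null >= true}) / (n_random + 1), so it is never exactly zero.
    """
    if n_random < 19:
        raise ValueError("n_random must be >= 19")
    cfg = search_cfg or SearchConfig()
    true_score = _cohort_explained_variance(patterns, conn, seeds, cfg)
    rng = np.random.default_rng(rng_seed)
    null_scores = np.empty(n_random)
    for i in range(n_random):
        rc = randomize_connectome(conn, rng_seed=int(rng.integers(0, 2**31 - 1)))
        null_scores[i] = _cohort_explained_variance(patterns, rc, seeds, cfg)
    p = (1.0 + np.sum(null_scores >= true_score)) / (n_random + 1.0)
    return true_score, null_scores, float(p)


def split_half_cv(
    patterns,
    conn: Connectome,
    seeds,
    n_splits: int,
    rng_seed: int,
    search_cfg: SearchConfig | None = None,
) -> np.ndarray:
    """Repeated random split-half cross-validation of group-level parameters.

    Each split halves the cohort at random; group parameters are the medians
    of the training subjects' fitted (beta0, delta0); the test score is the
    mean explained variance of the group-parameter trajectory (snapshot at
    each test subject's best-matching day) against the test patterns.
    """
    patterns = [np.asarray(p, dtype=float) for p in patterns]
    if len(patterns) < 4:
        raise ValueError("cohort size must be >= 4")
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    cfg = search_cfg or SearchConfig()
    rng = np.random.default_rng(rng_seed)
    n = len(patterns)
    scores = np.empty(n_splits)
    for s in range(n_splits):
        perm = rng.permutation(n)
        train, test = perm[: n // 2], perm[n // 2:]
        fits = fit_cohort([patterns[i] for i in train], conn, seeds, cfg)
        b = float(np.median([f.beta0 for f in fits]))
        d = float(np.median([f.delta0 for f in fits]))
        params = cfg.params.replace(beta0=b, delta0=d, noise_sd=0.0)
        traj = simulate(conn, params, sorted(seeds), rng_seed=None)
        split_scores = []
        for i in test:
            pat = patterns[i]
            d2 = np.einsum("ij,ij->i", traj.p, traj.p) - 2.0 * (traj.p @ pat)
            t = int(np.argmin(d2))
            try:
                split_scores.append(explained_variance(traj.p[t], pat))
            except ValueError:
                split_scores.append(0.0)
        scores[s] = np.mean(split_scores)
    return scores


def degree_time_correlation(
    conn: Connectome, times: ArrivalTimes, exclude=()
) -> tuple[float, float]:
    """Pearson correlation between weighted degree and arrival time.

    ``exclude`` (typically the seed regions) and never-reached regions are
    removed before correlating.  Returns (r, p-value).
    """
    deg = weighted_degree(conn)
    t = np.asarray(times.t_arrive, dtype=float)
    mask = np.isfinite(t)
    for i in exclude:
        mask[int(i)] = False
    if mask.sum() < 3:
        raise ValueError("need at least 3 finite, non-excluded regions")
    res = stats.pearsonr(deg[mask], t[mask])
    return float(res.statistic), float(res.pvalue)
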