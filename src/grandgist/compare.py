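"""Hydration-comparison statistics.

Covers the apparatus used to compare water sampling between simulations:
exponential equilibration fits N(t) = a + b(1 - e^{-kt}) with the 95%-of-
plateau equilibration time, average-linkage clustering of water oxygen
positions with same-frame exclusion, Tanimoto similarity between cluster
sets, crystal-water recovery curves over distance thresholds, pairwise
Kruskal-Wallis comparison of occupancy distributions, and site pairing with
R/MAD/Max/MRD metrics.

Matching everywhere is greedy one-to-one in ascending distance order:
deterministic, symmetric, and equal to optimal bipartite matching on
well-separated sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import curve_fit
from scipy.spatial.distance import cdist, pdist

#: same-frame pairs get this distance so they can never be clustered together
SAME_FRAME_DISTANCE = 1.0e6


# ---------------------------------------------------------------------------
# equilibration fitting

@dataclass
class OccupancyTrace:
    """Occupancy time series: times (ns) and per-repeat N series."""

    times: np.ndarray
    series: np.ndarray  # (n_repeats, n_points)
    label: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.series = np.atleast_2d(np.asarray(self.series, dtype=float))
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.series.shape[1] != len(self.times):
            raise ValueError("series length must match times")
        if np.any(self.series < 0):
            raise ValueError("occupancies must be non-negative")

    @property
    def mean_N(self) -> np.ndarray:
        return self.series.mean(axis=0)


class FitConvergenceError(RuntimeError):
    def __init__(self, message, p0=None, residuals=None):
        super().__init__(message)
        self.p0 = p0
        self.residuals = residuals


@dataclass
class EquilibrationFit:
    """Fitted exponential hydration model and derived quantities.

    ``a`` is the occupancy at t=0, ``a + b`` the plateau, ``k_rate`` the
    relaxation rate (ns^-1); ``t_eq`` is where N(t) reaches 95% of the
    plateau and ``N_eq`` the mean occupancy over t >= t_eq.
    """

    a: float
    b: float
    k_rate: float
    t_eq: float
    N_eq: float
    covariance: np.ndarray

    def model(self, t):
        return self.a + self.b * (1.0 - np.exp(-self.k_rate * np.asarray(t)))


def equilibration_time(a: float, b: float, k_rate: float) -> float:
    """t_eq solving N(t_eq) = 0.95 (a + b): (1/k) ln(b / (0.05 (a + b))),
    or 0 when b <= 0.05 (a + b) (already equilibrated at the start)."""
    plateau = a + b
    if plateau <= 0 or b <= 0.05 * plateau or k_rate <= 0:
        return 0.0
    return math.log(b / (0.05 * plateau)) / k_rate


def fit_equilibration(trace: OccupancyTrace) -> EquilibrationFit:
    """Nonlinear least-squares fit of N(t) = a + b(1 - e^{-kt}) with
    positivity bounds on all three parameters."""
    t = trace.times
    y = trace.mean_N
    if len(t) < 10:
        raise ValueError("need at least 10 time points")

    def model(tt, a, b, k):
        return a + b * (1.0 - np.exp(-k * tt))

    a0 = max(float(y[0]), 1e-6)
    b0 = max(float(y[-1] - y[0]), 1e-6)
    k0 = 3.0 / max(float(t[-1] - t[0]), 1e-9)
    p0 = (a0, b0, k0)
    try:
        popt, pcov = curve_fit(model, t, y, p0=p0,
                               bounds=([0, 0, 0], [np.inf, np.inf, np.inf]),
                               maxfev=20000)
    except RuntimeError as exc:
        raise FitConvergenceError(
            f"equilibration fit did not converge: {exc}", p0=p0,
            residuals=y - model(t, *p0)) from exc
    a, b, k = (float(v) for v in popt)
    t_eq = equilibration_time(a, b, k)
    n_eq = float(y[t >= t_eq].mean())
    return EquilibrationFit(a=a, b=b, k_rate=k, t_eq=t_eq, N_eq=n_eq,
                            covariance=pcov)


# ---------------------------------------------------------------------------
# water-site clustering

@dataclass
class WaterClusterSet:
    """Clustered water sites: centroids (Å), occupancies (fraction of frames
    populated), member counts, and the clustering parameters used."""

    centroids: np.ndarray  # (n_clusters, 3)
    occupancies: np.ndarray
    member_counts: np.ndarray
    n_frames: int
    cutoff: float
    occupancy_min: float

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 3)
        self.occupancies = np.asarray(self.occupancies, dtype=float)
        self.member_counts = np.asarray(self.member_counts, dtype=int)
        if np.any((self.occupancies < 0) | (self.occupancies > 1)):
            raise ValueError("occupancies must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.centroids)


def cluster_waters(frames, cutoff: float = 2.4,
                   occupancy_min: float = 0.3) -> WaterClusterSet:
    """Average-linkage hierarchical clustering of water oxygen positions.

    ``frames`` is a sequence of (n_i, 3) arrays, one per frame.  Distances
    between waters present in the same frame are set to an arbitrarily high
    value so they can never merge; the dendrogram is cut at ``cutoff`` (Å)
    and clusters populated in fewer than ``occupancy_min`` of the frames are
    dropped (keep everything by passing 0).
    """
    if len(frames) < 1:
        raise ValueError("at least one frame required")
    frames = [np.asarray(f, dtype=float).reshape(-1, 3) for f in frames]
    n_frames = len(frames)
    positions = (np.concatenate(frames) if any(len(f) for f in frames)
                 else np.zeros((0, 3)))
    frame_ids = np.concatenate(
        [np.full(len(f), i) for i, f in enumerate(frames)]) if len(positions) \
        else np.zeros(0, dtype=int)
    n = len(positions)
    if n == 0:
        return WaterClusterSet(np.zeros((0, 3)), np.zeros(0), np.zeros(0, int),
                               n_frames, cutoff, occupancy_min)
    if n == 1:
        labels = np.array([1])
    else:
        d = pdist(positions)
        same = pdist(frame_ids[:, None], metric=lambda u, v: float(u[0] == v[0]))
        d[same > 0.5] = SAME_FRAME_DISTANCE
        labels = fcluster(linkage(d, method="average"), t=cutoff,
                          criterion="distance")
    centroids, occupancies, counts = [], [], []
    for lab in np.unique(labels):
        members = labels == lab
        occ = len(np.unique(frame_ids[members])) / n_frames
        if occupancy_min > 0 and occ < occupancy_min:
            continue
        centroids.append(positions[members].mean(axis=0))
        occupancies.append(occ)
        counts.append(int(members.sum()))
    if not centroids:
        return WaterClusterSet(np.zeros((0, 3)), np.zeros(0), np.zeros(0, int),
                               n_frames, cutoff, occupancy_min)
    return WaterClusterSet(np.array(centroids), np.array(occupancies),
                           np.array(counts), n_frames, cutoff, occupancy_min)


# ---------------------------------------------------------------------------
# matching-based comparisons

def greedy_match(points_a: np.ndarray, points_b: np.ndarray,
                 max_dist: float) -> list[tuple[int, int, float]]:
    """One-to-one matching in ascending pair-distance order; pairs farther
    than ``max_dist`` stay unmatched.  Returns (i_a, i_b, distance) triples."""
    points_a = np.asarray(points_a, dtype=float).reshape(-1, 3)
    points_b = np.asarray(points_b, dtype=float).reshape(-1, 3)
    if len(points_a) == 0 or len(points_b) == 0:
        return []
    d = cdist(points_a, points_b)
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    used_a, used_b, matches = set(), set(), []
    for ia, ib in order:
        dist = d[ia, ib]
        if dist > max_dist + 1e-9:  # tolerance so boundary pairs count
            break
        if ia in used_a or ib in used_b:
            continue
        used_a.add(int(ia))
        used_b.add(int(ib))
        matches.append((int(ia), int(ib), float(dist)))
    return matches


def tanimoto_similarity(set_a: WaterClusterSet, set_b: WaterClusterSet,
                        match_dist: float = 1.4) -> float:
    """Tanimoto similarity T = c / (a + b - c) between two cluster sets,
    where c is the number of clusters agreeing within ``match_dist`` under
    greedy one-to-one matching.  Two empty sets are identically empty
    (T = 1); one empty set gives 0."""
    a, b = len(set_a), len(set_b)
    if a == 0 and b == 0:
        return 1.0
    if a == 0 or b == 0:
        return 0.0
    c = len(greedy_match(set_a.centroids, set_b.centroids, match_dist))
    return c / (a + b - c)


def crystal_recovery(clusters: WaterClusterSet, crystal_waters: np.ndarray,
                     thresholds=None) -> np.ndarray:
    """Fraction of crystal waters with a matched cluster centroid within
    each distance threshold (one-to-one greedy matching per threshold);
    the curve is nondecreasing in the threshold."""
    crystal = np.asarray(crystal_waters, dtype=float).reshape(-1, 3)
    if len(crystal) == 0:
        raise ValueError("no crystal waters to recover")
    if thresholds is None:
        thresholds = np.arange(0.0, 2.01, 0.1)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) < 0):
        raise ValueError("thresholds must be nondecreasing")
    out = np.empty(len(thresholds))
    for i, thr in enumerate(thresholds):
        matches = greedy_match(crystal, clusters.centroids, thr)
        out[i] = len(matches) / len(crystal)
    return out


# ---------------------------------------------------------------------------
# occupancy-distribution comparison

def _kruskal_two_sample(x: np.ndarray, y: np.ndarray,
                        permutation_below: int = 10) -> tuple[float, float]:
    """Two-sample Kruskal-Wallis H and p (tie-corrected chi-square
    approximation; permutation p-value when either sample is small)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0  # degenerate: everything identical
    h, p = stats.kruskal(x, y)
    if min(len(x), len(y)) < permutation_below:
        def statistic(a, b):
            return stats.kruskal(a, b).statistic

        res = stats.permutation_test(
            (x, y), statistic, permutation_type="independent",
            alternative="greater", n_resamples=5000,
            rng=np.random.default_rng(0))
        p = float(res.pvalue)
    return float(h), float(p)


def significance_stars(p: float) -> str:
    """Conventional significance marks: *** / ** / * / . at
    0.001 / 0.01 / 0.05 / 0.1."""
    for threshold, mark in ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, ".")):
        if p < threshold:
            return mark
    return ""


def compare_N_distributions(samples, subsample_interval: int = 1,
                            labels=None):
    """Pairwise Kruskal-Wallis comparison of occupancy-number samples.

    ``samples`` is a list of 1-D post-equilibration N series; each is
    subsampled by ``subsample_interval`` to thin autocorrelation.  Returns a
    symmetric p-value DataFrame with unit diagonal (a sample against itself
    has H = 0, p = 1).
    """
    import pandas as pd

    thinned = [np.asarray(s, dtype=float)[::subsample_interval] for s in samples]
    for s in thinned:
        if len(s) < 5:
            raise ValueError("each series needs >= 5 values after subsampling")
    k = len(thinned)
    labels = labels if labels is not None else list(range(k))
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            _, pij = _kruskal_two_sample(thinned[i], thinned[j])
            p[i, j] = p[j, i] = pij
    return pd.DataFrame(p, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# site pairing with scalar metrics

@dataclass
class SitePairingResult:
    pearson_r: float
    mad: float
    max_dev: float
    mrd: float
    n_paired: int


def pair_and_score_sites(sites_a: np.ndarray, values_a: np.ndarray,
                         sites_b: np.ndarray, values_b: np.ndarray,
                         pairing_dist: float = 1.0) -> SitePairingResult:
    """Pair sites across two runs by centroid distance and compare a scalar.

    Greedy one-to-one pairing under ``pairing_dist`` (Å); metrics are the
    Pearson correlation, mean absolute deviation, maximum deviation, and
    mean relative deviation (absolute difference over the larger of the two
    absolute values, averaged over pairs).
    """
    sites_a = np.asarray(sites_a, dtype=float).reshape(-1, 3)
    sites_b = np.asarray(sites_b, dtype=float).reshape(-1, 3)
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    matches = greedy_match(sites_a, sites_b, pairing_dist)
    if not matches:
        d = cdist(sites_a, sites_b) if len(sites_a) and len(sites_b) else np.array([[np.inf]])
        raise ValueError(
            "no site pairs within "
            f"{pairing_dist} Å (nearest distance {d.min():.3g} Å)")
    va = np.array([values_a[ia] for ia, _, _ in matches])
    vb = np.array([values_b[ib] for _, ib, _ in matches])
    diff = np.abs(va - vb)
    denom = np.maximum(np.abs(va), np.abs(vb))
    mrd = float(np.mean(np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0),
                                 0.0)))
    if len(va) >= 2 and np.std(va) > 0 and np.std(vb) > 0:
        r = float(stats.pearsonr(va, vb).statistic)
    else:
        r = 1.0 if np.allclose(va, vb) else 0.0
    return SitePairingResult(pearson_r=r, mad=float(diff.mean()),
                             max_dev=float(diff.max()), mrd=mrd,
                             n_paired=len(matches))
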