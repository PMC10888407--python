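"""Self-initializing p-norm k-means scoring of the feature vectors.

Because every feature grows with DAB expression, the p-norm of the feature
vector already orders the images by expression level.  The scorer exploits
this twice:

1. *Initialization.*  The sorted norms follow a power-law-like curve, so
   the norms are reshaped by a power ``q`` (fitted automatically, close to
   1/2 for the four-feature setup) and the reshaped range is split into
   ``n_clusters`` equal-length intervals; the images falling in interval k
   seed cluster k, and the initial centroid is the member mean.
2. *Ordering.*  After a fixed small number of k-means iterations (distance
   = p-norm, centroid = member mean), clusters are ranked by ascending
   centroid p-norm and scored "1+" (lowest expression) to "5+".

No random state anywhere: scoring is deterministic given the features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

DEFAULT_N_CLUSTERS = 5

#: (p, q, n_iters) defaults per feature-count T; q None means "auto".
_T_DEFAULTS = {
    2: (1.5, 1 / 1.8, 1),
    3: (1.9, 1 / 1.75, 2),
    4: (2.5, "auto", 3),
}


class ScoringError(ValueError):
    """Raised for cohorts the scorer cannot handle (e.g. identical images)."""


@dataclass
class ScoringConfig:
    """Knobs of the clustering stage.

    ``p`` is the norm order used both for initialization and as the k-means
    distance; values in [1, 3] are supported (others warn).  ``q`` reshapes
    the sorted norm curve before equal-interval splitting; "auto" fits it
    from the data.  ``n_features`` selects the leading T features
    (T=2 -> f1,f2; T=3 adds f3; T=4 adds f4).
    """

    p: float = 2.5
    q: float | str = "auto"
    n_iters: int = 3
    n_clusters: int = DEFAULT_N_CLUSTERS
    n_features: int = 4

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ScoringError("p must be >= 1")
        if not 1 <= self.p <= 3:
            warnings.warn(f"p={self.p} outside the supported interval [1, 3]", stacklevel=2)
        if self.n_clusters < 2 or self.n_iters < 1:
            raise ScoringError("need n_clusters >= 2 and n_iters >= 1")
        if self.n_features not in (2, 3, 4):
            raise ScoringError("n_features must be 2, 3 or 4")

    @classmethod
    def for_feature_count(cls, t: int) -> "ScoringConfig":
        """Defaults matched to the feature count: (p, q, iterations) =
        (1.5, 1/1.8, 1) for T=2, (1.9, 1/1.75, 2) for T=3,
        (2.5, auto ~ 1/2, 3) for T=4."""
        p, q, it = _T_DEFAULTS[t]
        return cls(p=p, q=q, n_iters=it, n_features=t)


@dataclass
class ScoreResult:
    """Outcome of scoring one cohort."""

    scores: np.ndarray
    clusters: list[np.ndarray]
    centroids: np.ndarray
    intervals: np.ndarray
    norms: np.ndarray
    p: float
    q: float
    config: ScoringConfig = field(repr=False, default=None)

    @property
    def labels(self) -> list[str]:
        """Scores as the conventional '1+'..'5+' strings."""
        return [f"{s}+" for s in self.scores]


def feature_pnorm(features: np.ndarray, p: float) -> np.ndarray:
    """p-norm of each feature vector (rows of ``features``)."""
    f = np.atleast_2d(np.asarray(features, dtype=float))
    return (np.abs(f) ** p).sum(axis=1) ** (1.0 / p)


def _fit_power(y: np.ndarray, ranks: np.ndarray) -> float | None:
    """Least-squares exponent b of y = a * rank^b.

    The fit is nonlinear least squares in linear space (a log-log slope
    only seeds it): fitting in linear space keeps a plateau of near-zero
    norms — a cohort with many unstained images — from dominating the
    exponent the way it would in log coordinates.
    """
    pos = y > 0
    if pos.sum() < 3:
        return None
    b0 = float(np.polyfit(np.log(ranks[pos]), np.log(y[pos]), 1)[0])
    a0 = float(np.exp(np.log(y[pos]).mean() - b0 * np.log(ranks[pos]).mean()))
    try:
        popt, _ = optimize.curve_fit(
            lambda m, a, b: a * m**b, ranks, y, p0=[a0, b0], maxfev=20000
        )
        return float(popt[1])
    except RuntimeError:
        return b0


def estimate_q(sorted_norms: np.ndarray) -> float:
    """Fit the reshaping power q from the sorted norm curve.

    Each half of the ascending norms is fit as ``y = a * rank^b`` by least
    squares in log-log coordinates; ``q = 2 / (b_first + b_second)`` (the
    inverse of the mean exponent).  Falls back to q = 1/2 — a good choice
    for the four-feature setup — when a half has fewer than 3 positive
    points to fit.
    """
    y = np.asarray(sorted_norms, dtype=float)
    if y.size < 4:
        raise ScoringError("need at least 4 images to fit q")
    if not (y >= 0).all():
        raise ScoringError("norms must be non-negative")
    if y.max() == 0:
        raise ScoringError("all feature norms are zero")
    ranks = np.arange(1, y.size + 1, dtype=float)
    half = y.size // 2
    b1 = _fit_power(y[:half], ranks[:half])
    b2 = _fit_power(y[half:], ranks[half:])
    if b1 is None or b2 is None:
        return 0.5
    denom = b1 + b2
    if denom <= 0:
        return 0.5
    return 2.0 / denom


def initialize_clusters(
    norms: np.ndarray, q: float, n_clusters: int = DEFAULT_N_CLUSTERS
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Equal-length interval split of the reshaped norms.

    ``v = norm^q``; [min v, max v] is partitioned into ``n_clusters``
    intervals of equal length, half-open [lower, upper) except the top one,
    which is closed so the maximum lands in the last cluster.  Returns the
    (n_clusters, 2) interval bounds and the member index arrays.
    """
    v = np.asarray(norms, dtype=float) ** q
    vmin, vmax = float(v.min()), float(v.max())
    if vmax <= vmin:
        raise ScoringError("all images have identical feature norms; unscorable")
    edges = vmin + (vmax - vmin) * np.arange(n_clusters + 1) / n_clusters
    idx = np.digitize(v, edges[1:-1], right=False)
    clusters = [np.where(idx == k)[0] for k in range(n_clusters)]
    intervals = np.column_stack([edges[:-1], edges[1:]])
    return intervals, clusters


def initial_centroids(
    features: np.ndarray,
    clusters: list[np.ndarray],
    intervals: np.ndarray,
    q: float,
    p: float,
) -> np.ndarray:
    """Member-mean centroids; an empty interval gets a synthetic centroid.

    The stand-in for an empty cluster is the uniform vector whose p-norm,
    raised to q, equals the interval midpoint: ``(v*^(1/q) / T^(1/p)) * 1``.
    """
    f = np.asarray(features, dtype=float)
    t = f.shape[1]
    cents = np.empty((len(clusters), t))
    for k, members in enumerate(clusters):
        if members.size:
            cents[k] = f[members].mean(axis=0)
        else:
            v_mid = intervals[k].mean()
            cents[k] = (v_mid ** (1.0 / q)) / (t ** (1.0 / p))
    return cents


def kmeans_pnorm(
    features: np.ndarray,
    centroids: np.ndarray,
    p: float,
    n_iters: int = 3,
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Fixed-iteration k-means under the p-norm distance.

    Each iteration assigns every image to its nearest centroid in p-norm
    distance and recomputes centroids as member means; a cluster that
    empties keeps its centroid frozen.  Returns (assignments, centroids,
    clusters) after exactly ``n_iters`` assignment+update rounds.
    """
    f = np.asarray(features, dtype=float)
    cents = np.array(centroids, dtype=float, copy=True)
    assign = None
    for _ in range(n_iters):
        dists = (np.abs(f[:, None, :] - cents[None, :, :]) ** p).sum(axis=2) ** (1 / p)
        assign = np.argmin(dists, axis=1)
        for k in range(cents.shape[0]):
            members = assign == k
            if members.any():
                cents[k] = f[members].mean(axis=0)
            else:
                warnings.warn(f"cluster {k} emptied; centroid frozen", stacklevel=2)
    clusters = [np.where(assign == k)[0] for k in range(cents.shape[0])]
    return assign, cents, clusters


def score_features(features: np.ndarray, config: ScoringConfig | None = None) -> ScoreResult:
    """Cluster a feature matrix and emit ordered scores 1..n_clusters.

    ``features`` is (M, >=T); the leading ``config.n_features`` columns are
    used.  Scores follow ascending centroid p-norm: the lowest-norm
    cluster's images get score 1, the highest-norm cluster's get
    ``n_clusters`` ("5+" = strongest DAB expression).
    """
    if config is None:
        config = ScoringConfig()
    f = np.asarray(features, dtype=float)
    if f.ndim != 2 or f.shape[0] < config.n_clusters:
        raise ScoringError(
            f"need at least {config.n_clusters} images, got {f.shape[0] if f.ndim == 2 else 0}"
        )
    f = f[:, : config.n_features]
    norms = feature_pnorm(f, config.p)
    q = estimate_q(np.sort(norms)) if config.q == "auto" else float(config.q)
    intervals, init_clusters = initialize_clusters(norms, q, config.n_clusters)
    cents0 = initial_centroids(f, init_clusters, intervals, q, config.p)
    assign, cents, clusters = kmeans_pnorm(f, cents0, config.p, config.n_iters)
    order = np.argsort(feature_pnorm(cents, config.p), kind="stable")
    rank_of_cluster = np.empty(config.n_clusters, dtype=int)
    rank_of_cluster[order] = np.arange(1, config.n_clusters + 1)
    scores = rank_of_cluster[assign]
    return ScoreResult(
        scores=scores,
        clusters=[clusters[k] for k in order],
        centroids=cents[order],
        intervals=intervals,
        norms=norms,
        p=config.p,
        q=q,
        config=config,
    )
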