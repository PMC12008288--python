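"""Inferential machinery for time-series and spatial brain-map analyses.

Four families of tests are implemented:

* cluster-based paired permutation tests over time (condition contrasts
  of energy time-series, null by per-subject sign flips, familywise
  control via the max-cluster-mass statistic);
* permutation Spearman correlations, optionally partialling out a
  ranked covariate of non-interest by least squares;
* spatial-autocorrelation-preserving "spin" nulls for cortical map
  associations (random 3-D rotations of spherical parcel centroids,
  greedy nearest-neighbour reassignment);
* dominance analysis, decomposing a multiple regression's explained
  variance into per-predictor percent relative importance by averaging
  R^2 increments over all 2^p - 1 predictor subsets.

All permutation p-values use the add-one convention
``p = (1 + #exceedances) / (1 + n_perm)`` and every stochastic routine
takes an explicit seed or Generator.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.spatial
import scipy.stats
from scipy.spatial.transform import Rotation
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusterResult",
    "SpinNullSet",
    "paired_cluster_test",
    "perm_spearman",
    "bh_correct",
    "build_spin_nulls",
    "spin_test",
    "dominance_analysis",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterResult:
    """Outcome of a cluster-based paired permutation test.

    ``clusters`` holds ``(start, end, mass, p)`` per supra-threshold run
    (``end`` exclusive); ``significant_mask`` marks time-points belonging
    to clusters with ``p <= alpha``.
    """

    point_stats: np.ndarray
    clusters: list[tuple[int, int, float, float]]
    significant_mask: np.ndarray
    threshold: float
    alpha: float


def _cluster_runs(stats: np.ndarray, thresh: float) -> list[tuple[int, int, float]]:
    """Maximal runs of |t| > thresh with signed mass (sum of t in the run)."""
    supra = np.abs(stats) > thresh
    out = []
    i = 0
    n = stats.size
    while i < n:
        if supra[i]:
            j = i
            while j < n and supra[j] and np.sign(stats[j]) == np.sign(stats[i]):
                j += 1
            out.append((i, j, float(stats[i:j].sum())))
            i = j
        else:
            i += 1
    return out


def _paired_t(d: np.ndarray) -> np.ndarray:
    """Per-column one-sample t statistic of the difference matrix d (subjects x time)."""
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(sd == 0, 0.0, t)


def _max_abs_cluster_mass(t: np.ndarray, thresh: float) -> float:
    """Vectorized max |cluster mass| of one statistic vector."""
    label = np.where(np.abs(t) > thresh, np.sign(t), 0.0)
    if not label.any():
        return 0.0
    # segment boundaries wherever the (signed) supra-threshold label changes
    change = np.flatnonzero(np.diff(label) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [t.size]])
    csum = np.concatenate([[0.0], np.cumsum(t)])
    masses = csum[ends] - csum[starts]
    keep = label[starts] != 0
    return float(np.max(np.abs(masses[keep]))) if keep.any() else 0.0


def _max_mass_null(
    d: np.ndarray, thresh: float, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Max |cluster mass| under random per-subject sign flips, vectorized.

    For sign-flipped differences the per-column sum of squares is
    invariant, so the permuted t statistics follow from the flipped
    means alone.
    """
    n, m = d.shape
    sumsq = (d * d).sum(axis=0)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
    means = (signs @ d) / n                       # n_perm x m
    var = (sumsq - n * means * means) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = means / np.sqrt(var / n)
    t_perm = np.nan_to_num(t_perm, nan=0.0, posinf=0.0, neginf=0.0)
    return np.array([_max_abs_cluster_mass(t_perm[p], thresh) for p in range(n_perm)])


def paired_cluster_test(
    a: np.ndarray,
    b: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> ClusterResult:
    """Cluster-based permutation test of paired (subjects x time) series.

    Per-time-point paired t statistics on ``a - b`` are thresholded at
    the two-tailed t critical value for ``alpha``; contiguous
    same-signed supra-threshold runs form clusters scored by the sum of
    their t values.  The null distribution is the maximum absolute
    cluster mass over random per-subject sign flips, controlling the
    familywise error across time.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("a and b must be equal-shape subjects x time arrays")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in input")
    if n_perm < 100:
        logger.warning("n_perm = %d is small; p-value resolution is coarse", n_perm)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    d = a - b
    n = d.shape[0]
    t_obs = _paired_t(d)
    thresh = float(scipy.stats.t.ppf(1 - alpha / 2, df=n - 1))
    runs = _cluster_runs(t_obs, thresh)
    null = _max_mass_null(d, thresh, n_perm, rng)

    clusters = []
    mask = np.zeros(d.shape[1], dtype=bool)
    for start, end, mass in runs:
        p = (1 + int(np.sum(null >= abs(mass)))) / (1 + n_perm)
        clusters.append((start, end, mass, p))
        if p <= alpha:
            mask[start:end] = True
    return ClusterResult(t_obs, clusters, mask, thresh, alpha)


def _rank(x: np.ndarray) -> np.ndarray:
    return scipy.stats.rankdata(x)


def _residualize(r: np.ndarray, rc: np.ndarray) -> np.ndarray:
    """Least-squares residual of ranked data on a ranked covariate (+ intercept)."""
    design = np.column_stack([np.ones_like(rc), rc])
    beta, *_ = np.linalg.lstsq(design, r, rcond=None)
    return r - design @ beta


def perm_spearman(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = None,
    covariate: np.ndarray | None = None,
) -> tuple[float, float]:
    """Spearman correlation with a permutation p-value (two-tailed).

    With a covariate, x and y are rank-transformed, residualized on the
    ranked covariate by least squares, and the residuals correlated
    (Pearson on residualized ranks); the permutation reshuffles the y
    residuals.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must share a length of at least 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: ranks undefined")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    rx, ry = _rank(x), _rank(y)
    if covariate is not None:
        rc = _rank(np.asarray(covariate, float).ravel())
        rx = _residualize(rx, rc)
        ry = _residualize(ry, rc)

    def _corr(u: np.ndarray, v: np.ndarray) -> float:
        u = u - u.mean()
        v = v - v.mean()
        return float(u @ v / np.sqrt((u @ u) * (v @ v)))

    rho = _corr(rx, ry)
    perms = np.array([_corr(rx, rng.permutation(ry)) for _ in range(n_perm)])
    p = (1 + int(np.sum(np.abs(perms) >= abs(rho)))) / (1 + n_perm)
    return rho, p


def bh_correct(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, float).ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class SpinNullSet:
    """Precomputed cortical spin permutations and the sphere they live on."""

    permutations: np.ndarray      # n_spins x N_cortex integer index arrays
    sphere_coords: np.ndarray     # N_cortex x 3 unit vectors

    def __post_init__(self) -> None:
        perms = np.asarray(self.permutations, dtype=int)
        coords = np.asarray(self.sphere_coords, float)
        n = coords.shape[0]
        if perms.ndim != 2 or perms.shape[1] != n:
            raise ValueError("permutation/coordinate size mismatch")
        if perms.min() < 0 or perms.max() >= n:
            raise ValueError("permutation indices out of range")
        norms = np.linalg.norm(coords, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("sphere coordinates must be unit-norm within 1e-9")
        object.__setattr__(self, "permutations", perms)
        object.__setattr__(self, "sphere_coords", coords)

    @property
    def n_spins(self) -> int:
        return self.permutations.shape[0]


def build_spin_nulls(
    coords: np.ndarray,
    n_spins: int = 10000,
    seed: int | np.random.Generator | None = None,
    include_identity: bool = False,
) -> SpinNullSet:
    """Spin permutations of cortical parcels on the sphere.

    Each null applies one uniform random 3-D rotation to every centroid
    and reassigns each parcel to the nearest rotated parcel (greedy
    nearest neighbour; duplicates allowed).  The spun maps preserve the
    spatial autocorrelation of the original while randomizing anatomy.
    """
    coords = np.asarray(coords, float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be N x 3")
    norms = np.linalg.norm(coords, axis=1)
    if np.any(norms == 0) or np.allclose(coords, coords[0]):
        raise ValueError("degenerate coordinates")
    coords = coords / norms[:, None]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    rots = Rotation.random(num=n_spins, random_state=rng)
    tree = scipy.spatial.cKDTree(coords)
    perms = np.empty((n_spins + include_identity, coords.shape[0]), dtype=int)
    row = 0
    if include_identity:
        perms[0] = np.arange(coords.shape[0])
        row = 1
    for r in range(n_spins):
        rotated = rots[r].apply(coords)
        _, idx = tree.query(rotated)
        perms[row + r] = idx
    return SpinNullSet(perms, coords)


def spin_test(
    map_a: np.ndarray, map_b: np.ndarray, nulls: SpinNullSet
) -> tuple[float, float]:
    """Spearman correlation of two cortical maps with a spin-null p-value.

    ``map_b`` is the map being spun; the null distribution is the
    correlation of ``map_a`` with each spun version of ``map_b``.
    """
    a = np.asarray(map_a, float).ravel()
    b = np.asarray(map_b, float).ravel()
    n = nulls.sphere_coords.shape[0]
    if a.size != n or b.size != n:
        raise ValueError("maps must cover the cortical parcels of the null set")
    rho = float(scipy.stats.spearmanr(a, b).statistic)
    ra = _rank(a)
    null_rhos = np.empty(nulls.n_spins)
    for i, perm in enumerate(nulls.permutations):
        rb = _rank(b[perm])
        null_rhos[i] = np.corrcoef(ra, rb)[0, 1]
    p = (1 + int(np.sum(np.abs(null_rhos) >= abs(rho)))) / (1 + nulls.n_spins)
    return rho, p


def _r2(X: np.ndarray, y: np.ndarray) -> float:
    """Unadjusted R^2 of an OLS fit with intercept."""
    design = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(resid @ resid) / ss_tot


def dominance_analysis(
    X: np.ndarray, y: np.ndarray, predictor_names: list[str] | None = None
) -> dict[str, float]:
    """Percent relative importance of each predictor via total dominance.

    Fits OLS for all 2^p - 1 non-empty predictor subsets.  A predictor's
    total dominance is the average - first within each subset size, then
    across sizes - of the R^2 increase from adding it to subsets that
    exclude it (the empty subset contributes its marginal R^2).  Percent
    importance divides by the full-model R^2, so the importances sum to
    100.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D (observations x predictors)")
    n, p = X.shape
    if p < 1 or n <= p + 1:
        raise ValueError("need p >= 1 predictors and n > p + 1 observations")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < p + 1:
        raise ValueError("singular design: collinear predictors")
    names = predictor_names or [f"x{j}" for j in range(p)]

    r2_cache: dict[frozenset[int], float] = {frozenset(): 0.0}
    for size in range(1, p + 1):
        for subset in itertools.combinations(range(p), size):
            key = frozenset(subset)
            r2_cache[key] = _r2(X[:, list(subset)], y)

    total = np.zeros(p)
    for j in range(p):
        others = [i for i in range(p) if i != j]
        # average increments within each subset size (0..p-1), then across sizes
        level_means = []
        for size in range(0, p):
            incs = [
                r2_cache[frozenset(sub) | {j}] - r2_cache[frozenset(sub)]
                for sub in itertools.combinations(others, size)
            ]
            level_means.append(np.mean(incs))
        total[j] = np.mean(level_means)

    full = r2_cache[frozenset(range(p))]
    importance = 100.0 * total / full
    return dict(zip(names, importance))
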