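"""Spatial weights and global/local Moran autocorrelation analysis.

Global Moran's I over n regions with weight matrix W and attribute x:

    I = n / S0 * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

with S0 the sum of all weights. Its null expectation is -1/(n-1); the
variance is computed with the standard Cliff-Ord moments under either
the normality or the randomization null, giving a z-score and a
two-sided normal p-value. A permutation test reports a pseudo p-value
as a distribution-free check.

The local decomposition

    I_i = n (x_i - xbar) * sum_j w_ij (x_j - xbar) / sum_i (x_i - xbar)^2

satisfies sum_i I_i = S0 * I identically, and the signs of the
deviation and the spatial lag place each region in a LISA quadrant:
HH (high among high neighbors, "strong-strong"), LL ("weak-weak"),
HL and LH.

Weights default to inverse Euclidean distance with a cutoff just large
enough that every region has at least one neighbor; distance-band and
k-nearest-neighbor weights and row standardization are available.

The often-quoted range [-1, 1] for I holds only approximately: the
exact attainable range is the spectral range of the centered,
symmetrized weight matrix scaled by n/S0 (see :func:`moran_bounds`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.spatial import distance_matrix

from .core import GlobalMoranResult, LocalMoranResult, SpatialWeights, ZeroVarianceError

NORMALITY = "normality"
RANDOMIZATION = "randomization"


class CoincidentPointsError(ValueError):
    """Two regions share coordinates; inverse-distance weight is infinite."""


def build_weights(
    coords: np.ndarray,
    labels: Optional[Sequence[str]] = None,
    method: str = "inverse_distance",
    *,
    power: float = 1.0,
    cutoff: Optional[float] = None,
    k: int = 4,
    row_standardize: bool = False,
) -> SpatialWeights:
    """Construct a spatial weight matrix from point coordinates.

    Parameters
    ----------
    coords
        (n, 2) array of planar coordinates.
    method
        ``inverse_distance`` (w_ij = 1/d_ij^power for d_ij <= cutoff),
        ``distance_band`` (binary within cutoff) or ``knn`` (binary,
        k nearest; generally asymmetric).
    cutoff
        Distance threshold. ``None`` selects the minimum-coverage
        cutoff (the largest nearest-neighbor distance, so every region
        keeps at least one neighbor); ``numpy.inf`` disables it.
    row_standardize
        Divide each nonzero row by its sum.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 regions")
    if labels is None:
        labels = [f"R{i+1}" for i in range(n)]
    labels = list(labels)

    d = distance_matrix(coords, coords)
    off = ~np.eye(n, dtype=bool)

    if method in ("inverse_distance", "distance_band"):
        if method == "inverse_distance":
            zero = off & (d == 0)
            if zero.any():
                i, j = np.argwhere(zero)[0]
                raise CoincidentPointsError(
                    f"regions {labels[i]!r} and {labels[j]!r} share coordinates"
                )
        if cutoff is None:
            # smallest cutoff guaranteeing every unit >= 1 neighbor
            nn = np.where(off, d, np.inf).min(axis=1)
            cutoff = float(nn.max())
        within = off & (d <= cutoff)
        if method == "inverse_distance":
            w = np.zeros_like(d)
            w[within] = 1.0 / d[within] ** power
        else:
            w = within.astype(float)
    elif method == "knn":
        if not 1 <= k < n:
            raise ValueError(f"knn requires 1 <= k < n, got k={k}")
        w = np.zeros_like(d)
        order = np.argsort(np.where(off, d, np.inf), axis=1, kind="stable")
        for i in range(n):
            w[i, order[i, :k]] = 1.0
    else:
        raise ValueError(f"unknown weights method {method!r}")

    weights = SpatialWeights(labels, w, standardized=False)
    if row_standardize:
        weights = weights.row_standardized()
    if weights.s0 <= 0:
        raise ValueError("weight matrix has zero total weight")
    return weights


def _deviations(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    z = x - x.mean()
    if np.all(z == 0):
        raise ZeroVarianceError("attribute is constant across regions")
    return z


def _moran_stat(z: np.ndarray, W: np.ndarray, s0: float) -> float:
    return float(z.size / s0 * (z @ W @ z) / (z @ z))


def moran_zscore(I: float, expected: float, variance: float) -> float:
    """Standard score of an observed Moran's I: (I - E[I]) / sqrt(Var)."""
    return (I - expected) / np.sqrt(variance)


def moran_variance(x: np.ndarray, W: SpatialWeights, method: str = RANDOMIZATION) -> float:
    """Cliff-Ord variance of Moran's I under the chosen null.

    ``normality`` assumes x is an i.i.d. Gaussian sample;
    ``randomization`` conditions on the observed values (equally likely
    permutations) and involves the sample kurtosis b2.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("variance requires at least 3 regions")
    w = W.matrix
    s0 = W.s0
    s1 = 0.5 * float(((w + w.T) ** 2).sum())
    s2 = float(((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum())
    e = -1.0 / (n - 1)

    if method == NORMALITY:
        ei2 = (n * n * s1 - n * s2 + 3 * s0 * s0) / (s0 * s0 * (n * n - 1))
    elif method == RANDOMIZATION:
        if n < 4:
            raise ValueError("randomization variance requires at least 4 regions")
        z = _deviations(x)
        b2 = n * float((z**4).sum()) / float((z**2).sum()) ** 2
        num = n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0) - b2 * (
            (n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0
        )
        ei2 = num / ((n - 1) * (n - 2) * (n - 3) * s0 * s0)
    else:
        raise ValueError(f"unknown variance method {method!r}")
    return float(ei2 - e * e)


def global_moran(
    x: np.ndarray,
    W: SpatialWeights,
    *,
    variance_method: str = RANDOMIZATION,
    permutations: Optional[int] = None,
    seed: int = 0,
) -> GlobalMoranResult:
    """Global Moran's I with analytic inference (optional permutations)."""
    z = _deviations(x)
    n = z.size
    if W.n != n:
        raise ValueError(f"weights are {W.n}x{W.n} but x has {n} values")
    I = _moran_stat(z, W.matrix, W.s0)
    expected = -1.0 / (n - 1)
    variance = moran_variance(x, W, variance_method)
    zsc = moran_zscore(I, expected, variance)
    p = float(2 * stats.norm.sf(abs(zsc)))
    p_perm = None
    if permutations is not None:
        p_perm = permutation_test(x, W, permutations, seed)
    return GlobalMoranResult(
        I=I,
        expected=expected,
        variance=float(variance),
        variance_method=variance_method,
        z=float(zsc),
        p_two_sided=p,
        n=n,
        p_permutation=p_perm,
    )


def permutation_test(x: np.ndarray, W: SpatialWeights, n_perm: int, seed: int = 0) -> float:
    """Two-sided permutation pseudo p-value for global Moran's I.

    pseudo-p = (1 + #{|I_perm - E| >= |I_obs - E|}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    z = _deviations(x)
    n = z.size
    rng = np.random.default_rng(seed)
    I_obs = _moran_stat(z, W.matrix, W.s0)
    e = -1.0 / (n - 1)
    # vectorized: all permuted deviation vectors at once
    perms = np.array([rng.permutation(z) for _ in range(n_perm)])
    num = ((perms @ W.matrix) * perms).sum(axis=1)
    I_perm = n / W.s0 * num / (z @ z)
    extreme = np.abs(I_perm - e) >= np.abs(I_obs - e) - 1e-14
    return float((1 + extreme.sum()) / (n_perm + 1))


def local_moran(
    x: np.ndarray,
    W: SpatialWeights,
    *,
    permutations: int = 999,
    seed: int = 0,
) -> LocalMoranResult:
    """Local Moran's I per region with LISA quadrants and pseudo p-values.

    The per-region pseudo p is a conditional permutation test: region
    i's value is held fixed while the remaining values are permuted
    over the other locations.
    """
    z = _deviations(x)
    n = z.size
    if W.n != n:
        raise ValueError(f"weights are {W.n}x{W.n} but x has {n} values")
    m2 = float(z @ z)
    lag = W.matrix @ z
    local_i = n * z * lag / m2

    quadrant = []
    for zi, li in zip(z, lag):
        hi_self = zi >= 0
        hi_lag = li >= 0
        quadrant.append(
            "HH" if hi_self and hi_lag else
            "LL" if not hi_self and not hi_lag else
            "HL" if hi_self else "LH"
        )

    rng = np.random.default_rng(seed)
    pseudo_p = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        others = z[idx != i]
        wi = W.matrix[i, idx != i]
        draws = np.array([rng.permutation(others) for _ in range(permutations)])
        lag_perm = draws @ wi
        i_perm = n * z[i] * lag_perm / m2
        if local_i[i] >= i_perm.mean():
            extreme = (i_perm >= local_i[i] - 1e-14).sum()
        else:
            extreme = (i_perm <= local_i[i] + 1e-14).sum()
        pseudo_p[i] = (1 + extreme) / (permutations + 1)

    return LocalMoranResult(
        labels=list(W.labels),
        local_i=local_i,
        deviation=z,
        lag=lag,
        quadrant=quadrant,
        pseudo_p=pseudo_p,
    )


@dataclass
class SubsetMoranResult:
    """Spatial association of a region subgroup.

    A single per-group association number is ambiguous, so both
    conventions are reported: the subset's own global I (weights
    restricted to the subset and re-standardized when applicable) and
    the mean of the subset's local I_i values.
    """

    labels: list[str]
    global_result: GlobalMoranResult
    mean_local_i: float
    local_result: LocalMoranResult

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "subset_global_i": self.global_result.I,
            "mean_local_i": self.mean_local_i,
            "global": self.global_result.to_dict(),
            "local": self.local_result.to_dict(),
        }


def subset_moran(
    x: np.ndarray,
    W: SpatialWeights,
    subset_labels: Sequence[str],
    *,
    variance_method: str = RANDOMIZATION,
    permutations: int = 999,
    seed: int = 0,
) -> SubsetMoranResult:
    """Global and local Moran analysis restricted to a region subgroup."""
    labels = list(subset_labels)
    unknown = [lab for lab in labels if lab not in W.labels]
    if unknown:
        raise ValueError(f"unknown region label(s): {', '.join(map(repr, unknown))}")
    if len(labels) < 3:
        raise ValueError("subset must contain at least 3 regions")
    pos = {lab: i for i, lab in enumerate(W.labels)}
    idx = [pos[lab] for lab in labels]
    x = np.asarray(x, dtype=float)
    W_sub = W.subset(idx)
    x_sub = x[idx]
    g = global_moran(x_sub, W_sub, variance_method=variance_method)
    loc = local_moran(x_sub, W_sub, permutations=permutations, seed=seed)
    return SubsetMoranResult(
        labels=labels,
        global_result=g,
        mean_local_i=float(loc.local_i.mean()),
        local_result=loc,
    )


def moran_bounds(W: SpatialWeights) -> tuple[float, float]:
    """Exact attainable range of global Moran's I for this weight matrix.

    I = (n/S0) z'Wz / z'z over centered z equals a Rayleigh quotient of
    the centered symmetrized weights, so the range is the scaled
    extreme eigenvalues. The textbook [-1, 1] is only approximate.
    """
    w = W.matrix
    n = W.n
    b = 0.5 * (w + w.T)
    center = np.eye(n) - np.ones((n, n)) / n
    eig = np.linalg.eigvalsh(center @ b @ center)
    return float(n / W.s0 * eig.min()), float(n / W.s0 * eig.max())
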