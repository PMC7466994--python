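"""Spatial statistics: great-circle distances, Moran's I, Mantel tests.

Population collections sampled across a landscape are rarely exchangeable:
trait values and allele frequencies both carry spatial autocorrelation.
Moran's I quantifies it for a single variable given a spatial weight
matrix; the Mantel test correlates two whole distance matrices
(e.g. genetic vs geographic) with a permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Mean Earth radius in meters (IUGG).
EARTH_RADIUS_M = 6_371_008.8


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with labelled rows/columns."""

    ids: list[str]
    D: np.ndarray
    units: str = "meters"

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.ids)
        if self.D.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.D.shape} != ({n}, {n})")
        if not np.allclose(self.D, self.D.T, atol=1e-8):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.D) != 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.D < 0):
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.ids)

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(self.n, k=-1)
        return self.D[i, j]


@dataclass
class MoranResult:
    """Moran's I with its randomization-null expectation, sd and p-value."""

    I: float
    expected: float
    sd: float
    p_value: float


def haversine_m(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in meters between points in decimal degrees."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def geo_distances(panel) -> DistanceMatrix:
    """Pairwise great-circle distances (meters) between panel populations."""
    lon = np.asarray(panel.lon, dtype=float)
    lat = np.asarray(panel.lat, dtype=float)
    D = haversine_m(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)
    return DistanceMatrix(ids=list(panel.pop_ids), D=D, units="meters")


def euclidean_distances(values: np.ndarray, ids, units: str = "euclidean-genetic") -> DistanceMatrix:
    """Pairwise Euclidean distances between rows of a value matrix."""
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(np.asarray(values, dtype=float)))
    return DistanceMatrix(ids=list(ids), D=D, units=units)


def inverse_distance_weights(D: DistanceMatrix) -> np.ndarray:
    """w_ij = 1/d_ij with zero diagonal; coincident pairs get the largest finite weight."""
    with np.errstate(divide="ignore"):
        W = 1.0 / D.D
    np.fill_diagonal(W, 0.0)
    if np.isinf(W).any():
        finite = W[np.isfinite(W)]
        cap = finite.max() if finite.size else 1.0
        W[np.isinf(W)] = cap
    return W


def morans_i(values, weights, row_normalize: bool = False) -> MoranResult:
    """Moran's spatial autocorrelation index with analytic significance.

    I = (n/S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2.
    Expectation is -1/(n-1); the variance is computed under the
    randomization assumption and the p-value from a two-sided normal
    approximation (requires n >= 4; reported as NaN below that).
    The raw statistic is reported unclamped — for some weight schemes it can
    leave the nominal [-1, 1] range.  ``row_normalize=True`` divides each
    weight row by its sum first (the convention of the common R
    implementation), which keeps I inside the nominal range in practice.
    """
    x = np.asarray(values, dtype=float)
    W = np.asarray(weights, dtype=float)
    if row_normalize:
        rs = W.sum(axis=1, keepdims=True)
        if np.any(rs == 0):
            raise ValueError("cannot row-normalize: zero row sum in weights")
        W = W / rs
    n = x.size
    if n < 2:
        raise ValueError("Moran's I needs at least 2 observations")
    if W.shape != (n, n):
        raise ValueError(f"weights shape {W.shape} != ({n}, {n})")
    if np.any(W < 0) or np.any(np.diag(W) != 0.0):
        raise ValueError("weights must be non-negative with zero diagonal")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("Moran's I undefined for constant values")
    S0 = float(W.sum())
    if S0 <= 0.0:
        raise ValueError("weight matrix sums to zero")
    num = float(z @ W @ z)
    I = (n / S0) * num / denom
    expected = -1.0 / (n - 1)
    if n < 4:
        return MoranResult(I=I, expected=expected, sd=float("nan"), p_value=float("nan"))
    S1 = 0.5 * float(((W + W.T) ** 2).sum())
    rs = W.sum(axis=1) + W.sum(axis=0)
    S2 = float((rs**2).sum())
    b2 = n * float((z**4).sum()) / denom**2
    var = (
        n * ((n**2 - 3 * n + 3) * S1 - n * S2 + 3 * S0**2)
        - b2 * ((n**2 - n) * S1 - 2 * n * S2 + 6 * S0**2)
    ) / ((n - 1) * (n - 2) * (n - 3) * S0**2) - expected**2
    sd = float(np.sqrt(max(var, 0.0)))
    if sd == 0.0:
        p = float("nan")
    else:
        p = 2.0 * stats.norm.sf(abs(I - expected) / sd)
    return MoranResult(I=I, expected=expected, sd=sd, p_value=float(p))


def mantel(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    n_perm: int = 500,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices with permutation test.

    r is the Pearson correlation of the strictly-lower-triangle entries.
    The one-tailed (greater) p-value jointly permutes rows and columns of
    the second matrix, with the add-one correction
    p = (1 + #{r* >= r_obs}) / (n_perm + 1).
    """
    if D1.n != D2.n:
        raise ValueError("distance matrices differ in size")
    if D1.ids != D2.ids:
        if set(D1.ids) == set(D2.ids):
            order = [D2.ids.index(i) for i in D1.ids]
            D2 = DistanceMatrix(ids=list(D1.ids), D=D2.D[np.ix_(order, order)], units=D2.units)
        else:
            raise ValueError("distance matrices have mismatched ids")
    n = D1.n
    if n < 4:
        raise ValueError("Mantel test needs at least 4 observations")
    il, jl = np.tril_indices(n, k=-1)
    v1 = D1.D[il, jl]
    v2 = D2.D[il, jl]
    if v1.std() == 0.0 or v2.std() == 0.0:
        raise ValueError("constant distance matrix; Mantel r undefined")
    r_obs = float(np.corrcoef(v1, v2)[0, 1])
    rng = np.random.default_rng(seed)
    z1 = (v1 - v1.mean()) / v1.std()
    count = 0
    for _ in range(int(n_perm)):
        perm = rng.permutation(n)
        vp = D2.D[np.ix_(perm, perm)][il, jl]
        r_star = float(np.mean(z1 * (vp - vp.mean()) / vp.std()))
        if r_star >= r_obs - 1e-12:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return r_obs, float(p)
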