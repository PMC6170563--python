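"""Spatial weights, Moran's I, the exact Moran test on OLS residuals, and
Moran-eigenvector (SEVM) spatial filtering.

The exact residual test treats Moran's I on OLS residuals as a ratio of
quadratic forms in the Gaussian errors: with hat-complement M = I - H and
symmetrized weights Ws,

    I = (n/S0) * e' Ws e / e' e,   e = M y,

so P(I >= i0) = P(q' L q >= 0) with L = M ((n/S0) Ws - i0 I) M and q ~ N(0, I).
The tail probability of the indefinite quadratic form is obtained by Imhof's
characteristic-function inversion over the nonzero eigenvalues of L — the
distribution is continuous, hence the null p-value is exactly uniform.

SEVM: eigenvectors of the doubly-centred weight matrix C Ws C (Moran
eigenvector maps) with positive eigenvalues are candidate spatial covariates;
forward selection adds whichever candidate best de-autocorrelates the
residuals (maximal exact Moran p) until the residual test is non-significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import integrate

__all__ = [
    "SpatialWeights",
    "MoranTestResult",
    "EigenvectorFilter",
    "build_weights",
    "great_circle_matrix",
    "morans_i",
    "moran_residual_test",
    "mem_eigenvectors",
    "select_spatial_filter",
]

EARTH_RADIUS_KM = 6371.0088


def great_circle_matrix(coords: np.ndarray) -> np.ndarray:
    """Pairwise haversine distances (km) for (lat, lon) rows in degrees."""
    coords = np.asarray(coords, dtype=float)
    lat = np.radians(coords[:, 0])[:, None]
    lon = np.radians(coords[:, 1])[:, None]
    dphi = lat - lat.T
    dlmb = lon - lon.T
    a = np.sin(dphi / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlmb / 2) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


@dataclass(frozen=True)
class SpatialWeights:
    """Site-by-site spatial weight matrix with zero diagonal."""

    W: np.ndarray
    coords: np.ndarray
    scheme: Literal["knn", "distance_band"] = "knn"
    k: int | None = None
    band_km: float | None = None
    row_standardized: bool = False

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weight matrix must be square")
        if np.any(np.diag(W) != 0):
            raise ValueError("weight matrix must have zero diagonal")
        if np.any(W < 0):
            raise ValueError("weights must be non-negative")

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def symmetrized(self) -> np.ndarray:
        return (self.W + self.W.T) / 2.0


@dataclass(frozen=True)
class MoranTestResult:
    I: float
    expected_I: float
    p_value: float
    method: Literal["exact", "normal", "permutation"]
    alternative: Literal["greater", "two_sided"]


@dataclass(frozen=True)
class EigenvectorFilter:
    """Selected Moran-eigenvector basis (columns orthonormal, orthogonal to 1)."""

    basis: np.ndarray  # n x q
    eigenvalues: tuple[float, ...] = ()
    selection_order: tuple[int, ...] = ()
    residual_p_path: tuple[float, ...] = ()
    converged: bool = True

    @property
    def q(self) -> int:
        return 0 if self.basis.size == 0 else self.basis.shape[1]


def build_weights(
    coords: Sequence[Sequence[float]] | np.ndarray,
    scheme: Literal["knn"] = "knn",
    k: int = 4,
    row_standardize: bool = True,
) -> SpatialWeights:
    """k-nearest-neighbour weights by great-circle distance.

    Ties in distance (duplicate coordinates) are broken by site index with a
    warning.  A disconnected neighbour graph triggers a warning, not an error.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 3:
        raise ValueError("need at least 3 sites")
    if scheme != "knn":
        raise ValueError(f"unsupported scheme {scheme!r}")
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n (got k={k}, n={n})")
    D = great_circle_matrix(coords)
    if np.any(D[~np.eye(n, dtype=bool)] == 0):
        warnings.warn("duplicate coordinates; kNN ties broken by site index")
    np.fill_diagonal(D, np.inf)
    W = np.zeros((n, n))
    # argsort is stable -> deterministic index tie-break
    order = np.argsort(D, axis=1, kind="stable")
    rows = np.repeat(np.arange(n), k)
    W[rows, order[:, :k].ravel()] = 1.0
    if not _connected((W + W.T) > 0):
        warnings.warn("kNN neighbour graph is not connected")
    if row_standardize:
        rs = W.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        W = W / rs
    return SpatialWeights(W, coords, "knn", k=k, row_standardized=row_standardize)


def _connected(adj: np.ndarray) -> bool:
    n = adj.shape[0]
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in np.flatnonzero(adj[i]):
            if not seen[j]:
                seen[j] = True
                stack.append(int(j))
    return bool(seen.all())


def morans_i(values: Sequence[float] | np.ndarray, weights: SpatialWeights) -> float:
    """Global Moran's I = (n/S0) z'Wz / z'z with z the centred values."""
    z = np.asarray(values, dtype=float)
    z = z - z.mean()
    denom = z @ z
    if denom == 0:
        raise ValueError("zero variance: Moran's I undefined for a constant vector")
    W = weights.W
    s0 = W.sum()
    return float((weights.n / s0) * (z @ W @ z) / denom)


def _imhof_upper_tail(lam: np.ndarray) -> float:
    """P(sum_j lam_j chi2_1j > 0) by Imhof characteristic-function inversion."""
    lam = lam[np.abs(lam) > 1e-12 * max(1.0, np.abs(lam).max())]
    if lam.size == 0:
        return 0.5
    if np.all(lam > 0):
        return 1.0
    if np.all(lam < 0):
        return 0.0

    def integrand(u: float) -> float:
        theta = 0.5 * np.sum(np.arctan(lam * u))
        rho = np.exp(0.25 * np.sum(np.log1p((lam * u) ** 2)))
        return float(np.sin(theta) / (u * rho))

    # integrand ~ sum(lam)/2 as u -> 0 and decays like u^{-(r/2+1)}
    upper = 200.0 / max(np.abs(lam).max(), 1e-12)
    val, _ = integrate.quad(integrand, 0.0, upper, limit=400, epsabs=1e-9, epsrel=1e-9)
    return float(min(max(0.5 + val / np.pi, 0.0), 1.0))


def _residual_moran_parts(
    X: np.ndarray, y: np.ndarray, Ws: np.ndarray
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Observed residual I, its null expectation, residuals, and MWsM."""
    n = X.shape[0]
    Q, _ = np.linalg.qr(X)
    # M = I - QQ'; apply without forming H explicitly
    MW = Ws - Q @ (Q.T @ Ws)
    MWM = MW - (MW @ Q) @ Q.T
    MWM = (MWM + MWM.T) / 2.0
    e = y - Q @ (Q.T @ y)
    s0 = Ws.sum()
    c = n / s0
    I_obs = float(c * (e @ Ws @ e) / (e @ e))
    p = X.shape[1]
    expected = float(c * np.trace(MWM) / (n - p))
    return I_obs, expected, e, MWM


def moran_residual_test(
    X: np.ndarray,
    y: np.ndarray,
    weights: SpatialWeights,
    method: Literal["exact", "normal", "permutation"] = "exact",
    alternative: Literal["greater", "two_sided"] = "greater",
    n_permutations: int = 9999,
    rng: np.random.Generator | None = None,
) -> MoranTestResult:
    """Moran test on the residuals of the OLS regression of y on X.

    X is the full design matrix (pass a column of ones for the intercept).
    method="exact" inverts the null distribution of the ratio of quadratic
    forms; "normal" uses the moment-based z approximation; "permutation"
    permutes residuals.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    if n <= p + 2:
        raise ValueError("too few observations for the residual Moran test")
    Ws = weights.symmetrized()
    c = n / Ws.sum()
    I_obs, expected, e, MWM = _residual_moran_parts(X, y, Ws)

    if method == "exact":
        try:
            p_greater = _exact_p_greater(I_obs, MWM, X, c)
        except Exception:  # integration failure: fall back per contract
            warnings.warn("exact Moran integration failed; falling back to permutation")
            return moran_residual_test(
                X, y, weights, method="permutation", alternative=alternative,
                n_permutations=n_permutations, rng=rng,
            )
    elif method == "normal":
        nu = n - p
        tr1 = np.trace(MWM)
        tr2 = np.trace(MWM @ MWM)
        mean_I = c * tr1 / nu
        var_I = c**2 * (2.0 * (nu * tr2 - tr1**2)) / (nu**2 * (nu + 2.0))
        z = (I_obs - mean_I) / np.sqrt(var_I)
        from scipy import stats

        p_greater = float(stats.norm.sf(z))
    elif method == "permutation":
        # Freedman-Lane randomization: permute the residuals, then residualize
        # the permuted vector on X again so the null statistic sees the same
        # hat-matrix projection as the observed one
        rng = rng if rng is not None else np.random.default_rng()
        Q, _ = np.linalg.qr(X)
        perms = np.argsort(rng.random((n_permutations, n)), axis=1)
        E = e[perms]
        E = E - (E @ Q) @ Q.T
        num = np.einsum("pi,ij,pj->p", E, Ws, E)
        I_perm = c * num / np.einsum("pi,pi->p", E, E)
        p_greater = float((1 + np.sum(I_perm >= I_obs)) / (n_permutations + 1))
    else:
        raise ValueError(f"unknown method {method!r}")

    if alternative == "greater":
        p_val = p_greater
    elif alternative == "two_sided":
        p_val = float(min(1.0, 2.0 * min(p_greater, 1.0 - p_greater)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return MoranTestResult(I_obs, expected, p_val, method, alternative)


def _exact_p_greater(I_obs: float, MWM: np.ndarray, X: np.ndarray, c: float) -> float:
    """P(I >= I_obs) for residual Moran's I, exact under Gaussian errors."""
    n, p = X.shape
    Q, _ = np.linalg.qr(X)
    # L = M (c Ws - I_obs I) M = c*MWM - I_obs*M ; eigenvalues on span(M)
    M = np.eye(n) - Q @ Q.T
    L = c * MWM - I_obs * M
    lam = np.linalg.eigvalsh((L + L.T) / 2.0)
    return _imhof_upper_tail(lam)


def mem_eigenvectors(
    weights: SpatialWeights, eigenvalue_ratio_floor: float = 0.01
) -> EigenvectorFilter:
    """Moran eigenvector maps: eigenvectors of C Ws C, C = I - 11'/n.

    Returns the candidate basis restricted to positive eigenvalues with
    lambda/lambda_max >= ``eigenvalue_ratio_floor`` (drops numerical-noise
    vectors), sorted by descending eigenvalue.  The leading vector maximizes
    Moran's I among unit vectors orthogonal to the constant vector.
    """
    Ws = weights.symmetrized()
    n = weights.n
    row_mean = Ws.mean(axis=0)
    centred = Ws - row_mean[None, :] - row_mean[:, None] + Ws.mean()
    lam, vec = np.linalg.eigh((centred + centred.T) / 2.0)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    lam_max = lam[0] if lam.size else 0.0
    keep = (lam > 0) & (lam >= eigenvalue_ratio_floor * max(lam_max, 0.0))
    return EigenvectorFilter(vec[:, keep], tuple(float(v) for v in lam[keep]))


def select_spatial_filter(
    X: np.ndarray,
    y: np.ndarray,
    weights: SpatialWeights,
    alpha: float = 0.05,
    q_max: int | None = None,
    candidates: EigenvectorFilter | None = None,
) -> EigenvectorFilter:
    """Forward selection of a Moran-eigenvector spatial filter.

    At each step, adds the candidate that maximizes the exact residual-Moran
    p-value (one-sided, positive autocorrelation) of y on [X, filter], subject
    to not increasing the residual autocorrelation |I - E0[I]| (deviation from
    the null expectation, which is negative for residual Moran's I); stops
    when the residual p >= alpha, q_max is hit, or no candidate improves.
    Tie-break: eigenvalue rank.  If alpha cannot be reached the best filter
    found is returned with ``converged=False``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    cand = candidates if candidates is not None else mem_eigenvectors(weights)
    if q_max is None:
        q_max = cand.q
    selected: list[int] = []
    p_path: list[float] = []
    current = moran_residual_test(X, y, weights, method="exact")
    while len(selected) < q_max and current.p_value < alpha:
        best_j, best_test = None, None
        for j in range(cand.q):  # eigenvalue-rank order -> deterministic tie-break
            if j in selected:
                continue
            Xj = np.column_stack([X, cand.basis[:, selected + [j]]])
            if Xj.shape[0] <= Xj.shape[1] + 2:
                break
            test = moran_residual_test(Xj, y, weights, method="exact")
            if abs(test.I - test.expected_I) > abs(current.I - current.expected_I) + 1e-12:
                continue
            if best_test is None or test.p_value > best_test.p_value:
                best_j, best_test = j, test
        if best_j is None or best_test.p_value <= current.p_value:
            break
        selected.append(best_j)
        current = best_test
        p_path.append(current.p_value)
    basis = cand.basis[:, selected] if selected else np.empty((len(y), 0))
    if basis.size:
        basis, _ = np.linalg.qr(basis)  # re-orthonormalize selected columns
    return EigenvectorFilter(
        basis,
        tuple(cand.eigenvalues[j] for j in selected),
        tuple(selected),
        tuple(p_path),
        converged=current.p_value >= alpha,
    )
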