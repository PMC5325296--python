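"""Spatial-autocorrelation diagnostics for model residuals.

Moran's I with k-nearest-neighbour row-standardised weights tests GLM
residuals for spatial structure; multiple regression on distance
matrices (MRM, Mantel-style permutation inference) does the same for
the multivariate DistLM residual structure.  Under no autocorrelation
the expectation of Moran's I is -1/(n-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distlm import DistanceMatrix

__all__ = ["SpatialWeights", "knn_weights", "morans_i", "MoranResult", "mrm", "MrmResult"]


@dataclass
class SpatialWeights:
    """Row-standardised spatial weights (zero diagonal, possibly asymmetric)."""

    w: np.ndarray
    site_ids: list[str]
    k: int

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if np.any(np.diag(w) != 0):
            raise ValueError("weights diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        self.w = w


def knn_weights(coords: np.ndarray, k: int = 2, site_ids: list[str] | None = None) -> SpatialWeights:
    """k-nearest-neighbour binary weights, row-standardised.

    Euclidean distances; distance ties are broken by site order (stable
    sort), with a warning on exactly duplicated coordinates.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1 = {k + 1} sites")
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    if np.any(d[~np.eye(n, dtype=bool)] == 0):
        import warnings

        warnings.warn("duplicate coordinates: neighbour ties broken by site order")
    w = np.zeros((n, n))
    for i in range(n):
        order = np.argsort(d[i], kind="stable")
        neighbours = [j for j in order if j != i][:k]
        w[i, neighbours] = 1.0 / k
    ids = site_ids or [str(i) for i in range(n)]
    return SpatialWeights(w, ids, k)


@dataclass
class MoranResult:
    i_stat: float
    expected: float  # -1/(n-1)
    p_value: float
    n_perm: int
    seed: int
    alternative: str


def _moran_stat(x: np.ndarray, w: np.ndarray) -> float:
    z = x - x.mean()
    return float(x.size / w.sum() * (z @ w @ z) / (z @ z))


def morans_i(
    x: np.ndarray,
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> MoranResult:
    """Moran's I of a residual vector with a permutation test.

    I = (n / sum w) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z centred x.
    The permutation null shuffles x over sites; ``alternative`` is
    'greater' (positive autocorrelation, the default), 'less', or
    'two-sided' (deviation from the permutation expectation).
    """
    x = np.asarray(x, dtype=float)
    if np.all(x == x[0]):
        raise ValueError("Moran's I undefined for a constant vector")
    w = weights.w
    n = x.size
    i_obs = _moran_stat(x, w)
    rng = np.random.default_rng(seed)
    perms = np.array([_moran_stat(x[rng.permutation(n)], w) for _ in range(n_perm)])
    if alternative == "greater":
        exceed = np.sum(perms >= i_obs - 1e-12)
    elif alternative == "less":
        exceed = np.sum(perms <= i_obs + 1e-12)
    elif alternative == "two-sided":
        centre = perms.mean()
        exceed = np.sum(np.abs(perms - centre) >= abs(i_obs - centre) - 1e-12)
    else:
        raise ValueError("alternative must be 'greater', 'less' or 'two-sided'")
    return MoranResult(
        i_stat=i_obs,
        expected=-1.0 / (n - 1),
        p_value=(exceed + 1) / (n_perm + 1),
        n_perm=n_perm,
        seed=seed,
        alternative=alternative,
    )


@dataclass
class MrmResult:
    coefficients: pd.Series
    coef_p: pd.Series
    r_squared: float
    f_stat: float
    overall_p: float
    n_perm: int
    seed: int


def mrm(
    d_response: DistanceMatrix,
    d_predictors: list[DistanceMatrix],
    n_perm: int = 999,
    seed: int = 0,
    predictor_names: list[str] | None = None,
) -> MrmResult:
    """Multiple regression on distance matrices.

    OLS of the response matrix's lower triangle on the predictors' lower
    triangles; inference permutes rows/columns of the *response* matrix
    only, comparing |coefficient| (per predictor) and R^2 (overall)
    against the permutation distribution.
    """
    n = len(d_response.site_ids)
    if n < 4:
        raise ValueError("MRM needs at least 4 sites")
    for dp in d_predictors:
        if len(dp.site_ids) != n:
            raise ValueError("predictor distance matrix has mismatched sites")
    names = predictor_names or [dp.provenance or f"d{i}" for i, dp in enumerate(d_predictors)]
    iu = np.triu_indices(n, k=1)
    Xcols = [dp.values.to_numpy()[iu] for dp in d_predictors]
    X = np.column_stack([np.ones(len(Xcols[0]))] + Xcols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular predictor-matrix design")
    resp_full = d_response.values.to_numpy()

    def fit(yvec: np.ndarray) -> tuple[np.ndarray, float, float]:
        beta, *_ = np.linalg.lstsq(X, yvec, rcond=None)
        resid = yvec - X @ beta
        sst = np.sum((yvec - yvec.mean()) ** 2)
        ssr = np.sum(resid**2)
        r2 = 1.0 - ssr / sst if sst > 0 else 0.0
        m = X.shape[1] - 1
        dfr = len(yvec) - X.shape[1]
        f = (sst - ssr) / m / (ssr / dfr) if ssr > 0 and dfr > 0 else np.inf
        return beta, r2, f

    y_obs = resp_full[iu]
    beta_obs, r2_obs, f_obs = fit(y_obs)

    rng = np.random.default_rng(seed)
    exceed_coef = np.zeros(len(names))
    exceed_r2 = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y_b = resp_full[np.ix_(perm, perm)][iu]
        beta_b, r2_b, _ = fit(y_b)
        exceed_coef += np.abs(beta_b[1:]) >= np.abs(beta_obs[1:]) - 1e-12
        if r2_b >= r2_obs - 1e-12:
            exceed_r2 += 1
    coef_p = (exceed_coef + 1) / (n_perm + 1)
    return MrmResult(
        coefficients=pd.Series(beta_obs[1:], index=names),
        coef_p=pd.Series(coef_p, index=names),
        r_squared=float(r2_obs),
        f_stat=float(f_obs),
        overall_p=(exceed_r2 + 1) / (n_perm + 1),
        n_perm=n_perm,
        seed=seed,
    )
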