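"""Distance-based linear models (DistLM).

Relates a site-by-site resemblance matrix to landscape predictors by
partitioning the total variation of the Gower-centered inner-product
matrix G around the hat matrix of the predictor design:

    pseudo-F = [tr(H G H) / m] / [tr((I-H) G (I-H)) / (n - m - 1)]

with significance from permuting site labels (rows and columns of G
simultaneously).  On Euclidean distances of a univariate response this
reduces exactly to the classical regression/ANOVA F.  Model selection
("BEST") scores every non-empty predictor subset with the
residual-sum-of-squares AICc

    AICc = n log(SS_res / n) + 2v + 2v(v+1)/(n - v - 1),   v = m + 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beta import SimilarityMatrix
from .glm import akaike_weights

__all__ = [
    "DistanceMatrix",
    "distance_from_similarity",
    "gower_center",
    "distlm_fit",
    "distlm_sequential",
    "distlm_best",
    "DistlmResult",
]


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarities with zero diagonal and provenance."""

    values: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if not np.allclose(arr, arr.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if np.any(arr < -1e-9):
            raise ValueError("distances must be non-negative")
        np.fill_diagonal(arr, 0.0)
        self.values = pd.DataFrame(arr, index=self.values.index, columns=self.values.index)

    @property
    def site_ids(self) -> list[str]:
        return list(self.values.index)

    def condensed(self) -> np.ndarray:
        arr = self.values.to_numpy()
        iu = np.triu_indices(arr.shape[0], k=1)
        return arr[iu]


def distance_from_similarity(s: SimilarityMatrix, sqrt_transform: bool = False) -> DistanceMatrix:
    """d = 100 - s (percent scale); optional sqrt for Euclidean embeddability."""
    d = 100.0 - s.values.to_numpy(dtype=float)
    if sqrt_transform:
        d = np.sqrt(d)
    prov = f"100-{s.index_name}" + ("(sqrt)" if sqrt_transform else "")
    return DistanceMatrix(pd.DataFrame(d, index=s.site_ids, columns=s.site_ids), prov)


def euclidean_distance_matrix(y: np.ndarray, labels: list[str] | None = None) -> DistanceMatrix:
    """Euclidean distances of a (possibly univariate) data matrix, for oracles."""
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    d = np.sqrt(((y[:, None, :] - y[None, :, :]) ** 2).sum(axis=2))
    labels = labels or [str(i) for i in range(y.shape[0])]
    return DistanceMatrix(pd.DataFrame(d, index=labels, columns=labels), "euclidean")


def gower_center(d: DistanceMatrix) -> np.ndarray:
    """Gower's centered inner-product matrix G = J (-d^2/2) J, J = I - 11'/n.

    For Euclidean distances of univariate y, tr(G) equals the total sum
    of squares of y; row sums of G are zero by construction.
    """
    arr = d.values.to_numpy(dtype=float)
    a = -0.5 * arr**2
    n = arr.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(X: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(X)
    return q @ q.T


@dataclass
class DistlmResult:
    predictors: tuple[str, ...]
    pseudo_f: float
    p_value: float | None
    explained_prop: float
    aicc: float
    df_model: int
    df_resid: int
    n_perm: int
    seed: int | None


def _design_matrix(X: pd.DataFrame) -> np.ndarray:
    arr = X.to_numpy(dtype=float)
    design = np.column_stack([np.ones(arr.shape[0]), arr])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("singular design: collinear predictor columns")
    return design


def _fit_stats(G: np.ndarray, design: np.ndarray) -> tuple[float, float, float, float]:
    """(pseudo_F, explained proportion, SS_res, AICc) for one design."""
    n = G.shape[0]
    m = design.shape[1] - 1
    if n <= m + 1:
        raise ValueError("need n sites > number of predictors + 1")
    H = _hat(design)
    I = np.eye(n)
    ss_total = np.trace(G)
    if ss_total <= 1e-12:
        raise ValueError("degenerate resemblance matrix: tr(G) = 0")
    ss_model = float(np.trace(H @ G @ H))
    ss_res = float(np.trace((I - H) @ G @ (I - H)))
    f = (ss_model / m) / (ss_res / (n - m - 1))
    v = m + 1
    # non-Euclidean resemblances can drive the residual trace negative
    # (negative eigenvalues of G); AICc is undefined there
    if ss_res > 0:
        aicc_val = n * np.log(ss_res / n) + 2 * v + 2 * v * (v + 1) / (n - v - 1)
    else:
        aicc_val = float("nan")
    return f, ss_model / ss_total, ss_res, aicc_val


def distlm_fit(
    G: np.ndarray,
    X: pd.DataFrame,
    n_perm: int = 9999,
    seed: int | None = 0,
) -> DistlmResult:
    """Marginal DistLM of a Gower-centered matrix on predictor columns.

    The permutation P-value shuffles site labels (simultaneous row/column
    permutation of G) under the full null, with the +1 correction.
    ``n_perm=0`` skips the test (P reported as None).
    """
    design = _design_matrix(X)
    n = G.shape[0]
    m = design.shape[1] - 1
    f_obs, prop, _, aicc_val = _fit_stats(G, design)
    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            f_b, _, _, _ = _fit_stats(G[np.ix_(perm, perm)], design)
            if f_b >= f_obs - 1e-12:
                exceed += 1
        p = (exceed + 1) / (n_perm + 1)
    return DistlmResult(
        predictors=tuple(X.columns),
        pseudo_f=f_obs,
        p_value=p,
        explained_prop=prop,
        aicc=aicc_val,
        df_model=m,
        df_resid=n - m - 1,
        n_perm=n_perm,
        seed=seed,
    )


def distlm_sequential(
    G: np.ndarray,
    X: pd.DataFrame,
    order: list[str],
    n_perm: int = 9999,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Sequential (conditional) tests adding predictors in the given order.

    The test for each added predictor uses the pseudo-F of its marginal
    gain over the model so far; P-values permute the residuals of the
    reduced model (Freedman-Lane on the Gower-centered matrix).
    """
    rng = np.random.default_rng(seed)
    n = G.shape[0]
    I = np.eye(n)
    rows = []
    fitted: list[str] = []
    for name in order:
        design_red = _design_matrix(X[fitted]) if fitted else np.ones((n, 1))
        design_full = _design_matrix(X[fitted + [name]])
        H0, H1 = _hat(design_red), _hat(design_full)
        m_full = design_full.shape[1] - 1
        ss_gain = float(np.trace(H1 @ G @ H1) - np.trace(H0 @ G @ H0))
        ss_res = float(np.trace((I - H1) @ G @ (I - H1)))
        f_obs = ss_gain / (ss_res / (n - m_full - 1))
        G_res = (I - H0) @ G @ (I - H0)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Gp = G_res[np.ix_(perm, perm)]
            ss_gain_b = float(np.trace(H1 @ Gp @ H1) - np.trace(H0 @ Gp @ H0))
            ss_res_b = float(np.trace((I - H1) @ Gp @ (I - H1)))
            f_b = ss_gain_b / (ss_res_b / (n - m_full - 1))
            if f_b >= f_obs - 1e-12:
                exceed += 1
        fitted.append(name)
        _, prop, _, aicc_val = _fit_stats(G, design_full)
        rows.append(
            {
                "added": name,
                "pseudo_f": f_obs,
                "df": 1,
                "p": (exceed + 1) / (n_perm + 1),
                "aicc": aicc_val,
                "cum_explained_prop": prop,
            }
        )
    return pd.DataFrame(rows).set_index("added")


def distlm_best(
    G: np.ndarray,
    X: pd.DataFrame,
    n_perm: int = 0,
    seed: int | None = 0,
) -> pd.DataFrame:
    """BEST selection: score all non-empty predictor subsets by AICc.

    Returns the ranked table with delta and Akaike weights (shared
    exp(-delta/2) normalisation); singular subsets are flagged and
    excluded from the weights.  Permutation tests are optional (marginal
    P per subset when ``n_perm > 0``).
    """
    candidates = list(X.columns)
    if len(candidates) > 12:
        raise ValueError("BEST enumeration capped at 12 candidates")
    rows = []
    for r in range(1, len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            try:
                res = distlm_fit(G, X[list(subset)], n_perm=n_perm, seed=seed)
            except ValueError as exc:
                rows.append(
                    {
                        "predictors": subset,
                        "pseudo_f": np.nan,
                        "p": np.nan,
                        "explained_prop": np.nan,
                        "aicc": np.nan,
                        "note": str(exc),
                    }
                )
                continue
            rows.append(
                {
                    "predictors": subset,
                    "pseudo_f": res.pseudo_f,
                    "p": res.p_value if res.p_value is not None else np.nan,
                    "explained_prop": res.explained_prop,
                    "aicc": res.aicc,
                    "note": "",
                }
            )
    df = pd.DataFrame(rows)
    ok = df["aicc"].notna()
    df = pd.concat([df[ok].sort_values("aicc"), df[~ok]]).reset_index(drop=True)
    df["delta"] = df["aicc"] - df.loc[df["aicc"].notna(), "aicc"].min()
    w = np.full(len(df), np.nan)
    w[df["aicc"].notna().to_numpy()] = akaike_weights(df.loc[df["aicc"].notna(), "aicc"].to_numpy())
    df["weight"] = w
    return df


def distlm_importance(best_table: pd.DataFrame) -> pd.Series:
    """Sum of Akaike weights over subsets containing each predictor."""
    ok = best_table[best_table["weight"].notna()]
    names = sorted({p for row in ok["predictors"] for p in row})
    return pd.Series(
        {
            name: float(ok.loc[[name in row for row in ok["predictors"]], "weight"].sum())
            for name in names
        }
    ).sort_values(ascending=False)
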