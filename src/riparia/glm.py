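"""GLMs with AICc all-subsets model selection and multi-model averaging.

Responses are regressed on screened landscape predictors with a Gaussian
(identity link) or Poisson (log link) GLM.  Candidate models are all
2^p predictor subsets including the intercept-only model; each is scored
with AICc (or qAICc for overdispersed counts), ranked, and summarised
through Akaike weights: the 95% confidence set, per-predictor importance
(sum of weights over containing models), and model-averaged coefficients
with unconditional variance.

Parameter-count convention: the Gaussian family counts the residual
variance as an estimated parameter (k = p_coefficients + 1), which makes
AICc values comparable with R's ``AICc`` conventions; Poisson counts the
regression coefficients only.  qAICc adds one parameter for the
estimated overdispersion c-hat.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "GlmFit",
    "fit_glm",
    "aicc",
    "qaicc",
    "all_subsets",
    "ModelSelectionTable",
    "confidence_set",
    "importance_and_average",
    "AveragedEstimate",
    "explained_deviance",
    "akaike_weights",
]

FAMILIES = ("gaussian", "poisson")


@dataclass
class GlmFit:
    """A fitted GLM with the quantities model selection needs."""

    family: str
    predictor_names: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    statistics: pd.Series  # t (Gaussian) or Z (Poisson) per coefficient
    pvalues: pd.Series
    llf: float
    deviance: float
    null_deviance: float
    n: int
    k: int  # estimated parameters incl. intercept (+ variance for Gaussian)
    df_resid: int
    fitted: np.ndarray
    residuals: np.ndarray  # response residuals (Gaussian) / deviance residuals (Poisson)
    pearson_chi2: float

    @property
    def stat_name(self) -> str:
        return "t" if self.family == "gaussian" else "z"


def _design(X: pd.DataFrame | np.ndarray | None, n: int) -> tuple[np.ndarray, tuple[str, ...]]:
    if X is None or (hasattr(X, "shape") and X.shape[1] == 0):
        return np.ones((n, 1)), ()
    if isinstance(X, pd.DataFrame):
        names = tuple(str(c) for c in X.columns)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        names = tuple(f"x{i}" for i in range(arr.shape[1]))
    return np.column_stack([np.ones(arr.shape[0]), arr]), names


def fit_glm(
    y: Sequence[float] | np.ndarray | pd.Series,
    X: pd.DataFrame | np.ndarray | None,
    family: str = "gaussian",
) -> GlmFit:
    """Fit y ~ intercept + X under a Gaussian or Poisson GLM.

    Gaussian fits use ordinary least squares (the exact ML solution) and
    report t statistics on n - p degrees of freedom; Poisson fits use
    iteratively reweighted least squares and report Wald Z statistics.
    """
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}")
    y = np.asarray(y, dtype=float)
    n = y.size
    design, names = _design(X, n)
    p = design.shape[1]
    if n <= p:
        raise ValueError(f"n = {n} observations cannot identify {p} coefficients")
    rank = np.linalg.matrix_rank(design)
    if rank < p:
        raise ValueError("singular design: collinear predictor columns")
    labels = ("intercept",) + names

    if family == "gaussian":
        res = sm.OLS(y, design).fit()
        deviance = float(res.ssr)
        null_dev = float(np.sum((y - y.mean()) ** 2))
        resid = y - res.fittedvalues
        pearson = deviance
        fit = GlmFit(
            family="gaussian",
            predictor_names=names,
            params=pd.Series(res.params, index=labels),
            bse=pd.Series(res.bse, index=labels),
            statistics=pd.Series(res.tvalues, index=labels),
            pvalues=pd.Series(res.pvalues, index=labels),
            llf=float(res.llf),
            deviance=deviance,
            null_deviance=null_dev,
            n=n,
            k=p + 1,  # + residual variance
            df_resid=int(res.df_resid),
            fitted=np.asarray(res.fittedvalues),
            residuals=np.asarray(resid),
            pearson_chi2=pearson,
        )
    else:
        if np.any(y < 0) or not np.allclose(y, np.round(y)):
            raise ValueError("Poisson family requires non-negative integer y")
        model = sm.GLM(y, design, family=sm.families.Poisson())
        res = model.fit(tol=1e-8, maxiter=100)
        if not res.converged:
            raise RuntimeError(f"Poisson IRLS did not converge in {res.fit_history['iteration']} iterations")
        fit = GlmFit(
            family="poisson",
            predictor_names=names,
            params=pd.Series(res.params, index=labels),
            bse=pd.Series(res.bse, index=labels),
            statistics=pd.Series(res.tvalues, index=labels),  # Wald z for GLM
            pvalues=pd.Series(res.pvalues, index=labels),
            llf=float(res.llf),
            deviance=float(res.deviance),
            null_deviance=float(res.null_deviance),
            n=n,
            k=p,
            df_resid=int(res.df_resid),
            fitted=np.asarray(res.fittedvalues),
            residuals=np.asarray(res.resid_deviance),
            pearson_chi2=float(res.pearson_chi2),
        )
    return fit


def aicc(fit: GlmFit) -> float:
    """AICc = -2 log L + 2k + 2k(k+1)/(n - k - 1)."""
    n, k = fit.n, fit.k
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n - k - 1 = {n - k - 1} <= 0")
    return -2.0 * fit.llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def qaicc(fit: GlmFit, c_hat: float) -> float:
    """Quasi-likelihood AICc with overdispersion c-hat counted as a parameter.

    qAICc = -2 log L / c_hat + 2k' + 2k'(k'+1)/(n - k' - 1), k' = k + 1.
    c_hat below 1 is floored at 1 (no underdispersion correction).
    """
    c = max(float(c_hat), 1.0)
    k = fit.k + 1
    n = fit.n
    if n - k - 1 <= 0:
        raise ValueError(f"qAICc undefined: n - k' - 1 = {n - k - 1} <= 0")
    return -2.0 * fit.llf / c + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def explained_deviance(fit: GlmFit) -> float:
    """D^2 = 1 - deviance / null deviance, in percent."""
    if fit.null_deviance <= 0:
        raise ValueError("explained deviance undefined: null deviance is 0")
    return 100.0 * (1.0 - fit.deviance / fit.null_deviance)


def akaike_weights(criteria: Sequence[float]) -> np.ndarray:
    """exp(-delta/2) weights normalised to 1; invariant to constant shifts."""
    c = np.asarray(criteria, dtype=float)
    delta = c - c.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class ModelSelectionTable:
    """Ranked all-subsets candidate models for one response.

    ``table`` rows are sorted ascending by the criterion, with columns
    ``predictors`` (tuple), ``criterion`` (AICc or qAICc), ``delta``,
    ``weight``, ``cum_weight``, ``k`` and ``d2_pct``; ``fits`` holds the
    corresponding GlmFit objects in the same order.
    """

    table: pd.DataFrame
    fits: list[GlmFit]
    criterion_name: str
    family: str
    c_hat: float | None = None
    failures: list[tuple[tuple[str, ...], str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["predictors"] = ["+".join(p) if p else "(intercept)" for p in out["predictors"]]
        return out


def all_subsets(
    y: Sequence[float] | np.ndarray | pd.Series,
    X: pd.DataFrame,
    family: str = "gaussian",
    use_qaicc: bool | None = None,
) -> ModelSelectionTable:
    """Fit and rank every predictor subset (2^p models, incl. intercept-only).

    For the Poisson family, ``use_qaicc`` defaults to True and c-hat is
    the Pearson chi^2 / df of the global (all-predictor) model.
    """
    candidates = list(X.columns)
    if len(candidates) > 12:
        raise ValueError("all-subsets enumeration capped at 12 candidates")
    if use_qaicc is None:
        use_qaicc = family == "poisson"
    c_hat = None
    if use_qaicc:
        global_fit = fit_glm(y, X, family=family)
        c_hat = max(global_fit.pearson_chi2 / global_fit.df_resid, 1.0)

    rows, fits, failures = [], [], []
    for r in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            try:
                fit = fit_glm(y, X[list(subset)] if subset else None, family=family)
                crit = qaicc(fit, c_hat) if use_qaicc else aicc(fit)
            except (ValueError, RuntimeError) as exc:
                failures.append((subset, str(exc)))
                warnings.warn(f"model {subset or '(intercept)'} failed: {exc}")
                continue
            rows.append(
                {
                    "predictors": subset,
                    "criterion": crit,
                    "k": fit.k + (1 if use_qaicc else 0),
                    "d2_pct": explained_deviance(fit) if fit.null_deviance > 0 else np.nan,
                }
            )
            fits.append(fit)

    df = pd.DataFrame(rows)
    order = np.argsort(df["criterion"].to_numpy(), kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    fits = [fits[i] for i in order]
    df["delta"] = df["criterion"] - df["criterion"].iloc[0]
    df["weight"] = akaike_weights(df["criterion"].to_numpy())
    df["cum_weight"] = df["weight"].cumsum()
    name = "qAICc" if use_qaicc else "AICc"
    return ModelSelectionTable(df, fits, name, family, c_hat, failures)


def confidence_set(t: ModelSelectionTable, mass: float = 0.95) -> dict:
    """Smallest prefix of ranked models whose cumulative weight exceeds mass.

    Also reports the delta < 2 set of essentially equivalent models.
    """
    cum = t.table["cum_weight"].to_numpy()
    n_models = int(np.searchsorted(cum, mass, side="right") + 1)
    n_models = min(n_models, len(cum))
    delta2 = t.table.index[t.table["delta"] < 2.0].tolist()
    return {
        "confidence_set": t.table.iloc[:n_models],
        "n_models": n_models,
        "delta2_set": t.table.loc[delta2],
    }


@dataclass
class AveragedEstimate:
    predictor: str
    importance: float  # sum of Akaike weights over containing models
    beta_avg: float
    unconditional_variance: float
    n_models: int


def importance_and_average(t: ModelSelectionTable, predictor: str) -> AveragedEstimate:
    """Predictor importance and conditional model-averaged coefficient.

    Importance is the sum of Akaike weights of the models containing the
    predictor.  The averaged coefficient and its unconditional variance
    follow the standard multi-model estimator on the containing subset,
    with weights renormalised over that subset:

        beta_bar = sum_i w'_i beta_i
        var_u    = [ sum_i w'_i sqrt(var(beta_i) + (beta_i - beta_bar)^2) ]^2
    """
    contains = [predictor in row for row in t.table["predictors"]]
    if not any(contains):
        return AveragedEstimate(predictor, 0.0, float("nan"), float("nan"), 0)
    w = t.table["weight"].to_numpy()[contains]
    betas = np.array([fit.params[predictor] for fit, c in zip(t.fits, contains) if c])
    ses = np.array([fit.bse[predictor] for fit, c in zip(t.fits, contains) if c])
    importance = float(w.sum())
    w_norm = w / w.sum()
    beta_bar = float(w_norm @ betas)
    se_u = float(w_norm @ np.sqrt(ses**2 + (betas - beta_bar) ** 2))
    return AveragedEstimate(predictor, importance, beta_bar, se_u**2, int(np.sum(contains)))


def multimodel_summary(t: ModelSelectionTable) -> pd.DataFrame:
    """Importance and averaged estimates for every candidate predictor."""
    names = sorted({p for row in t.table["predictors"] for p in row})
    rows = []
    for name in names:
        est = importance_and_average(t, name)
        rows.append(
            {
                "predictor": est.predictor,
                "importance": est.importance,
                "beta_avg": est.beta_avg,
                "unconditional_variance": est.unconditional_variance,
                "n_models": est.n_models,
            }
        )
    return pd.DataFrame(rows).set_index("predictor").sort_values("importance", ascending=False)
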