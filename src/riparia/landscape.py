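"""Landscape configuration metrics and predictor collinearity screening.

The remnant shape index SI = P / (2 sqrt(pi A)) measures departure from
circular compactness (a circle scores exactly 1); remnant width is the
arithmetic mean of perpendicular stream-to-edge distances.  Before any
regression modelling, predictors are screened with pairwise Spearman
correlations (keeping one variable per correlated set) and then with
variance inflation factors.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import LandscapeTable

__all__ = [
    "shape_index",
    "remnant_width",
    "spearman_screen",
    "vif_filter",
    "ScreenResult",
]


def shape_index(perimeter: float, area: float) -> float:
    """Patch shape index SI = P / (2 * sqrt(pi * A)).

    SI is 1.0 for a perfect circle and grows with boundary complexity;
    it is invariant to uniform rescaling of the patch (P -> cP, A -> c^2 A).
    """
    if perimeter <= 0 or area <= 0:
        raise ValueError("perimeter and area must be positive")
    return perimeter / (2.0 * math.sqrt(math.pi * area))


def remnant_width(distances: Sequence[float]) -> float:
    """Mean remnant width from perpendicular stream-to-edge distances (m)."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one width measurement")
    if np.any(d <= 0):
        raise ValueError("width measurements must be positive")
    return float(d.mean())


@dataclass
class ScreenResult:
    """Outcome of a collinearity screen.

    ``dropped`` maps each removed predictor to the retained partner (for the
    Spearman screen) or to ``"vif"`` and the offending VIF value; ``pairs``
    is the full pairwise table (predictor pair, rho, P, decision).
    """

    retained: list[str]
    dropped: dict[str, tuple[str, float]] = field(default_factory=dict)
    pairs: pd.DataFrame | None = None
    vif: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"predictor": p, "decision": "retained"} for p in self.retained]
        rows += [
            {"predictor": p, "decision": "dropped", "partner": why[0], "value": why[1]}
            for p, why in self.dropped.items()
        ]
        return pd.DataFrame(rows).set_index("predictor")


_EXACT_N_MAX = 7  # full permutation enumeration up to 7! = 5040 orderings


def spearman_rho_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    P-value: exact two-sided permutation P when n <= 7 (all n! orderings of
    one variable), otherwise the t-distribution approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= _EXACT_N_MAX:
        perms = np.array(list(itertools.permutations(range(n))))
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt((rxc**2).sum() * (ryc**2).sum())
        rhos = (ryc[perms] @ rxc) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        _, p = stats.spearmanr(x, y)
        p = float(p)
    return rho, p


def spearman_screen(
    t: LandscapeTable,
    predictors: Sequence[str],
    threshold: float = 0.05,
    keep_priority: Sequence[str] | None = None,
    use_p: bool = True,
) -> ScreenResult:
    """Drop predictors significantly rank-correlated with a higher-priority one.

    For each correlated pair (|rho| significant at ``threshold`` when
    ``use_p``, else |rho| >= ``threshold``), the predictor earlier in
    ``keep_priority`` is retained and the other dropped, greedily in
    priority order.  Constant predictors (undefined rho) are dropped.
    """
    X = t.predictors(predictors)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 sites for a correlation screen")
    names = list(predictors)
    priority = list(keep_priority) if keep_priority is not None else names
    order = sorted(names, key=lambda p: priority.index(p) if p in priority else len(priority))

    rows = []
    rho_mat: dict[tuple[str, str], tuple[float, float]] = {}
    for a, b in itertools.combinations(names, 2):
        rho, p = spearman_rho_p(X[a].to_numpy(), X[b].to_numpy())
        rho_mat[(a, b)] = rho_mat[(b, a)] = (rho, p)
        rows.append({"var_a": a, "var_b": b, "rho": rho, "p": p})

    dropped: dict[str, tuple[str, float]] = {}
    for name in names:
        if X[name].nunique() <= 1:
            dropped[name] = ("constant", float("nan"))
    retained: list[str] = []
    for name in order:
        if name in dropped:
            continue
        conflict = None
        for kept in retained:
            rho, p = rho_mat[(name, kept)]
            flagged = (p < threshold) if use_p else (abs(rho) >= threshold)
            if flagged:
                conflict = (kept, rho)
                break
        if conflict is None:
            retained.append(name)
        else:
            dropped[name] = conflict
    retained = [n for n in names if n in retained]  # restore input order

    pairs = pd.DataFrame(rows)
    if not pairs.empty:
        pairs["decision"] = [
            "dropped" if (r.var_a in dropped or r.var_b in dropped) else "kept"
            for r in pairs.itertuples()
        ]
    return ScreenResult(retained=retained, dropped=dropped, pairs=pairs)


def _vif_values(X: pd.DataFrame) -> dict[str, float]:
    from statsmodels.stats.outliers_influence import variance_inflation_factor
    import statsmodels.api as sm

    Xc = sm.add_constant(X.astype(float), has_constant="add")
    out = {}
    for i, name in enumerate(X.columns):
        with np.errstate(divide="ignore", invalid="ignore"):
            v = variance_inflation_factor(Xc.to_numpy(), i + 1)
        out[name] = float(v) if np.isfinite(v) else float("inf")
    return out


def vif_filter(
    t: LandscapeTable,
    predictors: Sequence[str],
    cutoff: float = 10.0,
) -> ScreenResult:
    """Iteratively drop the largest-VIF predictor until all VIF < cutoff.

    Perfectly collinear predictors show infinite VIF and are removed
    first (ties broken by column order).
    """
    X = t.predictors(predictors)
    if t.n_sites <= len(predictors) + 1:
        raise ValueError("need n sites > number of predictors + 1 for VIF")
    current = list(predictors)
    dropped: dict[str, tuple[str, float]] = {}
    vifs: dict[str, float] = {}
    while len(current) >= 2:
        vifs = _vif_values(X[current])
        worst = max(current, key=lambda n: vifs[n])
        if vifs[worst] < cutoff:
            break
        dropped[worst] = ("vif", vifs[worst])
        current.remove(worst)
    if len(current) == 1:
        vifs = {current[0]: 1.0}
    return ScreenResult(retained=current, dropped=dropped, vif=vifs)
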