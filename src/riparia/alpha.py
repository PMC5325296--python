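"""Alpha diversity: sample coverage, Hill numbers, rank-abundance profiles.

Diversity is measured on occurrence (incidence-frequency) vectors: the
abundance surrogate for species *i* at a site is the number of litter
samples in which it occurred.  Inventory completeness uses the
singleton/doubleton sample-coverage estimator

    C_n = (1 - (f1/n) * [(n-1) f1 / ((n-1) f1 + 2 f2)]) * 100

and diversity uses Hill numbers ``qD = (sum_i p_i^q)^(1/(1-q))`` with
relative frequencies ``p_i = y_i / n``: q=0 is species richness, q=1 the
exponential of Shannon entropy, q=2 the inverse Simpson concentration.
Confidence intervals come from a seeded multinomial bootstrap of the
occurrence vector at fixed n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CommunityMatrix, IncidenceVector, pool_incidence

__all__ = [
    "sample_coverage",
    "hill_number",
    "hill_ci",
    "rank_abundance",
    "alpha_summary",
    "CoverageEstimate",
    "HillEstimate",
    "RankAbundanceProfile",
]


@dataclass(frozen=True)
class CoverageEstimate:
    c_hat: float  # percent, in [0, 100]
    n: int
    f1: int
    f2: int


@dataclass(frozen=True)
class HillEstimate:
    q: int
    d: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


@dataclass(frozen=True)
class RankAbundanceProfile:
    species: tuple[str, ...]
    proportions: np.ndarray
    above_threshold: np.ndarray  # boolean mask, proportion >= min_prop
    min_prop: float


def sample_coverage(v: IncidenceVector) -> CoverageEstimate:
    """Estimated sample completeness (percent) from singletons and doubletons.

    With no singletons the inventory is judged complete (100%).  The
    degenerate all-singleton sample (f1 = n) yields 0: nothing recaptured,
    so coverage is indeterminate and reported as the pessimistic limit.
    """
    n, f1, f2 = v.n, v.f1, v.f2
    if n < 1:
        raise ValueError("coverage undefined for an empty sample (n = 0)")
    if f1 == 0:
        return CoverageEstimate(100.0, n, f1, f2)
    denom = (n - 1) * f1 + 2 * f2
    if denom == 0:
        # only possible when n == 1 and f1 == 1: a single occurrence
        warnings.warn("degenerate sample (n = 1): coverage reported as 0")
        return CoverageEstimate(0.0, n, f1, f2)
    bracket = (n - 1) * f1 / denom
    c = (1.0 - (f1 / n) * bracket) * 100.0
    if f1 == n and f2 == 0:
        warnings.warn("all species are singletons: coverage estimate is 0")
    return CoverageEstimate(float(c), n, f1, f2)


def hill_number(v: IncidenceVector, q: int) -> float:
    """Hill number of order q in {0, 1, 2} on relative occurrence frequencies."""
    if q not in (0, 1, 2):
        raise ValueError("q must be 0, 1 or 2")
    y = v.counts[v.counts > 0].astype(float)
    if y.size == 0:
        raise ValueError("diversity undefined for an empty sample (n = 0)")
    if q == 0:
        return float(y.size)
    p = y / y.sum()
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(1.0 / np.sum(p**2))


def hill_ci(
    v: IncidenceVector,
    q: int,
    n_boot: int = 1000,
    seed: int = 0,
) -> HillEstimate:
    """Percentile bootstrap 95% CI for a Hill number.

    Resamples n occurrences from the observed relative frequencies
    (multinomial at fixed n), recomputes qD per replicate, and takes the
    2.5/97.5 percentiles.  Deterministic under a fixed seed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    d = hill_number(v, q)
    y = v.counts[v.counts > 0].astype(float)
    n = int(y.sum())
    p = y / n
    rng = np.random.default_rng(seed)
    boot = rng.multinomial(n, p, size=n_boot).astype(float)
    if q == 0:
        ds = (boot > 0).sum(axis=1).astype(float)
    else:
        props = boot / n
        if q == 1:
            with np.errstate(divide="ignore", invalid="ignore"):
                plogp = np.where(props > 0, props * np.log(np.where(props > 0, props, 1.0)), 0.0)
            ds = np.exp(-plogp.sum(axis=1))
        else:
            ds = 1.0 / (props**2).sum(axis=1)
    lo, hi = np.percentile(ds, [2.5, 97.5])
    return HillEstimate(q, d, float(lo), float(hi), n_boot, seed)


def rank_abundance(v: IncidenceVector, min_prop: float = 0.05) -> RankAbundanceProfile:
    """Whittaker profile: proportional occurrence by decreasing rank.

    Species at or above ``min_prop`` relative abundance are flagged (the
    conventional cut for display is 5%).
    """
    if v.n < 1:
        raise ValueError("rank-abundance undefined for an empty sample")
    mask = v.counts > 0
    y = v.counts[mask].astype(float)
    names = (
        np.asarray(v.species_ids)[mask]
        if v.species_ids
        else np.array([f"sp{i}" for i in range(mask.sum())])
    )
    order = np.argsort(-y, kind="stable")
    props = y[order] / y.sum()
    return RankAbundanceProfile(
        species=tuple(names[order]),
        proportions=props,
        above_threshold=props >= min_prop,
        min_prop=min_prop,
    )


def alpha_summary(
    m: CommunityMatrix,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-site alpha table: n, f1, f2, coverage, and qD (q = 0, 1, 2) with CIs."""
    m.require_nonzero_sites()
    rows = []
    for i, site in enumerate(m.site_ids):
        v = m.incidence(site)
        cov = sample_coverage(v)
        row = {"site": site, "n": v.n, "f1": v.f1, "f2": v.f2, "coverage_pct": cov.c_hat}
        for q in (0, 1, 2):
            est = hill_ci(v, q, n_boot=n_boot, seed=seed + i)
            row[f"D{q}"] = est.d
            row[f"D{q}_lo"] = est.ci_low
            row[f"D{q}_hi"] = est.ci_high
        rows.append(row)
    return pd.DataFrame(rows).set_index("site")
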