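"""End-to-end orchestration: from input (or synthetic) tables to a ReportBundle.

Stage order: load/validate -> per-site alpha table -> similarity matrices
(three indices) -> UPGMA + SIMPROF per index -> collinearity screen ->
univariate GLMs per response x predictor -> all-subsets multi-model
selection per response -> DistLM marginal + BEST per index -> Moran's I
and MRM spatial diagnostics on residuals.  A stage failure marks the
bundle and skips dependent stages.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alpha import alpha_summary
from .beta import INDEX_DIVERSITY_ORDER, similarity_matrix, simprof, upgma
from .distlm import (
    distance_from_similarity,
    distlm_best,
    distlm_fit,
    distlm_importance,
    gower_center,
)
from .glm import all_subsets, confidence_set, fit_glm, multimodel_summary, aicc, qaicc
from .io import (
    CommunityMatrix,
    LandscapeTable,
    ReportBundle,
    read_community_matrix,
    read_landscape_table,
)
from .landscape import spearman_screen, vif_filter
from .spatial import knn_weights, morans_i, mrm
from .synth import SynthConfig, generate_community, generate_landscape

logger = logging.getLogger("riparia")

#: Default retention priority for the collinearity screen: the focal
#: habitat cover first, then native forest, then configuration metrics,
#: then the remaining covers in reporting order.
DEFAULT_KEEP_PRIORITY = (
    "riparian",
    "tmcf",
    "shape_index",
    "width_m",
    "scrub_fallow",
    "reforested_pinus",
    "tree_crops",
    "shrub_crops",
    "pasture_isolated_trees",
    "cattle_pasture",
    "human_settlements",
)

DEFAULT_PREDICTORS = DEFAULT_KEEP_PRIORITY

DEFAULT_INDICES = ("jaccard", "sorensen_quantitative", "morisita_horn")


@dataclass
class PipelineConfig:
    """Everything one analysis run needs, serialisable to/from YAML."""

    seed: int = 0
    community_path: str | None = None
    landscape_path: str | None = None
    synthetic: dict | None = None  # SynthConfig fields; used when paths absent
    samples_per_site: int = 20
    indices: tuple[str, ...] = DEFAULT_INDICES
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    keep_priority: tuple[str, ...] = DEFAULT_KEEP_PRIORITY
    screen_p_threshold: float = 0.05
    vif_cutoff: float = 10.0
    n_boot: int = 1000
    n_perm_mean: int = 1000
    n_perm_null: int = 999
    n_perm_distlm: int = 9999
    n_perm_spatial: int = 999
    alpha: float = 0.05
    knn_k: int = 2
    output_dir: str | None = None

    def __post_init__(self) -> None:
        unknown = [i for i in self.indices if i not in INDEX_DIVERSITY_ORDER]
        if unknown:
            raise ValueError(
                f"unknown similarity indices {unknown}; "
                f"choose from {sorted(INDEX_DIVERSITY_ORDER)}"
            )
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.community_path is None and self.landscape_path is None and self.synthetic is None:
            self.synthetic = {}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        for key in ("indices", "predictors", "keep_priority"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def load_inputs(self) -> tuple[CommunityMatrix, LandscapeTable]:
        if self.community_path and self.landscape_path:
            m = read_community_matrix(self.community_path, self.samples_per_site)
            t = read_landscape_table(self.landscape_path)
            return m, t.aligned_to(m)
        synth = dict(self.synthetic or {})
        synth.setdefault("seed", self.seed)
        synth.setdefault("samples_per_site", self.samples_per_site)
        cfg = SynthConfig(**synth)
        t = generate_landscape(cfg)
        m = generate_community(t, cfg)
        return m, t


#: The four responses modelled per the study design: total occurrences
#: (Poisson counts, qAICc) and the three Hill numbers (Gaussian, AICc).
RESPONSES = (
    ("abundance", "poisson"),
    ("D0", "gaussian"),
    ("D1", "gaussian"),
    ("D2", "gaussian"),
)


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    bundle = ReportBundle()
    t0 = time.time()
    try:
        m, t = cfg.load_inputs()
    except Exception as exc:
        bundle.mark_failed("load", str(exc))
        return bundle
    bundle.metadata = {
        "seed": cfg.seed,
        "version": __version__,
        "config": asdict(cfg),
        "community_digest": m.digest(),
        "landscape_digest": t.digest(),
        "n_sites": m.n_sites,
        "n_species": len(m.species_ids),
    }

    # --- alpha ---
    try:
        alpha_tab = alpha_summary(m, n_boot=cfg.n_boot, seed=cfg.seed)
        alpha_tab["abundance"] = m.site_totals()
        bundle.add("alpha_summary", alpha_tab)
    except Exception as exc:
        bundle.mark_failed("alpha", str(exc))
        return bundle
    logger.info("alpha stage: %d sites (%.1fs)", len(alpha_tab), time.time() - t0)

    # --- beta: similarity, UPGMA, SIMPROF ---
    sims = {}
    for index in cfg.indices:
        try:
            s = similarity_matrix(m, index)
            sims[index] = s
            bundle.add(f"similarity_{index}", s.values)
            tree = upgma(s)
            bundle.newick[f"upgma_{index}"] = tree.to_newick()
            sp = simprof(
                m,
                index,
                alpha=cfg.alpha,
                n_perm_mean=cfg.n_perm_mean,
                n_perm_null=cfg.n_perm_null,
                seed=cfg.seed,
            )
            bundle.add(f"simprof_{index}", sp.to_frame())
            bundle.metadata[f"simprof_{index}_partition"] = [list(b) for b in sp.partition]
        except Exception as exc:
            bundle.mark_failed(f"beta_{index}", str(exc))

    # --- predictor screen ---
    predictors = [p for p in cfg.predictors if p in t.table.columns]
    try:
        screen = spearman_screen(
            t, predictors, threshold=cfg.screen_p_threshold, keep_priority=cfg.keep_priority
        )
        bundle.add("spearman_pairs", screen.pairs)
        retained = screen.retained
        if len(retained) >= 2 and t.n_sites > len(retained) + 1:
            vif = vif_filter(t, retained, cutoff=cfg.vif_cutoff)
            retained = vif.retained
            bundle.add(
                "vif",
                pd.DataFrame({"vif": pd.Series(vif.vif)}),
            )
        bundle.metadata["retained_predictors"] = retained
    except Exception as exc:
        bundle.mark_failed("screen", str(exc))
        return bundle
    X = t.predictors(retained)

    # --- GLM stage ---
    uni_rows = []
    for response, family in RESPONSES:
        y = alpha_tab[response if response != "abundance" else "abundance"]
        for pred in retained:
            try:
                fit = fit_glm(y, X[[pred]], family=family)
                crit = (
                    qaicc(fit, max(fit.pearson_chi2 / fit.df_resid, 1.0))
                    if family == "poisson"
                    else aicc(fit)
                )
                uni_rows.append(
                    {
                        "response": response,
                        "predictor": pred,
                        "family": family,
                        "statistic": fit.statistics[pred],
                        "stat_name": fit.stat_name,
                        "df": fit.df_resid,
                        "p": fit.pvalues[pred],
                        "criterion": crit,
                    }
                )
            except Exception as exc:
                bundle.mark_failed(f"glm_uni_{response}_{pred}", str(exc))
    bundle.add("glm_univariate", pd.DataFrame(uni_rows))

    residuals: dict[str, np.ndarray] = {}
    for response, family in RESPONSES:
        y = alpha_tab[response if response != "abundance" else "abundance"]
        try:
            sel = all_subsets(y, X, family=family)
            bundle.add(f"model_selection_{response}", sel.to_frame())
            bundle.add(f"importance_{response}", multimodel_summary(sel))
            cs = confidence_set(sel)
            bundle.metadata[f"confidence_set_{response}"] = int(cs["n_models"])
            best_preds = list(sel.table["predictors"].iloc[0])
            best_fit = sel.fits[0] if best_preds == list(sel.fits[0].predictor_names) else None
            fit_for_resid = best_fit or fit_glm(y, X[best_preds] if best_preds else None, family)
            residuals[response] = fit_for_resid.residuals
        except Exception as exc:
            bundle.mark_failed(f"glm_multi_{response}", str(exc))

    # --- DistLM stage ---
    for index, s in sims.items():
        try:
            G = gower_center(distance_from_similarity(s))
            marg_rows = []
            for pred in retained:
                res = distlm_fit(G, X[[pred]], n_perm=cfg.n_perm_distlm, seed=cfg.seed)
                marg_rows.append(
                    {
                        "predictor": pred,
                        "pseudo_f": res.pseudo_f,
                        "df": res.df_model,
                        "p": res.p_value,
                        "explained_prop": res.explained_prop,
                        "aicc": res.aicc,
                    }
                )
            bundle.add(f"distlm_marginal_{index}", pd.DataFrame(marg_rows).set_index("predictor"))
            best = distlm_best(G, X)
            bundle.add(f"distlm_best_{index}", best.assign(
                predictors=["+".join(p) for p in best["predictors"]]
            ))
            bundle.add(
                f"distlm_importance_{index}",
                distlm_importance(best).to_frame("importance"),
            )
        except Exception as exc:
            bundle.mark_failed(f"distlm_{index}", str(exc))

    # --- spatial diagnostics ---
    try:
        coords = t.coords()
        w = knn_weights(coords, k=cfg.knn_k, site_ids=t.site_ids)
        sp_rows = []
        for response, resid in residuals.items():
            mr = morans_i(resid, w, n_perm=cfg.n_perm_spatial, seed=cfg.seed)
            sp_rows.append(
                {
                    "test": f"moran_{response}",
                    "statistic": mr.i_stat,
                    "expected": mr.expected,
                    "p": mr.p_value,
                }
            )
        from .distlm import euclidean_distance_matrix

        d_geo = euclidean_distance_matrix(coords, t.site_ids)
        for index, s in sims.items():
            d_resp = distance_from_similarity(s)
            d_preds = [euclidean_distance_matrix(X[[p]].to_numpy(), t.site_ids) for p in retained]
            res = mrm(
                d_resp,
                d_preds + [d_geo],
                n_perm=cfg.n_perm_spatial,
                seed=cfg.seed,
                predictor_names=retained + ["geographic"],
            )
            sp_rows.append(
                {
                    "test": f"mrm_{index}_geographic",
                    "statistic": res.coefficients["geographic"],
                    "expected": 0.0,
                    "p": res.coef_p["geographic"],
                }
            )
        bundle.add("spatial_diagnostics", pd.DataFrame(sp_rows).set_index("test"))
    except Exception as exc:
        bundle.mark_failed("spatial", str(exc))

    bundle.metadata["wall_time_s"] = round(time.time() - t0, 2)
    if cfg.output_dir:
        bundle.write(cfg.output_dir)
    return bundle
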