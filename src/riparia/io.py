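"""Core data containers and delimited-table I/O.

The pipeline revolves around two tables: a site-by-species occurrence
matrix (``CommunityMatrix``) whose entries count the litter samples in
which each species was detected at each site, and a site-by-predictor
landscape table (``LandscapeTable``) holding land-cover percentages and
remnant-configuration metrics.  Both are thin, validated wrappers around
pandas DataFrames; all readers accept comma- or tab-delimited text,
auto-detected from the file extension.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("riparia")

#: Land-cover classes recorded for each 200-m landscape buffer, in
#: conventional reporting order.  Percentages over these nine classes
#: must sum to 100 per site.
COVER_CLASSES: tuple[str, ...] = (
    "tmcf",
    "riparian",
    "scrub_fallow",
    "reforested_pinus",
    "tree_crops",
    "shrub_crops",
    "pasture_isolated_trees",
    "cattle_pasture",
    "human_settlements",
)

#: Configuration metrics of the focal remnant.
CONFIG_METRICS: tuple[str, ...] = ("shape_index", "width_m")

COORD_COLUMNS: tuple[str, ...] = ("x", "y")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _delimiter_for(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    return "\t" if suffix in {".tsv", ".tab", ".txt"} else ","


@dataclass(frozen=True)
class IncidenceVector:
    """Occurrence counts for one sampling unit (a site, or pooled sites).

    ``n`` is the total number of occurrences, ``f1``/``f2`` the singleton
    and doubleton species counts; all three are derived from ``counts``
    and never stored independently.
    """

    counts: np.ndarray
    species_ids: tuple[str, ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ValidationError("incidence vector must be one-dimensional")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValidationError("occurrence counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValidationError("occurrence counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def f1(self) -> int:
        return int(np.sum(self.counts == 1))

    @property
    def f2(self) -> int:
        return int(np.sum(self.counts == 2))

    @property
    def s_obs(self) -> int:
        return int(np.sum(self.counts > 0))


@dataclass
class CommunityMatrix:
    """Sites x species occurrence counts, bounded by the per-site sampling effort.

    Parameters
    ----------
    counts
        DataFrame indexed by site label with species labels as columns;
        integer occurrence counts (number of litter samples, out of
        ``samples_per_site``, in which the species was detected).
    samples_per_site
        Sampling effort per site; every count must lie in
        ``[0, samples_per_site]``.  The study design this layout mirrors
        used 20 litter samples per site (10 wet + 10 dry season).
    """

    counts: pd.DataFrame
    samples_per_site: int = 20

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            raise ValidationError("duplicate site labels")
        if df.columns.has_duplicates:
            raise ValidationError("duplicate species labels")
        if df.shape[0] < 2 or df.shape[1] < 1:
            raise ValidationError("need at least 2 sites and 1 species")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("non-numeric occurrence counts")
        if not np.allclose(arr, np.round(arr)):
            bad = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise ValidationError(
                f"non-integer count at site {df.index[bad[0]]!r}, "
                f"species {df.columns[bad[1]]!r}"
            )
        arr = arr.astype(np.int64)
        if (arr < 0).any():
            raise ValidationError("negative occurrence counts")
        if (arr > self.samples_per_site).any():
            bad = np.argwhere(arr > self.samples_per_site)[0]
            raise ValidationError(
                f"count exceeds samples_per_site={self.samples_per_site} at "
                f"site {df.index[bad[0]]!r}, species {df.columns[bad[1]]!r}"
            )
        self.counts = pd.DataFrame(arr, index=df.index.astype(str), columns=df.columns.astype(str))
        empty = self.counts.columns[self.counts.sum(axis=0) == 0]
        if len(empty):
            logger.info("retaining %d all-zero species: %s", len(empty), list(empty))

    @property
    def site_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    def site_totals(self) -> pd.Series:
        """Total occurrences per site (the study's 'abundance' response)."""
        return self.counts.sum(axis=1)

    def incidence(self, site: str) -> IncidenceVector:
        if site not in self.counts.index:
            raise KeyError(f"unknown site label {site!r}")
        return IncidenceVector(
            self.counts.loc[site].to_numpy(),
            species_ids=tuple(self.species_ids),
            label=site,
        )

    def require_nonzero_sites(self) -> None:
        """Reject sites with zero total occurrences (diversity is undefined there)."""
        zero = self.site_totals()[self.site_totals() == 0]
        if len(zero):
            raise ValidationError(f"sites with zero occurrences: {list(zero.index)}")

    def digest(self) -> str:
        payload = self.counts.to_csv().encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class LandscapeTable:
    """Sites x landscape predictors: cover percentages, configuration, coordinates.

    Cover percentages (one column per class in :data:`COVER_CLASSES`) must
    sum to 100 per site within ``cover_tolerance``; ``shape_index`` is the
    dimensionless perimeter-to-area compactness (>= 1 for simple shapes),
    ``width_m`` the mean remnant width in metres, and ``x``/``y`` planar
    site coordinates in metres.
    """

    table: pd.DataFrame
    cover_tolerance: float = 0.5

    def __post_init__(self) -> None:
        df = self.table
        if df.index.has_duplicates:
            raise ValidationError("duplicate site labels")
        missing = [c for c in COVER_CLASSES if c not in df.columns]
        if missing:
            raise ValidationError(f"missing cover columns: {missing}")
        covers = df[list(COVER_CLASSES)].to_numpy(dtype=float)
        if (covers < 0).any() or (covers > 100).any():
            raise ValidationError("cover percentages must lie in [0, 100]")
        sums = covers.sum(axis=1)
        bad = np.abs(sums - 100.0) > self.cover_tolerance
        if bad.any():
            sites = list(df.index[bad])
            raise ValidationError(
                f"cover percentages do not sum to 100 +/- {self.cover_tolerance} "
                f"for sites {sites} (sums: {sums[bad].round(3).tolist()})"
            )
        if "shape_index" in df.columns and (df["shape_index"] < 1 - 1e-9).any():
            raise ValidationError("shape_index must be >= 1")
        if "width_m" in df.columns and (df["width_m"] <= 0).any():
            raise ValidationError("width_m must be > 0")
        self.table = df.copy()
        self.table.index = self.table.index.astype(str)

    @property
    def site_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def n_sites(self) -> int:
        return self.table.shape[0]

    def predictors(self, names: Sequence[str]) -> pd.DataFrame:
        missing = [n for n in names if n not in self.table.columns]
        if missing:
            raise KeyError(f"unknown predictor columns: {missing}")
        return self.table[list(names)].astype(float)

    def coords(self) -> np.ndarray:
        missing = [c for c in COORD_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"missing coordinate columns: {missing}")
        return self.table[list(COORD_COLUMNS)].to_numpy(dtype=float)

    def aligned_to(self, m: CommunityMatrix) -> "LandscapeTable":
        """Reindex to a community matrix's sites, failing on mismatch."""
        missing = [s for s in m.site_ids if s not in self.table.index]
        if missing:
            raise ValidationError(f"landscape table lacks sites: {missing}")
        out = LandscapeTable.__new__(LandscapeTable)
        out.table = self.table.loc[m.site_ids].copy()
        out.cover_tolerance = self.cover_tolerance
        return out

    def digest(self) -> str:
        return hashlib.sha256(self.table.to_csv().encode()).hexdigest()[:12]


def read_community_matrix(
    path: str | Path,
    samples_per_site: int = 20,
    sites_as_rows: bool = True,
) -> CommunityMatrix:
    """Read a site-by-species occurrence table from CSV/TSV.

    ``sites_as_rows=False`` transposes on read, for the common supplementary
    layout with species as rows and site labels as the header.
    """
    df = pd.read_csv(path, sep=_delimiter_for(path), index_col=0)
    if not sites_as_rows:
        df = df.T
    try:
        return CommunityMatrix(df, samples_per_site=samples_per_site)
    except ValidationError:
        raise
    except (TypeError, ValueError) as exc:  # pragma: no cover - defensive
        raise ValidationError(f"failed to parse {path}: {exc}") from exc


def write_community_matrix(m: CommunityMatrix, path: str | Path) -> None:
    m.counts.to_csv(path, sep=_delimiter_for(path))


def read_landscape_table(path: str | Path, cover_tolerance: float = 0.5) -> LandscapeTable:
    df = pd.read_csv(path, sep=_delimiter_for(path), index_col=0)
    return LandscapeTable(df, cover_tolerance=cover_tolerance)


def write_landscape_table(t: LandscapeTable, path: str | Path) -> None:
    t.table.to_csv(path, sep=_delimiter_for(path))


def pool_incidence(m: CommunityMatrix, sites: Iterable[str] | None = None) -> IncidenceVector:
    """Pool occurrence counts over a subset of sites (default: all).

    Pooling sums counts per species, so it is associative: pooling
    {A, B} then C equals pooling {A, B, C} in one step.
    """
    if sites is None:
        chosen = m.site_ids
    else:
        chosen = list(sites)
        if not chosen:
            raise ValidationError("site subset must be non-empty")
        unknown = [s for s in chosen if s not in m.counts.index]
        if unknown:
            raise KeyError(f"unknown site labels: {unknown}")
    pooled = m.counts.loc[chosen].sum(axis=0).to_numpy()
    label = chosen[0] if len(chosen) == 1 else f"pooled[{len(chosen)}]"
    return IncidenceVector(pooled, species_ids=tuple(m.species_ids), label=label)


@dataclass
class ReportBundle:
    """Keyed collection of result tables plus run metadata.

    Every pipeline stage deposits its outputs here; :meth:`write` emits
    one CSV per table, Newick files for dendrograms, and a JSON metadata
    record (seed, permutation counts, input digests, configuration).
    """

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    newick: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    def add(self, key: str, table: pd.DataFrame) -> None:
        self.tables[key] = table

    def mark_failed(self, stage: str, reason: str) -> None:
        self.failures[stage] = reason
        logger.error("stage %s failed: %s", stage, reason)

    @property
    def ok(self) -> bool:
        return not self.failures

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for key, df in self.tables.items():
            df.to_csv(outdir / f"{key}.csv")
        for key, tree in self.newick.items():
            (outdir / f"{key}.nwk").write_text(tree + "\n", encoding="utf-8")
        meta = dict(self.metadata)
        if self.failures:
            meta["failures"] = self.failures
        (outdir / "metadata.json").write_text(
            json.dumps(meta, indent=2, default=str) + "\n", encoding="utf-8"
        )
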