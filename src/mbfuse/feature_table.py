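"""Feature tables: reading, filtering and normalizing -omics count matrices.

The :class:`FeatureTable` is the canonical container used throughout the
package — a samples x features matrix of non-negative values.  It holds
either 16S amplicon counts (integer reads per ASV) or quantified metabolite
concentrations.  This module implements the preprocessing applied to count
tables before any statistics are run:

* abundance/prevalence filtering — a feature is kept only if its total count
  reaches a fraction of the grand total (default 1%) *and* it is observed in
  a minimum fraction of samples (default 25%);
* cumulative sum scaling (CSS) — each sample is scaled by the sum of its
  counts up to a data-adaptive quantile, attenuating the influence of a few
  dominant taxa that distorts simple total-sum scaling;
* taxonomic aggregation (phylum / family / genus) and relative abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: taxonomic ranks in lineage order; aggregation is supported for a subset
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
AGGREGATION_RANKS = ("phylum", "family", "genus")

#: Greengenes-style rank prefixes accepted (and stripped) in lineage strings
_GG_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

UNASSIGNED = "Unassigned"


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Samples x features matrix of non-negative values.

    Parameters
    ----------
    data:
        DataFrame with sample IDs as the index and feature IDs as columns.
    feature_meta:
        Optional per-feature annotation (e.g. a taxonomy lineage string),
        indexed by feature ID.
    """

    data: pd.DataFrame
    feature_meta: pd.Series | None = None

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature IDs: {dups}")
        values = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("feature table contains non-finite values")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value at sample {df.index[i]!r}, "
                f"feature {df.columns[j]!r}"
            )
        if self.feature_meta is not None:
            missing = set(self.feature_meta.index) - set(df.columns)
            if missing:
                raise ValueError(
                    f"feature_meta annotates unknown features: {sorted(missing)[:5]}"
                )

    # -- basic accessors ----------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        """Dense samples x features array (float)."""
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy(self) -> "FeatureTable":
        meta = None if self.feature_meta is None else self.feature_meta.copy()
        return FeatureTable(self.data.copy(), meta)

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV, samples as rows, first column the sample ID."""
        self.data.to_csv(path, sep="\t", index_label="sample_id")

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.data.equals(other.data)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_table(path: str | Path, orientation: str = "samples") -> FeatureTable:
    """Read a TSV feature table.

    Parameters
    ----------
    path:
        TSV file; first column holds row IDs.  A dense BIOM-style dialect
        whose header line starts with ``#OTU ID`` is recognized and implies
        ``orientation="features"``.
    orientation:
        ``"samples"`` if rows are samples (canonical), ``"features"`` if
        rows are features (the table is transposed on read).
    """
    if orientation not in ("samples", "features"):
        raise ValueError(f"orientation must be 'samples' or 'features', got {orientation!r}")
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        second = fh.readline()
    skiprows = 0
    if first.startswith("#OTU ID"):
        orientation = "features"
    elif first.startswith("#") and second.startswith("#OTU ID"):
        # "# Constructed from biom file" banner line
        orientation = "features"
        skiprows = 1
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skiprows)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
    if len(non_numeric):
        raise ValueError(f"non-numeric columns in {path.name}: {list(non_numeric)[:5]}")
    if orientation == "features":
        df = df.T
    return FeatureTable(df)


def read_taxonomy(path: str | Path) -> pd.Series:
    """Read a 2-column TSV (feature_id, semicolon-delimited lineage)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["feature_id", "lineage"],
                     dtype=str, comment="#")
    if df["feature_id"].duplicated().any():
        raise ValueError("duplicate feature IDs in taxonomy file")
    return pd.Series(df["lineage"].values, index=df["feature_id"].values,
                     name="lineage")


def parse_lineage(lineage: str) -> dict[str, str]:
    """Split a semicolon-delimited lineage into a rank -> name mapping.

    Greengenes-style prefixes (``k__``, ``p__``, ...) are stripped; empty
    levels are dropped.  Un-prefixed lineages are assigned ranks positionally
    from kingdom downwards.
    """
    parts = [p.strip() for p in str(lineage).split(";")]
    out: dict[str, str] = {}
    prefixed = any(p[:3] in _GG_PREFIXES for p in parts if len(p) >= 3)
    for i, part in enumerate(parts):
        if prefixed:
            if len(part) >= 3 and part[:3] in _GG_PREFIXES:
                rank = RANKS[_GG_PREFIXES.index(part[:3])]
                name = part[3:].strip()
                if name:
                    out[rank] = name
        else:
            if part and i < len(RANKS):
                out[RANKS[i]] = part
    return out


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

class FilterResult(NamedTuple):
    table: FeatureTable
    removed: pd.DataFrame  # feature, total, prevalence, reason


def filter_features(table: FeatureTable,
                    min_total_fraction: float = 0.01,
                    min_prevalence: float = 0.25) -> FilterResult:
    """Remove rare features from a count table.

    A feature is retained iff its summed count across all samples is at
    least ``min_total_fraction`` of the grand total *and* it is nonzero in
    at least ``min_prevalence`` of the samples.  Both comparisons are
    inclusive (>=) at the boundary.  The sample set is unchanged.

    Returns
    -------
    FilterResult
        The filtered table plus a log DataFrame of the removed features.
    """
    X = table.values
    totals = X.sum(axis=0)
    grand = totals.sum()
    if grand <= 0:
        raise ValueError("cannot filter an all-zero table")
    prevalence = (X > 0).mean(axis=0)
    keep_total = totals >= min_total_fraction * grand
    keep_prev = prevalence >= min_prevalence
    keep = keep_total & keep_prev
    if not keep.any():
        raise ValueError(
            "filtering removed every feature "
            f"(min_total_fraction={min_total_fraction}, min_prevalence={min_prevalence})"
        )
    removed_idx = np.flatnonzero(~keep)
    reasons = []
    for j in removed_idx:
        r = []
        if not keep_total[j]:
            r.append("total")
        if not keep_prev[j]:
            r.append("prevalence")
        reasons.append("+".join(r))
    removed = pd.DataFrame({
        "feature": [table.feature_ids[j] for j in removed_idx],
        "total": totals[removed_idx],
        "prevalence": prevalence[removed_idx],
        "reason": reasons,
    })
    log.info("filter_features: removed %d of %d features", len(removed_idx), len(keep))
    meta = table.feature_meta
    kept_ids = [table.feature_ids[j] for j in np.flatnonzero(keep)]
    if meta is not None:
        meta = meta.reindex([f for f in kept_ids if f in meta.index])
    return FilterResult(FeatureTable(table.data.loc[:, kept_ids].copy(), meta), removed)


# ---------------------------------------------------------------------------
# cumulative sum scaling
# ---------------------------------------------------------------------------

#: default quantile grid scanned by :func:`css_reference_quantile`
CSS_QUANTILE_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))


def _sample_cumsum_at(counts_row: np.ndarray, level: float) -> float:
    """Sum of counts <= the ``level``-quantile of the row's nonzero counts."""
    nz = counts_row[counts_row > 0]
    q = np.quantile(nz, level)
    return float(counts_row[counts_row <= q].sum())


def css_reference_quantile(table: FeatureTable,
                           grid: Iterable[float] = CSS_QUANTILE_GRID,
                           threshold: float = 0.1) -> float:
    """Choose the data-adaptive CSS reference quantile.

    Scanning a fixed grid of quantile levels from low to high, the chosen
    level is the smallest one at which the median deviation of the
    per-sample cumulative sums from their across-sample reference (the
    median cumulative sum), relative to the median library size, first
    exceeds ``threshold``.  This deviation curve starts near zero (the
    counts below a low quantile are a negligible part of any library) and
    grows with the level, so the scan stops where the partial sums begin
    to diverge across samples — the point beyond which cumulative-sum
    scaling would no longer remove depth differences consistently.  If the
    criterion never triggers — e.g. all samples share the same count
    distribution — the conventional 0.5 is returned with a logged warning.
    """
    X = table.values
    if X.shape[0] < 2:
        raise ValueError("css_reference_quantile requires >= 2 samples")
    if (X.sum(axis=1) == 0).any():
        bad = table.sample_ids[int(np.argmin(X.sum(axis=1)))]
        raise ValueError(f"sample {bad!r} has all-zero counts")
    scale = np.median(X.sum(axis=1))
    for level in grid:
        cums = np.array([_sample_cumsum_at(row, level) for row in X])
        ref = np.median(cums)
        dev = np.median(np.abs(cums - ref)) / scale
        if dev > threshold:
            return float(level)
    log.warning("css_reference_quantile: stability criterion never triggered; "
                "falling back to 0.5")
    return 0.5


def css_normalize(table: FeatureTable,
                  quantile: float | None = None,
                  scale: float = 1000.0) -> FeatureTable:
    """Cumulative sum scaling normalization of a count table.

    Each sample's scaling factor is the sum of its counts that are <= its
    own empirical ``quantile`` of *nonzero* counts; every count is divided
    by that factor and multiplied by ``scale``.  Zeros stay zero.  When
    ``quantile`` is None the adaptive level from
    :func:`css_reference_quantile` is used.
    """
    if quantile is None:
        quantile = css_reference_quantile(table)
    if not 0 < quantile < 1:
        raise ValueError(f"quantile must be in (0, 1), got {quantile}")
    X = table.values
    if (X.sum(axis=1) == 0).any():
        bad = table.sample_ids[int(np.argmin(X.sum(axis=1)))]
        raise ValueError(f"sample {bad!r} has all-zero counts")
    factors = np.array([_sample_cumsum_at(row, quantile) for row in X])
    if (factors == 0).any():
        bad = table.sample_ids[int(np.argmin(factors))]
        raise ValueError(f"sample {bad!r} has a zero CSS scaling factor")
    out = X / factors[:, None] * scale
    df = pd.DataFrame(out, index=table.data.index, columns=table.data.columns)
    return FeatureTable(df, table.feature_meta)


def css_scaling_factors(table: FeatureTable, quantile: float) -> np.ndarray:
    """Per-sample CSS scaling factors (exposed for auditing)."""
    return np.array([_sample_cumsum_at(row, quantile) for row in table.values])


# ---------------------------------------------------------------------------
# aggregation / relative abundance
# ---------------------------------------------------------------------------

def aggregate_taxonomy(table: FeatureTable,
                       taxonomy: Mapping[str, str] | pd.Series,
                       rank: str) -> FeatureTable:
    """Sum features sharing a lineage at ``rank`` (phylum/family/genus).

    Features without a mapping, or whose lineage lacks the requested rank,
    are pooled under ``"Unassigned"``.  Per-sample totals are conserved
    exactly.
    """
    if rank not in AGGREGATION_RANKS:
        raise ValueError(f"rank must be one of {AGGREGATION_RANKS}, got {rank!r}")
    if isinstance(taxonomy, pd.Series):
        taxonomy = taxonomy.to_dict()
    depth = RANKS.index(rank)
    labels = []
    for fid in table.feature_ids:
        lineage = taxonomy.get(fid)
        if lineage is None:
            labels.append(UNASSIGNED)
            continue
        ranks = parse_lineage(lineage)
        if rank not in ranks:
            labels.append(UNASSIGNED)
            continue
        # label by the lineage truncated at the requested rank so that
        # identically-named genera in different families stay distinct
        path = [ranks[r] for r in RANKS[: depth + 1] if r in ranks]
        labels.append(";".join(path))
    grouped = table.data.T.groupby(pd.Index(labels, name=rank), sort=True).sum().T
    return FeatureTable(grouped)


def relative_abundance(table: FeatureTable) -> FeatureTable:
    """Scale each sample (row) to sum to 1."""
    X = table.values
    sums = X.sum(axis=1)
    if (sums == 0).any():
        bad = table.sample_ids[int(np.argmin(sums))]
        raise ValueError(f"sample {bad!r} has zero row sum")
    df = pd.DataFrame(X / sums[:, None], index=table.data.index,
                      columns=table.data.columns)
    return FeatureTable(df, table.feature_meta)
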