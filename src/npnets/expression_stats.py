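"""Single-cell and type-level descriptive expression statistics.

Peak expression (the ascending 99.9th-percentile single-cell value, the
"pFPKM" metric when computed on FPKM units), peak rank tables over a
gene universe, descending expression curves, detection fractions,
co-expression multiplicity counts, cross-area conservation
correlations, trimmed-mean type profiles, and within-subclass
coefficient-of-variation summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .datamodel import CellAnnotation, ExpressionMatrix, Taxonomy, ValidationError

DEFAULT_PEAK_QUANTILE = 0.999
DEFAULT_DETECTION_THRESHOLD = 1.0  # CPM; detection is strictly > threshold


# ---------------------------------------------------------------------------
# peak expression and rank tables


def peak_expression(m: ExpressionMatrix, gene: str,
                    quantile: float = DEFAULT_PEAK_QUANTILE) -> float:
    """Ascending nearest-rank percentile of a gene's single-cell values.

    Values are sorted ascending and the element at 1-based index
    ``ceil(quantile * n)`` (clamped to ``n``) is returned.  At the default
    0.999 this is the "peak" metric: robust to sporadic outliers yet close
    to the true maximum within even small expressing subsets.
    """
    values = m.gene_column(gene)
    return nearest_rank_quantile(values, quantile)


def nearest_rank_quantile(values: np.ndarray, quantile: float) -> float:
    n = values.size
    if n == 0:
        raise ValidationError("need at least one cell")
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    idx = min(max(math.ceil(quantile * n), 1), n)
    return float(np.sort(values, kind="stable")[idx - 1])


@dataclass
class PeakExpressionTable:
    """Per-gene peak value, percentile rank, absolute rank and detection.

    ``absolute_rank`` is 1 for the highest peak; ties are broken by
    gene-id lexicographic order so the table is deterministic.
    ``percentile_rank`` = 100·(1 − (rank−1)/N) over the N-gene universe.
    """

    table: pd.DataFrame  # index: gene; columns: peak_value, percentile_rank,
    #                       absolute_rank, detection_fraction

    def peak(self, gene: str) -> float:
        return float(self.table.loc[gene, "peak_value"])

    def percentile(self, gene: str) -> float:
        return float(self.table.loc[gene, "percentile_rank"])

    def rank(self, gene: str) -> int:
        return int(self.table.loc[gene, "absolute_rank"])


def peak_rank_table(m: ExpressionMatrix, gene_universe: list[str],
                    threshold: float = DEFAULT_DETECTION_THRESHOLD,
                    quantile: float = DEFAULT_PEAK_QUANTILE) -> PeakExpressionTable:
    """Rank peak expression over a reference gene universe."""
    if not gene_universe:
        raise ValidationError("empty gene universe")
    idx = m.gene_indices(gene_universe)
    sub = m.values[:, idx]
    n = sub.shape[0]
    pos = min(max(math.ceil(quantile * n), 1), n) - 1
    peaks = np.sort(sub, axis=0, kind="stable")[pos, :]
    det = (sub > threshold).mean(axis=0)
    order = sorted(range(len(gene_universe)),
                   key=lambda i: (-peaks[i], gene_universe[i]))
    ranks = np.empty(len(gene_universe), dtype=int)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    pct = 100.0 * (1.0 - (ranks - 1) / len(gene_universe))
    df = pd.DataFrame({
        "peak_value": peaks, "percentile_rank": pct,
        "absolute_rank": ranks, "detection_fraction": det,
    }, index=pd.Index(gene_universe, name="gene"))
    return PeakExpressionTable(df)


# ---------------------------------------------------------------------------
# expression curves, detection, co-expression


def expression_curves(m: ExpressionMatrix, genes: list[str],
                      mode: str = "per_gene") -> dict[str, pd.DataFrame]:
    """Descending single-cell expression curves on a population percentile axis.

    ``per_gene`` returns one curve per gene; ``max_over_set`` a single
    curve of per-cell maxima over the set.  The x-axis of a curve with n
    cells is ``100 * (rank - 0.5) / n``.
    """
    if not genes:
        raise ValidationError("empty gene set")
    idx = m.gene_indices(genes)
    n = m.n_cells
    x = 100.0 * (np.arange(1, n + 1) - 0.5) / n

    def curve(values: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame({
            "population_percentile": x,
            "value": np.sort(values, kind="stable")[::-1],
        })

    if mode == "per_gene":
        return {g: curve(m.values[:, i]) for g, i in zip(genes, idx)}
    if mode == "max_over_set":
        return {"max_over_set": curve(m.values[:, idx].max(axis=1))}
    raise ValueError(f"unknown mode {mode!r}")


def _group_mask(m: ExpressionMatrix, ann: CellAnnotation | None,
                group: dict | None) -> np.ndarray:
    mask = np.ones(m.n_cells, dtype=bool)
    if group:
        if ann is None:
            raise ValidationError("grouping requires a cell annotation")
        ann = ann.aligned_to(m)
        for col, val in group.items():
            mask &= (ann.table[col] == val).to_numpy()
    if not mask.any():
        raise ValidationError(f"empty cell group {group!r}")
    return mask


def detection_fraction(m: ExpressionMatrix, gene: str,
                       threshold: float = DEFAULT_DETECTION_THRESHOLD,
                       ann: CellAnnotation | None = None,
                       group: dict | None = None) -> float:
    """Fraction of (group) cells with expression strictly above threshold."""
    mask = _group_mask(m, ann, group)
    return float((m.gene_column(gene)[mask] > threshold).mean())


def coexpression_counts(m: ExpressionMatrix, gene_set: list[str],
                        threshold: float = DEFAULT_DETECTION_THRESHOLD,
                        ann: CellAnnotation | None = None,
                        group: dict | None = None):
    """Per-cell count of set genes detected, plus its histogram over 0..|set|."""
    if not gene_set:
        raise ValidationError("empty gene set")
    mask = _group_mask(m, ann, group)
    idx = m.gene_indices(gene_set)
    counts = (m.values[np.ix_(mask, idx)] > threshold).sum(axis=1)
    hist = np.bincount(counts, minlength=len(gene_set) + 1)
    return counts, hist


def cognate_pair_coexpression(m: ExpressionMatrix,
                              pairs: list[tuple[str, str]],
                              threshold: float = DEFAULT_DETECTION_THRESHOLD,
                              ann: CellAnnotation | None = None,
                              group: dict | None = None) -> pd.DataFrame:
    """Per cognate pair: fraction of cells expressing both members."""
    mask = _group_mask(m, ann, group)
    rows = []
    for g, h in pairs:
        a = m.gene_column(g)[mask] > threshold
        b = m.gene_column(h)[mask] > threshold
        rows.append({"npp_gene": g, "npgpcr_gene": h,
                     "fraction_both": float((a & b).mean()),
                     "fraction_npp": float(a.mean()),
                     "fraction_npgpcr": float(b.mean())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# conservation


def area_conservation(x: np.ndarray, y: np.ndarray,
                      method: str = "pearson") -> tuple[float, float]:
    """Correlation of a per-gene statistic between two areas.

    Returns (ρ, two-sided p).  Whether the correlation is Pearson or
    Spearman is a parameter; Pearson is the default.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("need equal-length 1-D vectors")
    if x.size < 3:
        raise ValidationError("need at least 3 genes")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero-variance vector: correlation undefined")
    if method == "pearson":
        r = sstats.pearsonr(x, y)
    elif method == "spearman":
        r = sstats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r.statistic), float(r.pvalue)


# ---------------------------------------------------------------------------
# type-level profiles


@dataclass
class TypeExpressionMatrix:
    """Genes × types profile matrix for one area (or pooled areas)."""

    values: np.ndarray  # (n_genes, n_types)
    gene_ids: list[str]
    type_ids: list[str]
    statistic: str  # "trimmed_mean_5pct" | "median" | "mean"
    area: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValidationError("type profiles must be non-negative")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    def gene_row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self._gene_index[gene]]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in type profile") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.type_ids)


def trimmed_mean(values: np.ndarray, trim: float = 0.05) -> float:
    """Symmetric trimmed mean; per-tail count = floor(trim * n).

    Falls back to the plain mean when trimming would leave nothing.
    """
    n = values.size
    k = int(trim * n)
    if n - 2 * k < 1:
        return float(values.mean())
    return float(np.sort(values, kind="stable")[k:n - k].mean())


def type_mean_expression(m: ExpressionMatrix, ann: CellAnnotation,
                         taxonomy: Taxonomy | None = None,
                         statistic: str = "trimmed_mean_5pct",
                         area: str | None = None,
                         genes: list[str] | None = None) -> TypeExpressionMatrix:
    """Per-type expression profiles (5%-trimmed mean by default).

    Types follow taxonomy leaf order when a taxonomy is given; types
    with no cells in the (area-restricted) data are omitted.
    """
    ann = ann.aligned_to(m)
    mask = np.ones(m.n_cells, dtype=bool)
    if area is not None:
        mask &= (ann.table["area"] == area).to_numpy()
    leaf_order = (taxonomy.leaf_names if taxonomy is not None
                  else sorted(ann.table.loc[mask, "leaf_type"].unique()))
    gene_ids = genes if genes is not None else m.gene_ids
    gidx = m.gene_indices(gene_ids)
    cols = []
    kept_types = []
    leaf_arr = ann.table["leaf_type"].to_numpy()
    for leaf in leaf_order:
        cell_mask = mask & (leaf_arr == leaf)
        if not cell_mask.any():
            continue
        sub = m.values[np.ix_(cell_mask, gidx)]
        if statistic == "trimmed_mean_5pct":
            col = np.apply_along_axis(trimmed_mean, 0, sub)
        elif statistic == "median":
            col = np.median(sub, axis=0)
        elif statistic == "mean":
            col = sub.mean(axis=0)
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
        cols.append(col)
        kept_types.append(leaf)
    if not cols:
        raise ValidationError("no types with cells in the requested area")
    return TypeExpressionMatrix(np.column_stack(cols), list(gene_ids),
                                kept_types, statistic, area)


# ---------------------------------------------------------------------------
# coefficient of variation across types, within subclasses


def cv_within_subclass(t: TypeExpressionMatrix, taxonomy: Taxonomy) -> pd.DataFrame:
    """Per gene: CV across types within each subclass, globally, and the ratio.

    CV uses the sample (n−1) standard deviation over type-level values.
    Subclasses containing a single type are excluded (their CV is
    trivially 0/undefined).  A zero-mean gene within a stratum yields a
    missing CV.  The returned tidy frame has one row per gene with
    columns ``cv_<subclass>``, ``cv_global`` and ``cv_ratio_mean`` (the
    mean over subclasses of within-subclass CV / global CV).
    """
    type_sub = {l: taxonomy.subclass_of(l) for l in t.type_ids}
    subclasses = [s for s in taxonomy.subclasses
                  if sum(v == s for v in type_sub.values()) >= 2]
    rows = []
    for gi, gene in enumerate(t.gene_ids):
        vals = t.values[gi]
        row: dict = {"gene": gene}
        ratios = []
        g_mean = vals.mean()
        cv_global = (float(vals.std(ddof=1) / g_mean)
                     if vals.size >= 2 and g_mean > 0 else np.nan)
        for s in subclasses:
            sv = np.array([vals[i] for i, l in enumerate(t.type_ids)
                           if type_sub[l] == s])
            mean = sv.mean()
            cv = float(sv.std(ddof=1) / mean) if mean > 0 else np.nan
            row[f"cv_{s}"] = cv
            if not np.isnan(cv) and cv_global and not np.isnan(cv_global):
                ratios.append(cv / cv_global)
        row["cv_global"] = cv_global
        row["cv_ratio_mean"] = float(np.mean(ratios)) if ratios else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")
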