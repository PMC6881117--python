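"""Type-level peptidergic coupling-matrix prediction.

For a cognate (precursor, receptor) pair the predicted coupling matrix
is the outer product of the precursor's type-expression profile (rows =
source types) and the receptor's profile (columns = target types), in
CPM·CPM units, displayed in log10.  Matrices pool to subclass level by
unweighted block means, and aggregate into Gi/o, Gs and Gq/11 channels
(log-scaled, per-pair max-normalized, summed by family, renormalized).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import Taxonomy, ValidationError
from .expression_stats import TypeExpressionMatrix
from .gene_selection import CognatePair

DEFAULT_LOG_FLOOR = 1e-2  # CPM·CPM floor before log10

GALPHA_FAMILIES = ("Gi/o", "Gs", "Gq/11")


@dataclass
class CouplingMatrix:
    """Rank-1 source-type × target-type coupling prediction for one pair."""

    pair: CognatePair
    area: str | None
    values: np.ndarray  # linear, CPM·CPM
    log_values: np.ndarray
    source_types: list[str]
    target_types: list[str]

    def to_frame(self, log: bool = False) -> pd.DataFrame:
        return pd.DataFrame(self.log_values if log else self.values,
                            index=self.source_types, columns=self.target_types)


def coupling_matrix(pair: CognatePair, t: TypeExpressionMatrix,
                    eps_log: float = DEFAULT_LOG_FLOOR) -> CouplingMatrix:
    """Outer product of the precursor row and receptor row of a profile."""
    u = t.gene_row(pair.npp_gene)
    v = t.gene_row(pair.npgpcr_gene)
    values = np.outer(u, v)
    log_values = np.log10(np.maximum(values, eps_log))
    return CouplingMatrix(pair, t.area, values, log_values,
                          list(t.type_ids), list(t.type_ids))


def pool_profile_by_subclass(t: TypeExpressionMatrix,
                             taxonomy: Taxonomy) -> TypeExpressionMatrix:
    """Unweighted mean of type columns within each subclass."""
    cols = []
    kept = []
    for s in taxonomy.subclasses:
        members = [i for i, l in enumerate(t.type_ids)
                   if taxonomy.subclass_of(l) == s]
        if not members:
            continue
        cols.append(t.values[:, members].mean(axis=1))
        kept.append(s)
    if not cols:
        raise ValidationError("no subclasses present in the profile")
    return TypeExpressionMatrix(np.column_stack(cols), list(t.gene_ids),
                                kept, t.statistic, t.area)


def pool_coupling_by_subclass(c: CouplingMatrix, taxonomy: Taxonomy,
                              eps_log: float = DEFAULT_LOG_FLOOR) -> CouplingMatrix:
    """Unweighted mean over each subclass × subclass block.

    For a rank-1 matrix this equals the outer product of the
    subclass-mean factor vectors exactly.
    """
    groups = []
    kept = []
    for s in taxonomy.subclasses:
        members = [i for i, l in enumerate(c.source_types)
                   if taxonomy.subclass_of(l) == s]
        if members:
            groups.append(members)
            kept.append(s)
    n = len(groups)
    pooled = np.empty((n, n))
    for i, gi in enumerate(groups):
        for j, gj in enumerate(groups):
            pooled[i, j] = c.values[np.ix_(gi, gj)].mean()
    return CouplingMatrix(c.pair, c.area, pooled,
                          np.log10(np.maximum(pooled, eps_log)), kept, kept)


@dataclass
class AggregateChannels:
    """Per-Gα-family aggregate coupling channels in [0, 1]."""

    area: str | None
    level: str  # "type" | "subclass"
    channels: dict[str, np.ndarray]
    type_ids: list[str]
    n_pairs: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fam, ch in self.channels.items():
            if ch.min() < -1e-12 or ch.max() > 1 + 1e-12:
                raise ValidationError(f"channel {fam} outside [0, 1]")


def aggregate_by_galpha(matrices: list[CouplingMatrix],
                        level: str = "type",
                        order: str = "log-normalize-sum") -> AggregateChannels:
    """Merge per-pair matrices into one channel per Gα family.

    ``log-normalize-sum`` (default): each pair's log matrix is shifted
    to min 0, scaled to max 1, summed within its family, and the family
    sum renormalized to [0, 1].  ``sum-log-normalize`` instead sums the
    linear matrices per family first, then log-scales and max-normalizes
    — an alternative reading of the aggregation recipe, kept available
    behind this flag.
    """
    import warnings

    if not matrices:
        raise ValidationError("no coupling matrices to aggregate")
    shape = matrices[0].values.shape
    type_ids = matrices[0].source_types
    area = matrices[0].area
    channels: dict[str, np.ndarray] = {}
    n_pairs: dict[str, int] = {}
    for fam in GALPHA_FAMILIES:
        members = [m for m in matrices if m.pair.galpha_family == fam]
        n_pairs[fam] = len(members)
        if not members:
            warnings.warn(f"no cognate pairs in family {fam}; all-zero channel")
            channels[fam] = np.zeros(shape)
            continue
        if order == "log-normalize-sum":
            acc = np.zeros(shape)
            for m in members:
                lv = m.log_values - m.log_values.min()
                peak = lv.max()
                acc += lv / peak if peak > 0 else lv
            peak = acc.max()
            channels[fam] = acc / peak if peak > 0 else acc
        elif order == "sum-log-normalize":
            lin = sum(m.values for m in members)
            lv = np.log10(np.maximum(lin, DEFAULT_LOG_FLOOR))
            lv = lv - lv.min()
            peak = lv.max()
            channels[fam] = lv / peak if peak > 0 else lv
        else:
            raise ValueError(f"unknown aggregation order {order!r}")
    return AggregateChannels(area, level, channels, list(type_ids), n_pairs)


def export_adjacency(c: CouplingMatrix, outdir) -> Path:
    """Write one deterministic CSV per pair per area (linear values)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    area = c.area or "all"
    path = outdir / f"{area}_{c.pair.npp_gene}__{c.pair.npgpcr_gene}.csv"
    c.to_frame().to_csv(path, float_format="%.6g")
    return path


def export_channels(agg: AggregateChannels, outdir) -> list[Path]:
    """Write one CSV per Gα family channel."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for fam, ch in agg.channels.items():
        safe = fam.replace("/", "")
        path = outdir / f"{agg.area or 'all'}_{agg.level}_{safe}.csv"
        pd.DataFrame(ch, index=agg.type_ids, columns=agg.type_ids).to_csv(
            path, float_format="%.6g")
        paths.append(path)
    return paths
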