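"""Selection of neuropeptide signaling gene sets and cognate pairs.

Reproduces the two-step logic behind the curated gene panels: a
candidate precursor gene is kept when (1) it is highly expressed at the
population peak (top-quintile peak percentile by default) and (2) at
least one cognate receptor gene is expressed locally; receptors are
kept when cognate to a retained precursor and locally expressed.  The
retained lists are mutually closed under the cognate relation, and the
resulting bipartite edges are the cognate pairs behind the predicted
coupling networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    CellAnnotation,
    ExpressionMatrix,
    NPGeneTable,
    ValidationError,
)
from .expression_stats import (
    PeakExpressionTable,
    TypeExpressionMatrix,
    type_mean_expression,
)

DEFAULT_MIN_MEDIAN_CPM = 10.0
DEFAULT_MIN_PEAK_PERCENTILE = 80.0  # top quintile
# receptor "locally expressed" criterion (deliberately permissive; the
# receptor panel spans peak percentiles down to ~40 and detection
# fractions down to ~0.5% of cells)
DEFAULT_RECEPTOR_MIN_DETECTION = 0.005
DEFAULT_RECEPTOR_MIN_PERCENTILE = 50.0


@dataclass
class CognatePair:
    """One directed precursor → receptor signaling channel."""

    npp_gene: str
    npgpcr_gene: str
    galpha_family: str
    fraction_of_type_pairs: float | None = None

    @property
    def symbol(self) -> str:
        return f"{self.npp_gene}->{self.npgpcr_gene}"


def screen_candidates_by_type_median(candidates: list[str],
                                     m: ExpressionMatrix,
                                     ann: CellAnnotation,
                                     taxonomy=None,
                                     min_median_cpm: float = DEFAULT_MIN_MEDIAN_CPM,
                                     ) -> list[str]:
    """Keep genes whose per-type median CPM exceeds the floor in ≥1 type."""
    profile = type_mean_expression(m, ann, taxonomy, statistic="median",
                                   genes=candidates)
    keep = []
    for g in candidates:
        if (profile.gene_row(g) > min_median_cpm).any():
            keep.append(g)
    return keep


def _receptor_expressed(gene: str, peaks: PeakExpressionTable,
                        min_detection: float,
                        min_percentile: float) -> bool:
    row = peaks.table.loc[gene]
    return (row["detection_fraction"] >= min_detection
            or row["percentile_rank"] >= min_percentile)


def peak_table_from_annotation(table: NPGeneTable) -> PeakExpressionTable:
    """Build a peak table from the summary columns of an annotation table.

    Uses each record's recorded peak value, transcriptome-wide
    percentile rank and detection fraction (``pct_cells`` is a
    percentage and is divided by 100).  Records missing a percentile are
    skipped; ``absolute_rank`` falls back to ordering by percentile when
    not recorded.
    """
    rows = {}
    for g, rec in table.records.items():
        if rec.pfpkm_percentile is None:
            continue
        rows[g] = {
            "peak_value": np.nan if rec.peak_fpkm is None else rec.peak_fpkm,
            "percentile_rank": rec.pfpkm_percentile,
            "absolute_rank": rec.pfpkm_rank,
            "detection_fraction": (
                np.nan if rec.pct_cells is None else rec.pct_cells / 100.0),
        }
    if not rows:
        raise ValidationError("no records with recorded peak percentile")
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene"
    missing = df["absolute_rank"].isna()
    if missing.any():
        fallback = (-df["percentile_rank"]).rank(method="first")
        df.loc[missing, "absolute_rank"] = fallback[missing]
    df["absolute_rank"] = df["absolute_rank"].astype(int)
    return PeakExpressionTable(df)


def select_np_genes(candidates: NPGeneTable, peaks: PeakExpressionTable,
                    min_peak_percentile: float = DEFAULT_MIN_PEAK_PERCENTILE,
                    receptor_min_detection: float = DEFAULT_RECEPTOR_MIN_DETECTION,
                    receptor_min_percentile: float = DEFAULT_RECEPTOR_MIN_PERCENTILE,
                    ) -> tuple[list[str], list[str]]:
    """Apply the two selection criteria and return (NPP list, NP-GPCR list).

    The output lists are closed under the cognate relation: every kept
    precursor has at least one kept cognate receptor and vice versa.
    Candidates missing from the peak table are skipped with a warning.
    """
    import warnings

    covered = set(peaks.table.index)
    npp_keep: list[str] = []
    for g in candidates.npp_genes:
        rec = candidates[g]
        if g not in covered:
            warnings.warn(f"candidate {g} absent from peak table; excluded")
            continue
        if not rec.cognate_partners:
            warnings.warn(f"candidate {g} lacks cognate annotation; excluded")
            continue
        if peaks.percentile(g) < min_peak_percentile:
            continue
        partners_ok = [
            h for h in rec.cognate_partners
            if h in covered and _receptor_expressed(
                h, peaks, receptor_min_detection, receptor_min_percentile)
        ]
        if partners_ok:
            npp_keep.append(g)
    gpcr_keep: list[str] = []
    for h in candidates.npgpcr_genes:
        if h not in covered:
            continue
        if not _receptor_expressed(h, peaks, receptor_min_detection,
                                   receptor_min_percentile):
            continue
        if any(g in npp_keep for g in candidates[h].cognate_partners):
            gpcr_keep.append(h)
    return npp_keep, gpcr_keep


def build_cognate_pairs(npp_genes: list[str], npgpcr_genes: list[str],
                        table: NPGeneTable,
                        peaks: PeakExpressionTable | None = None,
                        ) -> list[CognatePair]:
    """One pair per cognate edge with both members selected.

    Order is deterministic: precursors by peak rank when a peak table is
    given (gene id otherwise), receptors by gene id within a precursor.
    """
    selected_gpcr = set(npgpcr_genes)
    if peaks is not None:
        npp_sorted = sorted(npp_genes, key=lambda g: (peaks.rank(g), g))
    else:
        npp_sorted = list(npp_genes)
    pairs = []
    for g in npp_sorted:
        for h in sorted(table[g].cognate_partners):
            if h in selected_gpcr:
                pairs.append(CognatePair(g, h, table.galpha_of(h)))
    return pairs


def fraction_of_type_pairs(pair: CognatePair, t: TypeExpressionMatrix,
                           theta_npp: float = 1.0,
                           theta_gpcr: float = 1.0) -> float:
    """Fraction of ordered (source, target) type pairs with both sides on.

    Equals (fraction of source types with precursor profile ≥ θ_npp) ×
    (fraction of target types with receptor profile ≥ θ_gpcr).
    """
    u = t.gene_row(pair.npp_gene)
    v = t.gene_row(pair.npgpcr_gene)
    return float((u >= theta_npp).mean() * (v >= theta_gpcr).mean())


def selection_report(candidates: NPGeneTable, peaks: PeakExpressionTable,
                     npp_keep: list[str], gpcr_keep: list[str]) -> pd.DataFrame:
    """Tidy per-candidate report of criterion outcomes."""
    rows = []
    kept = set(npp_keep) | set(gpcr_keep)
    for g, rec in candidates.records.items():
        in_peaks = g in peaks.table.index
        rows.append({
            "gene": g, "role": rec.role,
            "peak_value": peaks.peak(g) if in_peaks else np.nan,
            "peak_percentile": peaks.percentile(g) if in_peaks else np.nan,
            "detection_fraction": (
                float(peaks.table.loc[g, "detection_fraction"])
                if in_peaks else np.nan),
            "selected": g in kept,
        })
    return pd.DataFrame(rows)


def pairs_table(pairs: list[CognatePair]) -> pd.DataFrame:
    """Tidy table of cognate pairs mirroring the annotation layout."""
    return pd.DataFrame([
        {"pair_symbol": p.symbol, "npp_gene": p.npp_gene,
         "npgpcr_gene": p.npgpcr_gene, "galpha_family": p.galpha_family,
         "fraction_of_type_pairs": p.fraction_of_type_pairs}
        for p in pairs
    ])
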