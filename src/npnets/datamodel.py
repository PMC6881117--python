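"""Core data containers and file I/O shared by every analysis stage.

The containers are deliberately thin wrappers around numpy arrays,
pandas frames and a dendropy-derived tree: an expression matrix with a
unit tag, per-cell annotations, a rooted cell-type taxonomy with node
heights, and the neuropeptide gene annotation table (precursor genes,
their cognate receptors, and each receptor's primary Gα family).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

VALID_UNITS = ("counts", "CPM", "FPKM")
VALID_ROLES = ("NPP", "NP-GPCR")
VALID_GALPHA = ("Gi/o", "Gs", "Gq/11")
CPM_TOTAL = 1e6


class ValidationError(ValueError):
    """Raised when a container's domain invariants are violated."""


class FormatError(ValueError):
    """Raised when an input file is structurally malformed."""


# ---------------------------------------------------------------------------
# ExpressionMatrix


@dataclass
class ExpressionMatrix:
    """Cells × genes non-negative expression values with a unit tag.

    Parameters
    ----------
    values
        Dense ``(n_cells, n_genes)`` array; absent measurements are 0.
    units
        One of ``counts``, ``CPM``, ``FPKM``.
    cell_ids, gene_ids
        Unique identifiers for rows and columns. Gene symbols are
        case-sensitive and matched by exact string throughout.
    is_full_transcriptome
        If true and units are CPM, each cell's row must sum to 1e6.
    """

    values: np.ndarray
    units: str
    cell_ids: list[str]
    gene_ids: list[str]
    is_full_transcriptome: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.units not in VALID_UNITS:
            raise ValidationError(f"unknown units {self.units!r}")
        if self.values.ndim != 2:
            raise ValidationError("values must be 2-D (cells × genes)")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells × {len(self.gene_ids)} genes"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError("expression values must be finite")
        if (self.values < 0).any():
            raise ValidationError("expression values must be non-negative")
        for name, ids in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique()
                raise ValidationError(f"duplicate {name} ids: {list(dupes)[:5]}")
        if self.units == "CPM" and self.is_full_transcriptome and self.n_genes:
            sums = self.values.sum(axis=1)
            if not np.allclose(sums, CPM_TOTAL, rtol=1e-6):
                bad = self.cell_ids[int(np.argmax(np.abs(sums - CPM_TOTAL)))]
                raise ValidationError(
                    f"CPM rows must sum to 1e6; cell {bad!r} does not"
                )
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._cell_index = {c: i for i, c in enumerate(self.cell_ids)}

    # -- basic accessors ----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_column(self, gene: str) -> np.ndarray:
        """Return the expression vector of one gene across all cells."""
        try:
            return self.values[:, self._gene_index[gene]]
        except KeyError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def gene_indices(self, genes: Sequence[str]) -> np.ndarray:
        missing = [g for g in genes if g not in self._gene_index]
        if missing:
            raise KeyError(f"unknown genes: {missing[:5]}")
        return np.array([self._gene_index[g] for g in genes], dtype=int)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_indices(genes)
        return ExpressionMatrix(
            self.values[:, idx], self.units, self.cell_ids, list(genes),
            is_full_transcriptome=False,
        )

    def subset_cells(self, mask_or_ids) -> "ExpressionMatrix":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            idx = np.array([self._cell_index[c] for c in mask_or_ids], dtype=int)
        return ExpressionMatrix(
            self.values[idx], self.units, [self.cell_ids[i] for i in idx],
            self.gene_ids, self.is_full_transcriptome,
        )


def counts_to_cpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Normalize raw counts to counts-per-million within each cell.

    Every cell must have a positive total; an all-zero cell is an error
    because its normalization is undefined.
    """
    if m.units != "counts":
        raise ValidationError(f"expected counts, got {m.units}")
    totals = m.values.sum(axis=1)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise ValidationError(
            f"cell {m.cell_ids[zero[0]]!r} has zero total counts"
        )
    cpm = m.values * (CPM_TOTAL / totals[:, None])
    return ExpressionMatrix(cpm, "CPM", m.cell_ids, m.gene_ids,
                            is_full_transcriptome=True)


def read_expression(path, units: str, layout: str = "dense-delimited",
                    is_full_transcriptome: bool = False) -> ExpressionMatrix:
    """Read an expression matrix from delimited text or Matrix Market triplets.

    ``dense-delimited``: one header line of gene ids, cells as rows, first
    column the cell id.  ``sparse-triplet``: an ``.mtx`` file (cells × genes)
    with sidecar ``<stem>.cells.tsv`` / ``<stem>.genes.tsv`` id lists.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout == "dense-delimited":
        sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.isna().any().any():
            raise FormatError(f"missing entries in {path}")
        return ExpressionMatrix(
            df.to_numpy(dtype=float), units,
            [str(c) for c in df.index], [str(g) for g in df.columns],
            is_full_transcriptome,
        )
    if layout == "sparse-triplet":
        mat = spio.mmread(str(path))
        cells = pd.read_csv(path.with_suffix("").with_suffix(".cells.tsv"),
                            header=None)[0].astype(str).tolist()
        genes = pd.read_csv(path.with_suffix("").with_suffix(".genes.tsv"),
                            header=None)[0].astype(str).tolist()
        dense = np.asarray(sparse.coo_matrix(mat).todense(), dtype=float)
        return ExpressionMatrix(dense, units, cells, genes, is_full_transcriptome)
    raise ValueError(f"unknown layout {layout!r}")


def write_expression(m: ExpressionMatrix, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    df = pd.DataFrame(m.values, index=m.cell_ids, columns=m.gene_ids)
    df.index.name = "cell_id"
    df.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# CellAnnotation

VALID_CLASSES = ("glutamatergic", "GABAergic")
ANNOTATION_COLUMNS = ["cell_id", "area", "leaf_type", "subclass", "class"]


@dataclass
class CellAnnotation:
    """Per-cell area and taxonomy labels, stored as a tidy DataFrame."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"annotation missing columns {missing}")
        self.table = self.table[ANNOTATION_COLUMNS].astype(str).reset_index(drop=True)
        if self.table["cell_id"].duplicated().any():
            raise ValidationError("duplicate cell ids in annotation")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def cell_ids(self) -> list[str]:
        return self.table["cell_id"].tolist()

    def aligned_to(self, m: ExpressionMatrix) -> "CellAnnotation":
        """Return annotation re-ordered to the matrix's cell order."""
        sub = self.table.set_index("cell_id").loc[m.cell_ids].reset_index()
        return CellAnnotation(sub)

    def validate_against(self, taxonomy: "Taxonomy") -> None:
        """Check leaf/subclass/class consistency with a taxonomy."""
        for _, row in self.table.iterrows():
            leaf = row["leaf_type"]
            if leaf not in taxonomy.leaf_names:
                raise ValidationError(f"unknown leaf type {leaf!r}")
            if taxonomy.subclass_of(leaf) != row["subclass"]:
                raise ValidationError(
                    f"cell {row['cell_id']}: subclass {row['subclass']!r} "
                    f"inconsistent with taxonomy"
                )
            if taxonomy.class_of(leaf) != row["class"]:
                raise ValidationError(
                    f"cell {row['cell_id']}: class inconsistent with taxonomy"
                )


def read_annotation(path) -> CellAnnotation:
    return CellAnnotation(pd.read_csv(path, sep="\t", dtype=str))


def write_annotation(ann: CellAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Taxonomy


class Taxonomy:
    """Rooted cell-type tree with per-node heights and subclass/class strata.

    Heights follow the cluster-dendrogram convention: every leaf has
    height 0, a parent is at least as high as its children, and the root
    is strictly above 0.  When branch lengths are absent, unit-length
    merges are assumed (a node's height is its maximum hop count to a
    descendant leaf).
    """

    def __init__(self, tree: dendropy.Tree,
                 leaf_to_subclass: Mapping[str, str] | None = None,
                 leaf_to_class: Mapping[str, str] | None = None) -> None:
        self.tree = tree
        self._compute_heights()
        leaves = self.leaf_names
        if leaf_to_subclass is None or leaf_to_class is None:
            sub, cls = self._infer_strata()
            leaf_to_subclass = leaf_to_subclass or sub
            leaf_to_class = leaf_to_class or cls
        self.leaf_to_subclass = {str(k): str(v) for k, v in leaf_to_subclass.items()}
        self.leaf_to_class = {str(k): str(v) for k, v in leaf_to_class.items()}
        for leaf in leaves:
            if leaf not in self.leaf_to_subclass or leaf not in self.leaf_to_class:
                raise ValidationError(f"leaf {leaf!r} lacks subclass/class labels")

    # -- construction helpers ----------------------------------------------
    def _compute_heights(self) -> None:
        root = self.tree.seed_node
        self.heights: dict = {}
        has_lengths = any(
            e.length is not None for e in self.tree.preorder_edge_iter()
            if e.head_node is not root
        )
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                self.heights[node] = 0.0
            else:
                if has_lengths:
                    h = max(
                        self.heights[ch] + (ch.edge.length or 0.0)
                        for ch in node.child_nodes()
                    )
                else:
                    h = max(self.heights[ch] for ch in node.child_nodes()) + 1.0
                self.heights[node] = h
        if self.heights[root] <= 0:
            raise ValidationError("root height must be > 0 (tree has no structure)")
        for node in self.tree.preorder_node_iter():
            for ch in node.child_nodes():
                if self.heights[node] < self.heights[ch] - 1e-12:
                    raise ValidationError("parent height below child height")

    def _infer_strata(self) -> tuple[dict, dict]:
        """Infer subclass/class from tree levels: root children are classes,
        grandchildren are subclasses (the synthetic-tree layout)."""
        sub: dict = {}
        cls: dict = {}
        for class_node in self.tree.seed_node.child_nodes():
            cname = class_node.taxon.label if class_node.taxon else (
                class_node.label or f"class_{id(class_node)}")
            for sub_node in (class_node.child_nodes() or [class_node]):
                sname = sub_node.taxon.label if sub_node.taxon else (
                    sub_node.label or f"subclass_{id(sub_node)}")
                for leaf in sub_node.leaf_iter():
                    sub[leaf.taxon.label] = sname
                    cls[leaf.taxon.label] = cname
            if class_node.is_leaf():
                sub[class_node.taxon.label] = cname
                cls[class_node.taxon.label] = cname
        return sub, cls

    # -- queries ------------------------------------------------------------
    @property
    def root(self):
        return self.tree.seed_node

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return len(self.tree.leaf_nodes())

    @property
    def root_height(self) -> float:
        return self.heights[self.root]

    def height(self, node) -> float:
        return self.heights[node]

    def subclass_of(self, leaf: str) -> str:
        return self.leaf_to_subclass[leaf]

    def class_of(self, leaf: str) -> str:
        return self.leaf_to_class[leaf]

    @property
    def subclasses(self) -> list[str]:
        seen: list[str] = []
        for leaf in self.leaf_names:
            s = self.leaf_to_subclass[leaf]
            if s not in seen:
                seen.append(s)
        return seen

    def leaves_in_subclass(self, subclass: str) -> list[str]:
        return [l for l in self.leaf_names if self.leaf_to_subclass[l] == subclass]

    def internal_nodes_ascending(self) -> list:
        """Non-leaf nodes sorted by ascending height (root last).

        Ties are broken by the lexicographically smallest descendant leaf
        so the merge order is deterministic.
        """
        nodes = [n for n in self.tree.preorder_node_iter() if not n.is_leaf()]
        return sorted(
            nodes,
            key=lambda n: (self.heights[n],
                           min(lf.taxon.label for lf in n.leaf_iter())),
        )

    def leaves_under(self, node) -> list[str]:
        return [lf.taxon.label for lf in node.leaf_iter()]


def read_taxonomy(path, fmt: str = "newick-with-heights",
                  strata_path=None) -> Taxonomy:
    """Read a taxonomy from Newick text or nested JSON.

    ``strata_path`` optionally points to a TSV with columns
    ``leaf_type, subclass, class``; otherwise strata are inferred from
    the first two levels below the root.
    """
    path = Path(path)
    if fmt == "newick-with-heights":
        try:
            tree = dendropy.Tree.get(path=str(path), schema="newick")
        except Exception as exc:  # dendropy raises several error types
            raise FormatError(f"malformed newick in {path}: {exc}") from exc
    elif fmt == "nested-json":
        with open(path) as fh:
            spec = json.load(fh)
        tree = _tree_from_nested(spec)
    else:
        raise ValueError(f"unknown taxonomy format {fmt!r}")
    sub = cls = None
    if strata_path is not None:
        df = pd.read_csv(strata_path, sep="\t", dtype=str)
        sub = dict(zip(df["leaf_type"], df["subclass"]))
        cls = dict(zip(df["leaf_type"], df["class"]))
    return Taxonomy(tree, sub, cls)


def _tree_from_nested(spec: dict) -> dendropy.Tree:
    """Build a dendropy tree from ``{"name": ..., "children": [...]}``."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)

    def build(node_spec: dict, node: dendropy.Node) -> None:
        children = node_spec.get("children", [])
        if children:
            node.label = node_spec.get("name")
            for ch_spec in children:
                child = dendropy.Node()
                if "length" in ch_spec:
                    child.edge.length = float(ch_spec["length"])
                node.add_child(child)
                build(ch_spec, child)
        else:
            node.taxon = taxa.new_taxon(str(node_spec["name"]))

    build(spec, tree.seed_node)
    return tree


def write_taxonomy(taxonomy: Taxonomy, path, strata_path=None) -> None:
    taxonomy.tree.write(path=str(path), schema="newick",
                        suppress_rooting=True)
    if strata_path is not None:
        rows = [
            {"leaf_type": l, "subclass": taxonomy.subclass_of(l),
             "class": taxonomy.class_of(l)}
            for l in taxonomy.leaf_names
        ]
        pd.DataFrame(rows).to_csv(strata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# NPGeneTable


@dataclass
class NPGeneRecord:
    gene_id: str
    role: str
    cognate_partners: list[str]
    galpha_family: str | None = None
    predicted_products: str = ""
    peak_fpkm: float | None = None
    pfpkm_percentile: float | None = None
    pfpkm_rank: int | None = None
    pct_cells: float | None = None


class NPGeneTable:
    """Annotation table of NPP and NP-GPCR genes with cognate links.

    The cognate relation is symmetric: if precursor g lists receptor h,
    then h lists g.  Receptors (and only receptors) carry a primary Gα
    transduction family.
    """

    def __init__(self, records: Iterable[NPGeneRecord]) -> None:
        records = list(records)
        self.records = {r.gene_id: r for r in records}
        if len(self.records) != len(records):
            raise ValidationError("duplicate gene ids in NP gene table")
        self._validate_and_close()

    def _validate_and_close(self) -> None:
        for r in self.records.values():
            if r.role not in VALID_ROLES:
                raise ValidationError(f"{r.gene_id}: unknown role {r.role!r}")
            if r.role == "NP-GPCR":
                if r.galpha_family not in VALID_GALPHA:
                    raise ValidationError(
                        f"{r.gene_id}: NP-GPCR requires a Gα family"
                    )
            elif r.galpha_family is not None:
                raise ValidationError(
                    f"{r.gene_id}: NPP rows must not carry a Gα family"
                )
        # symmetric closure of the cognate relation
        for r in self.records.values():
            for p in r.cognate_partners:
                if p not in self.records:
                    raise ValidationError(
                        f"{r.gene_id}: unknown cognate partner {p!r}"
                    )
                other = self.records[p]
                if other.role == r.role:
                    raise ValidationError(
                        f"{r.gene_id} and {p} share role {r.role}; cognate "
                        "links must pair an NPP with an NP-GPCR"
                    )
                if r.gene_id not in other.cognate_partners:
                    other.cognate_partners.append(r.gene_id)

    # -- queries ------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene: str) -> bool:
        return gene in self.records

    def __getitem__(self, gene: str) -> NPGeneRecord:
        return self.records[gene]

    @property
    def npp_genes(self) -> list[str]:
        return [g for g, r in self.records.items() if r.role == "NPP"]

    @property
    def npgpcr_genes(self) -> list[str]:
        return [g for g, r in self.records.items() if r.role == "NP-GPCR"]

    def cognate_pairs(self) -> list[tuple[str, str]]:
        """All (NPP, NP-GPCR) edges of the bipartite cognate graph."""
        pairs = []
        for g in self.npp_genes:
            for h in self.records[g].cognate_partners:
                pairs.append((g, h))
        return pairs

    def galpha_of(self, receptor: str) -> str:
        r = self.records[receptor]
        if r.role != "NP-GPCR":
            raise ValidationError(f"{receptor} is not an NP-GPCR")
        return r.galpha_family


NP_TABLE_COLUMNS = [
    "gene_id", "role", "cognate_partners", "galpha_family",
    "predicted_products", "peak_fpkm", "pfpkm_percentile", "pfpkm_rank",
    "pct_cells",
]


def read_np_gene_table(path) -> NPGeneTable:
    """Read the NP gene annotation TSV (partners ``|``-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty and "gene_id" not in df.columns:
        return NPGeneTable([])
    required = {"gene_id", "role", "cognate_partners"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"NP gene table missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        partners = [p for p in str(row.get("cognate_partners", "") or "").split("|")
                    if p and p != "nan"]
        gal = row.get("galpha_family")
        gal = None if (pd.isna(gal) or gal in ("", "nan")) else str(gal)

        def _num(col, cast=float):
            v = row.get(col)
            return None if (v is None or pd.isna(v) or v == "") else cast(float(v))

        records.append(NPGeneRecord(
            gene_id=str(row["gene_id"]), role=str(row["role"]),
            cognate_partners=partners, galpha_family=gal,
            predicted_products=str(row.get("predicted_products", "") or ""),
            peak_fpkm=_num("peak_fpkm"),
            pfpkm_percentile=_num("pfpkm_percentile"),
            pfpkm_rank=_num("pfpkm_rank", int),
            pct_cells=_num("pct_cells"),
        ))
    return NPGeneTable(records)


def write_np_gene_table(table: NPGeneTable, path) -> None:
    rows = []
    for r in table.records.values():
        rows.append({
            "gene_id": r.gene_id, "role": r.role,
            "cognate_partners": "|".join(r.cognate_partners),
            "galpha_family": r.galpha_family or "",
            "predicted_products": r.predicted_products,
            "peak_fpkm": r.peak_fpkm, "pfpkm_percentile": r.pfpkm_percentile,
            "pfpkm_rank": r.pfpkm_rank, "pct_cells": r.pct_cells,
        })
    pd.DataFrame(rows, columns=NP_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)
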