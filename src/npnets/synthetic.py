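"""Synthetic single-cell dataset generator.

Emulates the statistical structure the downstream analyses assume: a
2-class / ~12-subclass / ~100-type hierarchy, per-gene type-specific
mean expression spanning several orders of magnitude with many exact
zeros, overdispersed (gamma–Poisson) counts with variable library
sizes, and two cortical "areas" sharing type-level profiles up to a
controllable log-normal perturbation.  With the perturbation and the
dispersion driven to zero the generator's ground-truth type means are
recoverable from the data, which is what makes every downstream stage
testable without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .datamodel import (
    CellAnnotation,
    ExpressionMatrix,
    NPGeneRecord,
    NPGeneTable,
    Taxonomy,
    counts_to_cpm,
)
import pandas as pd

AREAS = ("VISp", "ALM")


@dataclass
class SynthConfig:
    """Parameters of the synthetic dataset.

    Defaults are the study conditions the generator emulates: type-level
    expression spanning four decades, overdispersed counts, a sampled
    population that is roughly 47% GABAergic / 53% glutamatergic, and a
    small area-specific perturbation of type means.
    """

    n_types: int = 100
    n_subclasses: int = 12
    n_cells_per_area: int = 2500
    n_genes_background: int = 400
    n_genes_np_like: int = 47
    dynamic_range_log10: float = 4.0
    expressor_fraction_range: tuple[float, float] = (0.05, 0.6)
    nb_dispersion: float = 0.5
    library_size_lognorm: tuple[float, float] = (np.log(2e5), 0.35)
    area_perturbation_sd: float = 0.05
    gaba_fraction: float = 0.47
    ensure_each_type_expresses: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subclasses > self.n_types:
            raise ValueError("n_subclasses must be ≤ n_types")
        for name in ("n_types", "n_subclasses", "n_cells_per_area",
                     "n_genes_background", "n_genes_np_like"):
            if getattr(self, name) < 0 or (name in ("n_types", "n_subclasses",
                                                    "n_cells_per_area")
                                           and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        lo, hi = self.expressor_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("expressor_fraction_range must be within [0,1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def generate_taxonomy(cfg: SynthConfig) -> Taxonomy:
    """Balanced 2-class tree: root → classes → subclasses → types.

    Subclasses are split as evenly as possible between the GABAergic
    and glutamatergic classes and types as evenly as possible across
    subclasses (sizes differ by at most 1).  Unit merge heights: leaves
    at 0, subclasses at 1, classes at 2, root at 3.
    """
    classes = ["GABAergic", "glutamatergic"]
    n_sub_per_class = [cfg.n_subclasses - cfg.n_subclasses // 2,
                       cfg.n_subclasses // 2]
    # even partition of types over subclasses
    base, extra = divmod(cfg.n_types, cfg.n_subclasses)
    sub_sizes = [base + (1 if i < extra else 0) for i in range(cfg.n_subclasses)]

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    leaf_to_subclass: dict[str, str] = {}
    leaf_to_class: dict[str, str] = {}
    sub_idx = 0
    type_idx = 0
    for cls_name, n_sub in zip(classes, n_sub_per_class):
        if n_sub == 0:
            continue
        cls_node = dendropy.Node(label=cls_name)
        tree.seed_node.add_child(cls_node)
        for _ in range(n_sub):
            sub_name = f"sub{sub_idx:02d}"
            sub_node = dendropy.Node(label=sub_name)
            cls_node.add_child(sub_node)
            for _ in range(sub_sizes[sub_idx]):
                leaf_name = f"t{type_idx:03d}"
                leaf = dendropy.Node()
                leaf.taxon = taxa.new_taxon(leaf_name)
                sub_node.add_child(leaf)
                leaf_to_subclass[leaf_name] = sub_name
                leaf_to_class[leaf_name] = cls_name
                type_idx += 1
            sub_idx += 1
    return Taxonomy(tree, leaf_to_subclass, leaf_to_class)


def generate_np_gene_table(cfg: SynthConfig,
                           multiplicities: list[int] | None = None) -> NPGeneTable:
    """Synthetic NP gene annotation with the real table's topology.

    Each precursor-like gene links to 1–4 receptor-like genes; each
    receptor carries a uniformly drawn Gα family.  ``multiplicities``
    fixes the per-precursor receptor counts explicitly (e.g. copied from
    the shipped annotation fixture); receptors are then partitioned
    accordingly, so ``sum(multiplicities)`` distinct receptors are
    required at most and receptors may be shared when the pool runs out.
    """
    rng = cfg.rng()
    n_total = cfg.n_genes_np_like
    if n_total == 0:
        return NPGeneTable([])
    n_npp = max(1, int(round(n_total * 18 / 47)))
    n_gpcr = n_total - n_npp
    if multiplicities is None:
        multiplicities = [int(rng.integers(1, 5)) for _ in range(n_npp)]
    if len(multiplicities) != n_npp:
        raise ValueError("need one multiplicity per precursor gene")
    npp_ids = [f"npp{i:02d}" for i in range(n_npp)]
    gpcr_ids = [f"npr{i:02d}" for i in range(n_gpcr)]
    if n_gpcr == 0 and any(m > 0 for m in multiplicities):
        raise ValueError("receptor multiplicities require receptor genes")
    records = [
        NPGeneRecord(g, "NP-GPCR", [],
                     galpha_family=str(rng.choice(["Gi/o", "Gs", "Gq/11"])))
        for g in gpcr_ids
    ]
    # deal receptors to precursors round-robin so every receptor is cognate
    # to at least one precursor
    cursor = 0
    npp_records = []
    for g, mult in zip(npp_ids, multiplicities):
        partners = []
        for _ in range(mult):
            partners.append(gpcr_ids[cursor % n_gpcr])
            cursor += 1
        npp_records.append(NPGeneRecord(g, "NPP", sorted(set(partners))))
    return NPGeneTable(npp_records + records)


def _type_mean_matrix(taxonomy: Taxonomy, gene_table: NPGeneTable,
                      cfg: SynthConfig, rng: np.random.Generator):
    """Ground-truth per-type mean expression μ(g,t) on a CPM-like scale."""
    leaves = taxonomy.leaf_names
    n_types = len(leaves)
    bg_genes = [f"bg{i:04d}" for i in range(cfg.n_genes_background)]
    np_genes = list(gene_table.records.keys())
    genes = bg_genes + np_genes

    mu = np.zeros((len(genes), n_types))
    # background genes: moderate constitutive expression, low variance
    # across types (log-normal, sd 0.2 decades)
    base = 10 ** rng.uniform(0.5, 2.5, size=cfg.n_genes_background)
    mu[:len(bg_genes)] = base[:, None] * 10 ** rng.normal(
        0.0, 0.2, size=(cfg.n_genes_background, n_types))
    # NP-like genes: zero outside expressor types, log-uniform over the
    # configured dynamic range inside them
    lo_f, hi_f = cfg.expressor_fraction_range
    top = 4.0  # log10 CPM ceiling of the expressing range
    for j, g in enumerate(np_genes):
        frac = rng.uniform(lo_f, hi_f)
        n_exp = int(round(frac * n_types))
        idx = rng.choice(n_types, size=n_exp, replace=False) if n_exp else []
        row = np.zeros(n_types)
        if n_exp:
            row[idx] = 10 ** rng.uniform(top - cfg.dynamic_range_log10, top,
                                         size=n_exp)
        mu[len(bg_genes) + j] = row
    if cfg.ensure_each_type_expresses and np_genes:
        npb = mu[len(bg_genes):]
        for t in range(n_types):
            if not (npb[:, t] > 0).any():
                j = int(rng.integers(len(np_genes)))
                npb[j, t] = 10 ** rng.uniform(top - 1.0, top)
    return genes, mu


def generate_dataset(taxonomy: Taxonomy, gene_table: NPGeneTable,
                     cfg: SynthConfig):
    """Draw cells for both areas and return (CPM, counts, annotation).

    Cell types are sampled with the configured GABAergic enrichment;
    area-specific type means are the shared means times a log-normal
    perturbation; counts are negative binomial (gamma–Poisson) around
    the mean scaled by a per-cell library-size factor.
    """
    rng = cfg.rng()
    genes, mu = _type_mean_matrix(taxonomy, gene_table, cfg, rng)
    leaves = taxonomy.leaf_names
    classes = np.array([taxonomy.class_of(l) for l in leaves])
    gaba_types = np.flatnonzero(classes == "GABAergic")
    glut_types = np.flatnonzero(classes == "glutamatergic")

    all_counts = []
    cell_ids: list[str] = []
    ann_rows = []
    for area in AREAS:
        pert = np.exp(rng.normal(0.0, cfg.area_perturbation_sd, size=mu.shape)) \
            if cfg.area_perturbation_sd > 0 else 1.0
        mu_area = mu * pert
        # normalize each type's profile to relative proportions
        prop = mu_area / mu_area.sum(axis=0, keepdims=True)
        for i in range(cfg.n_cells_per_area):
            if gaba_types.size and (not glut_types.size or
                                    rng.random() < cfg.gaba_fraction):
                t = int(rng.choice(gaba_types))
            else:
                t = int(rng.choice(glut_types))
            lib_mu, lib_sd = cfg.library_size_lognorm
            libsize = float(np.exp(rng.normal(lib_mu, lib_sd)))
            lam = prop[:, t] * libsize
            if cfg.nb_dispersion > 0:
                # gamma–Poisson: var = mean + dispersion * mean^2
                shape = 1.0 / cfg.nb_dispersion
                lam = lam * rng.gamma(shape, 1.0 / shape, size=lam.shape)
            counts = rng.poisson(lam)
            if counts.sum() == 0:
                counts[int(np.argmax(lam))] = 1  # avoid zero-total cells
            all_counts.append(counts)
            cid = f"{area}_c{i:05d}"
            cell_ids.append(cid)
            ann_rows.append({
                "cell_id": cid, "area": area, "leaf_type": leaves[t],
                "subclass": taxonomy.subclass_of(leaves[t]),
                "class": taxonomy.class_of(leaves[t]),
            })
    counts_mat = ExpressionMatrix(
        np.asarray(all_counts, dtype=float), "counts", cell_ids, genes)
    cpm = counts_to_cpm(counts_mat)
    ann = CellAnnotation(pd.DataFrame(ann_rows))
    return cpm, counts_mat, ann


def ground_truth_type_means(taxonomy: Taxonomy, gene_table: NPGeneTable,
                            cfg: SynthConfig):
    """The μ(g,t) matrix the generator used, for recoverability checks.

    Uses the same rng stream prefix as :func:`generate_dataset`, so the
    returned means are exactly those behind a dataset generated with the
    same config.
    """
    rng = cfg.rng()
    genes, mu = _type_mean_matrix(taxonomy, gene_table, cfg, rng)
    return genes, mu
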