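"""Gene-subset cell-type classification benchmark.

A reference autoencoder learns a low-dimensional latent space from a
large highly-expressed gene set; a second, linked autoencoder embeds a
small gene subset into a matching latent space by adding a latent
mismatch penalty (weight λ) to its reconstruction loss.  Quadratic
discriminant analysis on the latent coordinates, applied iteratively
while leaf labels are merged upward through the cell-type taxonomy,
yields a per-cell resolution index (RI): 1 for cells classified
correctly at the finest (leaf) level, 0 for cells wrong even at the
class level, and the merged node's normalized height in between.  Mean
RI summarizes how well a gene subset resolves the taxonomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.model_selection import KFold, StratifiedKFold

from .datamodel import CellAnnotation, ExpressionMatrix, Taxonomy, ValidationError
from .nn import Autoencoder


# ---------------------------------------------------------------------------
# specs and results


@dataclass
class AutoencoderSpec:
    """Architecture and training configuration for one autoencoder.

    The reference network uses four 100-unit hidden layers per side and
    heavy input dropout; the linked network uses four 50-unit layers and
    no dropout.  Epoch counts default to desk-scale values; the
    full-scale study values (50,000 / 10,000) remain reachable through
    this spec.
    """

    input_dim: int
    hidden_widths: tuple[int, ...] = (100, 100, 100, 100)
    latent_dim: int = 5
    input_dropout_rate: float = 0.8
    epochs: int = 500
    batch_size: int = 956
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_widths) != 4:
            raise ValidationError("four hidden layers per side are required")
        if self.latent_dim < 2:
            raise ValidationError("latent dimension must be ≥ 2")


def linked_spec(input_dim: int, width: int = 50, **kw) -> AutoencoderSpec:
    """Spec for the second (linked) network: Dense(50)×4, no dropout."""
    kw.setdefault("hidden_widths", (width,) * 4)
    kw.setdefault("input_dropout_rate", 0.0)
    kw.setdefault("epochs", 200)
    return AutoencoderSpec(input_dim=input_dim, **kw)


@dataclass
class LatentEmbedding:
    coordinates: np.ndarray  # (n_cells, d)
    source_gene_set: str
    role: str  # "reference" | "linked"

    def __post_init__(self) -> None:
        if not np.isfinite(self.coordinates).all():
            raise ValidationError("latent coordinates must be finite")


@dataclass
class RIResult:
    """Per-cell resolution indices and their summary."""

    ri: np.ndarray
    fold: np.ndarray
    node_ri: dict[str, float]
    mean_ri: float = field(init=False)

    def __post_init__(self) -> None:
        if ((self.ri < 0) | (self.ri > 1)).any():
            raise ValidationError("RI values must lie in [0, 1]")
        self.mean_ri = float(self.ri.mean())


# ---------------------------------------------------------------------------
# preprocessing and gene sets


def preprocess(m: ExpressionMatrix, genes: list[str],
               mode: str = "log1p+standardize") -> np.ndarray:
    """Prepare a cells × genes input block for the autoencoder.

    ``log1p`` is log10(CPM+1); ``standardize`` additionally centers and
    scales each gene (raw CPM spans several decades and would dominate
    the squared-error loss otherwise).
    """
    X = m.values[:, m.gene_indices(genes)].astype(float)
    if mode == "raw":
        return X
    X = np.log10(X + 1.0)
    if mode == "log1p":
        return X
    if mode == "log1p+standardize":
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        return (X - mu) / sd
    raise ValueError(f"unknown preprocessing mode {mode!r}")


def select_gene_sets(m: ExpressionMatrix, spec: str, n: int = 47,
                     ann: CellAnnotation | None = None,
                     taxonomy: Taxonomy | None = None,
                     seed: int = 0,
                     reference: list[str] | None = None,
                     pool: list[str] | None = None) -> list[str]:
    """Build one of the benchmark gene sets.

    ``HE``: top-n genes by per-gene maximum across cells.
    ``DE``: top-n by a one-vs-rest differential score over leaf-type
    mean profiles (max over types of the type's z-score against the
    remaining types) — a stand-in for an externally supplied
    differential-expression list.
    ``DE47``: the 47 most variable (by variance of type-level means)
    genes among the DE genes.
    ``Rand47``: n genes drawn uniformly from the HE pool.
    ``Rand47_ExpMatched``: n genes drawn so the per-gene maximum
    expression distribution matches the reference set's, decile bin by
    decile bin.
    """
    if n > m.n_genes:
        raise ValidationError("requested more genes than available")
    gene_ids = np.array(m.gene_ids)
    maxima = m.values.max(axis=0)
    if spec == "HE":
        order = np.lexsort((gene_ids, -maxima))
        return gene_ids[order[:n]].tolist()
    if spec in ("DE", "DE47"):
        if ann is None:
            raise ValidationError("DE selection requires a cell annotation")
        from .expression_stats import type_mean_expression
        prof = type_mean_expression(m, ann, taxonomy, statistic="mean")
        vals = prof.values  # genes × types
        n_types = vals.shape[1]
        scores = np.zeros(vals.shape[0])
        for t in range(n_types):
            rest = np.delete(vals, t, axis=1)
            mu = rest.mean(axis=1)
            sd = rest.std(axis=1) + 1e-9
            scores = np.maximum(scores, np.abs(vals[:, t] - mu) / sd)
        if spec == "DE":
            order = np.lexsort((gene_ids, -scores))
            return gene_ids[order[:n]].tolist()
        de_pool_n = max(4 * n, n)
        order = np.lexsort((gene_ids, -scores))
        de_pool = order[:min(de_pool_n, len(order))]
        var = vals.var(axis=1)
        sub_order = sorted(de_pool, key=lambda i: (-var[i], gene_ids[i]))
        return gene_ids[sub_order[:n]].tolist()
    rng = np.random.default_rng(seed)
    if spec == "Rand47":
        pool_ids = pool if pool is not None else gene_ids[maxima > 0].tolist()
        if len(pool_ids) < n:
            raise ValidationError("pool smaller than requested set")
        return sorted(rng.choice(pool_ids, size=n, replace=False).tolist())
    if spec == "Rand47_ExpMatched":
        if reference is None:
            raise ValidationError("expression matching requires a reference set")
        logmax = np.log10(maxima + 1.0)
        edges = np.quantile(logmax, np.linspace(0, 1, 11))
        edges[-1] += 1e-9
        bins = np.clip(np.searchsorted(edges, logmax, side="right") - 1, 0, 9)
        bin_of = dict(zip(gene_ids, bins))
        by_bin: dict[int, list[str]] = {}
        ref_set = set(reference)
        for g, b in zip(gene_ids, bins):
            if g not in ref_set:
                by_bin.setdefault(int(b), []).append(g)
        chosen: list[str] = []
        taken = set()
        ref_sample = list(reference)[:n] if len(reference) >= n else list(reference)
        for g in ref_sample:
            b = int(bin_of[g])
            # widen the bin search if the exact bin is exhausted
            for delta in range(10):
                cands = [c for bb in (b - delta, b + delta) if bb in by_bin
                         for c in by_bin[bb] if c not in taken]
                if cands:
                    pick = str(rng.choice(cands))
                    chosen.append(pick)
                    taken.add(pick)
                    break
        if len(chosen) < n:
            raise ValidationError("insufficient pool for expression matching")
        return sorted(chosen)
    raise ValueError(f"unknown gene-set spec {spec!r}")


# ---------------------------------------------------------------------------
# autoencoder training


def train_reference_autoencoder(X: np.ndarray, spec: AutoencoderSpec):
    """Train the reference network; return (embedding, loss report)."""
    net = Autoencoder(spec.input_dim, spec.hidden_widths, spec.latent_dim,
                      spec.input_dropout_rate, spec.seed, spec.learning_rate)
    history = net.fit(X, spec.epochs, spec.batch_size)
    z1 = net.encode(X)
    return LatentEmbedding(z1, "reference", "reference"), history, net


def train_linked_autoencoder(X_small: np.ndarray, z1: LatentEmbedding,
                             spec: AutoencoderSpec, lam: float = 100.0):
    """Train the linked network against a frozen reference latent space."""
    if z1.coordinates.shape[1] != spec.latent_dim:
        raise ValidationError("latent dimensions of z1 and the spec differ")
    if X_small.shape[0] != z1.coordinates.shape[0]:
        raise ValidationError("cell counts of X_small and z1 differ")
    net = Autoencoder(spec.input_dim, spec.hidden_widths, spec.latent_dim,
                      spec.input_dropout_rate, spec.seed, spec.learning_rate)
    history = net.fit(X_small, spec.epochs, spec.batch_size,
                      z_target=z1.coordinates, lam=lam)
    z2 = net.encode(X_small)
    return LatentEmbedding(z2, "linked", "linked"), history, net


# ---------------------------------------------------------------------------
# resolution index


def node_resolution_index(taxonomy: Taxonomy) -> dict:
    """RI(v) = 1 − height(v)/height(root) for every node of the tree."""
    hroot = taxonomy.root_height
    if hroot <= 0:
        raise ValidationError("degenerate taxonomy: root height must be > 0")
    return {node: 1.0 - taxonomy.height(node) / hroot
            for node in taxonomy.tree.preorder_node_iter()}


def _node_name(taxonomy: Taxonomy, node) -> str:
    if node.is_leaf():
        return node.taxon.label
    if node is taxonomy.root:
        return "<root>"
    return node.label or "|".join(sorted(taxonomy.leaves_under(node)))


def hierarchical_ri_classify(z: LatentEmbedding | np.ndarray,
                             labels: np.ndarray, taxonomy: Taxonomy,
                             k: int = 13, qda_ridge: float = 1e-4,
                             seed: int = 0) -> RIResult:
    """Iterative QDA over successively merged taxonomy labels.

    Per cross-validation fold, a QDA classifier is fit on the training
    cells at the leaf level; correctly predicted test cells receive
    RI = 1.  Internal nodes are then collapsed one at a time in
    ascending height order (finest merges first, deterministic
    tie-break); after each merge the classifier is refit and the
    still-misclassified cells that now land on the correct (merged)
    label receive that node's RI.  Cells wrong even when only the two
    class labels remain receive RI = 0.
    """
    X = z.coordinates if isinstance(z, LatentEmbedding) else np.asarray(z)
    labels = np.asarray(labels)
    if X.shape[0] != labels.shape[0]:
        raise ValidationError("embedding and labels differ in length")
    leaf_set = set(taxonomy.leaf_names)
    unknown = set(labels) - leaf_set
    if unknown:
        raise ValidationError(f"labels not in taxonomy: {sorted(unknown)[:5]}")

    node_ri_map = node_resolution_index(taxonomy)
    merge_nodes = [n for n in taxonomy.internal_nodes_ascending()
                   if n is not taxonomy.root]

    counts = pd.Series(labels).value_counts()
    if k > 1 and counts.min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(X, labels)
    elif k > 1:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(X)
    else:
        raise ValidationError("need k ≥ 2 folds")

    ri = np.full(X.shape[0], np.nan)
    fold_assign = np.full(X.shape[0], -1, dtype=int)

    def fit_predict(train_idx, lbl_train, test_X):
        # QDA needs ≥2 training cells per class to form a covariance;
        # drop singleton-label training cells (their label re-enters the
        # fit once merged into a larger node)
        counts_tr = pd.Series(lbl_train).value_counts()
        ok = counts_tr[lbl_train].to_numpy() >= 2
        qda = QuadraticDiscriminantAnalysis(reg_param=qda_ridge)
        qda.fit(X[train_idx][ok], lbl_train[ok])
        return qda.predict(test_X)

    for fold_no, (train_idx, test_idx) in enumerate(splits):
        fold_assign[test_idx] = fold_no
        current = {leaf: leaf for leaf in leaf_set}  # leaf -> merged label
        label_node = {leaf: None for leaf in leaf_set}

        def merged(arr):
            return np.array([current[l] for l in arr])

        train_lbl = merged(labels[train_idx])
        pred = fit_predict(train_idx, train_lbl, X[test_idx])
        correct = pred == merged(labels[test_idx])
        ri[test_idx[correct]] = 1.0
        unresolved = test_idx[~correct]

        for node in merge_nodes:
            if unresolved.size == 0:
                break
            name = _node_name(taxonomy, node)
            node_value = node_ri_map[node]
            for leaf in taxonomy.leaves_under(node):
                current[leaf] = name
                label_node[leaf] = node
            train_lbl = merged(labels[train_idx])
            if len(set(train_lbl)) < 2:
                break
            pred = fit_predict(train_idx, train_lbl, X[unresolved])
            truth = merged(labels[unresolved])
            now_correct = pred == truth
            for cell, ok, lbl in zip(unresolved, now_correct, truth):
                if ok:
                    # RI of the node whose label the cell now carries
                    leaf = labels[cell]
                    node_of_label = label_node[leaf]
                    ri[cell] = (node_ri_map[node_of_label]
                                if node_of_label is not None else 1.0)
            unresolved = unresolved[~now_correct]
        ri[unresolved] = 0.0

    named_ri = {_node_name(taxonomy, n): v for n, v in node_ri_map.items()
                if not n.is_leaf()}
    return RIResult(ri=ri, fold=fold_assign, node_ri=named_ri)


# ---------------------------------------------------------------------------
# gene-set comparison


def benchmark_gene_set(m: ExpressionMatrix, genes: list[str],
                       z1: LatentEmbedding, labels: np.ndarray,
                       taxonomy: Taxonomy, lam: float = 100.0,
                       spec: AutoencoderSpec | None = None,
                       k: int = 13, seed: int = 0,
                       preprocessing: str = "log1p+standardize") -> RIResult:
    """Full small-set pipeline: link → embed → iterative QDA → RI."""
    Xs = preprocess(m, genes, preprocessing)
    sp = spec or linked_spec(len(genes), latent_dim=z1.coordinates.shape[1],
                             seed=seed)
    z2, _, _ = train_linked_autoencoder(Xs, z1, sp, lam=lam)
    return hierarchical_ri_classify(z2, labels, taxonomy, k=k, seed=seed)


def compare_gene_sets(results: dict[str, list[float]],
                      n_bootstrap: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Summarize mean-RI replicates per gene set and pairwise bootstrap p.

    ``results`` maps a set name to the mean-RI values of its replicate
    runs.  For each ordered pair (a, b) the reported p-value is the
    bootstrap probability that mean(a) ≤ mean(b); when a set has a
    single replicate the comparison degenerates to the empirical rank
    p = (1 + #{b ≥ a}) / (n_b + 1).
    """
    rng = np.random.default_rng(seed)
    rows = []
    names = list(results)
    for name in names:
        vals = np.asarray(results[name], dtype=float)
        rows.append({
            "gene_set": name, "n_replicates": vals.size,
            "mean_ri": float(vals.mean()),
            "sd_ri": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
        })
    summary = pd.DataFrame(rows).set_index("gene_set")
    pvals = {}
    for a in names:
        for b in names:
            if a == b:
                continue
            va = np.asarray(results[a], dtype=float)
            vb = np.asarray(results[b], dtype=float)
            if va.size == 1 or vb.size == 1:
                single, many = (va, vb) if va.size == 1 else (vb, va)
                if va.size == 1:
                    p = (1 + int((many >= single[0]).sum())) / (many.size + 1)
                else:
                    p = (1 + int((many <= single[0]).sum())) / (many.size + 1)
            else:
                diffs = np.empty(n_bootstrap)
                for i in range(n_bootstrap):
                    diffs[i] = (rng.choice(va, va.size).mean()
                                - rng.choice(vb, vb.size).mean())
                p = float((diffs <= 0).mean())
            pvals[(a, b)] = float(p)
    summary.attrs["pairwise_p"] = pvals
    return summary
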