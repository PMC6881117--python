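"""npnets: dense intracortical neuropeptide network prediction from scRNA-seq.

Peak-expression statistics and gene selection for neuropeptide
precursor (NPP) and neuropeptide-selective GPCR (NP-GPCR) genes,
cross-area conservation analyses, a gene-subset cell-type
classification benchmark (linked autoencoders + hierarchical QDA +
resolution index), and type-level peptidergic coupling-matrix
prediction with Gα-family aggregation.
"""

from importlib import resources

from .datamodel import (
    CellAnnotation,
    ExpressionMatrix,
    NPGeneTable,
    Taxonomy,
    counts_to_cpm,
    read_annotation,
    read_expression,
    read_np_gene_table,
    read_taxonomy,
    write_annotation,
    write_expression,
    write_np_gene_table,
    write_taxonomy,
)
from .synthetic import (
    SynthConfig,
    generate_dataset,
    generate_np_gene_table,
    generate_taxonomy,
)
from .expression_stats import (
    PeakExpressionTable,
    TypeExpressionMatrix,
    area_conservation,
    coexpression_counts,
    cognate_pair_coexpression,
    detection_fraction,
    expression_curves,
    peak_expression,
    peak_rank_table,
    type_mean_expression,
)
from .gene_selection import (
    CognatePair,
    build_cognate_pairs,
    fraction_of_type_pairs,
    pairs_table,
    peak_table_from_annotation,
    screen_candidates_by_type_median,
    select_np_genes,
    selection_report,
)
from .latent import (
    AutoencoderSpec,
    LatentEmbedding,
    RIResult,
    benchmark_gene_set,
    compare_gene_sets,
    hierarchical_ri_classify,
    linked_spec,
    node_resolution_index,
    preprocess,
    select_gene_sets,
    train_linked_autoencoder,
    train_reference_autoencoder,
)
from .coupling import (
    AggregateChannels,
    CouplingMatrix,
    aggregate_by_galpha,
    coupling_matrix,
    export_adjacency,
    pool_coupling_by_subclass,
    pool_profile_by_subclass,
)

__version__ = "0.1.0"


def load_np_gene_annotation() -> NPGeneTable:
    """The shipped cortical NP gene annotation (18 NPPs, 29 NP-GPCRs)."""
    ref = resources.files("npnets").joinpath("data/np_gene_table.tsv")
    with resources.as_file(ref) as path:
        return read_np_gene_table(path)
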