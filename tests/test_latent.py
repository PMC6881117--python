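"""Autoencoder embedding, gene sets, and the resolution-index classifier."""

import numpy as np
import pytest

from npnets.datamodel import ExpressionMatrix, ValidationError
from npnets.latent import (
    AutoencoderSpec,
    LatentEmbedding,
    compare_gene_sets,
    hierarchical_ri_classify,
    linked_spec,
    node_resolution_index,
    preprocess,
    select_gene_sets,
    train_linked_autoencoder,
    train_reference_autoencoder,
)
from npnets.synthetic import SynthConfig, generate_taxonomy


def matrix(values: np.ndarray) -> ExpressionMatrix:
    return ExpressionMatrix(values.astype(float), "CPM",
                            [f"c{i}" for i in range(values.shape[0])],
                            [f"g{j}" for j in range(values.shape[1])])


class TestSpecs:
    def test_reference_defaults(self):
        sp = AutoencoderSpec(input_dim=100)
        assert sp.hidden_widths == (100,) * 4
        assert sp.input_dropout_rate == 0.8
        assert sp.latent_dim == 5
        assert sp.batch_size == 956

    def test_linked_defaults(self):
        sp = linked_spec(47)
        assert sp.hidden_widths == (50,) * 4
        assert sp.input_dropout_rate == 0.0

    def test_wrong_depth_rejected(self):
        with pytest.raises(ValidationError):
            AutoencoderSpec(input_dim=10, hidden_widths=(10, 10))

    def test_tiny_latent_rejected(self):
        with pytest.raises(ValidationError):
            AutoencoderSpec(input_dim=10, latent_dim=1)


class TestPreprocess:
    def test_standardized_columns(self, rng):
        m = matrix(rng.lognormal(3, 2, size=(200, 5)))
        X = preprocess(m, m.gene_ids)
        np.testing.assert_allclose(X.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(X.std(axis=0), 1, rtol=1e-10)

    def test_constant_gene_stays_finite(self):
        m = matrix(np.ones((10, 2)))
        X = preprocess(m, m.gene_ids)
        assert np.isfinite(X).all()

    def test_log1p_mode(self):
        m = matrix(np.array([[9.0], [99.0]]))
        X = preprocess(m, m.gene_ids, "log1p")
        np.testing.assert_allclose(X.ravel(), [1.0, 2.0])

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            preprocess(matrix(np.ones((2, 1))), ["g0"], "bogus")


class TestSelectGeneSets:
    def test_he_top_by_max(self, rng):
        vals = rng.uniform(0, 1, size=(50, 20))
        vals[:, 7] *= 1000
        m = matrix(vals)
        assert select_gene_sets(m, "HE", n=1) == ["g7"]

    def test_rand47_deterministic_and_disjoint_seeds(self, small_dataset):
        cpm, _, _ = small_dataset
        a = select_gene_sets(cpm, "Rand47", n=20, seed=3)
        b = select_gene_sets(cpm, "Rand47", n=20, seed=3)
        c = select_gene_sets(cpm, "Rand47", n=20, seed=4)
        assert a == b
        assert a != c
        assert len(set(a)) == 20

    def test_de_prefers_marker_gene(self, small_dataset, small_taxonomy):
        cpm, _, ann = small_dataset
        de = select_gene_sets(cpm, "DE", n=10, ann=ann,
                              taxonomy=small_taxonomy)
        assert len(de) == 10

    def test_de47_subset_of_de_pool(self, small_dataset, small_taxonomy):
        cpm, _, ann = small_dataset
        de = select_gene_sets(cpm, "DE", n=40, ann=ann,
                              taxonomy=small_taxonomy)
        de47 = select_gene_sets(cpm, "DE47", n=10, ann=ann,
                                taxonomy=small_taxonomy)
        assert set(de47) <= set(de)

    def test_expression_matched_distribution(self, small_dataset):
        cpm, _, _ = small_dataset
        ref = select_gene_sets(cpm, "HE", n=15)
        match = select_gene_sets(cpm, "Rand47_ExpMatched", n=15,
                                 reference=ref, seed=0)
        assert len(match) == 15
        assert not set(match) & set(ref)
        logmax = np.log10(cpm.values.max(axis=0) + 1)
        gi = {g: i for i, g in enumerate(cpm.gene_ids)}
        mu_ref = np.mean([logmax[gi[g]] for g in ref])
        mu_match = np.mean([logmax[gi[g]] for g in match])
        mu_all = logmax.mean()
        # matched draw is closer to the reference mean than a typical gene
        assert abs(mu_match - mu_ref) < abs(mu_all - mu_ref)

    def test_too_many_genes_rejected(self, small_dataset):
        with pytest.raises(ValidationError):
            select_gene_sets(small_dataset[0], "HE", n=10**6)


class TestAutoencoders:
    def test_reference_trains_and_loss_decreases(self, rng):
        X = rng.normal(size=(300, 20))
        X[:, 10:] = X[:, :10] + 0.1 * rng.normal(size=(300, 10))
        sp = AutoencoderSpec(input_dim=20, hidden_widths=(16,) * 4,
                             latent_dim=3, input_dropout_rate=0.3,
                             epochs=40, batch_size=100, seed=0)
        z1, hist, _ = train_reference_autoencoder(X, sp)
        assert z1.coordinates.shape == (300, 3)
        assert hist[-1]["R"] < hist[0]["R"]

    def test_embedding_deterministic(self, rng):
        X = rng.normal(size=(120, 8))
        sp = AutoencoderSpec(input_dim=8, hidden_widths=(8,) * 4,
                             latent_dim=2, epochs=10, batch_size=60, seed=1)
        z_a, _, _ = train_reference_autoencoder(X, sp)
        z_b, _, _ = train_reference_autoencoder(X, sp)
        np.testing.assert_array_equal(z_a.coordinates, z_b.coordinates)

    def test_linked_matches_reference_latent(self, rng):
        # the linked net sees the same signal; with λ=100 its latent
        # space should correlate strongly with the reference one
        n = 400
        s = rng.normal(size=(n, 2))
        X1 = np.column_stack([s @ rng.normal(size=(2, 10))])
        X2 = s @ rng.normal(size=(2, 6))
        sp1 = AutoencoderSpec(input_dim=10, hidden_widths=(16,) * 4,
                              latent_dim=2, input_dropout_rate=0.2,
                              epochs=80, batch_size=200, seed=0)
        z1, _, _ = train_reference_autoencoder(X1, sp1)
        sp2 = linked_spec(6, width=16, latent_dim=2, epochs=80,
                          batch_size=200, seed=0)
        z2, hist, _ = train_linked_autoencoder(X2, z1, sp2, lam=100.0)
        mse = np.mean((z2.coordinates - z1.coordinates) ** 2)
        var = z1.coordinates.var()
        assert mse < 0.5 * var
        assert hist[-1]["C"] < hist[0]["C"]

    def test_linked_shape_mismatch_rejected(self, rng):
        z1 = LatentEmbedding(rng.normal(size=(50, 3)), "ref", "reference")
        sp = linked_spec(4, width=8, latent_dim=2, epochs=1, batch_size=25)
        with pytest.raises(ValidationError):
            train_linked_autoencoder(rng.normal(size=(50, 4)), z1, sp)


class TestResolutionIndex:
    def test_node_values(self):
        cfg = SynthConfig(n_types=4, n_subclasses=2, seed=0)
        tax = generate_taxonomy(cfg)
        values = node_resolution_index(tax)
        by_height = sorted(set(values.values()))
        # heights 0,1,2,3 -> RI 1, 2/3, 1/3, 0
        np.testing.assert_allclose(by_height, [0.0, 1 / 3, 2 / 3, 1.0])

    def test_perfect_separation_gives_ri_one(self, rng):
        cfg = SynthConfig(n_types=6, n_subclasses=2, seed=0)
        tax = generate_taxonomy(cfg)
        leaves = tax.leaf_names
        centers = 50 * rng.normal(size=(len(leaves), 3))
        labels = np.repeat(leaves, 30)
        X = centers[np.repeat(np.arange(len(leaves)), 30)] + \
            rng.normal(size=(len(labels), 3))
        res = hierarchical_ri_classify(X, labels, tax, k=5)
        assert res.mean_ri == 1.0

    def test_pure_noise_is_worse_than_separated(self, rng):
        cfg = SynthConfig(n_types=6, n_subclasses=2, seed=0)
        tax = generate_taxonomy(cfg)
        leaves = tax.leaf_names
        labels = np.repeat(leaves, 30)
        X = rng.normal(size=(len(labels), 3))
        res = hierarchical_ri_classify(X, labels, tax, k=5)
        assert res.mean_ri < 0.9

    def test_subclass_level_signal_gives_intermediate_ri(self, rng):
        # cells separable by subclass but identical within it: RI should
        # concentrate at the subclass node value, not 0 or 1
        cfg = SynthConfig(n_types=8, n_subclasses=4, seed=0)
        tax = generate_taxonomy(cfg)
        leaves = tax.leaf_names
        sub_ids = {s: i for i, s in enumerate(tax.subclasses)}
        centers = np.array([[100.0 * sub_ids[tax.subclass_of(l)], 0.0]
                            for l in leaves])
        labels = np.repeat(leaves, 40)
        X = centers[np.repeat(np.arange(len(leaves)), 40)] + \
            rng.normal(size=(len(labels), 2))
        res = hierarchical_ri_classify(X, labels, tax, k=5)
        subclass_ri = 1.0 - 1.0 / tax.root_height
        assert 0.3 < res.mean_ri < 0.95
        # at least half the cells resolve exactly at the subclass node
        assert (np.abs(res.ri - subclass_ri) < 1e-9).mean() > 0.3

    def test_unknown_label_rejected(self, small_taxonomy, rng):
        labels = np.array(["not_a_leaf"] * 10)
        with pytest.raises(ValidationError):
            hierarchical_ri_classify(rng.normal(size=(10, 2)), labels,
                                     small_taxonomy, k=2)

    def test_every_cell_gets_a_fold(self, rng):
        cfg = SynthConfig(n_types=4, n_subclasses=2, seed=0)
        tax = generate_taxonomy(cfg)
        labels = np.repeat(tax.leaf_names, 20)
        X = rng.normal(size=(len(labels), 2))
        res = hierarchical_ri_classify(X, labels, tax, k=4)
        assert (res.fold >= 0).all()
        assert np.isfinite(res.ri).all()


class TestCompareGeneSets:
    def test_summary_means(self):
        df = compare_gene_sets({"A": [0.9, 0.8], "B": [0.5, 0.4]},
                               n_bootstrap=200)
        assert df.loc["A", "mean_ri"] == pytest.approx(0.85)
        assert df.loc["B", "n_replicates"] == 2

    def test_single_vs_many_empirical_p(self):
        rand = [0.5 + 0.001 * i for i in range(99)]
        df = compare_gene_sets({"marker": [0.99], "rand": rand})
        p = df.attrs["pairwise_p"][("marker", "rand")]
        assert p == pytest.approx(1 / 100)

    def test_marker_not_better_gives_large_p(self):
        rand = [0.9] * 19
        df = compare_gene_sets({"marker": [0.5], "rand": rand})
        assert df.attrs["pairwise_p"][("marker", "rand")] == 1.0

    def test_bootstrap_p_obvious_separation(self):
        df = compare_gene_sets({"A": [0.9, 0.91, 0.92], "B": [0.1, 0.11, 0.12]},
                               n_bootstrap=500, seed=0)
        assert df.attrs["pairwise_p"][("A", "B")] == 0.0
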