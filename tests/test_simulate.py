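import numpy as np
import pytest
from scipy import stats

from lcmarray import simulate
from lcmarray.containers import ValidationError


class TestGenerateDesign:
    @pytest.mark.parametrize(
        "tissues,fractions,conditions,reps,expected",
        [
            (2, 2, ("GF", "CR"), 5, 40),  # GF/CR experiment
            (1, 1, ("GF", "CR"), 2, 4),  # minimal crossed design
            (2, 2, ("0", "1", "3", "5", "7"), 3, 60),  # colonization course
        ],
    )
    def test_sample_counts(self, tissues, fractions, conditions, reps, expected):
        design = simulate.generate_design(
            [f"t{i}" for i in range(tissues)],
            [f"f{i}" for i in range(fractions)],
            conditions,
            reps,
        )
        assert design.n_samples == expected
        assert len(design.sample_ids()) == expected

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            simulate.generate_design(("ileum", "ileum"), ("tip",), ("GF", "CR"), 2)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValidationError):
            simulate.generate_design(("ileum",), ("tip",), ("GF", "CR"), 1)

    def test_deterministic(self):
        a = simulate.generate_design(("i",), ("t",), ("GF", "CR"), 3, seed=5)
        b = simulate.generate_design(("i",), ("t",), ("GF", "CR"), 3, seed=5)
        assert a == b


class TestSimulateExpression:
    def test_regulated_fractions_match_rates(self, gfcr_design):
        matrix, truth = simulate.simulate_expression(
            gfcr_design, n_genes=20000, fraction_specific_rate=0.086,
            shared_rate=0.014, seed=3,
        )
        n_specific = sum(
            len(v) for k, v in truth.regulated_genes.items() if isinstance(k, tuple)
        )
        n_shared = len(truth.regulated_genes["shared"])
        assert n_specific + n_shared == pytest.approx(2000, abs=2)
        assert n_specific / (n_specific + n_shared) == pytest.approx(0.86, abs=0.01)
        assert matrix.data.shape == (20000, 40)

    def test_zero_rates_give_empty_truth(self, gfcr_design):
        _, truth = simulate.simulate_expression(
            gfcr_design, n_genes=500, fraction_specific_rate=0.0, shared_rate=0.0,
            seed=0,
        )
        assert truth.all_regulated() == set()

    def test_bit_identical_under_same_seed(self, gfcr_design):
        m1, _ = simulate.simulate_expression(gfcr_design, n_genes=300, seed=7)
        m2, _ = simulate.simulate_expression(gfcr_design, n_genes=300, seed=7)
        assert np.array_equal(m1.values, m2.values)
        m3, _ = simulate.simulate_expression(gfcr_design, n_genes=300, seed=8)
        assert not np.array_equal(m1.values, m3.values)

    def test_null_gene_group_means_scale_with_noise(self, gfcr_design):
        # effect_size_mean=0: per-group means deviate from baseline by
        # O(noise_sd / sqrt(n)); check the spread matches the theory
        matrix, truth = simulate.simulate_expression(
            gfcr_design, n_genes=1000, effect_size_mean=0.0, noise_sd=1.0,
            seed=9, fraction_offset_sd=0.0, tissue_offset_sd=0.0,
        )
        ann = gfcr_design.annotation()
        samples = ann.samples_where(tissue="ileum", fraction="tip", condition="GF")
        group_means = matrix.data[samples].mean(axis=1)
        other = ann.samples_where(tissue="ileum", fraction="tip", condition="CR")
        diffs = group_means - matrix.data[other].mean(axis=1)
        # difference of two 5-replicate means: sd = sqrt(2/5)
        assert diffs.std() == pytest.approx(np.sqrt(2 / 5), rel=0.15)

    def test_null_pvalues_uniform(self, gfcr_design):
        matrix, _ = simulate.simulate_expression(
            gfcr_design, n_genes=5000, fraction_specific_rate=0.0,
            shared_rate=0.0, seed=10, fraction_offset_sd=0.0, tissue_offset_sd=0.0,
        )
        ann = gfcr_design.annotation()
        a = matrix.data[ann.samples_where(tissue="ileum", fraction="tip",
                                          condition="CR")].to_numpy()
        b = matrix.data[ann.samples_where(tissue="ileum", fraction="tip",
                                          condition="GF")].to_numpy()
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_invalid_parameters_rejected(self, gfcr_design):
        with pytest.raises(ValidationError):
            simulate.simulate_expression(gfcr_design, n_genes=50, seed=0)
        with pytest.raises(ValidationError):
            simulate.simulate_expression(gfcr_design, n_genes=200, noise_sd=0.0)
        with pytest.raises(ValidationError):
            simulate.simulate_expression(
                gfcr_design, n_genes=200, fraction_specific_rate=0.9,
                shared_rate=0.2,
            )


class TestSimulateTimecourse:
    def test_noiseless_profiles_equal_archetype_shape(self, timecourse_design):
        gfcr = simulate.generate_design(
            ("ileum", "colon"), ("tip", "crypt"), ("GF", "CR"), 5, seed=0
        )
        _, truth = simulate.simulate_expression(gfcr, n_genes=300, seed=4)
        genes = [f"g{i:03d}" for i in range(1, 301)]
        matrix = simulate.simulate_timecourse(
            timecourse_design, truth, genes, noise_sd=0.0, seed=4,
            fraction_offset_sd=0.0, tissue_offset_sd=0.0,
        )
        ann = timecourse_design.annotation()
        assigned = truth.cluster_assignments[("ileum", "tip")]
        shapes = simulate.default_archetype_shapes(("0", "1", "3", "5", "7"), 3)
        for gene, archetype in list(assigned.items())[:10]:
            day_means = [
                matrix.data.loc[gene, ann.samples_where(
                    tissue="ileum", fraction="tip", condition=d)].mean()
                for d in ("0", "1", "3", "5", "7")
            ]
            rel = np.array(day_means) - day_means[0]
            expected = shapes[archetype] - shapes[archetype][0]
            assert np.allclose(rel, expected, atol=1e-10)

    def test_colon_steps_earlier_than_ileum(self):
        shapes_ileum = simulate.default_archetype_shapes(("0", "1", "3", "5", "7"), 3)
        shapes_colon = simulate.default_archetype_shapes(("0", "1", "3", "5", "7"), 1)
        # archetype 1: ileum jumps between day 3 and 5, colon between 1 and 3
        assert shapes_ileum[1][2] == 0.0 and shapes_ileum[1][3] == 2.0
        assert shapes_colon[1][1] == 0.0 and shapes_colon[1][2] == 2.0

    def test_flat_genes_pass_anova_at_nominal_rate(self, timecourse_design):
        from lcmarray.clustering import anova_gate

        gfcr = simulate.generate_design(
            ("ileum",), ("tip",), ("GF", "CR"), 5, seed=0
        )
        _, truth = simulate.simulate_expression(
            gfcr, n_genes=2000, fraction_specific_rate=0.0, shared_rate=0.0,
            seed=6,
        )
        design = simulate.generate_design(
            ("ileum",), ("tip",), ("0", "1", "3", "5", "7"), 3, seed=0
        )
        genes = [f"g{i:04d}" for i in range(1, 2001)]
        matrix = simulate.simulate_timecourse(design, truth, genes,
                                              noise_sd=0.3, seed=6)
        gate = anova_gate(matrix, design.annotation(), alpha=0.05)
        # ~95% of null genes survive a raw alpha=0.05 test
        frac_kept = (gate.table["p_raw"] >= 0.05).mean()
        assert frac_kept == pytest.approx(0.95, abs=0.02)

    def test_missing_archetype_shape_rejected(self, timecourse_design):
        gfcr = simulate.generate_design(
            ("ileum", "colon"), ("tip", "crypt"), ("GF", "CR"), 5, seed=0
        )
        _, truth = simulate.simulate_expression(gfcr, n_genes=200, seed=1)
        genes = [f"g{i:03d}" for i in range(1, 201)]
        with pytest.raises(ValidationError, match="archetype"):
            simulate.simulate_timecourse(
                timecourse_design, truth, genes,
                archetype_shapes={"ileum": {1: np.zeros(5)}}, seed=0,
            )


class TestGenerateGeneSets:
    def test_strength_one_terms_subset_of_regulated(self, small_synthetic):
        matrix, truth = small_synthetic
        collection = simulate.generate_gene_sets(
            matrix.gene_ids, truth, n_terms=30, term_size_range=(10, 40),
            enrichment_strength=1.0, seed=1,
        )
        for combo, terms in truth.enriched_terms.items():
            regulated = truth.regulated_in(*combo)
            for term in terms:
                assert collection[term][1] <= regulated

    def test_strength_zero_overlap_hypergeometric(self, small_synthetic):
        matrix, truth = small_synthetic
        collection = simulate.generate_gene_sets(
            matrix.gene_ids, truth, n_terms=300, term_size_range=(50, 50),
            enrichment_strength=0.0, n_enriched_per_fraction=0, seed=2,
        )
        regulated = truth.regulated_in("ileum", "tip")
        overlaps = [
            len(genes & regulated) for _, (_, genes) in collection.items()
        ]
        N, K, n = len(matrix.gene_ids), len(regulated), 50
        expected_mean = n * K / N
        assert np.mean(overlaps) == pytest.approx(expected_mean, rel=0.2)
        # chi-square goodness of fit against the hypergeometric pmf
        ks = np.arange(0, max(overlaps) + 1)
        pmf = stats.hypergeom.pmf(ks, N, K, n)
        observed = np.bincount(overlaps, minlength=len(ks))
        mask = pmf * len(overlaps) >= 1
        chi2 = ((observed[mask] - len(overlaps) * pmf[mask]) ** 2
                / (len(overlaps) * pmf[mask])).sum()
        assert stats.chi2.sf(chi2, mask.sum() - 1) > 0.001

    def test_sizes_respect_member_floor(self, small_synthetic):
        matrix, truth = small_synthetic
        collection = simulate.generate_gene_sets(
            matrix.gene_ids, truth, n_terms=100, term_size_range=(6, 200), seed=3,
        )
        assert all(len(genes) > 5 for _, (_, genes) in collection.items())

    def test_bad_params_rejected(self, small_synthetic):
        matrix, truth = small_synthetic
        with pytest.raises(ValidationError):
            simulate.generate_gene_sets(matrix.gene_ids, truth, n_terms=0)


class TestSimulateQpcr:
    def test_replicate_counts_match_design(self):
        design = simulate.generate_design(
            ("ileum", "colon"), ("tip", "crypt"), ("GF", "CR"), 4, seed=0
        )
        plate = simulate.simulate_qpcr(design, {"tgt": 2.0}, seed=0)
        counts = plate[plate["gene"] == "tgt"].groupby(
            ["tissue", "fraction", "status"]
        ).size()
        assert (counts == 4).all()

    def test_fold_one_recovers_unity(self):
        from lcmarray.qpcr import delta_delta_ct

        design = simulate.generate_design(("ileum",), ("tip",), ("GF", "CR"), 5,
                                          seed=0)
        folds = []
        for s in range(200):
            plate = simulate.simulate_qpcr(design, {"tgt": 1.0}, noise_sd=0.1,
                                           seed=s)
            rel = delta_delta_ct(plate, "tgt", "L32")
            folds.append(rel[rel["status"] == "CR"]["fold"].mean())
        assert np.mean(folds) == pytest.approx(1.0, abs=0.02)

    def test_nonpositive_fold_rejected(self, gfcr_design):
        with pytest.raises(ValidationError):
            simulate.simulate_qpcr(gfcr_design, {"tgt": 0.0})


def test_child_rng_streams_are_independent_and_reproducible():
    a1 = simulate.child_rng(3, "expression").normal(size=5)
    a2 = simulate.child_rng(3, "expression").normal(size=5)
    b = simulate.child_rng(3, "timecourse").normal(size=5)
    assert np.array_equal(a1, a2)
    assert not np.array_equal(a1, b)
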