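import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from lcmarray import clustering, simulate
from lcmarray.clustering import (
    anova_gate,
    cluster_profiles,
    consensus_cluster,
    day_profiles,
    hierarchical_cluster,
    pearson_distance,
)
from lcmarray.containers import ValidationError


class TestPearsonDistance:
    def test_identical_and_anticorrelated(self):
        X = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        D = pearson_distance(X)
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert D[0, 2] == pytest.approx(2.0, abs=1e-12)
        assert np.allclose(np.diag(D), 0.0)
        assert np.allclose(D, D.T)

    def test_hand_computed_value(self):
        # r((1,2,3),(1,2,4)) = 0.98198..., distance = 0.018019...
        D = pearson_distance(np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 4.0]]))
        r = stats.pearsonr([1, 2, 3], [1, 2, 4]).statistic
        assert D[0, 1] == pytest.approx(1 - r, abs=1e-12)
        assert D[0, 1] == pytest.approx(0.01801949, abs=1e-7)

    def test_constant_profile_named(self):
        with pytest.raises(ValidationError, match="flatgene"):
            pearson_distance(
                np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]),
                labels=["flatgene", "ok"],
            )


def average_linkage_oracle(D):
    """O(n^3) brute-force average linkage over a distance matrix.

    Returns merge heights in order, for comparison with scipy's tree.
    """
    D = D.copy().astype(float)
    clusters = {i: [i] for i in range(D.shape[0])}
    heights = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                d = np.mean(
                    [D[i, j] for i in clusters[a] for j in clusters[b]]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return np.array(heights)


class TestHierarchical:
    def test_two_items_single_merge(self):
        D = np.array([[0.0, 0.3], [0.3, 0.0]])
        dendro = hierarchical_cluster(D, ["a", "b"])
        assert dendro.linkage_matrix.shape == (1, 4)
        assert dendro.linkage_matrix[0, 2] == pytest.approx(0.3)

    def test_forced_merge_order(self):
        D = np.array([[0.0, 0.1, 1.0], [0.1, 0.0, 1.0], [1.0, 1.0, 0.0]])
        dendro = hierarchical_cluster(D, ["A", "B", "C"])
        # (A,B) merge first at 0.1
        assert set(dendro.linkage_matrix[0, :2].astype(int)) == {0, 1}
        assert dendro.cut(2) == {"A": 1, "B": 1, "C": 2}

    def test_matches_bruteforce_oracle_on_random_matrices(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            X = rng.normal(size=(8, 12))
            D = pearson_distance(X)
            dendro = hierarchical_cluster(D, list("abcdefgh"))
            assert np.allclose(
                np.sort(dendro.linkage_matrix[:, 2]),
                np.sort(average_linkage_oracle(D)),
                atol=1e-10,
            )

    def test_nan_distance_rejected(self):
        D = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValidationError):
            hierarchical_cluster(D, ["a", "b"])


def _tc_matrix(n_genes, noise_sd, seed, with_truth=False, n_genes_design=None):
    design = simulate.generate_design(
        ("ileum",), ("tip",), ("0", "1", "3", "5", "7"), 3, seed=0
    )
    gfcr = simulate.generate_design(("ileum",), ("tip",), ("GF", "CR"), 5, seed=0)
    _, truth = simulate.simulate_expression(gfcr, n_genes=n_genes, seed=seed,
                                            fraction_specific_rate=0.2,
                                            shared_rate=0.0)
    genes = [f"g{str(i).zfill(len(str(n_genes)))}" for i in range(1, n_genes + 1)]
    matrix = simulate.simulate_timecourse(
        design, truth, genes, noise_sd=noise_sd, seed=seed
    )
    return design, truth, matrix


class TestAnovaGate:
    def test_flat_genes_uniform_p(self):
        design, truth, matrix = _tc_matrix(5000, noise_sd=0.3, seed=2)
        gate = anova_gate(matrix, design.annotation())
        flat = [g for g in matrix.gene_ids
                if g not in truth.cluster_assignments[("ileum", "tip")]]
        p = gate.table.loc[flat, "p_raw"].to_numpy()
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_two_groups_F_equals_t_squared(self):
        rng = np.random.default_rng(3)
        design = simulate.generate_design(("ileum",), ("tip",), ("0", "7"), 5, seed=0)
        from lcmarray.containers import ExpressionMatrix

        data = pd.DataFrame(
            rng.normal(size=(100, 10)),
            index=[f"g{i}" for i in range(100)],
            columns=design.sample_ids(),
        )
        matrix = ExpressionMatrix(data)
        gate = anova_gate(matrix, design.annotation())
        t, _ = stats.ttest_ind(data.values[:, :5], data.values[:, 5:], axis=1)
        assert np.allclose(gate.table["F"], t**2, rtol=1e-10)

    def test_step_gene_power_matches_noncentral_f(self):
        # 2-unit step, sd 0.5, 3 replicates/day: Monte-Carlo detection rate
        # at raw alpha 0.001 must match the exact noncentral-F power
        rng = np.random.default_rng(4)
        design = simulate.generate_design(
            ("ileum",), ("tip",), ("0", "1", "3", "5", "7"), 3, seed=0
        )
        from lcmarray.containers import ExpressionMatrix

        shape = np.array([0.0, 0.0, 0.0, 2.0, 2.0])
        sd, reps, n = 0.5, 3, 2000
        step = np.repeat(shape, reps)
        data = pd.DataFrame(
            step + rng.normal(0, sd, size=(n, 15)),
            index=[f"g{i}" for i in range(n)],
            columns=design.sample_ids(),
        )
        gate = anova_gate(ExpressionMatrix(data), design.annotation())
        rate = (gate.table["p_raw"] < 0.001).mean()
        lam = reps * np.sum((shape - shape.mean()) ** 2) / sd**2
        crit = stats.f.isf(0.001, 4, 10)
        power = stats.ncf.sf(crit, 4, 10, lam)
        tol = 3 * np.sqrt(power * (1 - power) / n)
        assert rate == pytest.approx(power, abs=tol)

    def test_single_replicate_day_rejected(self):
        design = simulate.generate_design(("ileum",), ("tip",), ("0", "7"), 2, seed=0)
        from lcmarray.containers import ExpressionMatrix, SampleAnnotation

        ann = design.annotation()
        keep = ann.sample_ids[:-1]  # drop one replicate of the last day
        sub = SampleAnnotation(ann.table.loc[keep])
        data = pd.DataFrame(
            np.random.default_rng(0).normal(size=(10, len(keep))),
            index=[f"g{i}" for i in range(10)], columns=keep,
        )
        with pytest.raises(ValidationError, match="replicate"):
            anova_gate(ExpressionMatrix(data), sub)


class TestConsensusClustering:
    def test_point_mass_clusters_give_binary_consensus(self):
        # two exactly separated shapes: consensus must be a {0,1} block matrix
        up = np.array([0.0, 0.0, 1.0, 1.0, 1.0])
        down = -up
        rows, labels = [], []
        for i in range(15):
            rows.append(up + 1e-3 * np.sin(i + np.arange(5)))  # tiny jitter, same shape
            labels.append(1)
        for i in range(15):
            rows.append(down + 1e-3 * np.cos(i + np.arange(5)))
            labels.append(2)
        profiles = pd.DataFrame(rows, index=[f"g{i}" for i in range(30)])
        result = consensus_cluster(profiles, k_range=range(2, 4), n_resamples=40,
                                   seed=0)
        C = result.consensus[2]
        assert set(np.round(np.unique(C), 6)) <= {0.0, 1.0}
        at2 = result.assignment_for(2)
        pred = [at2[f"g{i}"] for i in range(30)]
        assert adjusted_rand_score(labels, pred) == 1.0

    def test_recovers_four_archetypes_and_k(self):
        design, truth, matrix = _tc_matrix(1500, noise_sd=0.1, seed=9)
        ann = design.annotation()
        gate = anova_gate(matrix, ann)
        gated = sorted(gate.gated)
        assert len(gated) >= 100
        profiles = day_profiles(matrix, ann, genes=gated)
        result = consensus_cluster(profiles, k_range=range(2, 7),
                                   n_resamples=100, seed=1)
        assert result.chosen_k == 4
        planted = truth.cluster_assignments[("ileum", "tip")]
        genes = [g for g in result.assignment if g in planted]
        ari = adjusted_rand_score(
            [planted[g] for g in genes], [result.assignment[g] for g in genes]
        )
        assert ari >= 0.9

    def test_permutation_equivariance(self):
        design, truth, matrix = _tc_matrix(400, noise_sd=0.1, seed=5)
        ann = design.annotation()
        gated = sorted(anova_gate(matrix, ann).gated)
        profiles = day_profiles(matrix, ann, genes=gated)
        res = consensus_cluster(profiles, k_range=[2, 3], n_resamples=30, seed=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(profiles))
        res_p = consensus_cluster(profiles.iloc[perm], k_range=[2, 3],
                                  n_resamples=30, seed=3)
        # consensus entries stay in [0,1], symmetric, unit diagonal
        for C in res.consensus.values():
            assert np.all((C >= 0) & (C <= 1))
            assert np.allclose(C, C.T)
            assert np.allclose(np.diag(C), 1.0)
        # cluster structure is invariant under relabeling (same partition)
        genes = list(profiles.index)
        a = [res.assignment[g] for g in genes]
        b = [res_p.assignment[g] for g in genes]
        assert adjusted_rand_score(a, b) == pytest.approx(1.0)

    def test_k_range_validation(self):
        profiles = pd.DataFrame(np.random.default_rng(0).normal(size=(12, 5)))
        with pytest.raises(ValidationError):
            consensus_cluster(profiles, k_range=range(2, 20))


class TestClusterProfiles:
    def test_counts_and_single_gene_sd(self):
        design, truth, matrix = _tc_matrix(400, noise_sd=0.1, seed=6)
        ann = design.annotation()
        assignment = {matrix.gene_ids[0]: 1, matrix.gene_ids[1]: 2,
                      matrix.gene_ids[2]: 2}
        prof = cluster_profiles(assignment, matrix, ann)
        assert set(prof["cluster"]) == {1, 2}
        c1 = prof[prof["cluster"] == 1]
        assert np.allclose(c1["sd"], 0.0)
        assert (prof.groupby("cluster")["n_genes"].first().sum()
                == len(assignment))

    def test_planted_archetype_means_recovered(self):
        design, truth, matrix = _tc_matrix(800, noise_sd=0.1, seed=7)
        ann = design.annotation()
        planted = truth.cluster_assignments[("ileum", "tip")]
        # genes of archetype 1 follow a +2 step between days 3 and 5 (ileum)
        a1 = [g for g, a in planted.items() if a == 1]
        prof = cluster_profiles({g: 1 for g in a1}, matrix, ann)
        day_means = prof.set_index("day")["mean"]
        jump = day_means["5"] - day_means["3"]
        n = len(a1)
        assert jump == pytest.approx(2.0, abs=3 * 0.5 / np.sqrt(n) + 0.1)

    def test_empty_assignment_rejected(self, small_synthetic):
        matrix, _ = small_synthetic
        with pytest.raises(ValidationError):
            cluster_profiles({}, matrix, None)


def test_sample_dendrogram_separates_fraction_then_tissue_then_status():
    """Planted fraction > tissue > status effects are mirrored in the
    cophenetic structure of the sample dendrogram."""
    design = simulate.generate_design(
        ("ileum", "colon"), ("tip", "crypt"), ("GF", "CR"), 3, seed=0
    )
    matrix, _ = simulate.simulate_expression(design, n_genes=3000, seed=21)
    from lcmarray.normalize import quantile_normalize

    matrix = quantile_normalize(matrix)
    D = pearson_distance(matrix.values.T, labels=matrix.sample_ids)
    dendro = hierarchical_cluster(D, matrix.sample_ids)
    ann = design.annotation().table

    def mean_coph(pred):
        vals = []
        ids = list(ann.index)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if pred(ann.loc[a], ann.loc[b]):
                    vals.append(dendro.cophenetic_distance(a, b))
        return np.mean(vals)

    d_status = mean_coph(lambda r, s: r["tissue"] == s["tissue"]
                         and r["fraction"] == s["fraction"]
                         and r["condition"] != s["condition"])
    d_tissue = mean_coph(lambda r, s: r["tissue"] != s["tissue"]
                         and r["fraction"] == s["fraction"])
    d_fraction = mean_coph(lambda r, s: r["fraction"] != s["fraction"])
    assert d_status < d_tissue < d_fraction
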