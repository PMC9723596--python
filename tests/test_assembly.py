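import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from assemblytrace import (
    CommunityTable,
    NullConfig,
    ValidationError,
    beta_mntd,
    beta_nti,
    classify_assembly,
    classify_pairs,
    estimate_niche_optima,
    mantel_correlogram,
    process_contributions,
    raup_crick_bray,
    read_newick,
    simulate_phylogeny,
)
from assemblytrace.data_model import cophenetic_matrix
from conftest import random_count_table


def table_of(rows, taxa=None):
    rows = np.atleast_2d(rows)
    taxa = taxa or [f"t{j}" for j in range(rows.shape[1])]
    return CommunityTable(
        pd.DataFrame(rows, index=[f"s{i}" for i in range(rows.shape[0])], columns=taxa),
        keep_empty_taxa=True,
    )


class TestNicheOptima:
    def test_weighted_mean(self):
        tbl = table_of([[1], [3]], taxa=["A"])
        env = pd.Series({"s0": 0.0, "s1": 4.0})
        assert estimate_niche_optima(tbl, env)["A"] == pytest.approx(3.0)

    def test_single_environment_taxon(self):
        tbl = table_of([[2, 0], [0, 1]], taxa=["A", "B"])
        env = pd.Series({"s0": 5.0, "s1": -1.0})
        assert estimate_niche_optima(tbl, env)["A"] == 5.0

    def test_constant_environment(self):
        rng = np.random.default_rng(0)
        tbl = random_count_table(rng, 4, 6)
        env = pd.Series(2.5, index=tbl.sample_ids)
        optima = estimate_niche_optima(tbl, env)
        assert np.allclose(optima.to_numpy(), 2.5)


class TestMantelCorrelogram:
    @staticmethod
    def _distance_pair(seed, shuffle=False):
        tree = simulate_phylogeny(30, seed=3)
        d_phylo = cophenetic_matrix(tree)
        from assemblytrace import evolve_traits

        traits = evolve_traits(tree, 1.0, seed=seed).loc[list(d_phylo.ids)]
        vals = traits.to_numpy()
        if shuffle:
            vals = np.random.default_rng(seed + 500).permutation(vals)
        d_trait = DistanceMatrix(np.abs(vals[:, None] - vals[None, :]), list(d_phylo.ids))
        return d_trait, d_phylo

    def test_matched_matrices_give_significant_first_class(self):
        hits = 0
        for seed in range(100):
            tree_dm = cophenetic_matrix(simulate_phylogeny(30, seed=3))
            d_trait = tree_dm  # trait distance identical to phylogenetic distance
            res = mantel_correlogram(
                d_trait, tree_dm, n_classes=4, config=NullConfig(n_reps=99, seed=seed)
            )
            first = res.iloc[0]
            hits += (first["mantel_r"] > 0) and (first["p"] <= 0.05)
        assert hits >= 95

    def test_type_one_error_rate_under_shuffled_traits(self):
        false_pos = total = 0
        for seed in range(100):
            d_trait, d_phylo = self._distance_pair(seed, shuffle=True)
            res = mantel_correlogram(
                d_trait, d_phylo, n_classes=4, config=NullConfig(n_reps=99, seed=seed)
            )
            ok = res[~res["flagged"]]
            false_pos += int((ok["p"] <= 0.05).sum())
            total += len(ok)
        assert false_pos / total <= 0.10

    def test_relabeling_invariance(self):
        d_trait, d_phylo = self._distance_pair(1)
        res1 = mantel_correlogram(d_trait, d_phylo, 4, NullConfig(n_reps=49, seed=0))
        perm = np.random.default_rng(9).permutation(len(d_trait.ids))
        ids = [d_trait.ids[i] for i in perm]
        res2 = mantel_correlogram(
            d_trait.filter(ids), d_phylo.filter(ids), 4, NullConfig(n_reps=49, seed=0)
        )
        assert np.allclose(res1["mantel_r"], res2["mantel_r"], equal_nan=True)


def brute_force_bmntd(counts, d, weighted=True):
    """Independent O(n^2) double-loop betaMNTD oracle."""
    n = counts.shape[0]
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            ia = np.flatnonzero(counts[a] > 0)
            ib = np.flatnonzero(counts[b] > 0)
            if weighted:
                wa = counts[a, ia] / counts[a, ia].sum()
            else:
                wa = np.full(ia.size, 1.0 / ia.size)
            total = 0.0
            for t, wt in zip(ia, wa):
                total += wt * min(d[t, u] for u in ib)
            out[a, b] = total
    return 0.5 * (out + out.T)


class TestBetaMNTD:
    def test_hand_example_single_taxa(self, balanced_tree):
        tbl = table_of([[1, 0, 0, 0], [0, 0, 1, 0]], taxa=list("ABCD"))
        assert beta_mntd(tbl, balanced_tree)["s0", "s1"] == pytest.approx(4.0)

    def test_identical_samples_zero(self, balanced_tree):
        tbl = table_of([[1, 2, 0, 1], [1, 2, 0, 1]], taxa=list("ABCD"))
        assert beta_mntd(tbl, balanced_tree)["s0", "s1"] == 0.0

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_brute_force_oracle(self, weighted):
        rng = np.random.default_rng(11)
        for trial in range(5):
            tree = simulate_phylogeny(16, seed=trial)
            dm = cophenetic_matrix(tree)
            tbl = random_count_table(rng, 5, 16)
            tbl = CommunityTable(
                tbl.data.set_axis(list(dm.ids), axis=1), keep_empty_taxa=True
            )
            ours = beta_mntd(tbl, tree, abundance_weighted=weighted).data
            oracle = brute_force_bmntd(tbl.matrix(), dm.data, weighted)
            assert np.allclose(ours, oracle, atol=1e-10)


class TestBetaNTI:
    def test_star_phylogeny_flagged_undefined(self):
        star = read_newick("(" + ",".join(f"x{j}:1" for j in range(6)) + "):0;")
        tbl = table_of([[1, 1, 0, 0, 0, 0], [0, 0, 1, 1, 0, 0]],
                       taxa=[f"x{j}" for j in range(6)])
        z = beta_nti(tbl, star, NullConfig(n_reps=99, seed=0))
        assert np.isnan(z.loc["s0", "s1"])

    def test_same_clade_pairs_are_negative(self):
        # both communities confined to one of the two clades of a
        # two-clade tree: phylogenetically closer than the tip-shuffle null
        def cherry(a, b, stem):
            return f"({a}:0.1,{b}:0.1):{stem}"

        left = ",".join(cherry(f"L{i}a", f"L{i}b", 0.3) for i in range(4))
        right = ",".join(cherry(f"R{i}a", f"R{i}b", 0.3) for i in range(4))
        tree = read_newick(f"(({left}):0.6,({right}):0.6):0;")
        taxa = [t.name for t in tree.tips()]
        left_idx = [i for i, t in enumerate(taxa) if t.startswith("L")]
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rows = np.zeros((2, 16))
            rows[0, rng.choice(left_idx, 4, replace=False)] = 1
            rows[1, rng.choice(left_idx, 4, replace=False)] = 1
            z = beta_nti(
                table_of(rows, taxa=taxa),
                tree,
                NullConfig(n_reps=199, seed=seed, abundance_weighted=False),
            )
            hits += z.loc["s0", "s1"] < 0
        assert hits >= 90

    def test_seeded_determinism_and_relabeling_invariance(self):
        tree = simulate_phylogeny(16, seed=2)
        rng = np.random.default_rng(4)
        tbl = random_count_table(rng, 4, 16)
        tbl = CommunityTable(
            tbl.data.set_axis([t.name for t in tree.tips()], axis=1),
            keep_empty_taxa=True,
        )
        cfg = NullConfig(n_reps=199, seed=5)
        z1 = beta_nti(tbl, tree, cfg)
        z2 = beta_nti(tbl, tree, cfg)
        assert z1.equals(z2)
        # reordering samples permutes the matrix identically
        order = ["s2", "s0", "s3", "s1"]
        z3 = beta_nti(tbl.select_samples(order), tree, cfg)
        assert np.allclose(z3.loc[order, order], z1.loc[order, order], equal_nan=True)

    def test_doubling_counts_leaves_znti_unchanged(self):
        tree = simulate_phylogeny(16, seed=3)
        rng = np.random.default_rng(6)
        tbl = random_count_table(rng, 4, 16)
        taxa = [t.name for t in tree.tips()]
        t1 = CommunityTable(tbl.data.set_axis(taxa, axis=1), keep_empty_taxa=True)
        t2 = CommunityTable(t1.data * 2, keep_empty_taxa=True)
        cfg = NullConfig(n_reps=99, seed=1)
        assert np.allclose(
            beta_nti(t1, tree, cfg), beta_nti(t2, tree, cfg), equal_nan=True
        )

    def test_replicate_count_consistency(self):
        # 999 and 9999 null replicates agree within 3 null standard errors
        tree = simulate_phylogeny(16, seed=8)
        rng = np.random.default_rng(9)
        tbl = random_count_table(rng, 2, 16)
        tbl = CommunityTable(
            tbl.data.set_axis([t.name for t in tree.tips()], axis=1),
            keep_empty_taxa=True,
        )
        z1 = beta_nti(tbl, tree, NullConfig(n_reps=999, seed=0)).iloc[0, 1]
        z2 = beta_nti(tbl, tree, NullConfig(n_reps=9999, seed=1)).iloc[0, 1]
        se = np.sqrt((1 + z1**2 / 2) / 999)
        assert abs(z1 - z2) <= 3 * se

    def test_pair_union_null_variant_runs(self, balanced_tree):
        tbl = table_of([[3, 1, 0, 0], [0, 1, 2, 1]], taxa=list("ABCD"))
        z = beta_nti(tbl, balanced_tree, NullConfig(n_reps=199, seed=0),
                     within_pair_union=True)
        assert z.shape == (2, 2) and z.loc["s0", "s0"] == 0.0


class TestRaupCrick:
    def test_identical_samples_strongly_negative(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pool = random_count_table(rng, 6, 30)
            data = pool.data.copy()
            data.iloc[1] = data.iloc[0]  # make one pair identical
            tbl = CommunityTable(data, keep_empty_taxa=True)
            rc = raup_crick_bray(tbl, NullConfig(n_reps=199, seed=seed))
            hits += rc.loc["s0", "s1"] <= -0.9
        assert hits >= 95

    def test_disjoint_supports_strongly_positive(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed + 1000)
            counts = np.zeros((4, 30))
            counts[0, :10] = rng.integers(1, 50, 10)
            counts[1, 10:20] = rng.integers(1, 50, 10)
            counts[2] = rng.integers(0, 20, 30)
            counts[3] = rng.integers(0, 20, 30)
            counts[2:, 0] += 1
            tbl = table_of(counts)
            rc = raup_crick_bray(tbl, NullConfig(n_reps=199, seed=seed))
            hits += rc.loc["s0", "s1"] >= 0.9
        assert hits >= 90

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(2)
        tbl = random_count_table(rng, 6, 20)
        rc = raup_crick_bray(tbl, NullConfig(n_reps=199, seed=0))
        assert (rc.to_numpy() >= -1).all() and (rc.to_numpy() <= 1).all()
        assert np.allclose(rc.to_numpy(), rc.to_numpy().T)

    def test_single_taxon_pool_rejected(self):
        tbl = table_of([[5], [3]], taxa=["A"])
        with pytest.raises(ValidationError):
            raup_crick_bray(tbl, NullConfig(n_reps=9, seed=0))


class TestClassification:
    @pytest.mark.parametrize(
        "bnti, rc, expected",
        [
            (2.5, 0.0, "variable_selection"),
            (-2.5, 0.0, "homogeneous_selection"),
            (1.0, 0.97, "dispersal_limitation"),
            (0.0, -0.99, "homogenizing_dispersal"),
            (0.0, 0.0, "drift"),
            (2.0, 0.0, "drift"),  # thresholds are strict inequalities
        ],
    )
    def test_threshold_rules(self, bnti, rc, expected):
        assert classify_assembly(bnti, rc) == expected

    def test_undefined_pairs_are_excluded_and_counted(self):
        ids = ["a", "b", "c"]
        bnti = pd.DataFrame(
            [[0, np.nan, 1], [np.nan, 0, 3], [1, 3, 0]], index=ids, columns=ids
        )
        rc = pd.DataFrame(np.zeros((3, 3)), index=ids, columns=ids)
        pairs = classify_pairs(bnti, rc)
        assert pairs.attrs["n_excluded"] == 1
        assert len(pairs) == 2

    def test_contribution_percentages(self):
        results = pd.DataFrame(
            {
                "sample_1": ["a", "a", "a", "b"],
                "sample_2": ["b", "c", "d", "c"],
                "beta_nti": [3.0, 2.5, 0.0, 1.0],
                "rc_bray": [0.0, 0.0, 0.0, 0.99],
                "process": [
                    "variable_selection",
                    "variable_selection",
                    "drift",
                    "dispersal_limitation",
                ],
            }
        )
        pct = process_contributions(results)
        row = pct.loc["all"]
        assert row["variable_selection"] == pytest.approx(50.0)
        assert row["drift"] == pytest.approx(25.0)
        assert row["dispersal_limitation"] == pytest.approx(25.0)
        assert row.sum() == pytest.approx(100.0)
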