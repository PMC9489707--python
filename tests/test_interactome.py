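"""Receptor-ligand interaction means, permutation p-values and the
specificity/consensus filters, checked against hand computation and an
exhaustive relabeling oracle."""

import itertools

import anndata as ad
import numpy as np
import pandas as pd
import pytest

from ecatlas import interactome as ia
from ecatlas import markers as mk
from ecatlas import qc
from ecatlas import syndata as sd


def _nm(X, genes, counts=None):
    nm = ad.AnnData(X=np.asarray(X, dtype=float))
    nm.var_names = genes
    if counts is not None:
        nm.layers["counts"] = np.asarray(counts)
    return nm


def _db(rows):
    return pd.DataFrame(
        rows, columns=["pair_id", "ligand_components", "receptor_components"]
    )


class TestInteractionMeans:
    def test_expression_fraction_threshold_excludes_pair(self):
        # ligand detected in 24% of source cells -> below threshold 0.25
        counts = np.zeros((100, 2), dtype=int)
        counts[:24, 0] = 5  # ligand in 24/100 cells
        counts[:, 1] = 3  # receptor everywhere
        X = np.log1p(counts.astype(float))
        nm = _nm(X, ["L", "R"], counts)
        labels = np.array(["src"] * 100)
        it = ia.interaction_means(nm, labels, _db([("p", "L", "R")]))
        row = it.table.iloc[0]
        assert not row["expressed"]
        assert np.isnan(row["mean"])

    def test_single_subunit_equal_means(self):
        counts = np.full((40, 2), 4, dtype=int)
        X = np.log1p(counts.astype(float))
        nm = _nm(X, ["L", "R"], counts)
        labels = np.array(["a"] * 20 + ["b"] * 20)
        it = ia.interaction_means(nm, labels, _db([("p", "L", "R")]))
        m = np.log1p(4.0)
        assert np.allclose(it.table["mean"], m)

    def test_toy_fixture_matches_hand_computation(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3.0, size=(60, 6)) + 1  # everything expressed
        genes = ["L1", "R1", "L2a", "L2b", "R2", "X"]
        X = np.log1p(counts.astype(float))
        nm = _nm(X, genes, counts)
        labels = np.array(["a"] * 30 + ["b"] * 30)
        db = _db([("p1", "L1", "R1"), ("p2", "L2a|L2b", "R2")])
        it = ia.interaction_means(nm, labels, db)
        ma = {g: X[:30, genes.index(g)].mean() for g in genes}
        mb = {g: X[30:, genes.index(g)].mean() for g in genes}
        row = it.table.set_index(["pair_id", "source", "target"])
        assert row.loc[("p1", "a", "b"), "mean"] == pytest.approx(
            0.5 * (ma["L1"] + mb["R1"])
        )
        # multi-subunit ligand aggregates by the component minimum
        assert row.loc[("p2", "b", "a"), "mean"] == pytest.approx(
            0.5 * (min(mb["L2a"], mb["L2b"]) + ma["R2"])
        )

    def test_missing_gene_skips_pair_with_warning(self):
        nm = _nm(np.ones((10, 1)), ["L"], np.ones((10, 1), dtype=int))
        with pytest.warns(UserWarning, match="skipped"):
            it = ia.interaction_means(
                nm, np.array(["a"] * 10), _db([("p", "L", "MISSING")])
            )
        assert it.table.empty

    def test_means_invariant_to_cell_order(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(2.0, size=(50, 2)) + 1
        X = np.log1p(counts.astype(float))
        labels = np.array(["a"] * 25 + ["b"] * 25)
        db = _db([("p", "L", "R")])
        it1 = ia.interaction_means(_nm(X, ["L", "R"], counts), labels, db)
        perm = rng.permutation(50)
        it2 = ia.interaction_means(
            _nm(X[perm], ["L", "R"], counts[perm]), labels[perm], db
        )
        pd.testing.assert_frame_equal(
            it1.table.sort_values(["source", "target"]).reset_index(drop=True),
            it2.table.sort_values(["source", "target"]).reset_index(drop=True),
        )


class TestPermutationTest:
    def test_matches_exhaustive_enumeration_on_tiny_instance(self):
        """6 cells, 2 clusters of 3: enumerate all 20 label assignments."""
        rng = np.random.default_rng(2)
        counts = rng.poisson(4.0, size=(6, 2)) + 1
        X = np.log1p(counts.astype(float))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        db = _db([("p", "L", "R")])
        nm = _nm(X, ["L", "R"], counts)
        iterations = 4000
        it = ia.permutation_test(nm, labels, db, iterations=iterations, seed=0)
        row = it.table.set_index(["source", "target"]).loc[("a", "b")]
        obs = row["mean"]

        null_means = []
        for combo in itertools.combinations(range(6), 3):
            in_a = np.zeros(6, dtype=bool)
            in_a[list(combo)] = True
            null_means.append(0.5 * (X[in_a, 0].mean() + X[~in_a, 1].mean()))
        exact_p = np.mean(np.array(null_means) >= obs)
        mc_se = np.sqrt(exact_p * (1 - exact_p) / iterations) + 1 / iterations
        assert abs(row["p"] - exact_p) <= 2 * mc_se + 2 / iterations

    def test_null_pvalues_uniform_on_support(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        n_pairs = 100
        genes = [f"L{i}" for i in range(n_pairs)] + [f"R{i}" for i in range(n_pairs)]
        counts = rng.poisson(2.0, size=(120, 2 * n_pairs)) + 1
        X = np.log1p(counts.astype(float))
        labels = np.array(["a"] * 60 + ["b"] * 60)
        db = _db([(f"p{i}", f"L{i}", f"R{i}") for i in range(n_pairs)])
        it = ia.permutation_test(
            _nm(X, genes, counts), labels, db, iterations=99, seed=1
        )
        ps = it.table.loc[
            (it.table.source == "a") & (it.table.target == "b"), "p"
        ].to_numpy()
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_pair_reaches_minimum_attainable_p(self):
        cfg = sd.SimConfig(
            n_genes=300, n_clusters=3, n_cells_per_cluster=[200] * 3, seed=5
        )
        plants = [sd.LRPlant("G0010", "G0020", 0, 1, fold=10)]
        adata, truth = sd.simulate_interactome(cfg, plants)
        nm = qc.normalize_scale(adata)
        db = _db([("planted", "G0010", "G0020")])
        it = ia.permutation_test(nm, truth.true_labels, db, iterations=500, seed=2)
        row = it.table.set_index(["source", "target"]).loc[(0, 1)]
        assert row["p"] == pytest.approx(1.0 / 501.0)


class TestFilters:
    @pytest.fixture()
    def tested_rows(self):
        clusters = ["ec_v1", "ec_v2", "ec_v3", "ec_v4", "ec_angio", "mac", "tiny"]
        rows = []
        rng = np.random.default_rng(6)
        for pair in ("p1", "p2"):
            for s in clusters:
                for t in clusters:
                    rows.append(
                        {
                            "pair_id": pair,
                            "source": s,
                            "target": t,
                            "expressed": True,
                            "mean": rng.uniform(0.5, 2.0),
                            "p": 0.01 if (pair == "p1" and s.startswith("ec")) else 0.5,
                        }
                    )
        it = ia.InteractionTest(table=pd.DataFrame(rows), iterations=500)
        ec = {"ec_v1", "ec_v2", "ec_v3", "ec_v4", "ec_angio"}
        sizes = {c: (99 if c == "tiny" else 500) for c in it.table["source"].unique()}
        lfc = pd.DataFrame(
            1.0, index=["L1", "R1", "L2", "R2"], columns=sorted(ec)
        )
        db = _db([("p1", "L1", "R1"), ("p2", "L2", "R2")])
        return it, ec, sizes, lfc, db

    def test_small_cluster_and_self_rows_excluded(self, tested_rows):
        it, ec, sizes, lfc, db = tested_rows
        out = ia.apply_specificity_filters(
            it, lfc, ec, sizes, db, venous_set={"ec_v1", "ec_v2", "ec_v3", "ec_v4"}
        )
        tab = out.table
        assert tab.loc[tab.source.eq("tiny") | tab.target.eq("tiny"),
                       "excluded_small_cluster"].all()
        both_ec = tab.source.isin(ec) & tab.target.isin(ec)
        assert (tab["excluded_self"] == both_ec).all()
        assert not tab.loc[tab["kept"], "excluded_small_cluster"].any()

    def test_specificity_flag_follows_min_pairwise_lfc(self, tested_rows):
        it, ec, sizes, lfc, db = tested_rows
        lfc.loc["L1", "ec_v1"] = 0.1  # below 0.25: p1 rows with ec_v1 ligand fail
        out = ia.apply_specificity_filters(it, lfc, ec, sizes, db)
        tab = out.table
        bad = tab[(tab.pair_id == "p1") & (tab.source == "ec_v1")]
        assert not bad["ec_specific"].any()
        ok = tab[(tab.pair_id == "p1") & (tab.source == "ec_v2") & ~tab.target.isin(ec)]
        assert ok["ec_specific"].all()

    def test_venous_consensus_requires_three_of_four(self, tested_rows):
        it, ec, sizes, lfc, db = tested_rows
        tab = it.table
        # p2 significant in exactly 3 venous subclusters for target 'mac'
        sel = (
            (tab.pair_id == "p2")
            & tab.source.isin(["ec_v1", "ec_v2", "ec_v3"])
            & (tab.target == "mac")
        )
        tab.loc[sel, "p"] = 0.001
        out = ia.apply_specificity_filters(
            it, lfc, ec, sizes, db, venous_set={"ec_v1", "ec_v2", "ec_v3", "ec_v4"}
        )
        ven = out.venous.set_index(["pair_id", "partner", "direction"])
        row = ven.loc[("p2", "mac", "venous_ligand")]
        assert row["n_venous_significant"] == 3
        assert bool(row["venous_consensus"])
        # p1: significant in all 4 -> consensus; direction receptor-side: 0 -> no
        assert bool(ven.loc[("p1", "mac", "venous_ligand"), "venous_consensus"])
        # excluded partners (small cluster, EC-self) never enter the consensus
        assert "tiny" not in set(out.venous["partner"])
        assert not out.venous["partner"].isin({"ec_v1", "ec_angio"}).any()

    def test_wrong_venous_set_size_errors(self, tested_rows):
        it, ec, sizes, lfc, db = tested_rows
        with pytest.raises(ValueError, match="exactly 4"):
            ia.apply_specificity_filters(it, lfc, ec, sizes, db, venous_set={"ec_v1"})

    def test_flags_match_rule_by_rule_oracle(self, tested_rows):
        it, ec, sizes, lfc, db = tested_rows
        out = ia.apply_specificity_filters(it, lfc, ec, sizes, db)
        comp = {"p1": ("L1", "R1"), "p2": ("L2", "R2")}
        for _, row in out.table.iterrows():
            self_flag = row.source in ec and row.target in ec
            small_flag = sizes[row.source] < 100 or sizes[row.target] < 100
            lig, rec = comp[row.pair_id]
            specific = True
            if row.source in ec:
                specific &= lfc.loc[lig, row.source] >= 0.25
            if row.target in ec:
                specific &= lfc.loc[rec, row.target] >= 0.25
            assert row.excluded_self == self_flag
            assert row.excluded_small_cluster == small_flag
            assert row.ec_specific == specific
            assert row.kept == (
                (row.p < 0.05) and specific and not self_flag and not small_flag
            )


def test_min_pairwise_lfc_matches_pair_tables(small_nm):
    nm, labels, _ = small_nm
    pairs = mk.pairwise_de(nm, labels)
    out = ia.min_pairwise_lfc(pairs)
    tgt = pairs[0].target
    refs = [p.table["log2fc"] for p in pairs if p.target == tgt]
    np.testing.assert_allclose(
        out[tgt].to_numpy(), np.minimum.reduce([r.to_numpy() for r in refs])
    )


def test_bundled_database_loads():
    db = ia.bundled_lr_database()
    assert {"GAS6_MERTK", "VEGFA_KDR", "SELE_SELPLG"} <= set(db["pair_id"])
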