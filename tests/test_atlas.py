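"""Clustering, contaminant removal, marker detection, composition, queries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import cloneatlas as ca
from cloneatlas.atlas import ClusterResult, benjamini_hochberg
from cloneatlas.counts import Archetype, SimCountsParams
from conftest import make_counts_adata


@pytest.fixture(scope="module")
def two_state_result(two_state_counts):
    return ca.embed_and_cluster(two_state_counts, seed=0)


class TestEmbedAndCluster:
    def test_two_archetype_recovery(self, two_state_counts, two_state_result):
        """Disjoint 10-gene programs at fold 8 are recovered near-perfectly."""
        ari = adjusted_rand_score(two_state_counts.obs["archetype"], two_state_result.labels)
        assert two_state_result.n_clusters == 2
        assert ari > 0.95

    def test_single_archetype_single_cluster(self):
        arks = (Archetype(name="1", markers={"M1": 8.0}, healthy_share=0.5),)
        p = SimCountsParams(n_cells=(150, 150), n_genes=600, archetypes=arks,
                            contaminant_fraction=0.0, lowdepth_cell_fraction=0.0,
                            mito_law=("fixed", 0.05), seed=8)
        res = ca.embed_and_cluster(ca.simulate_counts(p), seed=0)
        assert res.n_clusters == 1

    def test_too_few_cells_rejected(self, two_state_counts):
        with pytest.raises(ValueError, match="fewer cells"):
            ca.embed_and_cluster(two_state_counts[:10].copy(), n_pcs=30)

    def test_cell_order_invariance(self, two_state_counts, two_state_result):
        """Permuting cells yields the same partition up to label renaming."""
        rng = np.random.default_rng(1)
        perm = rng.permutation(two_state_counts.n_obs)
        res_p = ca.embed_and_cluster(two_state_counts[perm].copy(), seed=0)
        ari = adjusted_rand_score(
            two_state_result.labels.iloc[perm], res_p.labels
        )
        assert ari == pytest.approx(1.0)

    def test_seeded_reproducibility(self, two_state_counts, two_state_result):
        res2 = ca.embed_and_cluster(two_state_counts, seed=0)
        assert (res2.labels == two_state_result.labels).all()

    def test_duplicated_cells_get_same_cluster(self, two_state_counts):
        import anndata as ad_mod

        dup = ad_mod.concat([two_state_counts, two_state_counts], index_unique="-")
        res = ca.embed_and_cluster(dup, seed=0)
        n = two_state_counts.n_obs
        agree = (res.labels.to_numpy()[:n] == res.labels.to_numpy()[n:]).mean()
        assert agree > 0.99

    def test_tsne_display_only(self, two_state_counts, two_state_result):
        res = ca.embed_and_cluster(two_state_counts[:120].copy(), n_pcs=20, seed=0, tsne=True)
        assert res.adata.obsm["X_tsne3d"].shape == (120, 3)


class TestContaminantRemoval:
    @pytest.fixture(scope="class")
    def with_contaminant(self):
        p = ca.counts_preset(seed=13, n_cells=(350, 350), n_genes=1000,
                             contaminant_fraction=0.05, lowdepth_cell_fraction=0.0)
        adata = ca.simulate_counts(p)
        res = ca.embed_and_cluster(adata, n_clusters_hint=11, seed=0)
        return adata, res

    def test_contaminant_cluster_removed(self, with_contaminant):
        adata, res = with_contaminant
        out = ca.remove_contaminant_cluster(res)
        assert out.contaminant_removed
        removed_cells = res.labels.isin(out.removed_clusters)
        majority = adata.obs.loc[removed_cells.to_numpy(), "archetype"].value_counts().idxmax()
        assert majority == "contaminant"
        assert (out.adata.obs["archetype"] == "contaminant").mean() < 0.005

    def test_double_positive_fraction_reported(self, with_contaminant):
        _, res = with_contaminant
        out = ca.remove_contaminant_cluster(res)
        assert out.double_positive_fraction is not None
        assert 0.0 <= out.double_positive_fraction < 0.05

    def test_no_contaminant_removes_nothing(self, two_state_counts):
        res = ca.embed_and_cluster(two_state_counts, seed=0)
        out = ca.remove_contaminant_cluster(res)
        assert not out.contaminant_removed
        assert out.n_clusters == res.n_clusters

    def test_split_contaminant_both_flagged(self):
        """Two distinct haematopoietic archetypes are both removed."""
        low_ec = {"Pecam1": 0.01, "Kdr": 0.01, "Cdh5": 0.01, "Ptprc": 300.0}
        arks = (
            Archetype(name="EC1", markers={f"E{i}": 8.0 for i in range(8)}, healthy_share=0.5),
            Archetype(name="EC2", markers={f"F{i}": 8.0 for i in range(8)}, healthy_share=0.5),
            Archetype(name="blood1", markers={**low_ec, **{f"B{i}": 8.0 for i in range(8)}},
                      healthy_share=0.5, weight=0.08),
            Archetype(name="blood2", markers={**low_ec, **{f"C{i}": 8.0 for i in range(8)}},
                      healthy_share=0.5, weight=0.08),
        )
        p = SimCountsParams(n_cells=(400, 400), n_genes=800, archetypes=arks,
                            contaminant_fraction=0.0, lowdepth_cell_fraction=0.0,
                            mito_law=("fixed", 0.05), seed=17)
        adata = ca.simulate_counts(p)
        res = ca.embed_and_cluster(adata, n_clusters_hint=4, seed=0)
        out = ca.remove_contaminant_cluster(res)
        assert len(out.removed_clusters) == 2
        assert set(out.adata.obs["archetype"].unique()) == {"EC1", "EC2"}

    def test_absent_marker_gene_named(self, two_state_result):
        with pytest.raises(KeyError, match="Cd45_missing"):
            ca.remove_contaminant_cluster(
                two_state_result,
                markers=dict(positive=("Cd45_missing",), negative=("Pecam1", "Kdr")),
            )


class TestClusterMarkers:
    def test_planted_markers_recovered(self, two_state_counts, two_state_result):
        table = ca.cluster_markers(two_state_result)
        maj = two_state_counts.obs.groupby(two_state_result.labels, observed=True)[
            "archetype"].agg(lambda s: s.value_counts().idxmax())
        for cl in table["cluster"].unique():
            top = table[table["cluster"] == cl].iloc[0]
            prefix = "GA" if maj[cl] == "A" else "GB"
            assert top["gene"].startswith(prefix)
            assert top["padj"] < 0.01
        # planted markers are specific to their cluster
        planted = table[table["gene"].str.startswith(("GA", "GB")) & (table["lfc"] > 1)]
        assert planted["specific"].all()

    def test_background_gene_not_flagged(self, two_state_result):
        table = ca.cluster_markers(two_state_result)
        bg = table[~table["gene"].str.startswith(("GA", "GB"))]
        # background genes are not systematically significant markers
        assert (bg["padj"] < 0.05).mean() < 0.1

    def test_adjusted_p_not_below_raw(self, two_state_result):
        table = ca.cluster_markers(two_state_result)
        assert (table["padj"] >= table["pval"] - 1e-12).all()

    def test_shared_marker_not_specific(self):
        arks = (
            Archetype(name="A", markers={"SHARED": 8.0, "OA": 8.0}, healthy_share=0.5),
            Archetype(name="B", markers={"SHARED": 8.0, "OB": 8.0}, healthy_share=0.5),
        )
        p = SimCountsParams(n_cells=(200, 200), n_genes=600, archetypes=arks,
                            contaminant_fraction=0.0, lowdepth_cell_fraction=0.0,
                            mito_law=("fixed", 0.05), seed=19)
        res = ca.embed_and_cluster(ca.simulate_counts(p), n_clusters_hint=2, seed=0)
        table = ca.cluster_markers(res)
        shared = table[table["gene"] == "SHARED"]
        assert not shared["specific"].any()
        assert table.loc[table["gene"] == "OA", "specific"].any()


class TestBenjaminiHochberg:
    @given(st.lists(st.floats(1e-12, 1.0), min_size=2, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_matches_reference_implementation(self, pvals):
        """BH step-up computed directly from the definition."""
        p = np.asarray(pvals)
        m = len(p)
        order = np.argsort(p)
        ref = np.empty(m)
        running = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            rank = m - rank_from_end
            running = min(running, p[idx] * m / rank)
            ref[idx] = running
        got = benjamini_hochberg(p)
        np.testing.assert_allclose(got, ref, rtol=1e-10)

    def test_monotone_on_sorted_input(self, rng):
        p = np.sort(rng.random(100))
        adj = benjamini_hochberg(p)
        assert (np.diff(adj) >= -1e-12).all()


class TestCompositionTest:
    def _result_from_labels(self, labels, groups):
        X = np.ones((len(labels), 5))
        adata = make_counts_adata(X, [f"g{i}" for i in range(5)], groups=list(groups))
        lab = pd.Series(labels, index=adata.obs_names).astype(str)
        return ClusterResult(adata=adata, labels=lab, n_clusters=lab.nunique(),
                             resolution=1.0, composition=None)

    def test_exclusive_cluster_flagged(self):
        labels = ["0"] * 50 + ["1"] * 50
        groups = ["healthy"] * 25 + ["MI"] * 25 + ["MI"] * 50
        out = ca.composition_test(self._result_from_labels(labels, groups))
        row = out.set_index("cluster").loc["1"]
        assert row["exclusive"]
        assert row["mi_fraction" if "mi_fraction" in out.columns else "MI_fraction"] == 1.0
        assert row["p"] < 0.001

    def test_single_cell_cluster_underpowered(self):
        labels = ["0"] * 99 + ["1"]
        groups = (["healthy", "MI"] * 50)[:100]
        out = ca.composition_test(self._result_from_labels(labels, groups))
        row = out.set_index("cluster").loc["1"]
        assert row["p"] == 1.0
        assert row["underpowered"]

    def test_null_calibration(self, rng):
        """Clusters drawn at the global ratio give approximately uniform p."""
        pvals = []
        for _ in range(300):
            groups = np.where(rng.random(400) < 0.5, "healthy", "MI")
            labels = np.repeat([str(i) for i in range(4)], 100)
            out = ca.composition_test(self._result_from_labels(labels, groups))
            pvals.extend(out["p"].tolist())
        rate = np.mean(np.asarray(pvals) < 0.05)
        assert 0.01 < rate < 0.08  # exact binomial is conservative

    def test_missing_group_labels(self):
        X = np.ones((10, 3))
        adata = make_counts_adata(X, ["a", "b", "c"])
        res = ClusterResult(adata=adata, labels=pd.Series(["0"] * 10, index=adata.obs_names),
                            n_clusters=1, resolution=1.0, composition=None)
        with pytest.raises(KeyError, match="group"):
            ca.composition_test(res)


class TestGeneQuery:
    def test_planted_gene_tops_its_cluster(self, two_state_counts, two_state_result):
        out = ca.gene_query(two_state_result, "GA0")
        maj = two_state_counts.obs.groupby(two_state_result.labels, observed=True)[
            "archetype"].agg(lambda s: s.value_counts().idxmax())
        assert maj[out.iloc[0]["cluster"]] == "A"
        # fold-8 planted effect remains a clear separation on the log1p scale
        assert out.iloc[0]["mean"] > 2 * out.iloc[-1]["mean"]

    def test_all_zero_gene(self):
        X = np.ones((20, 3))
        X[:, 1] = 0.0  # the queried gene is silent everywhere
        adata = make_counts_adata(X, ["g0", "zero", "g2"], groups=["healthy", "MI"] * 10)
        res = ClusterResult(
            adata=adata,
            labels=pd.Series(["0"] * 10 + ["1"] * 10, index=adata.obs_names),
            n_clusters=2, resolution=1.0, composition=None,
        )
        out = ca.gene_query(res, "zero")
        assert (out["mean"] == 0).all()
        assert (out["detection_fraction"] == 0).all()

    def test_absent_gene_suggestions(self, two_state_result):
        with pytest.raises(KeyError, match="closest"):
            ca.gene_query(two_state_result, "GA0_typo")
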