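import itertools

import numpy as np
import pandas as pd
import pytest
import anndata as ad

from oracles import hypergeom_tail_enumeration, rank_sum_u
from screp import gex
from screp.clonotyping import ClonotypeStrategy, clonotype_cells
from screp.gex import (
    GeneSet,
    assign_phenotype,
    benjamini_hochberg,
    cluster_cells,
    cluster_membership_per_clone,
    de_expanded_vs_unexpanded,
    filter_cells_by_mito,
    go_enrichment,
    gsea_preranked,
    match_barcodes,
    normalize_barcode,
    remove_vdj_genes,
    sample_cluster_membership,
)


def adata_from(counts, genes, barcodes):
    return ad.AnnData(
        X=np.asarray(counts, dtype=float),
        obs=pd.DataFrame(index=barcodes),
        var=pd.DataFrame(index=genes),
    )


class TestMitoFilter:
    def test_above_threshold_removed(self):
        adata = adata_from([[75, 25], [90, 10]], ["GENE1", "MT-1"], ["a", "b"])
        out = filter_cells_by_mito(adata, 0.20)
        assert list(out.obs_names) == ["b"]

    def test_boundary_retained(self):
        adata = adata_from([[80, 20]], ["GENE1", "MT-1"], ["a"])
        out = filter_cells_by_mito(adata, 0.20)
        assert list(out.obs_names) == ["a"]

    def test_max_fraction_one_identity(self):
        adata = adata_from([[1, 99]], ["GENE1", "MT-1"], ["a"])
        assert filter_cells_by_mito(adata, 1.0).n_obs == 1

    def test_no_mito_genes_warns_keeps_all(self, caplog):
        adata = adata_from([[1, 99]], ["GENE1", "GENE2"], ["a"])
        with caplog.at_level("WARNING"):
            out = filter_cells_by_mito(adata)
        assert out.n_obs == 1
        assert "no genes" in caplog.text

    def test_invalid_fraction(self):
        adata = adata_from([[1]], ["MT-1"], ["a"])
        with pytest.raises(ValueError):
            filter_cells_by_mito(adata, 1.5)

    def test_planted_fractions_exact(self, gex_sim):
        adata = gex_sim.to_anndata()
        out = filter_cells_by_mito(adata, 0.20)
        expected = set(gex_sim.truth.loc[gex_sim.truth["mito_fraction"] <= 0.20, "barcode"])
        assert set(out.obs_names) == expected


class TestRemoveVdjGenes:
    @pytest.mark.parametrize(
        "gene", ["IGHV3-23", "IGKV1-39", "IGLJ2", "IGHA1", "IGHM", "TRBV19", "TRAC", "TRGV9"]
    )
    def test_receptor_gene_dropped(self, gene):
        adata = adata_from([[1, 2]], [gene, "ACTB"], ["a"])
        out = remove_vdj_genes(adata)
        assert list(out.var_names) == ["ACTB"]

    @pytest.mark.parametrize("gene", ["IGF1", "TRAF1", "IGFBP3", "TRIM21"])
    def test_non_receptor_gene_retained(self, gene):
        adata = adata_from([[1]], [gene], ["a"])
        assert gene in remove_vdj_genes(adata).var_names

    def test_identity_without_receptor_genes(self):
        adata = adata_from([[1, 2]], ["ACTB", "GAPDH"], ["a"])
        assert remove_vdj_genes(adata).n_vars == 2


class TestClusterCells:
    def test_planted_clusters_ari(self, gex_sim):
        from sklearn.metrics import adjusted_rand_score

        adata = gex_sim.to_anndata()
        annotation = cluster_cells(adata, n_hvg=100, n_pcs=10, resolution=0.5, seed=0)
        truth = gex_sim.truth.set_index("barcode").loc[annotation.index, "cluster"]
        assert adjusted_rand_score(truth, annotation["cluster"]) >= 0.9

    def test_deterministic_under_seed(self, gex_sim):
        adata = gex_sim.to_anndata()
        a = cluster_cells(adata.copy(), n_hvg=100, seed=3)
        b = cluster_cells(adata.copy(), n_hvg=100, seed=3)
        assert (a["cluster"] == b["cluster"]).all()

    def test_too_few_cells(self):
        adata = adata_from([[1, 2]], ["G1", "G2"], ["a"])
        with pytest.raises(ValueError):
            cluster_cells(adata)


class TestMatchBarcodes:
    def test_suffix_normalization(self, repertoire):
        barcodes = [b + "-1" for b in list(repertoire.barcodes())[:5]]
        annotation = pd.DataFrame({"cluster": [0] * 5}, index=barcodes)
        out = match_barcodes(repertoire, annotation)
        assert out["in_vdj"].all()

    def test_disjoint_errors(self, repertoire):
        annotation = pd.DataFrame({"cluster": [0]}, index=["NOTABARCODE-1"])
        with pytest.raises(ValueError, match="suffix"):
            match_barcodes(repertoire, annotation)

    def test_overlap_equals_set_intersection(self, repertoire, gex_sim):
        annotation = pd.DataFrame(
            {"cluster": 0}, index=gex_sim.truth["barcode"].tolist()
        )
        out = match_barcodes(repertoire, annotation)
        expected = {normalize_barcode(b) for b in annotation.index} & {
            normalize_barcode(b) for b in repertoire.barcodes()
        }
        assert out["in_vdj"].sum() == len(expected)

    def test_normalize_barcode(self):
        assert normalize_barcode("AAAC-1") == "AAAC"
        assert normalize_barcode("AAAC") == "AAAC"
        assert normalize_barcode("AAAC-12") == "AAAC"


class TestClusterMembership:
    def _annotation(self, assignments):
        df = pd.DataFrame(
            {"cluster": list(assignments.values()), "in_vdj": True},
            index=list(assignments.keys()),
        )
        return df

    def test_fractions(self, repertoire):
        clones = clonotype_cells(repertoire, ClonotypeStrategy(name="cdr3.nt"))
        clone = max(clones, key=lambda c: c.size)
        barcodes = sorted(clone.barcodes)
        assignments = {b: (0 if i < 3 else 6) for i, b in enumerate(barcodes)}
        table = cluster_membership_per_clone(clones, self._annotation(assignments), 1)
        if clone.size >= 4:
            assert table.loc[clone.clonotype_id, 0] == pytest.approx(3 / clone.size)
        assert table.sum(axis=1).iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_single_cell_clone(self, repertoire):
        clones = clonotype_cells(repertoire, ClonotypeStrategy(name="cdr3.nt"))
        singleton = min(clones, key=lambda c: c.size)
        annotation = self._annotation({sorted(singleton.barcodes)[0]: 2})
        table = cluster_membership_per_clone([singleton], annotation, 1)
        assert table.iloc[0][2] == 1.0

    def test_rows_sum_to_one(self, repertoire, gex_sim):
        adata = gex_sim.to_anndata()
        annotation = cluster_cells(adata, n_hvg=100, seed=0)
        annotation = match_barcodes(repertoire, annotation)
        clones = clonotype_cells(repertoire, ClonotypeStrategy(name="cdr3.nt"))
        table = cluster_membership_per_clone(clones, annotation, 10)
        assert np.allclose(table.sum(axis=1), 1.0, atol=1e-9)

    def test_requires_in_vdj(self, repertoire):
        clones = clonotype_cells(repertoire, ClonotypeStrategy(name="cdr3.nt"))
        with pytest.raises(ValueError, match="in_vdj"):
            cluster_membership_per_clone(clones, pd.DataFrame({"cluster": []}), 1)

    def test_whole_sample_rows_sum_to_one(self):
        annotation = pd.DataFrame(
            {"sample_id": ["p1", "p1", "p2"], "cluster": [0, 1, 0]},
            index=["a", "b", "c"],
        )
        table = sample_cluster_membership(annotation)
        assert np.allclose(table.sum(axis=1), 1.0)
        assert table.loc["p1", 0] == 0.5


MEMORY_DEF = ("memory_like", ["CD8A", "CD44", "SELL", "IL7R"], ["CCL5"])
EFFECTOR_DEF = ("effector_like", ["CD8A", "CD44", "CCL5"], ["SELL", "IL7R"])
PHENO_GENES = ["CD8A", "CD44", "CCL5", "SELL", "IL7R", "TCF7"]


class TestAssignPhenotype:
    def _run(self, counts, genes=PHENO_GENES):
        adata = adata_from([counts], genes, ["cell1"])
        annotation = pd.DataFrame({"cluster": [0]}, index=["cell1"])
        out = assign_phenotype(annotation, adata, [MEMORY_DEF, EFFECTOR_DEF])
        return out.loc["cell1", "phenotype"]

    def test_effector_like(self):
        # CD8A=2, CD44=1, CCL5=3, SELL=0, IL7R=0
        assert self._run([2, 1, 3, 0, 0, 0]) == "effector_like"

    def test_memory_like(self):
        assert self._run([2, 1, 0, 1, 2, 0]) == "memory_like"

    def test_all_zero_unclassified(self):
        assert self._run([0, 0, 0, 0, 0, 0]) == "unclassified"

    def test_definitions_mutually_exclusive(self):
        # exhaustively over indicator patterns of the 5 marker genes:
        # no cell can satisfy both definitions (SELL/IL7R/CCL5 disjoint)
        for pattern in itertools.product([0, 1], repeat=5):
            cd8a, cd44, ccl5, sell, il7r = pattern
            memory = cd8a and cd44 and sell and il7r and not ccl5
            effector = cd8a and cd44 and ccl5 and not sell and not il7r
            assert not (memory and effector)
            label = self._run([cd8a, cd44, ccl5, sell, il7r, 0])
            if memory:
                assert label == "memory_like"
            elif effector:
                assert label == "effector_like"
            else:
                assert label == "unclassified"

    def test_missing_gene_treated_as_zero(self, caplog):
        adata = adata_from([[2, 1, 3]], ["CD8A", "CD44", "CCL5"], ["cell1"])
        annotation = pd.DataFrame({"cluster": [0]}, index=["cell1"])
        with caplog.at_level("WARNING"):
            out = assign_phenotype(annotation, adata, [MEMORY_DEF, EFFECTOR_DEF])
        assert out.loc["cell1", "phenotype"] == "effector_like"
        assert "absent" in caplog.text

    def test_empty_definitions(self):
        adata = adata_from([[1]], ["CD8A"], ["cell1"])
        with pytest.raises(ValueError):
            assign_phenotype(pd.DataFrame(index=["cell1"]), adata, [])


class TestDifferentialExpression:
    def _setup(self, n_per_group=50, n_genes=30, fold=4.0, seed=0):
        rng = np.random.default_rng(seed)
        from conftest import make_pair
        from screp.io import assemble_cells

        pairs = []
        # one expanded clone of n_per_group cells + n_per_group singletons
        for i in range(n_per_group):
            pairs.append(make_pair(f"EXP{i:04d}", cdr3h_aa="CAREXPANDW"))
        for i in range(n_per_group):
            nt = "".join(rng.choice(list("ACGT"), 12))
            pairs.append(
                make_pair(f"SGL{i:04d}", cdr3h_aa=f"CAR{i:04d}W", cdr3h_nt=nt)
            )
        rep = assemble_cells([c for p in pairs for c in p], "s1")
        clones = clonotype_cells(rep, ClonotypeStrategy(name="cdr3.aa"))
        barcodes = [c.barcode for c in rep.cells]
        counts = rng.poisson(5.0, size=(len(barcodes), n_genes)).astype(float)
        genes = [f"G{i:03d}" for i in range(n_genes)]
        expanded_rows = [i for i, b in enumerate(barcodes) if b.startswith("EXP")]
        counts[expanded_rows, 0] *= fold  # plant upregulation in gene G000
        adata = adata_from(counts, genes, barcodes)
        annotation = match_barcodes(rep, pd.DataFrame(index=barcodes))
        return adata, clones, annotation

    def test_planted_gene_detected(self):
        adata, clones, annotation = self._setup()
        table = de_expanded_vs_unexpanded(adata, clones, annotation)
        row = table.set_index("gene").loc["G000"]
        assert row["avg_logFC"] > 0
        assert row["p_adj"] < 0.05

    def test_identical_gene_null(self):
        adata, clones, annotation = self._setup(fold=1.0)
        # identical expression profile in every cell -> identical normalized
        # values in both groups for every gene
        adata.X = np.tile(adata.X[0], (adata.n_obs, 1))
        table = de_expanded_vs_unexpanded(adata, clones, annotation).set_index("gene")
        assert (table["avg_logFC"] == 0.0).all()
        assert (table["p_value"] == 1.0).all()

    def test_wilcoxon_statistic_matches_pair_counting(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        for _ in range(30):
            a = rng.integers(0, 5, size=rng.integers(2, 9)).astype(float)
            b = rng.integers(0, 5, size=rng.integers(2, 9)).astype(float)
            u = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
            assert u == rank_sum_u(a.tolist(), b.tolist())

    def test_empty_group_rejected(self):
        adata, clones, annotation = self._setup()
        expanded_only = [c for c in clones if c.size > 1]
        with pytest.raises(ValueError):
            de_expanded_vs_unexpanded(adata, expanded_only, annotation)


class TestBenjaminiHochberg:
    def test_monotone_in_raw_order(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=100)
        adjusted = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(adjusted[order]) >= -1e-12).all()

    def test_matches_known_case(self):
        p = np.array([0.01, 0.04, 0.03, 0.005])
        # sorted: .005,.01,.03,.04 -> adj: .02,.02,.04,.04
        assert np.allclose(benjamini_hochberg(p), [0.02, 0.04, 0.04, 0.02])


class TestGoEnrichment:
    def test_closed_form_one_sixth(self):
        universe = {"a", "b", "c", "d"}
        sets = [GeneSet("s", frozenset({"a", "b"}))]
        table = go_enrichment({"a", "b"}, sets, universe)
        assert table.iloc[0]["p_value"] == pytest.approx(1 / 6)
        assert table.iloc[0]["ratio"] == 1.0

    def test_zero_overlap_p_one(self):
        universe = {"a", "b", "c", "d"}
        table = go_enrichment({"c", "d"}, [GeneSet("s", frozenset({"a", "b"}))], universe)
        assert table.iloc[0]["overlap"] == 0
        assert table.iloc[0]["p_value"] >= table.iloc[0]["ratio"]  # p for X>=0 ... 1
        table_all = go_enrichment(set(), [GeneSet("s", frozenset({"a"}))], universe)
        assert table_all.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_matches_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            total = int(rng.integers(4, 13))
            successes = int(rng.integers(1, total + 1))
            draws = int(rng.integers(1, total + 1))
            universe = {f"g{i}" for i in range(total)}
            gene_set = GeneSet("s", frozenset(f"g{i}" for i in range(successes)))
            query = set(rng.choice(sorted(universe), size=draws, replace=False))
            k = len(query & gene_set.genes)
            expected = hypergeom_tail_enumeration(total, successes, draws, k)
            table = go_enrichment(query, [gene_set], universe)
            assert table.iloc[0]["p_value"] == pytest.approx(expected)

    def test_gene_order_invariant(self):
        universe = {f"g{i}" for i in range(10)}
        gene_set = GeneSet("s", frozenset({"g1", "g2", "g3"}))
        a = go_enrichment({"g1", "g3", "g5"}, [gene_set], universe)
        b = go_enrichment({"g5", "g1", "g3"}, [gene_set], universe)
        assert a.iloc[0]["p_value"] == b.iloc[0]["p_value"]

    def test_empty_universe(self):
        with pytest.raises(ValueError):
            go_enrichment({"a"}, [], set())


class TestGsea:
    TOY = [("gene1", 3.0), ("gene2", 2.0), ("gene3", 1.0), ("gene4", 0.5)]

    def test_toy_es_one(self):
        es, _ = gsea_preranked(self.TOY, GeneSet("s", frozenset({"gene1"})), n_perm=10, seed=0)
        assert es == pytest.approx(1.0)

    def test_all_hits_at_top(self):
        ranked = [(f"g{i}", float(100 - i)) for i in range(100)]
        gene_set = GeneSet("s", frozenset(f"g{i}" for i in range(5)))
        es, _ = gsea_preranked(ranked, gene_set, n_perm=10, seed=0)
        assert es > 0.9

    def test_permutation_p_reproducible(self):
        ranked = [(f"g{i}", float(50 - i)) for i in range(50)]
        gene_set = GeneSet("s", frozenset({"g0", "g3", "g10"}))
        r1 = gsea_preranked(ranked, gene_set, n_perm=200, seed=42)
        r2 = gsea_preranked(ranked, gene_set, n_perm=200, seed=42)
        assert r1 == r2
        assert 0.0 <= r1[1] <= 1.0

    def test_sign_flips_under_negation(self):
        ranked = [(f"g{i}", float(20 - i)) for i in range(20)]
        gene_set = GeneSet("s", frozenset({"g0", "g1", "g2"}))
        es_pos, _ = gsea_preranked(ranked, gene_set, n_perm=1, seed=0)
        negated = [(g, -s) for g, s in ranked]
        es_neg, _ = gsea_preranked(negated, gene_set, n_perm=1, seed=0)
        assert es_neg == pytest.approx(-es_pos)

    def test_empty_intersection(self):
        with pytest.raises(ValueError):
            gsea_preranked(self.TOY, GeneSet("s", frozenset({"absent"})), n_perm=1)


def test_read_gmt(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("SET1\tdesc\tg1\tg2\nSET2\tdesc\tg3\n")
    sets = gex.read_gmt(path)
    assert [s.name for s in sets] == ["SET1", "SET2"]
    assert sets[0].genes == {"g1", "g2"}


def test_mtx_round_trip(tmp_path, gex_sim):
    outdir = gex_sim.write(tmp_path / "gexdir")
    adata = gex.read_mtx_dir(outdir)
    assert adata.n_obs == gex_sim.spec.n_cells
    assert list(adata.obs_names) == gex_sim.barcodes
    dense = adata.X.toarray()
    assert np.allclose(dense, gex_sim.counts.toarray())
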