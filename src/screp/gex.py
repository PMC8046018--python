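"""Transcriptome processing and VDJ/GEX integration.

Mitochondrial and receptor-gene filtering, graph clustering of expression
profiles, barcode matching between the expression and receptor libraries,
clone-level cluster membership, rule-based phenotype labels, differential
expression between expanded and unexpanded clones, hypergeometric gene-set
enrichment and preranked GSEA.

Expression matrices are handled as :class:`anndata.AnnData` with cells as
rows and raw counts in ``.X``; all normalization here is counts-per-10k +
log1p and is applied to internal copies only.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.io import mmread

from screp.clonotyping import Clonotype, rank_clones
from screp.io import Repertoire

logger = logging.getLogger(__name__)

#: Receptor-segment gene patterns excluded before clustering and DE.
VDJ_GENE_PATTERN = re.compile(r"^(IG[HKL][VDJ]|IGH[ADEGM]|TR[ABGD][VDJC])")


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(name=parts[0], genes=frozenset(g for g in parts[2:] if g)))
    return sets


def read_mtx_dir(path: str | Path) -> ad.AnnData:
    """Read a cellranger-style MTX triplet directory (genes x cells on disk)
    into a cells x genes AnnData."""
    path = Path(path)
    matrix = sp.csr_matrix(mmread(path / "matrix.mtx").T)
    barcodes = pd.read_csv(path / "barcodes.tsv", header=None, sep="\t")[0].tolist()
    feat = pd.read_csv(path / "features.tsv", header=None, sep="\t")
    genes = (feat[1] if feat.shape[1] >= 2 else feat[0]).tolist()
    adata = ad.AnnData(
        X=matrix,
        obs=pd.DataFrame(index=barcodes),
        var=pd.DataFrame(index=genes),
    )
    adata.var_names_make_unique()
    return adata


def read_counts_csv(path: str | Path) -> ad.AnnData:
    """Read a dense genes-by-cells CSV counts matrix."""
    df = pd.read_csv(path, index_col=0)
    return ad.AnnData(
        X=df.T.to_numpy(dtype=float),
        obs=pd.DataFrame(index=df.columns),
        var=pd.DataFrame(index=df.index),
    )


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)


def filter_cells_by_mito(
    adata: ad.AnnData, max_fraction: float = 0.20, mito_prefix: str = "MT-"
) -> ad.AnnData:
    """Remove cells whose mitochondrial UMI fraction exceeds ``max_fraction``.

    Strict inequality: a cell exactly at the threshold is retained. If no
    genes carry the prefix, a warning is logged and nothing is removed.
    """
    if not (0.0 <= max_fraction <= 1.0):
        raise ValueError("max_fraction must lie in [0, 1]")
    mito = adata.var_names.str.startswith(mito_prefix)
    if not mito.any():
        logger.warning("no genes with prefix %r; no cells removed", mito_prefix)
        return adata.copy()
    totals = np.ravel(adata.X.sum(axis=1)).astype(float)
    mito_counts = np.ravel(adata[:, mito].X.sum(axis=1)).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        fraction = np.where(totals > 0, mito_counts / totals, 0.0)
    keep = fraction <= max_fraction
    return adata[keep].copy()


def remove_vdj_genes(adata: ad.AnnData) -> ad.AnnData:
    """Drop B/T receptor segment and heavy-constant genes before clustering."""
    drop = adata.var_names.str.match(VDJ_GENE_PATTERN)
    n_dropped = int(drop.sum())
    logger.info("removed %d receptor genes", n_dropped)
    out = adata[:, ~drop].copy()
    out.uns["n_vdj_genes_removed"] = n_dropped
    return out


def cluster_cells(
    adata: ad.AnnData,
    n_hvg: int = 2000,
    n_pcs: int = 10,
    resolution: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Log-normalize, select variable genes, PCA and Leiden clustering.

    Writes integer labels to ``adata.obs['cluster']`` and returns a per-cell
    annotation frame (barcode index, ``cluster`` column). Deterministic under
    a fixed seed. ``.X`` of the caller's object is left as raw counts.
    """
    import scanpy as sc

    if adata.n_obs < 2:
        raise ValueError("need at least 2 cells to cluster")
    work = adata.copy()
    sc.pp.normalize_total(work, target_sum=1e4)
    sc.pp.log1p(work)
    if n_hvg < work.n_vars:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.pp.highly_variable_genes(work, n_top_genes=n_hvg)
        work = work[:, work.var["highly_variable"]].copy()
    else:
        logger.warning("n_hvg=%d >= %d genes; using all genes", n_hvg, work.n_vars)
    sc.pp.scale(work, max_value=10)
    n_comps = min(n_pcs, work.n_obs - 1, work.n_vars - 1)
    sc.tl.pca(work, n_comps=n_comps, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(work, n_pcs=n_comps, random_state=seed)
    sc.tl.leiden(
        work,
        resolution=resolution,
        random_state=seed,
        flavor="igraph",
        n_iterations=2,
        directed=False,
    )
    labels = work.obs["leiden"].astype(int)
    adata.obs["cluster"] = labels.values
    annotation = pd.DataFrame({"cluster": labels.values}, index=adata.obs_names)
    if "sample_id" in adata.obs:
        annotation["sample_id"] = adata.obs["sample_id"].values
    return annotation


def normalize_barcode(barcode: str) -> str:
    """Strip a trailing '-<digits>' GEM-well suffix."""
    return re.sub(r"-\d+$", "", barcode)


def match_barcodes(
    repertoire: Repertoire, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Flag annotation rows whose barcode also appears in the repertoire.

    Barcodes are compared after suffix normalization. Zero overlap raises, as
    it almost always indicates a naming mismatch between libraries.
    """
    vdj = {normalize_barcode(b) for b in repertoire.barcodes()}
    out = annotation.copy()
    out["in_vdj"] = [normalize_barcode(b) in vdj for b in out.index]
    if len(out) and not out["in_vdj"].any():
        raise ValueError(
            "no barcodes shared between GEX and VDJ libraries; "
            "check barcode suffixes (e.g. trailing '-1')"
        )
    return out


def cluster_membership_per_clone(
    clonotypes: list[Clonotype], annotation: pd.DataFrame, top_n: int
) -> pd.DataFrame:
    """Fraction of each top clone's matched cells in each cluster.

    Rows sum to 1; only cells flagged ``in_vdj`` and present in the
    annotation are counted. Clones with no matched cells are omitted with a
    warning.
    """
    if "in_vdj" not in annotation.columns:
        raise ValueError("run match_barcodes first (in_vdj column missing)")
    lookup = {
        normalize_barcode(b): c
        for b, c in annotation.loc[annotation["in_vdj"], "cluster"].items()
    }
    clusters = sorted(annotation["cluster"].unique())
    rows, index = [], []
    for clone in rank_clones(clonotypes, top_n):
        counts = {c: 0 for c in clusters}
        matched = 0
        for barcode in clone.barcodes:
            cluster = lookup.get(normalize_barcode(barcode))
            if cluster is not None:
                counts[cluster] += 1
                matched += 1
        if matched == 0:
            logger.warning(
                "clone %s has no cells in the GEX data; omitted", clone.clonotype_id
            )
            continue
        rows.append([counts[c] / matched for c in clusters])
        index.append(clone.clonotype_id)
    return pd.DataFrame(rows, index=index, columns=clusters)


def sample_cluster_membership(annotation: pd.DataFrame) -> pd.DataFrame:
    """Fraction of each sample's cells per cluster (rows sum to 1)."""
    if "sample_id" not in annotation.columns:
        raise ValueError("annotation lacks a sample_id column")
    table = pd.crosstab(annotation["sample_id"], annotation["cluster"])
    return table.div(table.sum(axis=1), axis=0)


def assign_phenotype(
    annotation: pd.DataFrame,
    adata: ad.AnnData,
    definitions: list[tuple[str, list[str], list[str]]],
    positive_threshold: float = 0.0,
) -> pd.DataFrame:
    """Rule-based phenotype labels from marker-gene expression.

    ``definitions`` is an ordered list of ``(label, required_positive,
    required_zero)``; a cell is positive for a gene iff its raw count exceeds
    ``positive_threshold``. The first matching definition wins; otherwise the
    cell is ``unclassified``. Genes absent from the matrix are treated as
    all-zero with a warning.
    """
    if not definitions:
        raise ValueError("definitions must be non-empty")
    gene_index = {g: i for i, g in enumerate(adata.var_names)}
    needed = sorted({g for _, pos, neg in definitions for g in pos + neg})
    columns = {}
    for gene in needed:
        if gene in gene_index:
            columns[gene] = np.ravel(_dense(adata[:, gene].X)) > positive_threshold
        else:
            logger.warning("gene %s absent from matrix; treated as all-zero", gene)
            columns[gene] = np.zeros(adata.n_obs, dtype=bool)
    positive = pd.DataFrame(columns, index=adata.obs_names)

    out = annotation.copy()
    labels = pd.Series("unclassified", index=out.index, dtype=object)
    common = out.index.intersection(adata.obs_names)
    for label, pos_genes, zero_genes in reversed(definitions):
        mask = pd.Series(True, index=common)
        for g in pos_genes:
            mask &= positive.loc[common, g]
        for g in zero_genes:
            mask &= ~positive.loc[common, g]
        labels.loc[common[mask]] = label
    out["phenotype"] = labels
    return out


def _log_normalize(x: np.ndarray) -> np.ndarray:
    totals = x.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(x / totals * 1e4)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def de_expanded_vs_unexpanded(
    adata: ad.AnnData,
    clonotypes: list[Clonotype],
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum DE: cells of expanded (size > 1) clones
    versus cells of singleton clones.

    Values are counts-per-10k log1p; ``avg_logFC`` is the difference of group
    means on that scale; p-values are BH-adjusted over all tested genes.
    Ranking by ``avg_logFC`` descending gives the "top upregulated" view.
    """
    if "in_vdj" not in annotation.columns:
        raise ValueError("run match_barcodes first (in_vdj column missing)")
    matched = {
        normalize_barcode(b)
        for b in annotation.index[annotation["in_vdj"]]
    }
    position = {normalize_barcode(b): i for i, b in enumerate(adata.obs_names)}
    expanded_idx, unexpanded_idx = [], []
    for clone in clonotypes:
        bucket = expanded_idx if clone.size > 1 else unexpanded_idx
        for barcode in clone.barcodes:
            key = normalize_barcode(barcode)
            if key in matched and key in position:
                bucket.append(position[key])
    if not expanded_idx or not unexpanded_idx:
        raise ValueError("both expanded and unexpanded groups must be non-empty")

    x = _log_normalize(_dense(adata.X).astype(float))
    a, b = x[sorted(set(expanded_idx))], x[sorted(set(unexpanded_idx))]
    logfc = a.mean(axis=0) - b.mean(axis=0)
    pvals = np.ones(adata.n_vars)
    for g in range(adata.n_vars):
        col_a, col_b = a[:, g], b[:, g]
        if np.ptp(np.concatenate([col_a, col_b])) == 0:
            pvals[g] = 1.0
            continue
        pvals[g] = stats.mannwhitneyu(col_a, col_b, alternative="two-sided").pvalue
    return pd.DataFrame(
        {
            "gene": list(adata.var_names),
            "avg_logFC": logfc,
            "p_value": pvals,
            "p_adj": benjamini_hochberg(pvals),
        }
    ).sort_values("avg_logFC", ascending=False, ignore_index=True)


def go_enrichment(
    gene_list: set[str], gene_sets: list[GeneSet], universe: set[str]
) -> pd.DataFrame:
    """Upper-tail hypergeometric overlap test of a gene list against sets.

    ``p = P(X >= k)`` with population ``N = |universe|``, successes
    ``K = |set ∩ universe|`` and draws ``n = |gene_list|``; ``ratio = k / K``.
    Genes outside the universe are dropped with a warning; BH correction is
    applied over the tested sets.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    outside = gene_list - universe
    if outside:
        logger.warning("%d query genes outside the universe; dropped", len(outside))
    query = gene_list & universe
    n, total = len(query), len(universe)
    rows = []
    for gs in gene_sets:
        members = gs.genes & universe
        k_size = len(members)
        overlap = len(query & members)
        p = float(stats.hypergeom.sf(overlap - 1, total, k_size, n)) if k_size else 1.0
        rows.append(
            {
                "set": gs.name,
                "overlap": overlap,
                "set_size": k_size,
                "ratio": overlap / k_size if k_size else 0.0,
                "p_value": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = benjamini_hochberg(table["p_value"].to_numpy())
    return table


def _running_es(scores: np.ndarray, hit_mask: np.ndarray) -> float:
    """Signed maximum deviation of the weighted KS running sum."""
    weights = np.abs(scores)
    hit_total = weights[hit_mask].sum()
    n_miss = (~hit_mask).sum()
    steps = np.where(
        hit_mask,
        weights / hit_total if hit_total > 0 else 0.0,
        -1.0 / n_miss if n_miss > 0 else 0.0,
    )
    running = np.cumsum(steps)
    peak = running[np.argmax(np.abs(running))]
    return float(peak)


def gsea_preranked(
    ranked_genes: list[tuple[str, float]],
    gene_set: GeneSet,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Classic weighted KS preranked enrichment score with permutation p.

    ``ranked_genes`` is a (gene, score) list; it is sorted by descending score
    internally. Hit steps are ``|score| / Σ|score over hits|``; miss steps are
    ``-1/(N-K)``. The p-value is the fraction of ``n_perm`` random gene-label
    permutations with ``|ES_perm| >= |ES|``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ordered = sorted(ranked_genes, key=lambda gs: -gs[1])
    genes = [g for g, _ in ordered]
    scores = np.array([s for _, s in ordered], dtype=float)
    hit_mask = np.array([g in gene_set.genes for g in genes])
    k = int(hit_mask.sum())
    if k == 0:
        raise ValueError(f"gene set {gene_set.name!r} shares no genes with the list")
    es = _running_es(scores, hit_mask)

    rng = np.random.default_rng(seed)
    n = len(genes)
    exceed = 0
    for _ in range(n_perm):
        perm_mask = np.zeros(n, dtype=bool)
        perm_mask[rng.choice(n, size=k, replace=False)] = True
        if abs(_running_es(scores, perm_mask)) >= abs(es):
            exceed += 1
    return es, exceed / n_perm
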