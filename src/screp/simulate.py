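"""Deterministic synthetic-data generators with planted ground truth.

``simulate_repertoire`` emits cellranger-dialect contig tables, contig and
germline reference FASTA and a truth table with planted clonal lineages
(germline pick + planted CDR3 pair, per-cell Poisson substitution loads).
``simulate_gex`` emits an MTX-triplet expression matrix with planted
clusters, marker genes, mitochondrial fractions and a configurable barcode
overlap with the repertoire.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmwrite
from Bio.Seq import Seq

from screp import germline_pool
from screp.io import (
    CellReceptor,
    Chain,
    ContigRecord,
    Repertoire,
    assemble_cells,
    assign_isotype,
    filter_contigs,
    write_contigs,
)

_BASES = "ACGT"
# codons avoiding stop codons so planted CDR3s always translate cleanly
_SAFE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if str(Seq(a + b + c).translate()) != "*"
]

_ISOTYPE_C_GENE = {
    "IgA": "IGHA1",
    "IgD": "IGHD",
    "IgE": "IGHE",
    "IgG": "IGHG1",
    "IgM": "IGHM",
}


@dataclass(frozen=True)
class RepertoireSimSpec:
    """Parameters of a simulated paired-chain repertoire."""

    n_cells: int = 200
    n_clones: int = 20
    clone_size_law: str = "uniform"  # or "power_law"
    power_alpha: float = 1.5
    shm_rate: float = 0.0  # Poisson mean substitutions per chain
    isotype_mix: dict = field(
        default_factory=lambda: {"IgA": 0.3, "IgG": 0.3, "IgM": 0.4}
    )
    receptor: str = "BCR"  # or "TCR"
    seed: int = 0
    sample_id: str = "sample1"

    def __post_init__(self):
        if self.n_clones > self.n_cells:
            raise ValueError("n_clones must not exceed n_cells")
        if self.shm_rate < 0:
            raise ValueError("shm_rate must be >= 0")
        total = sum(self.isotype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("isotype_mix probabilities must sum to 1")
        if self.receptor not in ("BCR", "TCR"):
            raise ValueError("receptor must be 'BCR' or 'TCR'")
        if self.clone_size_law not in ("uniform", "power_law"):
            raise ValueError("clone_size_law must be 'uniform' or 'power_law'")


@dataclass
class SimulatedRepertoire:
    spec: RepertoireSimSpec
    contigs: list[ContigRecord]
    contig_fasta: dict[str, str]
    germline_fasta: dict[str, str]
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_contigs(self.contigs, outdir / "filtered_contig_annotations.csv")
        _write_fasta(self.contig_fasta, outdir / "filtered_contig.fasta")
        _write_fasta(self.germline_fasta, outdir / "concat_ref.fasta")
        self.truth.to_csv(outdir / "truth_repertoire.csv", index=False)
        return outdir

    def to_repertoire(self, doublet_policy: str = "drop") -> Repertoire:
        """Assemble the simulated contigs in memory (filter -> pair ->
        attach sequences -> germline refs)."""
        rep = assemble_cells(
            filter_contigs(self.contigs), self.spec.sample_id, doublet_policy
        )
        attached = []
        for cell in rep.cells:
            heavy = replace(cell.heavy, full_nt=self.contig_fasta[cell.heavy.contig_id])
            light = replace(cell.light, full_nt=self.contig_fasta[cell.light.contig_id])
            attached.append(
                CellReceptor(
                    barcode=cell.barcode,
                    sample_id=cell.sample_id,
                    heavy=heavy,
                    light=light,
                    isotype=cell.isotype,
                )
            )
        rep.cells = attached
        rep.germline_refs = dict(self.germline_fasta)
        return rep


def _write_fasta(seqs: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def _random_cdr3_nt(rng: np.random.Generator, n_aa: int) -> str:
    return "".join(rng.choice(_SAFE_CODONS) for _ in range(n_aa))


def _mutate(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    """Apply exactly n_sub substitutions at distinct positions."""
    n_sub = min(n_sub, len(seq))
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    chars = list(seq)
    for pos in positions:
        chars[pos] = rng.choice([b for b in _BASES if b != chars[pos]])
    return "".join(chars)


def _clone_sizes(spec: RepertoireSimSpec, rng: np.random.Generator) -> np.ndarray:
    k, n = spec.n_clones, spec.n_cells
    if spec.clone_size_law == "uniform":
        sizes = np.full(k, n // k)
        sizes[: n % k] += 1
        return sizes
    weights = np.arange(1, k + 1, dtype=float) ** (-spec.power_alpha)
    weights /= weights.sum()
    extra = rng.multinomial(n - k, weights)
    return np.ones(k, dtype=int) + extra


def _barcodes(rng: np.random.Generator, n: int) -> list[str]:
    seen: set[str] = set()
    out = []
    while len(out) < n:
        bc = "".join(rng.choice(list(_BASES), size=16))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def simulate_repertoire(spec: RepertoireSimSpec) -> SimulatedRepertoire:
    """Generate a repertoire with ``n_clones`` planted lineages.

    Each clone picks a heavy and a light germline entry and a random CDR3
    pair; the unmutated ``v_part + cdr3_nt + j_part`` concatenation is the
    clone's germline reference. Every cell carries Poisson(``shm_rate``)
    substitutions per chain (indel-free), applied uniformly over the full
    sequence, with CDR3 fields re-extracted after mutation. Outputs parse
    losslessly through the contig-table reader.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.receptor == "BCR":
        heavy_pool, light_pool = germline_pool.HEAVY, germline_pool.LIGHT
        heavy_chain, light_chains = Chain.IGH, [Chain.IGK, Chain.IGL]
        light_c = {"IGK": "IGKC", "IGL": "IGLC1"}
    else:
        heavy_pool, light_pool = germline_pool.TRB, germline_pool.TRA
        heavy_chain, light_chains = Chain.TRB, [Chain.TRA]
        light_c = {"TRA": "TRAC"}

    sizes = _clone_sizes(spec, rng)
    barcodes = _barcodes(rng, spec.n_cells)
    iso_labels = list(spec.isotype_mix)
    iso_probs = np.array([spec.isotype_mix[i] for i in iso_labels])

    contigs: list[ContigRecord] = []
    contig_fasta: dict[str, str] = {}
    germline_fasta: dict[str, str] = {}
    truth_rows = []
    cell_idx = 0
    for k, size in enumerate(sizes, start=1):
        clone_id = f"clonotype{k}"
        hg = heavy_pool[int(rng.integers(len(heavy_pool)))]
        lg = light_pool[int(rng.integers(len(light_pool)))]
        cdr3h_nt = _random_cdr3_nt(rng, int(rng.integers(8, 17)))
        cdr3l_nt = _random_cdr3_nt(rng, int(rng.integers(5, 12)))
        germ_h = hg.v_part + cdr3h_nt + hg.j_part
        germ_l = lg.v_part + cdr3l_nt + lg.j_part
        germline_fasta[f"{clone_id}_concat_ref_1"] = germ_h
        germline_fasta[f"{clone_id}_concat_ref_2"] = germ_l
        light_chain = light_chains[int(rng.integers(len(light_chains)))]
        for _ in range(size):
            barcode = barcodes[cell_idx]
            cell_idx += 1
            n_sub_h = int(rng.poisson(spec.shm_rate))
            n_sub_l = int(rng.poisson(spec.shm_rate))
            seq_h = _mutate(rng, germ_h, n_sub_h)
            seq_l = _mutate(rng, germ_l, n_sub_l)
            mut_cdr3h = seq_h[len(hg.v_part) : len(hg.v_part) + len(cdr3h_nt)]
            mut_cdr3l = seq_l[len(lg.v_part) : len(lg.v_part) + len(cdr3l_nt)]
            if spec.receptor == "BCR":
                isotype = str(rng.choice(iso_labels, p=iso_probs))
                c_gene_h = _ISOTYPE_C_GENE[isotype]
            else:
                isotype = "TR"
                c_gene_h = "TRBC1"
            umis_h, umis_l = int(rng.integers(2, 60)), int(rng.integers(2, 60))
            for suffix, chain, v, d, j, c, cdr3_nt, seq, umis in (
                ("_contig_1", heavy_chain, hg.v_gene, "IGHD3-10", hg.j_gene,
                 c_gene_h, mut_cdr3h, seq_h, umis_h),
                ("_contig_2", light_chain, lg.v_gene, None, lg.j_gene,
                 light_c[light_chain.value], mut_cdr3l, seq_l, umis_l),
            ):
                contig_id = barcode + suffix
                contigs.append(
                    ContigRecord(
                        barcode=barcode,
                        contig_id=contig_id,
                        chain=chain,
                        v_gene=v,
                        d_gene=d if chain.is_heavy_like else None,
                        j_gene=j,
                        c_gene=c,
                        cdr3_aa=str(Seq(cdr3_nt).translate()),
                        cdr3_nt=cdr3_nt,
                        productive=True,
                        high_confidence=True,
                        is_cell=True,
                        umis=umis,
                        reads=umis * 10,
                        raw_clonotype_id=clone_id,
                    )
                )
                contig_fasta[contig_id] = seq
            truth_rows.append(
                {
                    "barcode": barcode,
                    "clone_id": clone_id,
                    "n_sub_heavy": n_sub_h,
                    "n_sub_light": n_sub_l,
                    "isotype": isotype,
                    "sample_id": spec.sample_id,
                }
            )
    truth = pd.DataFrame(truth_rows)
    return SimulatedRepertoire(
        spec=spec,
        contigs=contigs,
        contig_fasta=contig_fasta,
        germline_fasta=germline_fasta,
        truth=truth,
    )


@dataclass(frozen=True)
class GexSimSpec:
    """Parameters of a simulated expression matrix with planted clusters."""

    n_cells: int = 200
    n_genes: int = 300
    n_clusters: int = 2
    n_markers_per_cluster: int = 20
    marker_mean: float = 25.0
    background_nb_n: float = 2.0
    background_nb_p: float = 0.5
    n_mito_genes: int = 5
    high_mito_fraction: float = 0.1  # fraction of cells pushed above 20% mito
    fraction_in_vdj: float = 0.5
    seed: int = 0
    sample_id: str = "sample1"

    def __post_init__(self):
        if self.n_clusters * self.n_markers_per_cluster > self.n_genes:
            raise ValueError("marker genes exceed n_genes")
        if not (0.0 <= self.fraction_in_vdj <= 1.0):
            raise ValueError("fraction_in_vdj must lie in [0, 1]")


@dataclass
class SimulatedGex:
    spec: GexSimSpec
    counts: sp.csr_matrix  # cells x genes
    barcodes: list[str]
    genes: list[str]
    truth: pd.DataFrame  # barcode, cluster, mito_fraction, in_vdj

    def to_anndata(self):
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.copy(),
            obs=pd.DataFrame(
                {"sample_id": self.spec.sample_id}, index=self.barcodes
            ),
            var=pd.DataFrame(index=self.genes),
        )
        return adata

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(self.counts.T))
        with open(outdir / "barcodes.tsv", "w") as fh:
            fh.write("\n".join(self.barcodes) + "\n")
        with open(outdir / "features.tsv", "w") as fh:
            for g in self.genes:
                fh.write(f"{g}\t{g}\tGene Expression\n")
        self.truth.to_csv(outdir / "truth_gex.csv", index=False)
        return outdir


def simulate_gex(
    spec: GexSimSpec, vdj_barcodes: Optional[Sequence[str]] = None
) -> SimulatedGex:
    """Generate counts with planted clusters, marker blocks and mito load.

    Cluster ``c`` elevates its disjoint marker block by Poisson(marker_mean)
    on top of negative-binomial background. A ``high_mito_fraction`` of cells
    receives a mitochondrial fraction drawn in (0.25, 0.45); the rest in
    (0, 0.15); realized fractions are recorded in the truth table. When
    ``vdj_barcodes`` is given, the first ``fraction_in_vdj * n_cells`` cells
    reuse those barcodes (with a '-1' suffix) to plant the GEX/VDJ overlap.
    """
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_cells, spec.n_genes
    counts = rng.negative_binomial(spec.background_nb_n, spec.background_nb_p, size=(n, g)).astype(float)

    clusters = rng.integers(spec.n_clusters, size=n)
    genes = [f"GENE{i:05d}" for i in range(g)]
    for c in range(spec.n_clusters):
        lo = c * spec.n_markers_per_cluster
        hi = lo + spec.n_markers_per_cluster
        members = clusters == c
        counts[np.ix_(members, np.arange(lo, hi))] += rng.poisson(
            spec.marker_mean, size=(int(members.sum()), hi - lo)
        )
        for i in range(lo, hi):
            genes[i] = f"MARKER{c}-{i - lo:03d}"

    # mitochondrial genes appended with planted per-cell target fractions
    mito_genes = [f"MT-{i}" for i in range(spec.n_mito_genes)]
    n_high = int(round(spec.high_mito_fraction * n))
    high_cells = rng.choice(n, size=n_high, replace=False)
    target = rng.uniform(0.0, 0.15, size=n)
    target[high_cells] = rng.uniform(0.25, 0.45, size=n_high)
    non_mito_totals = counts.sum(axis=1)
    mito_totals = np.round(target / (1 - target) * non_mito_totals)
    mito_block = np.zeros((n, spec.n_mito_genes))
    for i in range(n):
        mito_block[i] = rng.multinomial(int(mito_totals[i]), np.full(spec.n_mito_genes, 1 / spec.n_mito_genes))
    counts = np.hstack([counts, mito_block])
    genes = genes + mito_genes
    realized = mito_block.sum(axis=1) / (mito_block.sum(axis=1) + non_mito_totals)

    n_shared = int(np.floor(spec.fraction_in_vdj * n))
    if vdj_barcodes is not None:
        if n_shared > len(vdj_barcodes):
            raise ValueError("not enough VDJ barcodes to plant the overlap")
        shared = [f"{b}-1" for b in list(vdj_barcodes)[:n_shared]]
    else:
        shared = []
        n_shared = 0
    fresh = _barcodes(rng, n - n_shared)
    barcodes = shared + [f"{b}-1" for b in fresh]

    truth = pd.DataFrame(
        {
            "barcode": barcodes,
            "cluster": clusters,
            "mito_fraction": realized,
            "in_vdj": [i < n_shared for i in range(n)],
        }
    )
    return SimulatedGex(
        spec=spec,
        counts=sp.csr_matrix(counts),
        barcodes=barcodes,
        genes=genes,
        truth=truth,
    )
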