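"""Clone-level descriptive statistics.

Isotype composition per clone, paired CDR3 length distributions, position
probability matrices for logo rendering, V/J usage tables and diversity
indices.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from screp.clonotyping import Clonotype, rank_clones
from screp.io import Isotype

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


def isotype_per_clone(clonotypes: list[Clonotype], top_n: int) -> pd.DataFrame:
    """Cell-level isotype counts for the ``top_n`` most expanded clones.

    Rows are clones in expansion order; columns are isotype labels. Row sums
    equal clone sizes. Raises on T-cell input (TR constant genes carry no
    antibody isotype).
    """
    top = rank_clones(clonotypes, top_n)
    for clone in top:
        if any(
            cell.heavy is not None and not cell.heavy.chain.is_b_cell
            for cell in clone.members
        ):
            raise ValueError(
                "isotype_per_clone requires a B-cell repertoire; "
                "TR chains carry no isotype"
            )
    columns = [iso.value for iso in Isotype if iso is not Isotype.TR]
    rows = []
    for clone in top:
        counts = Counter(cell.isotype.value for cell in clone.members)
        rows.append([counts.get(col, 0) for col in columns])
    return pd.DataFrame(rows, index=[c.clonotype_id for c in top], columns=columns)


def cdr3_length_distribution(clonotypes: list[Clonotype]) -> dict[int, int]:
    """Histogram of combined CDRH3+CDRL3 amino-acid length, at clone level."""
    hist: Counter[int] = Counter()
    for clone in clonotypes:
        hist[len(clone.representative_cdr3h_aa) + len(clone.representative_cdr3l_aa)] += 1
    return dict(hist)


def position_probability_matrix(sequences: list[str]) -> pd.DataFrame:
    """Per-position amino-acid frequencies for equal-length sequences.

    Returns an L x 20 DataFrame whose rows sum to 1 (positions are rows to
    match logo-tool input conventions; ``.values[pos, aa]`` is the frequency
    of ``aa`` at ``pos``).
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    length = len(sequences[0])
    if length < 1:
        raise ValueError("sequences must be non-empty")
    if any(len(s) != length for s in sequences):
        raise ValueError("all sequences must have equal length")
    counts = np.zeros((length, len(AMINO_ACIDS)))
    index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for seq in sequences:
        for pos, aa in enumerate(seq):
            if aa not in index:
                raise ValueError(f"unknown amino acid {aa!r} at position {pos}")
            counts[pos, index[aa]] += 1
    return pd.DataFrame(
        counts / len(sequences), index=range(1, length + 1), columns=list(AMINO_ACIDS)
    )


def vj_pairing_counts(
    clonotypes: list[Clonotype],
    chain: str,
    top_n_clones: int,
    cell_level: bool = True,
    count_threshold: int = 1,
    label_threshold: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """V-J gene pair counts among the most expanded clones.

    ``chain`` is ``"heavy"`` or ``"light"``. With ``cell_level`` each member
    cell contributes one count, otherwise each clone contributes one. Pairs
    below ``count_threshold`` are dropped; the returned boolean mask marks
    pairs at or above ``label_threshold``.
    """
    if chain not in ("heavy", "light"):
        raise ValueError(f"unknown chain {chain!r}; expected 'heavy' or 'light'")
    top = rank_clones(clonotypes, top_n_clones)
    counts: Counter[tuple[str, str]] = Counter()
    for clone in top:
        pair = (clone.hv, clone.hj) if chain == "heavy" else (clone.lv, clone.lj)
        counts[pair] += clone.size if cell_level else 1
    counts = Counter({k: v for k, v in counts.items() if v >= count_threshold})
    v_genes = sorted({v for v, _ in counts})
    j_genes = sorted({j for _, j in counts})
    matrix = pd.DataFrame(0, index=v_genes, columns=j_genes)
    for (v, j), n in counts.items():
        matrix.loc[v, j] = n
    label_mask = matrix >= label_threshold
    return matrix, label_mask


def vgene_usage(
    clonotypes: list[Clonotype], top_n_genes: int, clone_level: bool = True
) -> pd.Series:
    """Heavy-chain V gene usage, descending, first ``top_n_genes`` genes."""
    if top_n_genes <= 0:
        raise ValueError("top_n_genes must be positive")
    counts: Counter[str] = Counter()
    for clone in clonotypes:
        counts[clone.hv] += 1 if clone_level else clone.size
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n_genes]
    return pd.Series(dict(ordered), dtype=int).reindex([g for g, _ in ordered])


def vgene_usage_by_sample(
    clonotypes_by_sample: dict[str, list[Clonotype]],
    top_n_genes: int,
    clone_level: bool = True,
) -> pd.DataFrame:
    """Per-sample V gene usage over the union of each sample's top genes."""
    per_sample = {
        sample: vgene_usage(clones, top_n_genes, clone_level)
        for sample, clones in clonotypes_by_sample.items()
    }
    union = sorted(set().union(*(set(s.index) for s in per_sample.values())))
    table = pd.DataFrame(0, index=union, columns=sorted(per_sample))
    for sample, series in per_sample.items():
        full = vgene_usage(clonotypes_by_sample[sample], len(union) + top_n_genes,
                           clone_level)
        for gene in union:
            table.loc[gene, sample] = int(full.get(gene, 0))
    return table


def diversity(clone_sizes: list[int], metric: str = "shannon") -> float:
    """Clonal diversity of a size distribution.

    shannon = -sum p ln p (nats); simpson = sum p^2; gini_simpson = 1 - simpson.
    """
    if not clone_sizes:
        raise ValueError("need at least one clone")
    if any(s <= 0 for s in clone_sizes):
        raise ValueError("clone sizes must be positive")
    p = np.asarray(clone_sizes, dtype=float)
    p = p / p.sum()
    if metric == "shannon":
        return float(-(p * np.log(p)).sum())
    if metric == "simpson":
        return float((p**2).sum())
    if metric == "gini_simpson":
        return float(1.0 - (p**2).sum())
    raise ValueError(f"unknown diversity metric: {metric!r}")
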