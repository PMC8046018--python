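"""Clonotype calling under multiple grouping strategies and expansion ranking.

Strategies range from strict (identical paired CDR3 nucleotide sequence)
to relaxed (shared germline V/J genes, equal CDR3 lengths and a CDR3
amino-acid homology threshold with single-linkage merging).
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from screp.io import CellReceptor, Repertoire

STRATEGIES = (
    "cdr3.nt",
    "cdr3.aa",
    "hvj.lvj",
    "hvj.lvj.cdr3lengths",
    "hvj.lvj.cdr3length.cdr3homology",
)

_ALLELE = re.compile(r"\*\d+$")


def strip_allele(gene: str) -> str:
    """Drop a trailing IMGT-style allele suffix ('IGHV1-18*01' -> 'IGHV1-18')."""
    return _ALLELE.sub("", gene)


@dataclass(frozen=True)
class ClonotypeStrategy:
    """Named grouping strategy; ``homology_threshold`` applies only to the
    homology strategy."""

    name: str = "cdr3.nt"
    homology_threshold: float = 0.70

    def __post_init__(self):
        if self.name not in STRATEGIES:
            raise ValueError(
                f"unknown strategy {self.name!r}; expected one of {STRATEGIES}"
            )
        if not (0.0 <= self.homology_threshold <= 1.0):
            raise ValueError("homology_threshold must lie in [0, 1]")


@dataclass
class Clonotype:
    """A group of cells sharing a receptor under a grouping strategy."""

    clonotype_id: str
    strategy: ClonotypeStrategy
    barcodes: set[str]
    sample_id: str
    representative_cdr3h_aa: str
    representative_cdr3l_aa: str
    representative_cdr3h_nt: str
    representative_cdr3l_nt: str
    hv: str
    hj: str
    lv: str
    lj: str
    members: list[CellReceptor] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.barcodes)


def hamming_similarity(a: str, b: str) -> float:
    """1 - Hamming(a, b) / len for equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming similarity requires equal-length strings")
    if not a:
        return 1.0
    mismatches = sum(x != y for x, y in zip(a, b))
    return 1.0 - mismatches / len(a)


def _vj_key(cell: CellReceptor) -> tuple[str, str, str, str]:
    return (
        strip_allele(cell.heavy.v_gene),
        strip_allele(cell.heavy.j_gene),
        strip_allele(cell.light.v_gene),
        strip_allele(cell.light.j_gene),
    )


def _group_keys(cells: list[CellReceptor], strategy: ClonotypeStrategy):
    """Return a hashable grouping key per cell for the exact-key strategies."""
    name = strategy.name
    keys = []
    for cell in cells:
        if name == "cdr3.nt":
            keys.append(cell.heavy.cdr3_nt + "|" + cell.light.cdr3_nt)
        elif name == "cdr3.aa":
            keys.append(cell.heavy.cdr3_aa + "|" + cell.light.cdr3_aa)
        elif name == "hvj.lvj":
            keys.append(_vj_key(cell))
        elif name in ("hvj.lvj.cdr3lengths", "hvj.lvj.cdr3length.cdr3homology"):
            keys.append(
                _vj_key(cell) + (len(cell.heavy.cdr3_aa), len(cell.light.cdr3_aa))
            )
        else:  # pragma: no cover - guarded by ClonotypeStrategy
            raise AssertionError(name)
    return keys


def _single_linkage(concats: list[str], threshold: float) -> list[int]:
    """Union-find single-linkage over equal-length strings; two items link
    when Hamming similarity >= threshold. Returns a component label per item."""
    n = len(concats)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    # deduplicate identical strings first: identical -> similarity 1 >= any t
    first_of: dict[str, int] = {}
    for i, s in enumerate(concats):
        if s in first_of:
            parent[find(i)] = find(first_of[s])
        else:
            first_of[s] = i
    uniq = list(first_of.items())
    for a in range(len(uniq)):
        sa, ia = uniq[a]
        for b in range(a + 1, len(uniq)):
            sb, ib = uniq[b]
            if hamming_similarity(sa, sb) >= threshold:
                ra, rb = find(ia), find(ib)
                if ra != rb:
                    parent[ra] = rb
    return [find(i) for i in range(n)]


def clonotype_cells(
    repertoire: Repertoire, strategy: ClonotypeStrategy
) -> list[Clonotype]:
    """Partition a paired repertoire into clonotypes.

    The returned list is ordered by descending clone size (ties broken by
    lexicographic representative CDR3 nucleotide sequence), and
    ``clonotype_id`` encodes the strategy name and rank, so the output is
    deterministic and invariant to input cell order.
    """
    cells = list(repertoire.cells)
    for cell in cells:
        if not cell.paired:
            raise ValueError(f"unpaired cell in repertoire: {cell.barcode}")

    groups: dict = defaultdict(list)
    if strategy.name == "hvj.lvj.cdr3length.cdr3homology":
        pre = defaultdict(list)
        for cell, key in zip(cells, _group_keys(cells, strategy)):
            pre[key].append(cell)
        for key in pre:
            members = sorted(pre[key], key=lambda c: c.barcode)
            concats = [c.heavy.cdr3_aa + c.light.cdr3_aa for c in members]
            labels = _single_linkage(concats, strategy.homology_threshold)
            for cell, lab in zip(members, labels):
                groups[(key, lab)].append(cell)
    else:
        for cell, key in zip(cells, _group_keys(cells, strategy)):
            groups[key].append(cell)

    clonotypes = []
    for members in groups.values():
        members = sorted(members, key=lambda c: c.barcode)
        # representative = most common paired CDR3, ties lexicographic
        counts = Counter(
            (c.heavy.cdr3_aa, c.light.cdr3_aa, c.heavy.cdr3_nt, c.light.cdr3_nt)
            for c in members
        )
        rep = min(counts, key=lambda k: (-counts[k], k))
        lead = members[0]
        clonotypes.append(
            Clonotype(
                clonotype_id="",
                strategy=strategy,
                barcodes={c.barcode for c in members},
                sample_id=repertoire.sample_id,
                representative_cdr3h_aa=rep[0],
                representative_cdr3l_aa=rep[1],
                representative_cdr3h_nt=rep[2],
                representative_cdr3l_nt=rep[3],
                hv=strip_allele(lead.heavy.v_gene),
                hj=strip_allele(lead.heavy.j_gene),
                lv=strip_allele(lead.light.v_gene),
                lj=strip_allele(lead.light.j_gene),
                members=members,
            )
        )
    clonotypes.sort(
        key=lambda c: (
            -c.size,
            c.representative_cdr3h_nt + c.representative_cdr3l_nt,
        )
    )
    for rank, clone in enumerate(clonotypes, start=1):
        clone.clonotype_id = f"{strategy.name}_{rank}"
    return clonotypes


def count_clones(repertoire: Repertoire, strategy: ClonotypeStrategy) -> int:
    """Number of clonotypes under the given strategy."""
    return len(clonotype_cells(repertoire, strategy))


def rank_clones(clonotypes: list[Clonotype], top_n: int) -> list[Clonotype]:
    """Most expanded ``top_n`` clones, descending size, deterministic ties."""
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    ordered = sorted(
        clonotypes,
        key=lambda c: (
            -c.size,
            c.representative_cdr3h_nt + c.representative_cdr3l_nt,
            c.clonotype_id,
        ),
    )
    return ordered[:top_n]
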