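"""Somatic hypermutation quantification and germline-rooted clone trees.

Mutations are counted as substitution columns in a global alignment between a
cell's full-length V(D)J nucleotide sequence and the extracted germline
reference. Clone trees are neighbor-joining trees over pairwise alignment
distances of collapsed unique heavy+light concatenations, rooted at the
germline.
"""

from __future__ import annotations

import hashlib
import io as _stdio
import logging
from dataclasses import dataclass

from Bio import Phylo
from Bio.Align import PairwiseAligner
from Bio.Phylo.TreeConstruction import DistanceMatrix, DistanceTreeConstructor

from screp.clonotyping import Clonotype
from screp.io import Repertoire

logger = logging.getLogger(__name__)

#: Global alignment scoring for mismatch counting (config-exposed).
DEFAULT_SCORING = {
    "match_score": 1.0,
    "mismatch_score": -1.0,
    "open_gap_score": -4.0,
    "extend_gap_score": -1.0,
}

GERMLINE_LABEL = "germline"


@dataclass(frozen=True)
class SHMRecord:
    """Per-cell mismatch counts against the clone germline."""

    barcode: str
    clonotype_id: str
    mismatches_heavy: int
    mismatches_light: int

    @property
    def total(self) -> int:
        return self.mismatches_heavy + self.mismatches_light


@dataclass(frozen=True)
class TreeTip:
    label: str
    n_cells: int
    sequence_hash: str


@dataclass
class CloneTree:
    newick: str
    tips: list[TreeTip]
    root_label: str = GERMLINE_LABEL


def _make_aligner(**scoring) -> PairwiseAligner:
    params = {**DEFAULT_SCORING, **scoring}
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params["match_score"]
    aligner.mismatch_score = params["mismatch_score"]
    aligner.open_gap_score = params["open_gap_score"]
    aligner.extend_gap_score = params["extend_gap_score"]
    return aligner


def align_mismatches(a: str, b: str, **scoring) -> tuple[int, int]:
    """(substitution columns, gap columns) of the best global alignment."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(**scoring)
    alignment = aligner.align(a, b)[0]
    top, bottom = str(alignment[0]), str(alignment[1])
    substitutions = 0
    gaps = 0
    for x, y in zip(top, bottom):
        if x == "-" or y == "-":
            gaps += 1
        elif x != y:
            substitutions += 1
    return substitutions, gaps


def count_shm(cell_seq: str, germline_seq: str, **scoring) -> int:
    """Nucleotide substitution count between a cell sequence and its
    germline (gap columns excluded; see :func:`align_mismatches`)."""
    return align_mismatches(cell_seq, germline_seq, **scoring)[0]


def germline_ref_ids(clonotype: Clonotype) -> tuple[str, str]:
    """Reference ids for a clone's heavy and light germline sequences.

    Follows the cellranger concatenated-reference naming:
    ``<raw_clonotype_id>_concat_ref_1`` (heavy) and ``..._2`` (light).
    """
    ids = {c.heavy.raw_clonotype_id for c in clonotype.members if c.heavy is not None}
    ids.discard(None)
    if not ids:
        raise KeyError(
            f"clone {clonotype.clonotype_id}: no raw_clonotype_id on members"
        )
    rcid = sorted(ids)[0]
    return f"{rcid}_concat_ref_1", f"{rcid}_concat_ref_2"


def extract_germline(
    repertoire: Repertoire, clonotype: Clonotype
) -> tuple[str, str]:
    """Paired (heavy, light) germline nucleotide sequences for a clone."""
    hid, lid = germline_ref_ids(clonotype)
    try:
        return repertoire.germline_refs[hid], repertoire.germline_refs[lid]
    except KeyError as exc:
        raise KeyError(
            f"missing germline reference {exc.args[0]!r} for clone "
            f"{clonotype.clonotype_id}"
        ) from None


def shm_records(
    repertoire: Repertoire, clonotype: Clonotype
) -> list[SHMRecord]:
    """Per-cell heavy/light mismatch counts for one clone.

    Cells without attached full-length sequences are skipped with a warning.
    """
    germ_h, germ_l = extract_germline(repertoire, clonotype)
    records = []
    for cell in clonotype.members:
        if cell.heavy.full_nt is None or cell.light.full_nt is None:
            logger.warning(
                "cell %s in clone %s has no attached sequence; skipped",
                cell.barcode,
                clonotype.clonotype_id,
            )
            continue
        records.append(
            SHMRecord(
                barcode=cell.barcode,
                clonotype_id=clonotype.clonotype_id,
                mismatches_heavy=count_shm(cell.heavy.full_nt, germ_h),
                mismatches_light=count_shm(cell.light.full_nt, germ_l),
            )
        )
    return records


def shm_per_clone(
    repertoire: Repertoire, clonotypes: list[Clonotype], top_n: int
) -> list[tuple[str, float]]:
    """Mean heavy+light mismatch count per clone, in expansion-rank order.

    Clones with no attached sequences are omitted with a warning.
    """
    from screp.clonotyping import rank_clones

    result = []
    for clone in rank_clones(clonotypes, top_n):
        records = shm_records(repertoire, clone)
        if not records:
            logger.warning(
                "clone %s has no attached sequences; omitted", clone.clonotype_id
            )
            continue
        result.append(
            (clone.clonotype_id, sum(r.total for r in records) / len(records))
        )
    return result


def _alignment_distance(a: str, b: str) -> int:
    subs, gaps = align_mismatches(a, b)
    return subs + gaps


def _sequence_hash(seq: str) -> str:
    return hashlib.sha1(seq.encode()).hexdigest()[:10]


def build_clone_tree(
    clonotype: Clonotype, germline: tuple[str, str]
) -> CloneTree:
    """Neighbor-joining clone tree rooted at the germline.

    Each cell's heavy and light full-length sequences are concatenated;
    identical concatenations collapse to one tip carrying ``n_cells``.
    Distances are substitution + gap columns of the pairwise global
    alignment. The tree is emitted as Newick with the germline as root.
    """
    variants: dict[str, list[str]] = {}
    for cell in clonotype.members:
        if cell.heavy.full_nt is None or cell.light.full_nt is None:
            continue
        concat = cell.heavy.full_nt + cell.light.full_nt
        variants.setdefault(concat, []).append(cell.barcode)
    if not variants:
        raise ValueError(
            f"clone {clonotype.clonotype_id} has no attached sequences"
        )
    germ_concat = germline[0] + germline[1]

    # stable variant order: most cells first, then lexicographic sequence
    ordered = sorted(variants.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    tips = [
        TreeTip(
            label=f"variant{i}_{len(barcodes)}cells",
            n_cells=len(barcodes),
            sequence_hash=_sequence_hash(seq),
        )
        for i, (seq, barcodes) in enumerate(ordered, start=1)
    ]
    labels = [GERMLINE_LABEL] + [t.label for t in tips]
    seqs = [germ_concat] + [seq for seq, _ in ordered]

    if len(seqs) == 2:
        if seqs[0] == seqs[1]:
            logger.warning(
                "clone %s identical to germline; degenerate two-taxon tree",
                clonotype.clonotype_id,
            )
        d = _alignment_distance(seqs[0], seqs[1])
        newick = f"({labels[0]}:0.0,{labels[1]}:{float(d)}):0.0;"
        return CloneTree(newick=newick, tips=tips)

    matrix = [
        [float(_alignment_distance(seqs[i], seqs[j])) for j in range(i)] + [0.0]
        for i in range(len(seqs))
    ]
    dm = DistanceMatrix(names=labels, matrix=matrix)
    tree = DistanceTreeConstructor().nj(dm)
    tree.root_with_outgroup(GERMLINE_LABEL)
    for clade in tree.get_nonterminals():
        clade.name = None  # drop NJ's auto inner labels
    handle = _stdio.StringIO()
    Phylo.write(tree, handle, "newick")
    return CloneTree(newick=handle.getvalue().strip(), tips=tips)
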