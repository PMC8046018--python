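"""Reading, validation and per-cell assembly of VDJ contig tables.

Consumes the cellranger ``filtered_contig_annotations.csv`` dialect plus
contig/germline FASTA files, and assembles one paired-chain record per cell
barcode with deterministic tie-breaking.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)


class Chain(str, enum.Enum):
    IGH = "IGH"
    IGK = "IGK"
    IGL = "IGL"
    TRA = "TRA"
    TRB = "TRB"

    @property
    def is_heavy_like(self) -> bool:
        """IGH and TRB carry the D segment and define the 'heavy' slot."""
        return self in (Chain.IGH, Chain.TRB)

    @property
    def is_b_cell(self) -> bool:
        return self in (Chain.IGH, Chain.IGK, Chain.IGL)


class Isotype(str, enum.Enum):
    IgA = "IgA"
    IgD = "IgD"
    IgE = "IgE"
    IgG = "IgG"
    IgM = "IgM"
    TR = "TR"
    unknown = "unknown"


#: CSV columns that must be present in a contig annotation table.
REQUIRED_COLUMNS = (
    "barcode",
    "chain",
    "v_gene",
    "j_gene",
    "cdr3",
    "cdr3_nt",
    "productive",
    "high_confidence",
    "is_cell",
    "umis",
)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


@dataclass(frozen=True)
class ContigRecord:
    """One sequenced receptor chain of one cell barcode."""

    barcode: str
    contig_id: str
    chain: Chain
    v_gene: str
    j_gene: str
    cdr3_aa: str
    cdr3_nt: str
    productive: bool
    high_confidence: bool
    is_cell: bool
    umis: int
    reads: int = 0
    d_gene: Optional[str] = None
    c_gene: Optional[str] = None
    raw_clonotype_id: Optional[str] = None
    full_nt: Optional[str] = None


@dataclass(frozen=True)
class CellReceptor:
    """A barcode's paired heavy/light (or beta/alpha) chains."""

    barcode: str
    sample_id: str
    heavy: Optional[ContigRecord] = None
    light: Optional[ContigRecord] = None
    isotype: Isotype = Isotype.unknown

    @property
    def paired(self) -> bool:
        return self.heavy is not None and self.light is not None


@dataclass
class Repertoire:
    """All paired cells of one sample plus optional germline references."""

    sample_id: str
    cells: list[CellReceptor] = field(default_factory=list)
    germline_refs: dict[str, str] = field(default_factory=dict)
    unpaired: list[CellReceptor] = field(default_factory=list)
    assembly_summary: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.cells)

    def barcodes(self) -> set[str]:
        return {c.barcode for c in self.cells}


_TRUE = {"true", "t", "1", "yes"}
_FALSE = {"false", "f", "0", "no", "none", ""}


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if pd.isna(value):
        return False
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValueError(f"unparseable boolean value: {value!r}")


def _opt(value) -> Optional[str]:
    """Map cellranger's empty/'None' cells to absent."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    if text in ("", "None", "nan", "NA"):
        return None
    return text


def load_contigs(path: str | Path) -> list[ContigRecord]:
    """Read a cellranger-style contig annotation CSV.

    Booleans are accepted case-insensitively; missing ``c_gene``/``d_gene``
    map to absent. Raises :class:`SchemaError` naming the first missing
    required column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    if df.empty:
        logger.warning("contig table %s is empty", path)
        return []
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ContigRecord(
                barcode=row.barcode,
                contig_id=getattr(row, "contig_id", row.barcode),
                chain=Chain(row.chain),
                v_gene=row.v_gene,
                d_gene=_opt(getattr(row, "d_gene", None)),
                j_gene=row.j_gene,
                c_gene=_opt(getattr(row, "c_gene", None)),
                cdr3_aa=_opt(row.cdr3) or "",
                cdr3_nt=_opt(row.cdr3_nt) or "",
                productive=_parse_bool(row.productive),
                high_confidence=_parse_bool(row.high_confidence),
                is_cell=_parse_bool(row.is_cell),
                umis=int(row.umis),
                reads=int(getattr(row, "reads", 0) or 0),
                raw_clonotype_id=_opt(getattr(row, "raw_clonotype_id", None)),
            )
        )
    return records


def write_contigs(contigs: Iterable[ContigRecord], path: str | Path) -> None:
    """Write records back to the contig-CSV dialect (round-trips with
    :func:`load_contigs`)."""
    rows = []
    for c in contigs:
        rows.append(
            {
                "barcode": c.barcode,
                "is_cell": str(c.is_cell),
                "contig_id": c.contig_id,
                "high_confidence": str(c.high_confidence),
                "chain": c.chain.value,
                "v_gene": c.v_gene,
                "d_gene": c.d_gene if c.d_gene is not None else "None",
                "j_gene": c.j_gene,
                "c_gene": c.c_gene if c.c_gene is not None else "None",
                "productive": str(c.productive),
                "cdr3": c.cdr3_aa,
                "cdr3_nt": c.cdr3_nt,
                "reads": c.reads,
                "umis": c.umis,
                "raw_clonotype_id": (
                    c.raw_clonotype_id if c.raw_clonotype_id is not None else "None"
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def filter_contigs(contigs: Iterable[ContigRecord]) -> list[ContigRecord]:
    """Keep productive, high-confidence, cell-associated contigs with a CDR3."""
    return [
        c
        for c in contigs
        if c.productive and c.high_confidence and c.is_cell and c.cdr3_aa
    ]


def assign_isotype(c_gene: Optional[str]) -> Isotype:
    """Derive antibody isotype from the heavy-chain constant gene name."""
    if not c_gene:
        return Isotype.unknown
    for prefix, iso in (
        ("IGHA", Isotype.IgA),
        ("IGHG", Isotype.IgG),
        ("IGHM", Isotype.IgM),
        ("IGHD", Isotype.IgD),
        ("IGHE", Isotype.IgE),
    ):
        if c_gene.startswith(prefix):
            return iso
    if c_gene.startswith("TR"):
        return Isotype.TR
    return Isotype.unknown


def _contig_sort_key(c: ContigRecord):
    # highest UMIs first; ties -> higher reads, then lexicographic contig_id
    return (-c.umis, -c.reads, c.contig_id)


def assemble_cells(
    contigs: Iterable[ContigRecord],
    sample_id: str,
    doublet_policy: str = "drop",
) -> Repertoire:
    """Group filtered contigs by barcode into paired cell records.

    Within each locus class (heavy-like = IGH/TRB, light-like = IGK/IGL/TRA)
    the highest-UMI contig wins, with deterministic tie-breaks. Barcodes with
    two or more contigs in the same class are dropped under ``drop`` or
    resolved to the top-UMI contig under ``keep_top_umi``. Barcodes mixing B
    and T chains are always dropped as suspected doublets. Unpaired barcodes
    are kept in ``repertoire.unpaired`` and excluded from ``cells``.
    """
    if doublet_policy not in ("drop", "keep_top_umi"):
        raise ValueError(f"unknown doublet_policy: {doublet_policy!r}")

    by_barcode: dict[str, list[ContigRecord]] = {}
    for c in contigs:
        by_barcode.setdefault(c.barcode, []).append(c)

    rep = Repertoire(sample_id=sample_id)
    summary = {
        "barcodes": len(by_barcode),
        "paired": 0,
        "unpaired": 0,
        "dropped_multichain": 0,
        "dropped_mixed_bt": 0,
    }
    for barcode in sorted(by_barcode):
        group = by_barcode[barcode]
        if {c.chain.is_b_cell for c in group} == {True, False}:
            summary["dropped_mixed_bt"] += 1
            logger.info("barcode %s mixes B and T chains; dropped as doublet", barcode)
            continue
        heavy = sorted((c for c in group if c.chain.is_heavy_like), key=_contig_sort_key)
        light = sorted(
            (c for c in group if not c.chain.is_heavy_like), key=_contig_sort_key
        )
        if doublet_policy == "drop" and (len(heavy) > 1 or len(light) > 1):
            summary["dropped_multichain"] += 1
            continue
        h = heavy[0] if heavy else None
        l = light[0] if light else None
        cell = CellReceptor(
            barcode=barcode,
            sample_id=sample_id,
            heavy=h,
            light=l,
            isotype=assign_isotype(h.c_gene) if h is not None else Isotype.unknown,
        )
        if cell.paired:
            rep.cells.append(cell)
            summary["paired"] += 1
        else:
            rep.unpaired.append(cell)
            summary["unpaired"] += 1
    rep.assembly_summary = summary
    return rep


def attach_sequences(repertoire: Repertoire, fasta: str | Path) -> Repertoire:
    """Populate ``full_nt`` on contigs from a FASTA keyed by contig id.

    Unmatched contigs are left absent and counted in
    ``assembly_summary['unmatched_fasta']``. Duplicate FASTA ids are an error.
    """
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta), "fasta"):
        if record.id in seqs:
            raise ValueError(f"duplicate FASTA id: {record.id}")
        seqs[record.id] = str(record.seq).upper()

    unmatched = 0

    def _attach(contig: Optional[ContigRecord]) -> Optional[ContigRecord]:
        nonlocal unmatched
        if contig is None:
            return None
        if contig.contig_id in seqs:
            return replace(contig, full_nt=seqs[contig.contig_id])
        unmatched += 1
        return contig

    new_cells = []
    for cell in repertoire.cells:
        new_cells.append(
            CellReceptor(
                barcode=cell.barcode,
                sample_id=cell.sample_id,
                heavy=_attach(cell.heavy),
                light=_attach(cell.light),
                isotype=cell.isotype,
            )
        )
    repertoire.cells = new_cells
    repertoire.assembly_summary["unmatched_fasta"] = unmatched
    if unmatched:
        logger.warning("%d contigs had no matching FASTA entry", unmatched)
    return repertoire


def load_germline_refs(fasta: str | Path) -> dict[str, str]:
    """Load a germline reference FASTA into an id -> sequence map."""
    refs: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta), "fasta"):
        if record.id in refs:
            raise ValueError(f"duplicate germline reference id: {record.id}")
        refs[record.id] = str(record.seq).upper()
    return refs
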