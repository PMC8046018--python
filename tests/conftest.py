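import pytest

from screp.io import Chain, ContigRecord
from screp.simulate import (
    GexSimSpec,
    RepertoireSimSpec,
    simulate_gex,
    simulate_repertoire,
)


def make_contig(
    barcode="AAACCTGAGAAACCAT",
    contig_id=None,
    chain=Chain.IGH,
    v_gene="IGHV1-18",
    j_gene="IGHJ4",
    cdr3_aa="CARDYW",
    cdr3_nt="TGTGCTCGTGATTATTGG",
    c_gene="IGHG1",
    umis=5,
    reads=50,
    **kwargs,
):
    return ContigRecord(
        barcode=barcode,
        contig_id=contig_id or f"{barcode}_contig_1",
        chain=chain,
        v_gene=v_gene,
        j_gene=j_gene,
        cdr3_aa=cdr3_aa,
        cdr3_nt=cdr3_nt,
        productive=kwargs.pop("productive", True),
        high_confidence=kwargs.pop("high_confidence", True),
        is_cell=kwargs.pop("is_cell", True),
        umis=umis,
        reads=reads,
        c_gene=c_gene,
        **kwargs,
    )


def make_pair(barcode, cdr3h_aa="CARDYW", cdr3l_aa="CQQSYSTPYTF", hv="IGHV1-18",
              hj="IGHJ4", lv="IGKV1-39", lj="IGKJ1", c_gene="IGHG1",
              cdr3h_nt=None, cdr3l_nt=None):
    """One heavy + one light contig for a barcode (aa-consistent nt defaults)."""
    heavy = make_contig(
        barcode=barcode,
        contig_id=f"{barcode}_contig_1",
        chain=Chain.IGH,
        v_gene=hv,
        j_gene=hj,
        cdr3_aa=cdr3h_aa,
        cdr3_nt=cdr3h_nt or "NNN" * len(cdr3h_aa),
        c_gene=c_gene,
    )
    light = make_contig(
        barcode=barcode,
        contig_id=f"{barcode}_contig_2",
        chain=Chain.IGK,
        v_gene=lv,
        j_gene=lj,
        cdr3_aa=cdr3l_aa,
        cdr3_nt=cdr3l_nt or "NNN" * len(cdr3l_aa),
        c_gene="IGKC",
    )
    return [heavy, light]


@pytest.fixture(scope="session")
def sim():
    return simulate_repertoire(
        RepertoireSimSpec(
            n_cells=100,
            n_clones=20,
            clone_size_law="power_law",
            shm_rate=1.5,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def repertoire(sim):
    return sim.to_repertoire()


@pytest.fixture(scope="session")
def gex_sim(sim):
    return simulate_gex(
        GexSimSpec(n_cells=150, n_genes=300, n_clusters=2, seed=11,
                   fraction_in_vdj=0.5),
        vdj_barcodes=sim.truth["barcode"].tolist(),
    )
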