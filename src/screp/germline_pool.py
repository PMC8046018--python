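"""Fixed in-repo germline segment mini-pool for the simulator.

Each entry holds a V-side and a J-side nucleotide stretch; a full-length
variable region is formed as ``v_part + cdr3_nt + j_part``. Sequences are
arbitrary fixed strings of realistic length — no external reference download
is required or attempted.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GermlineSegment:
    v_gene: str
    j_gene: str
    v_part: str
    j_part: str


HEAVY = [
    GermlineSegment("IGHV1-18", "IGHJ4",
        "GAGTACAGCCACAACCCGAATAGATAAATAACCAGTCAACTGGTACAGCGTCTTTTTAAATTATTGTCGTACCCAAAAAAGAAGGAGAGTTCGAGGCACCATTAACGACTTCAAACTTTAGGGACTCGCTTTATCACCTCCGTATAGTTTAAAAGAATCGCGGGAAGTTTGAATCGGCAGATGGTACGTAAGAGTGCTTTCCTTCTCTTT",
        "TCAGAGCACTACCCAAAGCCTTCCCGGTGGTAGGGGTATCAGACTCAT"),
    GermlineSegment("IGHV3-23", "IGHJ6",
        "AAGCAACCGATCTTCCCCCACGCCGGCGAATGAGTTTAGGCCAACTTCGTTAACCATGCATAACTACTGTTGCATGATCTGGATGCCACAAACGCAACCAGTAGGTAAGTCTGCCATTGGACTAGCTGAGCCAACCGTGTTCACTGAGTCTGGGTTTCTCCGGTTAAAATTTAGAACCCTCTGGAGAATACTTGAAGAATGAACGAGCGA",
        "CTGGATCGAATGCTGATGCATGATACTACTGCCCGCCCAAGAACGGTA"),
    GermlineSegment("IGHV4-34", "IGHJ3",
        "CTCACTTTGTCCAGCTCTTTATTAATGCATTATCCGGCACTTATCGGTCCCCACAGATCCCGGATAGGTTACACCCGCAAGCACCCCTCGGTTCACGGCGCCCTCACATATTCTCGCGACTCACTCCCCGCTCTTGGCCGTACAGCGCGTAATCGACATAATCCTGTTACATAGACCCCTCCTGGATAAGAGACCGCCAGAATGCAACTT",
        "TTGTACGTCTTGGGAATACACAGTGTGAGGTCATCGACCATTTGTGGG"),
    GermlineSegment("IGHV1-69", "IGHJ4",
        "CACTAAGAAGAGCTCACTTCTTTTATGAAGGCGGACAACACTTTGGACATTTTTGTTGAACGCCACATCTTGAAGCCAAGCTTGTGGGATGTGTCGCGAGGGGTAATATCTGCTATGAAAGCTTCCAGACTCACATTTTCGAGTGAACTGGTACTCTCATGATCTAGGCCCCAGTAACGCTAGACCGACTTCCCTCTGCGCGAACCCTTA",
        "ACGACAAACCATGCCTGGTACTTATTAGCTGAGTGCGTCGTGGACTCT"),
    GermlineSegment("IGHV3-30", "IGHJ5",
        "GGCGACGTCTGCGCTAGTAGTGTGTGGTTTATACCCAAATTTACGGGGCTTCGCTGGCATGGATGCGGTACCGAGGCCATGTTATGTCAACGCAGTGTGCAGATCAGTGTGCAATTTTACCTAATATACAGCACATGGGGCACGTCGCATGTATTGCGTGCCAGACTGGGATTCGTTCCCTACATAGGCGATTATGACAGGTACCCGAGC",
        "ACCTTGAATGTGAAGGGACTTCGACGTTTCCTCCCTGCGGCACTTTGA"),
    GermlineSegment("IGHV5-51", "IGHJ2",
        "GAACCGCTTAGCCACGACTCGTCCGCTCGGTTAACGATCTTCAATGGGGAAGAGCCGAATCTATTAGCACTTGAGTGGCGGCTGCCACTATCCAGTTAATTAGGAGGCAGGTGTTTCTATGACCGGGAAGAGCGCTAGGACACGTTTAATCGCCTATCCTGCGGTGATGGAGTCAACCCCCAAACCTCGGAGGCTTAGCTCGAATTGGAA",
        "CAAATTATTCCTATCTATGGTGGCAAACTGGTAGCTCCAATACCTACA"),
    GermlineSegment("IGHV4-59", "IGHJ6",
        "TTGCTCGGGCACTCTAACCCGCCGGCGCCTTACAGGCTTACATAAAACGTTTAATGCCTTGCAAGGGGAAGCGCGTGCGGGCAAGAATTCCTCTCCTAAAACGATGACGATTTCAGCCGACGGTAGAAGTCCGAAGTCCTCTGGGTCGTAAAGGGCGGGCCGTCGATATTTATGGTGCCGGACGGTTCCTGGTCATGATACTCGTGGCCT",
        "GTTCCAATCGCACTAAAAACCTATATGCGATTTTAGAATCTACAACGA"),
    GermlineSegment("IGHV3-7", "IGHJ1",
        "CAAACTCCTGGATGGTCGTTAATTGTGTTTCTACCTGTTGTTCCGGAGCGGGTCCATTTAAAGTGCATATCACCCGCTACGCGCAGCGCTGATCATTAGATTCAAGCACAAAACCTTAATGGAATCTCCGAATGGCGCGCCAGCCGTCAGCCGACATCATAGTTGTCTGTGCTAGCTGATCAAGGATTGCGGGGCGCTTGTTATTCTGGA",
        "AGGATGGTTTGGTAATTAATTATTGCAGCTATACCAAAGCTGCACGCC"),
]

LIGHT = [
    GermlineSegment("IGKV1-39", "IGKJ1",
        "CCCTCGTCTGGTTCTTTGTAACTATTTATTCCAGTTTGAGCTTTATGACTCATGTTAAGAAACTCATCCGCACAGTCATCAACCCGCAGGTTCGATACTCTCCAAGTCCACAGTCCAGTCAGAAGCCTCGGTCATTGAAATTATGTCACATCGCGTTCTTGGAACACGCTGCAGAATCTTTTATGCTAATTAGAC",
        "CGGAACACACTCCTGCTCATGCCGCCGGCATGCTCCAATGTATAA"),
    GermlineSegment("IGKV3-20", "IGKJ2",
        "AATCGGGCCAGATTCTGTGGAACTGGTAAGGACGTATTCTGATAAACTGGCGTTAGCTCGCATAAACCGAGAGGTGCCGGATTCTAGTGCAGCCCTATTGTGCCGACATTTTTGAATTGCACGGTACTATAATCTCCCGTATGACCCATAAATGCAGAAAGTAGCCAGGCATACCGGTGGTTCCAACGATCTTAT",
        "TCATTCTGAGATCCCACATACATTGGCCGGCGTCAGGAGGGATAA"),
    GermlineSegment("IGKV1-5", "IGKJ4",
        "AGCCGACCCCTGAACGTGCGGCTCGGTCACTCCCAATGTTTCTGTTTACTACTCGGTACGCCCGTTCAATGGACTCATGGCTACCAGTGCTTTATCTTAAACCCAACGTTAGCGTATCATCCTAGCACACGAAATTGGTCAATATTTGCATACGGCGTTGTTAAAAGTAGCATGAGTCGCACGAAGAATGGATAG",
        "TATATCGTACCATCGACGCGGGTGGGAGGGTGGAGGGACGTTCAC"),
    GermlineSegment("IGLV2-14", "IGLJ3",
        "GTTATGCCCTCAAGTGGGCATCAATGGTGAGGCGATGTAAATAACGGCACTTAAAGGGCACAATGATTCTTGGACATCGTAGGTTGTCCTGTGTGATGTTACAAAGACAAAGCGTCCCCTACTCGCTCAGCCTACCATGCATCGTGGGTGAAGGCTGGAAAAGCGCGGCGCGGACGCTCTTATCGATATAAGCTT",
        "TACGAGACCAATTAGTAAGGGGGAACGCCCACATGAGTATAATGG"),
    GermlineSegment("IGLV1-44", "IGLJ2",
        "ATTGTAGTAGCGTTCAAGATAGCGTCTGGAAACTTAGTACGCCGGCACCATATCACTATCCAAGGCAACACAAAACAGCATGCAAACAACTTGAGCATGTAGTTAATTTCGACAATAGCAGCTTCGTCAAGTGCTGTACCCGATATCTGCAAGAGGGCATGTGAGCAGCCCCACTTACGGAAGTCGAAGAGTTGC",
        "AATGGAGCCCTCGCACGCGCCGATACCGTAGCTATGTAGGCGAGT"),
    GermlineSegment("IGKV4-1", "IGKJ5",
        "GGCTTGGGATATATTCGAGGGATCCGGTTGAGGTATGCCTGGCAACTAGCGCATGATATCTACCCAGAGTGTTGGGCCACCTGAACCTCGCCAGGTTCCACAGGGCTGGTGTGAGTGGGGCGTCTAATGAGTACGGCGAGGACACTAGGGAATGCACGACCAGACCTTTCTTACTTATAAATATAATTCTTGCAT",
        "CGGTTAGTGCTAAATGCCTCGGTCGACGTATTAAAGAGCGCGGTC"),
]

TRB = [
    GermlineSegment("TRBV19", "TRBJ2-1",
        "GCCGCTCCTGGTCCTTGGTTTACCACCTTGTATCCAACTTAGGTGCTCAACCATGGCACGCCAGGTTCACCAGCGGCTTAAATTGGATGATCGCCAGCCGTGGCCATTAGCTCTTAAGGGCGGGTTCCCTAGGCGATCCAGTATGTATCAAAGTTTAAAATCACGTCTAGACCGGTGAAAATCCTCCCATAGGGGGGAGA",
        "GGCCACCGCTACACGATGTATAGCGTCTGGGGGCGGAACGTTACA"),
    GermlineSegment("TRBV5-1", "TRBJ1-2",
        "AGGCTTGCCATAGCCGTCGCGAACGGTCGTTCGACAGCGAGACAAAAGCGTACAAGACATGTTCCGTAACCCATCGGGGAATCGAGCTTATGGACTAGTTTGTAGCGCCTCAGGTAGGCGCTGGGGCGCCGGCCTTTACCACCTCGTGAATGCCGTGTCAATAGCAAAACTAATATCCACGATGTCATTGGCCAGTGGCC",
        "GCGTTGTGGCAGTTACGCCGTAGTAGTAACTATATCCCCCGCGTC"),
    GermlineSegment("TRBV20-1", "TRBJ2-7",
        "ATCGCATTTGGCCGGTCGGTGGAGGCACAAATGAGCGTCAGCTATTCCGTAGGGTCGATAACTGACAGAGCTATAAGTGTTACTGCCTCTTCGACCCCGGGATAAACTAGTATTCGGTAACTCCAAAGGCGCTGCTCCTAGGAGGGGAGACGTGCCCGGGATCAATATATTGCATACGACGAAAGCTTATACTTTGAACG",
        "GTGCAGCAAGCTGCGCGAGATAGCCCGTCTTCGGACTCCCCTGCC"),
    GermlineSegment("TRBV9", "TRBJ1-1",
        "CGCTTCGCAAAAGCAGAGATCCGTCTTCTGTGTAAACGCGGGAAGTCCTACCGTCGCGAGGTCCGGAAACCAATGTGGCATTTGGGTATGACCCAGCTATTCATGACCACACTTCTGGTGCCCAGTTGAAGTTGCCGACTATATTCAGAGCCTATGTCTATAAACCCGGGCAAATTCGGTAAGAGGAGTGGGGAAAGCCA",
        "CAGCGGGCCCGCTTACAGGCCGGCCCCAAGACGTAATTTCTTGCG"),
]

TRA = [
    GermlineSegment("TRAV12-1", "TRAJ33",
        "GGAAAAGCGACCCTAAACGGGCTTAGAGGTTCTAACAGGCAAAACCACAGAGTCCCCTCCCAAGTTCATGTAGTTGTGGAAACCTTAGTAAAGGAGCGGATTCCTGGAATATACGTGATGTTCTGGAAGCTGCTGAACGATACTGGTACCTGCTCAGTAGACGCCGAGTCGCTGCGGTACCCTCTCCCCC",
        "GCCCCGTACATATGTCCAACTTGACATACTGAGATCCAGATA"),
    GermlineSegment("TRAV29", "TRAJ49",
        "ACGCGTCCCCCGACCGCGGATAACAGGATTCAAGTTAGTACTGCGCCGCGCTTATTCAAGAGAAATAAATTCTTGATATCTATGGCACCATTACTCTTCCTCCAGACAGACCCACCTACGGGGTATCAGTCGCCACCTTCATGCGTGGCTAGTGAGATACACCAAGACCGTAAAGTTTATATTTACCTTC",
        "TAAAGCGATTTCATATCCCTGCCTGACTGTTTCGTCTCATGA"),
    GermlineSegment("TRAV8-4", "TRAJ20",
        "TCCGATAGACGAGAAATTCTGTATCTACCGTCCGTAAGTATTGCGGTTGATACTTCCTTAGATGATAACGGCGGGTTCCTGTCAGAGCATAGGAAGCCCCCATCCTAAAGAGATAATGTATTGACGGTTTAGCTATTAACAGCCCTCATCGAATATCTGTGTCAGCAACCGGCCACGCCCCTAGTGGTGA",
        "CCAACCAGTAAAATTCTCTTGAAACACCCGATGTGCAATACG"),
    GermlineSegment("TRAV21", "TRAJ39",
        "TCCGATCTTCAGGTGAGTCGATGTCAACGGCTTACTGGCCAGATTTACAGACGGGCCTTCGCACGTAGACACCTCTCAGATCGCCCCACTTGGGGTGAAGTGGAAGGACGGTTAAAAGGTTTACCGTTTCCACACAACGTAAGAAGGTTGTAAAATATGCTTATTTGTTATGGGTGCCACCGATCTTTAT",
        "ACTTCCCAAATCACAAGGTGCCTATTGAGTCGTCCGTGGTCG"),
]
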