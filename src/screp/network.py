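"""Clone similarity networks from summed per-chain CDR3 edit distances.

The distance between two clones is the Levenshtein distance of their CDRH3
amino-acid representatives plus that of their CDRL3 representatives; edges
connect clones strictly below a user threshold.
"""

from __future__ import annotations

import networkx as nx

from screp.clonotyping import Clonotype, rank_clones


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance, iterative rolling-row dynamic program."""
    if len(a) < len(b):
        a, b = b, a
    previous = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        current = [i]
        for j, cb in enumerate(b, start=1):
            current.append(
                min(
                    previous[j] + 1,  # deletion
                    current[j - 1] + 1,  # insertion
                    previous[j - 1] + (ca != cb),  # substitution / match
                )
            )
        previous = current
    return previous[-1]


def cdr3_pair_distance(a: Clonotype, b: Clonotype, per_chain: bool = False) -> int:
    """Summed CDRH3 + CDRL3 edit distance between clone representatives.

    With ``per_chain`` the minimum of the two per-chain distances is returned
    instead of the sum, for thresholding either chain individually.
    """
    dh = levenshtein(a.representative_cdr3h_aa, b.representative_cdr3h_aa)
    dl = levenshtein(a.representative_cdr3l_aa, b.representative_cdr3l_aa)
    return min(dh, dl) if per_chain else dh + dl


def build_network(
    clonotypes: list[Clonotype],
    top_n_per_sample: int,
    threshold: int,
    per_chain: bool = False,
) -> nx.Graph:
    """Similarity graph over the most expanded clones of each sample.

    Vertices are the ``top_n_per_sample`` most expanded clones from each
    sample (attributes: ``sample_id``, ``size``); an undirected edge joins two
    clones iff their distance is strictly below ``threshold`` (edge attribute
    ``distance``).
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    by_sample: dict[str, list[Clonotype]] = {}
    for clone in clonotypes:
        by_sample.setdefault(clone.sample_id, []).append(clone)
    selected: list[Clonotype] = []
    for sample in sorted(by_sample):
        selected.extend(rank_clones(by_sample[sample], top_n_per_sample))

    graph = nx.Graph(threshold=threshold)
    for clone in selected:
        graph.add_node(
            f"{clone.sample_id}:{clone.clonotype_id}",
            sample_id=clone.sample_id,
            size=clone.size,
            cdr3h=clone.representative_cdr3h_aa,
            cdr3l=clone.representative_cdr3l_aa,
        )
    for i in range(len(selected)):
        for j in range(i + 1, len(selected)):
            d = cdr3_pair_distance(selected[i], selected[j], per_chain=per_chain)
            if d < threshold:
                graph.add_edge(
                    f"{selected[i].sample_id}:{selected[i].clonotype_id}",
                    f"{selected[j].sample_id}:{selected[j].clonotype_id}",
                    distance=d,
                )
    return graph


def cross_sample_components(
    network: nx.Graph,
) -> list[dict]:
    """Connected components with per-sample membership counts.

    Each entry: ``{"nodes": set, "sample_counts": {sample: n}, "cross_sample":
    bool}``; ``cross_sample`` flags components spanning two or more samples.
    """
    components = []
    for nodes in nx.connected_components(network):
        sample_counts: dict[str, int] = {}
        for node in nodes:
            sample = network.nodes[node]["sample_id"]
            sample_counts[sample] = sample_counts.get(sample, 0) + 1
        components.append(
            {
                "nodes": set(nodes),
                "sample_counts": sample_counts,
                "cross_sample": len(sample_counts) >= 2,
            }
        )
    components.sort(key=lambda c: (-len(c["nodes"]), sorted(c["nodes"])))
    return components


def write_edge_list(network: nx.Graph, path) -> None:
    """Edge list TSV: node_a, node_b, distance."""
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tdistance\n")
        for a, b, data in sorted(network.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['distance']}\n")
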