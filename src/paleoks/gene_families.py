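"""Similarity graph construction and Markov clustering into gene families.

Paralog/ortholog grouping follows the graph-clustering recipe: all-vs-all
protein hits filtered at E-value ≤ 1e-10 and identity ≥ 40% (inclusive)
become an undirected similarity graph with max-bitscore edge weights, which
Markov clustering (MCL, inflation 1.5) partitions into families. Duplicate
pairs are all within-species pairs of a family; single-copy ortholog groups
are families with exactly one member per species.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .io_formats import HitRecord, species_of

__all__ = [
    "GeneFamily",
    "build_graph",
    "mcl_cluster",
    "single_copy_orthologs",
    "within_species_pairs",
]

EVALUE_MAX = 1e-10
IDENTITY_MIN = 40.0


@dataclass(frozen=True)
class GeneFamily:
    """One cluster of genes, possibly spanning species."""

    family_id: str
    members: frozenset[str]

    def members_of(self, species: str) -> list[str]:
        return sorted(g for g in self.members if species_of(g) == species)

    def __len__(self) -> int:
        return len(self.members)


def build_graph(
    hits: list[HitRecord],
    evalue_max: float = EVALUE_MAX,
    identity_min: float = IDENTITY_MIN,
) -> nx.Graph:
    """Thresholded, undirected similarity graph with max-bitscore weights.

    Self-hits are dropped; reciprocal hits merge keeping the better
    bitscore; both thresholds are inclusive (≤ E-value, ≥ identity).
    """
    graph = nx.Graph()
    for h in hits:
        if h.query == h.subject:
            continue
        if h.evalue > evalue_max or h.identity < identity_min:
            continue
        if graph.has_edge(h.query, h.subject):
            if h.bitscore > graph[h.query][h.subject]["weight"]:
                graph[h.query][h.subject]["weight"] = h.bitscore
        else:
            graph.add_edge(h.query, h.subject, weight=h.bitscore)
    return graph


def _mcl_matrix(graph: nx.Graph, nodes: list[str]) -> sp.csr_matrix:
    """Weighted adjacency with self-loops of weight = max incident weight."""
    index = {n: i for i, n in enumerate(nodes)}
    rows, cols, vals = [], [], []
    loop = np.zeros(len(nodes))
    for a, b, data in graph.edges(data=True):
        w = float(data["weight"])
        if not np.isfinite(w):
            raise ValueError(f"non-finite edge weight on {a} ~ {b}")
        i, j = index[a], index[b]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
        loop[i] = max(loop[i], w)
        loop[j] = max(loop[j], w)
    loop[loop == 0] = 1.0  # isolated vertices self-loop
    rows += list(range(len(nodes)))
    cols += list(range(len(nodes)))
    vals += list(loop)
    return sp.csr_matrix((vals, (rows, cols)), shape=(len(nodes), len(nodes)))


def _normalize_columns(m: sp.csr_matrix) -> sp.csr_matrix:
    col_sums = np.asarray(m.sum(axis=0)).ravel()
    col_sums[col_sums == 0] = 1.0
    return m @ sp.diags(1.0 / col_sums)


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 1.5,
    tol: float = 1e-6,
    prune: float = 1e-12,
    max_iter: int = 200,
) -> list[GeneFamily]:
    """Markov clustering of the similarity graph into gene families.

    Column-normalize the self-looped adjacency, then alternate expansion
    (matrix square) and inflation (elementwise power, renormalize), pruning
    entries below ``prune``, until the maximum elementwise change drops
    below ``tol``. Clusters are read off the converged matrix's attractor
    structure; the result partitions the vertex set and is independent of
    vertex labelling and edge order.
    """
    nodes = sorted(graph.nodes)
    if not nodes:
        return []
    m = _normalize_columns(_mcl_matrix(graph, nodes).tocsc())
    for _ in range(max_iter):
        expanded = (m @ m).tocsc()
        expanded.data = np.power(expanded.data, inflation)
        expanded.data[expanded.data < prune] = 0.0
        expanded.eliminate_zeros()
        expanded = _normalize_columns(expanded)
        delta = abs(expanded - m).max()
        m = expanded
        if delta < tol:
            break
    # attractors have mass on their own diagonal; cluster = connected
    # component of the nonzero structure of the converged matrix
    m = m.tocoo()
    comp_graph = nx.Graph()
    comp_graph.add_nodes_from(range(len(nodes)))
    comp_graph.add_edges_from(
        (i, j) for i, j, v in zip(m.row, m.col, m.data) if v > prune
    )
    families = []
    components = sorted(
        (sorted(c) for c in nx.connected_components(comp_graph)),
        key=lambda c: nodes[c[0]],
    )
    width = max(4, len(str(len(components))))
    for k, comp in enumerate(components):
        families.append(
            GeneFamily(f"fam{k:0{width}d}", frozenset(nodes[i] for i in comp))
        )
    return families


def single_copy_orthologs(
    families: list[GeneFamily], species: list[str]
) -> list[GeneFamily]:
    """Families with exactly one member in each listed species, stable order."""
    wanted = set(species)
    out = []
    for fam in families:
        counts: dict[str, int] = {}
        for g in fam.members:
            sp_name = species_of(g)
            if sp_name not in wanted:
                raise ValueError(
                    f"family {fam.family_id}: gene {g!r} has unknown species "
                    f"prefix {sp_name!r}"
                )
            counts[sp_name] = counts.get(sp_name, 0) + 1
        if len(counts) == len(wanted) and all(v == 1 for v in counts.values()):
            out.append(fam)
    return out


def within_species_pairs(family: GeneFamily, species: str) -> list[tuple[str, str]]:
    """All unordered duplicate pairs among one species' members of a family."""
    members = family.members_of(species)
    return [
        (members[i], members[j])
        for i in range(len(members))
        for j in range(i + 1, len(members))
    ]
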