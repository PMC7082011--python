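"""Median-joining haplotype networks and haplogroup partitioning.

The construction follows the classic two-step recipe: build the minimum
spanning network (the union of all minimum spanning trees, so ties are kept
as reticulations), then iteratively propose median (Steiner) sequences as
the per-site majority consensus of triplets of connected nodes, admitting a
median only when adding it strictly shortens the network.  Median nodes have
zero observed frequency; obsolete medians are pruned after convergence.

Haplogroups are obtained by deleting the longest bridge edge of the final
network — on two-haplogroup data that is the long branch separating the
clusters — and letting each specimen inherit its haplotype's component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .errors import AmbiguousPartitionError, MitopopError
from .seqio import HaplotypeTable


@dataclass
class HaplotypeNetwork:
    """Graph over observed haplotypes plus inferred median vectors.

    Node keys are sequence strings; ``graph`` carries per-node attributes
    ``frequency`` (0 for medians), ``is_median``, ``label`` and
    ``site_counts``; edges carry ``mutations``.
    """

    graph: nx.Graph
    site_labels: list[str] = field(default_factory=list)

    @property
    def observed(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d["is_median"]]

    @property
    def medians(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["is_median"]]

    @property
    def total_length(self) -> int:
        return sum(d["mutations"] for _, _, d in self.graph.edges(data=True))

    def edge_list(self) -> list[tuple[str, str, int, bool]]:
        out = []
        g = self.graph
        for u, v, d in g.edges(data=True):
            out.append(
                (
                    g.nodes[u]["label"],
                    g.nodes[v]["label"],
                    d["mutations"],
                    g.nodes[u]["is_median"] or g.nodes[v]["is_median"],
                )
            )
        return out


def _distance(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _dist_matrix(seqs: list[str]) -> np.ndarray:
    """Integer Hamming distance matrix (vectorized)."""
    mat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    return (mat[:, None, :] != mat[None, :, :]).sum(axis=2)


def _msn_edges(dmat: np.ndarray, epsilon: int = 0) -> list[tuple[int, int, int]]:
    """Union-of-all-MSTs edges by levelwise Kruskal.

    Process edges in increasing weight; at each weight level, admit every
    edge joining two components as the components stood ``epsilon`` levels
    earlier (``epsilon = 0``: before this level), so tied — and with ε > 0,
    near-tied — alternative connections are all retained.
    """
    n = dmat.shape[0]
    edges = sorted(
        (int(dmat[i, j]), i, j) for i, j in combinations(range(n), 2)
    )
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    out: list[tuple[int, int, int]] = []
    pending: list[tuple[int, int, int]] = []  # admitted but not yet unioned
    i = 0
    while i < len(edges):
        w = edges[i][0]
        level = []
        while i < len(edges) and edges[i][0] == w:
            level.append(edges[i])
            i += 1
        for pw, a, b in list(pending):
            if pw <= w - 1 - epsilon:
                union(a, b)
                pending.remove((pw, a, b))
        admitted = [(w, a, b) for w, a, b in level if find(a) != find(b)]
        out.extend(admitted)
        pending.extend(admitted)
    return [(a, b, w) for w, a, b in out]


def _build_network(
    seqs: list[str],
    freqs: dict[str, int],
    site_counts: dict[str, np.ndarray],
    site_labels: list[str],
    dmat: np.ndarray | None = None,
    epsilon: int = 0,
) -> HaplotypeNetwork:
    if dmat is None:
        dmat = _dist_matrix(seqs)
    g = nx.Graph()
    n_obs = 0
    n_med = 0
    for s in seqs:
        is_median = freqs.get(s, 0) == 0
        if is_median:
            n_med += 1
            label = f"mv{n_med}"
        else:
            n_obs += 1
            label = f"H{n_obs}"
        g.add_node(
            s,
            frequency=freqs.get(s, 0),
            is_median=is_median,
            label=label,
            site_counts=site_counts.get(s),
        )
    for a, b, w in _msn_edges(dmat, epsilon):
        g.add_edge(seqs[a], seqs[b], mutations=w)
    return HaplotypeNetwork(g, site_labels)


def _table_context(ht: HaplotypeTable):
    # deterministic node order: by descending frequency then lexicographic
    order = sorted(
        range(ht.k), key=lambda i: (-int(ht.counts[i].sum()), ht.haplotypes[i])
    )
    seqs = [ht.haplotypes[i] for i in order]
    freqs = {ht.haplotypes[i]: int(ht.counts[i].sum()) for i in order}
    site_counts = {ht.haplotypes[i]: ht.counts[i] for i in order}
    return seqs, freqs, site_counts


def minimum_spanning_network(
    haplotype_table: HaplotypeTable, epsilon: int = 0
) -> HaplotypeNetwork:
    """Minimum spanning network (union of all MSTs) over observed haplotypes."""
    if haplotype_table.k == 0:
        raise MitopopError("empty haplotype table")
    seqs, freqs, site_counts = _table_context(haplotype_table)
    return _build_network(seqs, freqs, site_counts, haplotype_table.site_labels,
                          epsilon=epsilon)


def _median_sequence(u: str, v: str, w: str) -> str:
    """Per-site majority consensus of three sequences; ties resolve to u."""
    out = []
    for a, b, c in zip(u, v, w):
        if b == c and a != b:
            out.append(b)
        else:
            out.append(a)  # a matches someone, or all three differ
    return "".join(out)


def median_joining(
    haplotype_table: HaplotypeTable,
    epsilon: int = 0,
    max_iter: int = 200,
) -> HaplotypeNetwork:
    """Median-joining network: MSN plus inferred Steiner intermediates.

    Each round proposes the majority-consensus median of every connected
    triplet (two edges sharing a node) of the current network, scoring each
    candidate by the total network length after insertion; the shortest
    strictly-improving candidate (ties broken lexicographically) is added
    and the network rebuilt.  ``epsilon`` relaxes the spanning-network step,
    retaining alternative connections within ε mutations of minimal.
    Terminates because total length is a decreasing integer.  Degree-≤2 medians whose removal leaves
    length unchanged are pruned at the end.
    """
    if epsilon < 0:
        raise MitopopError("epsilon must be >= 0")
    seqs, freqs, site_counts = _table_context(haplotype_table)
    if len({len(s) for s in seqs}) > 1:
        raise MitopopError("haplotypes must be aligned to equal length")

    current = list(seqs)
    dmat = _dist_matrix(current)
    net = _build_network(current, freqs, site_counts,
                         haplotype_table.site_labels, dmat, epsilon)

    def extend(dm, new_seq, pool):
        row = _dist_matrix([new_seq] + pool)[0, 1:]
        out = np.zeros((dm.shape[0] + 1, dm.shape[0] + 1), dtype=dm.dtype)
        out[:-1, :-1] = dm
        out[-1, :-1] = row
        out[:-1, -1] = row
        return out

    for _ in range(max_iter):
        base_len = net.total_length
        g = net.graph
        candidates: set[str] = set()
        for u in g.nodes:
            nbrs = list(g.neighbors(u))
            for v, w in combinations(nbrs, 2):
                m = _median_sequence(u, v, w)
                if m not in g.nodes:
                    candidates.add(m)
        best = None
        for m in sorted(candidates):
            dm_try = extend(dmat, m, current)
            trial = _build_network(current + [m], freqs, site_counts,
                                   haplotype_table.site_labels, dm_try, epsilon)
            tl = trial.total_length
            if tl < base_len and (best is None or tl < best[0]):
                best = (tl, m, trial, dm_try)
        if best is None:
            break
        current.append(best[1])
        net = best[2]
        dmat = best[3]

    # prune obsolete medians: low-degree medians whose removal doesn't
    # lengthen the network over the remaining nodes
    changed = True
    while changed:
        changed = False
        for m in net.medians:
            if net.graph.degree(m) <= 2:
                remaining = [s for s in current if s != m]
                trial = _build_network(remaining, freqs, site_counts,
                                       haplotype_table.site_labels,
                                       epsilon=epsilon)
                if trial.total_length <= net.total_length:
                    current = remaining
                    net = trial
                    changed = True
                    break
    return net


def assign_haplogroups(
    network: HaplotypeNetwork,
    haplotype_table: HaplotypeTable,
    alignment_site_labels=None,
    cut_rule: str = "longest_bridge",
    min_mutations: int = 10,
) -> dict:
    """Split the network into two haplogroups and assign specimens.

    ``longest_bridge`` removes the heaviest bridge edge; ``threshold``
    removes every bridge with ≥ ``min_mutations`` mutations (must yield
    exactly two components).  Returns a dict with haplogroup membership per
    haplotype row and per specimen record index.
    """
    g = network.graph
    if not nx.is_connected(g):
        raise MitopopError("network must be connected")
    bridges = list(nx.bridges(g))
    if not bridges:
        raise AmbiguousPartitionError("no bridge edge; cut manually")
    if cut_rule == "longest_bridge":
        cut_edges = [max(bridges, key=lambda e: g.edges[e]["mutations"])]
    elif cut_rule == "threshold":
        cut_edges = [e for e in bridges if g.edges[e]["mutations"] >= min_mutations]
        if not cut_edges:
            raise AmbiguousPartitionError(
                f"no bridge with >= {min_mutations} mutations"
            )
    else:
        raise MitopopError(f"unknown cut_rule {cut_rule!r}")

    h = g.copy()
    h.remove_edges_from(cut_edges)
    comps = sorted(nx.connected_components(h), key=len, reverse=True)
    if len(comps) != 2:
        raise AmbiguousPartitionError(f"cut produced {len(comps)} components, not 2")

    # larger observed component is haplogroup 'alpha' by convention
    def obs_size(comp):
        return sum(g.nodes[n]["frequency"] for n in comp)

    comps = sorted(comps, key=obs_size, reverse=True)
    group_of_seq: dict[str, str] = {}
    for name, comp in zip(("alpha", "beta"), comps):
        for node in comp:
            group_of_seq[node] = name

    hap_groups = [group_of_seq[s] for s in haplotype_table.haplotypes]
    specimen_groups = [hap_groups[h_i] for h_i in haplotype_table.assignments]
    freq = {
        name: sum(
            g.nodes[n]["frequency"] for n in comp
        )
        for name, comp in zip(("alpha", "beta"), comps)
    }
    total = sum(freq.values())
    return {
        "haplotype_groups": hap_groups,
        "specimen_groups": specimen_groups,
        "group_frequencies": {k: v / total for k, v in freq.items()},
        "haplotypes_per_group": {
            name: sum(1 for n in comp if not g.nodes[n]["is_median"])
            for name, comp in zip(("alpha", "beta"), comps)
        },
        "cut_edges": [
            (g.nodes[u]["label"], g.nodes[v]["label"], g.edges[u, v]["mutations"])
            for u, v in cut_edges
        ],
    }


def write_network(network: HaplotypeNetwork, edge_tsv=None, gml=None) -> None:
    """Export as edge-list TSV (source, target, mutations, is_median) and GML."""
    if edge_tsv is not None:
        with open(edge_tsv, "w") as fh:
            fh.write("source\ttarget\tmutations\tis_median\n")
            for s, t, m, is_med in network.edge_list():
                fh.write(f"{s}\t{t}\t{m}\t{int(is_med)}\n")
    if gml is not None:
        g = nx.relabel_nodes(
            network.graph, {n: d["label"] for n, d in network.graph.nodes(data=True)}
        )
        for _, d in g.nodes(data=True):
            d.pop("site_counts", None)
            d["is_median"] = int(d["is_median"])
        nx.write_gml(g, gml)
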