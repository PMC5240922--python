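"""Residue interaction networks: contact graphs, shortest paths,
betweenness centrality, and persistent Girvan–Newman communities.

Edges of the contact graph require an interaction strength
I_ij = 100 · n_ij / sqrt(N_i N_j) of at least ``I_min`` percent, where
n_ij counts heavy-atom pairs within 4.5 Å and N_i is a residue-type
normalization (the largest heavy-atom contact count that residue type
attains in a reference structure set). Edge lengths come from the
coupling matrix as w_ij = -ln r_MI, so strongly coupled residues are
close in communication distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import igraph as ig
import networkx as nx
import numpy as np
from scipy.sparse.csgraph import floyd_warshall

from .coupling import CouplingMatrix
from .ensemble import StructureModel, residue_pair_contacts
from .errors import GraphError, InputError

CONTACT_CUTOFF = 4.5
#: Default interaction-strength cutoff (percent), calibrated on the
#: bundled fixture set so the contact graph's giant component covers the
#: whole structure (single-bead contacts score 100/sqrt(N_i N_j) ≈ 1.3-2.6
#: under the bundled normalization table).
DEFAULT_I_MIN = 1.0
_DIST_TOL = 1e-9


def load_contact_normalization(path: str | Path | None = None) -> dict[str, float]:
    """Residue-type normalization values N_i.

    The bundled table holds, per residue type, the maximum heavy-atom
    contact count (4.5 Å) observed over the packaged synthetic structure
    set; substitute your own table (e.g. values from the protein
    structure network literature) for production structures.
    """
    if path is None:
        text = (resources.files("allonet.data") / "residue_contact_norm.tsv").read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, val = line.split("\t")
        table[name] = float(val)
    return table


def compute_contact_normalization(
    structures: list[StructureModel], cutoff: float = CONTACT_CUTOFF
) -> dict[str, float]:
    """Max total heavy-atom contact count per residue type over a
    structure set (the recipe behind the bundled table)."""
    best: dict[str, float] = {}
    for s in structures:
        totals = np.zeros(s.n_residues)
        for (i, j), cnt in residue_pair_contacts(s, s.coords, cutoff).items():
            totals[i] += cnt
            totals[j] += cnt
        for res, tot in zip(s.residues, totals):
            best[res.name] = max(best.get(res.name, 0.0), float(tot))
    return best


@dataclass
class ResidueGraph:
    """Undirected residue graph with interaction strengths and w lengths.

    Backed by a networkx Graph whose nodes are residue indices into the
    source structure; node attribute ``number`` holds the author residue
    number. Edge attributes: ``strength`` (I_ij, percent) and ``length``
    (w_ij, finite and positive).
    """

    g: nx.Graph
    frame: int | None = None

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    def lengths_matrix(self) -> tuple[np.ndarray, list[int]]:
        nodes = sorted(self.g.nodes)
        n = len(nodes)
        pos = {u: k for k, u in enumerate(nodes)}
        w = np.full((n, n), np.inf)
        np.fill_diagonal(w, 0.0)
        for u, v, data in self.g.edges(data=True):
            w[pos[u], pos[v]] = w[pos[v], pos[u]] = data["length"]
        return w, nodes


def build_contact_graph(
    structure: StructureModel,
    coords: np.ndarray,
    coupling: CouplingMatrix,
    I_min: float = DEFAULT_I_MIN,
    contact_cutoff: float = CONTACT_CUTOFF,
    normalization: dict[str, float] | None = None,
    frame: int | None = None,
) -> ResidueGraph:
    """Contact graph of one frame, weighted by the coupling matrix.

    Edges require I_ij >= ``I_min`` (percent) and a finite w_ij.
    Residue types absent from the normalization table fall back to the
    table's mean value (with a warning).
    """
    if I_min < 0:
        raise InputError("I_min must be nonnegative")
    if coupling.n_residues != structure.n_residues:
        raise InputError("coupling matrix not congruent with structure")
    if normalization is None:
        normalization = load_contact_normalization()
    table_mean = float(np.mean(list(normalization.values())))
    missing = sorted(
        {r.name for r in structure.residues if r.name not in normalization}
    )
    if missing:
        warnings.warn(
            f"residue types missing from normalization table, using table "
            f"mean {table_mean:.1f}: {missing}",
            stacklevel=2,
        )
    norm = np.array(
        [normalization.get(r.name, table_mean) for r in structure.residues]
    )
    g = nx.Graph()
    for idx, res in enumerate(structure.residues):
        g.add_node(idx, number=res.number, name=res.name, chain=res.chain)
    counts = residue_pair_contacts(structure, coords, contact_cutoff)
    for (i, j), n_ij in counts.items():
        strength = 100.0 * n_ij / np.sqrt(norm[i] * norm[j])
        w_ij = coupling.w[i, j]
        if strength >= I_min and np.isfinite(w_ij):
            g.add_edge(i, j, strength=float(strength), length=float(w_ij))
    return ResidueGraph(g=g, frame=frame)


@dataclass
class PathMatrix:
    """All-pairs shortest distances and shortest-path counts.

    ``dist[j, k]`` is the shortest communication distance, ``counts[j, k]``
    the number of distinct co-optimal paths (0 for disconnected pairs,
    1 on the diagonal).
    """

    dist: np.ndarray
    counts: np.ndarray
    nodes: list[int]


def all_pairs_shortest_paths(graph: ResidueGraph) -> PathMatrix:
    """Exact all-pairs shortest distances with co-optimal path counting.

    Distances come from Floyd–Warshall on the dense length matrix; path
    counts from a per-source dynamic program over nodes in increasing
    distance order (every co-optimal path is counted). Edge lengths must
    be strictly positive.
    """
    w, nodes = graph.lengths_matrix()
    n = len(nodes)
    off = ~np.eye(n, dtype=bool)
    if np.any(w[off][np.isfinite(w[off])] <= 0):
        raise GraphError("shortest-path counting requires positive edge lengths")
    dist = floyd_warshall(w, directed=False)
    counts = np.zeros((n, n))
    for s in range(n):
        d = dist[s]
        reach = np.isfinite(d)
        order = np.argsort(d[reach], kind="stable")
        idx = np.nonzero(reach)[0][order]
        c = np.zeros(n)
        c[s] = 1.0
        for v in idx:
            if v == s:
                continue
            pred = np.isfinite(w[:, v]) & (np.abs(d + w[:, v] - d[v]) <= _DIST_TOL * (1 + abs(d[v])))
            pred[v] = False
            c[v] = c[pred].sum()
        counts[s] = c
    return PathMatrix(dist=dist, counts=counts, nodes=nodes)


@dataclass
class CentralityProfile:
    """Betweenness per node: raw path-share sums and the normalized form
    (divided by the (N-1)(N-2)/2 transit pairs of the node's component)."""

    raw: np.ndarray
    normalized: np.ndarray
    nodes: list[int]


def betweenness(graph: ResidueGraph, paths: PathMatrix | None = None) -> CentralityProfile:
    """Betweenness centrality with fractional credit over co-optimal paths.

    C_b(i) = Σ_{j<k, j≠i≠k} g_jk(i) / g_jk, where g_jk counts shortest
    j–k paths and g_jk(i) those passing through i; the normalized value
    divides by (N-1)(N-2)/2 with N the size of i's connected component.
    """
    if paths is None:
        paths = all_pairs_shortest_paths(graph)
    d, g = paths.dist, paths.counts
    n = d.shape[0]
    raw = np.zeros(n)
    comp_size = np.isfinite(d).sum(axis=1)  # includes self
    for i in range(n):
        through = d[:, i][:, None] + d[i, :][None, :]
        on_path = np.isfinite(through) & (np.abs(through - d) <= _DIST_TOL * (1 + np.abs(d)))
        gi = g[:, i][:, None] * g[i, :][None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(on_path & (g > 0), gi / np.where(g > 0, g, 1), 0.0)
        share[i, :] = share[:, i] = 0.0
        raw[i] = np.triu(share, k=1).sum()
    denom = (comp_size - 1) * (comp_size - 2) / 2.0
    normalized = np.where(denom > 0, raw / np.where(denom > 0, denom, 1), 0.0)
    return CentralityProfile(raw=raw, normalized=normalized, nodes=paths.nodes)


@dataclass
class CommunityPartition:
    """Disjoint residue communities with their Newman modularity.

    ``persistence`` is filled by :func:`persistent_communities`.
    """

    communities: list[frozenset[int]]
    modularity: float
    persistence: float | None = None

    def membership(self) -> dict[int, int]:
        return {u: c for c, comm in enumerate(self.communities) for u in comm}


def _unweighted_modularity(g: ig.Graph, membership: list[int]) -> float:
    return float(g.modularity(membership))


def girvan_newman(graph: ResidueGraph) -> CommunityPartition:
    """Girvan–Newman community detection on the residue graph.

    Edges are removed in decreasing order of weighted edge betweenness
    (lengths w as distances); among the dendrogram's partitions the one
    maximizing unweighted Newman modularity on the contact topology is
    returned, preferring fewer communities on ties. Communities are
    sorted by smallest member for deterministic output, and are labelled
    by the nodes' ``number`` attribute (residue numbers) when present.
    """
    nodes = sorted(graph.g.nodes)
    if not nodes:
        raise GraphError("empty graph")
    pos = {u: k for k, u in enumerate(nodes)}
    edges = [(pos[u], pos[v]) for u, v in graph.g.edges]
    lengths = [graph.g.edges[u, v]["length"] for u, v in graph.g.edges]
    g = ig.Graph(n=len(nodes), edges=edges)
    if not edges:
        comms = [frozenset([u]) for u in nodes]
        return CommunityPartition(communities=comms, modularity=0.0)
    dendro = g.community_edge_betweenness(directed=False, weights=lengths)
    n_comp = len(g.connected_components())
    best_q, best_membership = -1.0, None
    for k in range(n_comp, len(nodes) + 1):
        try:
            clustering = dendro.as_clustering(k)
        except Exception:
            continue
        q = _unweighted_modularity(g, clustering.membership)
        if q > best_q + 1e-12:
            best_q, best_membership = q, list(clustering.membership)
    comms: dict[int, set[int]] = {}
    for u, c in zip(nodes, best_membership):
        label = graph.g.nodes[u].get("number", u)
        comms.setdefault(c, set()).add(label)
    ordered = sorted((frozenset(v) for v in comms.values()), key=min)
    return CommunityPartition(communities=ordered, modularity=best_q)


def _jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b)


def persistent_communities(
    partitions: list[CommunityPartition],
    persistence: float = 0.75,
    jaccard_threshold: float = 0.8,
) -> list[CommunityPartition]:
    """Communities stable across an ensemble of frame partitions.

    Communities are matched across frames by greedy maximum Jaccard
    matching (threshold 0.8, each community matched at most once per
    frame); a reference community (its first occurrence) is reported iff
    it appears in strictly more than ``persistence`` of the frames. Each
    reported partition holds one community with its persistence fraction.
    """
    if len(partitions) < 2:
        raise InputError("need at least 2 frame partitions")
    if not 0 < persistence <= 1:
        raise InputError("persistence must be in (0, 1]")
    refs: list[frozenset[int]] = []
    hits: list[int] = []
    for part in partitions:
        cands = [
            (_jaccard(ref, comm), r_i, comm)
            for r_i, ref in enumerate(refs)
            for comm in part.communities
        ]
        cands = [c for c in cands if c[0] >= jaccard_threshold]
        cands.sort(key=lambda c: (-c[0], c[1], sorted(c[2])))
        used_refs: set[int] = set()
        used_comms: set[frozenset[int]] = set()
        for score, r_i, comm in cands:
            if r_i in used_refs or comm in used_comms:
                continue
            used_refs.add(r_i)
            used_comms.add(comm)
            hits[r_i] += 1
        for comm in part.communities:
            if comm not in used_comms:
                refs.append(comm)
                hits.append(1)
                used_comms.add(comm)
    n_frames = len(partitions)
    out = []
    for ref, h in zip(refs, hits):
        frac = h / n_frames
        if frac > persistence:
            out.append(
                CommunityPartition(communities=[ref], modularity=float("nan"), persistence=frac)
            )
    out.sort(key=lambda p: (-p.persistence, min(p.communities[0])))
    return out


def community_cliques(graph: ResidueGraph, partition: CommunityPartition) -> list[list[int]]:
    """Maximal cliques within each community (3+ members), mimicking
    clique-percolation-style small-module output. Off the main pipeline."""
    out: list[list[int]] = []
    for comm in partition.communities:
        sub = graph.g.subgraph(comm)
        out.extend(sorted(c) for c in nx.find_cliques(sub) if len(c) >= 3)
    out.sort()
    return out
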