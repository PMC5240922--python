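"""Community-hopping allosteric communication pathways.

Communication propensity (CP) scores each residue by the ensemble
variance of (a) its mean Cα distance to all other residues and (b) its
mean absolute pMI difference to all other residues: residues whose
composite distance to the rest of the protein fluctuates little
communicate efficiently. Source→sink signalling is modelled as an
ensemble of per-frame shortest paths on the contact graph with
w = -ln r_MI lengths; the fraction of frames in which a particular
residue sequence is optimal is its occupancy. Crossings between
communities along a path are "hops" — the stepping stones of the
community-hopping picture.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .coupling import CouplingMatrix, PMIProfile
from .ensemble import ConformationalEnsemble
from .errors import GraphError, InputError
from .network import (
    CommunityPartition,
    ResidueGraph,
    build_contact_graph,
    girvan_newman,
)

DEFAULT_TEMPERATURE = 300.0


@dataclass
class CPProfile:
    """Per-residue communication propensity, in units of k_B T.

    ``normalized`` records whether the two variance channels were
    rescaled by their across-residue pooled spread (making w1/w2 unitless
    mixing weights) or left in raw units (Å² and pMI-score²).
    """

    cp: np.ndarray
    residue_numbers: list[int]
    w1: float
    w2: float
    temperature: float
    normalized: bool


def _mean_abs_diff_to_all(x: np.ndarray) -> np.ndarray:
    """mean_j |x_i - x_j| (j ≠ i) per row of each frame, via sorting.

    ``x`` is (n_frames, n) and the result has the same shape.
    """
    n = x.shape[1]
    if n < 2:
        return np.zeros_like(x)
    order = np.argsort(x, axis=1)
    xs = np.take_along_axis(x, order, axis=1)
    csum = np.cumsum(xs, axis=1)
    ranks = np.arange(n)
    total = csum[:, -1][:, None]
    below = np.where(ranks > 0, np.take_along_axis(csum, np.maximum(ranks - 1, 0)[None, :].repeat(x.shape[0], 0), axis=1), 0.0)
    sums = ranks[None, :] * xs - below + (total - csum) - (n - 1 - ranks)[None, :] * xs
    out = np.empty_like(x)
    np.put_along_axis(out, order, sums / (n - 1), axis=1)
    return out


def communication_propensity(
    ensemble: ConformationalEnsemble,
    pmi: PMIProfile,
    w1: float = 0.5,
    w2: float = 0.5,
    temperature: float = DEFAULT_TEMPERATURE,
    normalize: bool = True,
) -> CPProfile:
    """CP_i = 3 ⟨ w1 (d_i - ⟨d_i⟩)² + w2 (ΔpM_i - ⟨ΔpM_i⟩)² ⟩ in k_B T units.

    Per frame, d_i is residue i's mean Cα distance to all other residues
    and ΔpM_i its mean |pMI_i - pMI_j| over all j. With ``normalize``
    (default) each deviation channel is divided by its pooled
    across-residue RMS, so the weights mix unitless channels; raw-units
    mode keeps Å² and score² (the w2 = 0 limit then equals
    3·w1·Var(d_i) exactly). The k_B T factor is reported out, i.e. values
    are in units of k_B T.
    """
    if ensemble.frame_count < 2:
        raise InputError("CP needs at least 2 frames")
    if w1 < 0 or w2 < 0:
        raise InputError("w1 and w2 must be nonnegative")
    s = ensemble.structure
    ok = s.ca_indices >= 0
    ca = ensemble.frames[:, s.ca_indices[ok], :]
    n_frames, n = ca.shape[0], ca.shape[1]
    d_i = np.empty((n_frames, n))
    for f in range(n_frames):
        diff = ca[f][:, None, :] - ca[f][None, :, :]
        dm = np.sqrt((diff * diff).sum(axis=2))
        d_i[f] = dm.sum(axis=1) / (n - 1)
    if pmi.per_frame.shape[0] != n_frames:
        raise InputError("pMI series not congruent with the ensemble")
    dpm = _mean_abs_diff_to_all(pmi.per_frame[:, ok])
    dev_d = d_i - d_i.mean(axis=0, keepdims=True)
    dev_p = dpm - dpm.mean(axis=0, keepdims=True)
    if normalize:
        # pooled RMS per channel; spreads indistinguishable from rounding
        # noise (relative to the signal magnitude) count as zero
        s1 = np.sqrt((dev_d**2).mean())
        s2 = np.sqrt((dev_p**2).mean())
        tol1 = 1e-9 * max(1.0, float(np.abs(d_i).mean()))
        tol2 = 1e-9 * max(1.0, float(np.abs(dpm).mean()))
        dev_d = dev_d / s1 if s1 > tol1 else np.zeros_like(dev_d)
        dev_p = dev_p / s2 if s2 > tol2 else np.zeros_like(dev_p)
    cp_active = 3.0 * (w1 * dev_d**2 + w2 * dev_p**2).mean(axis=0)
    cp = np.zeros(s.n_residues)
    cp[ok] = cp_active
    return CPProfile(
        cp=cp,
        residue_numbers=s.residue_numbers,
        w1=w1,
        w2=w2,
        temperature=temperature,
        normalized=normalize,
    )


def tune_weights(
    ensemble: ConformationalEnsemble,
    pmi: PMIProfile,
    coupling: CouplingMatrix,
    grid: list[tuple[float, float]] | None = None,
    I_min: float | None = None,
    normalization: dict[str, float] | None = None,
) -> tuple[float, float]:
    """Choose (w1, w2) on a w1 + w2 = 1 grid by community modularity.

    For each candidate, edge lengths on the mean-frame contact graph are
    the w1/w2-weighted pairwise composite fluctuations (variance of the
    inter-residue Cα distance, and of the pMI difference, each channel
    rescaled by its pooled spread); the weighted Girvan–Newman partition
    is scored by unweighted modularity on the contact topology and the
    maximizer returned, ties resolved toward larger w1. Deterministic.
    """
    from .network import DEFAULT_I_MIN

    if grid is None:
        grid = [(round(w1, 1), round(1 - w1, 1)) for w1 in np.arange(0.0, 1.01, 0.1)]
    if not grid:
        raise InputError("empty tuning grid")
    if I_min is None:
        I_min = DEFAULT_I_MIN
    s = ensemble.structure
    ok = s.ca_indices >= 0
    ca = ensemble.frames[:, s.ca_indices[ok], :]
    diff = ca[:, :, None, :] - ca[:, None, :, :]
    dmat = np.sqrt((diff * diff).sum(axis=3))          # (frames, n, n)
    var_d = dmat.var(axis=0)
    p = pmi.per_frame[:, ok]
    dp = np.abs(p[:, :, None] - p[:, None, :])
    var_p = dp.var(axis=0)
    s1 = var_d[var_d > 0].mean() if np.any(var_d > 0) else 1.0
    s2 = var_p[var_p > 0].mean() if np.any(var_p > 0) else 1.0
    mean_frame = ensemble.frames.mean(axis=0)
    base = build_contact_graph(
        s, mean_frame, coupling, I_min=I_min, normalization=normalization
    )
    best = None
    for w1, w2 in sorted(grid, key=lambda t: -t[0]):
        if w1 < 0 or w2 < 0:
            raise InputError("grid weights must be nonnegative")
        f = w1 * var_d / s1 + w2 * var_p / s2
        g = base.g.copy()
        for u, v in g.edges:
            g.edges[u, v]["length"] = float(f[u, v]) + 1e-9
        part = girvan_newman(ResidueGraph(g=g, frame=None))
        if best is None or part.modularity > best[0] + 1e-12:
            best = (part.modularity, w1, w2)
    return best[1], best[2]


@dataclass
class Hop:
    """An inter-community crossing along a path."""

    from_residue: int
    to_residue: int
    from_community: int
    to_community: int
    cp_from: float | None = None
    cp_to: float | None = None


@dataclass
class Path:
    residues: tuple[int, ...]       # residue numbers, source → sink
    occupancy: float
    length: float                   # Σ w along the path (representative frame)
    hops: list[Hop] = field(default_factory=list)


@dataclass
class PathEnsemble:
    """Distinct optimal source→sink routes with ensemble occupancies."""

    paths: list[Path]
    source: int
    sink: int
    n_frames: int
    n_connected_frames: int


def _dijkstra(w: np.ndarray, src: int) -> np.ndarray:
    n = w.shape[0]
    dist = np.full(n, np.inf)
    dist[src] = 0.0
    done = np.zeros(n, dtype=bool)
    heap = [(0.0, src)]
    while heap:
        d, u = heapq.heappop(heap)
        if done[u]:
            continue
        done[u] = True
        nbrs = np.nonzero(np.isfinite(w[u]))[0]
        for v in nbrs:
            if v == u or done[v]:
                continue
            nd = d + w[u, v]
            if nd < dist[v] - 1e-15:
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    return dist


def _best_path(w: np.ndarray, src: int, dst: int) -> tuple[tuple[int, ...], float] | None:
    """Shortest src→dst path; ties resolved by fewer nodes, then by the
    lexicographically smallest node sequence."""
    ds = _dijkstra(w, src)
    if not np.isfinite(ds[dst]):
        return None
    dt = _dijkstra(w, dst)
    total = ds[dst]
    tol = 1e-9 * (1 + total)
    on_dag = np.nonzero(np.abs(ds + dt - total) <= tol)[0]
    # hop-count DP to the sink over the shortest-path DAG
    hops = {int(dst): 0}
    order = sorted(on_dag, key=lambda v: -ds[v])
    nxt: dict[int, list[int]] = {}
    for v in order:
        v = int(v)
        if v == dst:
            continue
        succ = [
            int(u)
            for u in on_dag
            if np.isfinite(w[v, u])
            and abs(ds[v] + w[v, u] - ds[u]) <= tol
            and int(u) in hops
        ]
        if not succ:
            continue
        hops[v] = 1 + min(hops[u] for u in succ)
        nxt[v] = succ
    path = [src]
    u = src
    while u != dst:
        cand = [v for v in nxt.get(u, []) if hops[v] == hops[u] - 1]
        u = min(cand)
        path.append(u)
    return tuple(path), float(total)


def path_ensemble(
    ensemble: ConformationalEnsemble,
    coupling: CouplingMatrix,
    source: int,
    sink: int,
    I_min: float | None = None,
    contact_cutoff: float | None = None,
    normalization: dict[str, float] | None = None,
    mode: str = "frames",
    k_paths: int = 5,
) -> PathEnsemble:
    """Ensemble of optimal source→sink communication routes.

    ``mode="frames"`` (default): each frame contributes the shortest path
    on its own contact graph (ensemble w lengths); the occupancy of a
    distinct residue sequence is the fraction of connected frames in
    which it is optimal. ``mode="mean"`` is a comparison estimator:
    Yen's k shortest paths on the mean-frame graph, occupancies from
    Boltzmann-like weights exp(-(L - L_min)) over the k routes.
    Source/sink disconnected in more than half the frames raises
    :class:`GraphError`.
    """
    from .network import CONTACT_CUTOFF, DEFAULT_I_MIN

    s = ensemble.structure
    numbers = s.residue_numbers
    if source not in numbers or sink not in numbers:
        raise InputError("source/sink not among structure residue numbers")
    if source == sink:
        raise InputError("source and sink must differ")
    if I_min is None:
        I_min = DEFAULT_I_MIN
    if contact_cutoff is None:
        contact_cutoff = CONTACT_CUTOFF
    src = numbers.index(source)
    dst = numbers.index(sink)

    if mode == "mean":
        import networkx as nx

        graph = build_contact_graph(
            s, ensemble.frames.mean(axis=0), coupling,
            I_min=I_min, contact_cutoff=contact_cutoff, normalization=normalization,
        )
        try:
            gen = nx.shortest_simple_paths(graph.g, src, dst, weight="length")
            routes = []
            for path in gen:
                length = sum(
                    graph.g.edges[u, v]["length"] for u, v in zip(path, path[1:])
                )
                routes.append((tuple(path), length))
                if len(routes) >= k_paths:
                    break
        except nx.NetworkXNoPath as exc:
            raise GraphError("source and sink are disconnected on the mean graph") from exc
        l_min = min(l for _, l in routes)
        weights = np.array([np.exp(-(l - l_min)) for _, l in routes])
        weights /= weights.sum()
        paths = [
            Path(residues=tuple(numbers[i] for i in p), occupancy=float(o), length=l)
            for (p, l), o in zip(routes, weights)
        ]
        paths.sort(key=lambda p: (-p.occupancy, p.residues))
        return PathEnsemble(
            paths=paths, source=source, sink=sink,
            n_frames=ensemble.frame_count, n_connected_frames=ensemble.frame_count,
        )
    if mode != "frames":
        raise InputError("mode must be 'frames' or 'mean'")

    tallies: dict[tuple[int, ...], int] = {}
    lengths: dict[tuple[int, ...], float] = {}
    n_disconnected = 0
    for f in range(ensemble.frame_count):
        graph = build_contact_graph(
            s, ensemble.frames[f], coupling,
            I_min=I_min, contact_cutoff=contact_cutoff,
            normalization=normalization, frame=f,
        )
        w, _ = graph.lengths_matrix()
        found = _best_path(w, src, dst)
        if found is None:
            n_disconnected += 1
            continue
        path, total = found
        tallies[path] = tallies.get(path, 0) + 1
        lengths[path] = total
    n_frames = ensemble.frame_count
    n_connected = n_frames - n_disconnected
    if n_disconnected > n_frames / 2:
        raise GraphError(
            f"source {source} and sink {sink} disconnected in "
            f"{n_disconnected}/{n_frames} frames (I_min={I_min}, "
            f"contact_cutoff={contact_cutoff}); lower I_min or check inputs"
        )
    paths = [
        Path(
            residues=tuple(numbers[i] for i in p),
            occupancy=cnt / n_connected,
            length=lengths[p],
        )
        for p, cnt in tallies.items()
    ]
    paths.sort(key=lambda p: (-p.occupancy, p.residues))
    return PathEnsemble(
        paths=paths, source=source, sink=sink,
        n_frames=n_frames, n_connected_frames=n_connected,
    )


def annotate_hops(
    path: Path,
    partition: CommunityPartition,
    cp_profile: CPProfile | None = None,
) -> Path:
    """Mark inter-community crossings along a path.

    Consecutive path residues in different communities form a hop; each
    hop records the two communities, the residue pair, and (when a CP
    profile is given) both residues' communication propensities. The
    partition must cover every path residue.
    """
    member = partition.membership()
    cp_of: dict[int, float] = {}
    if cp_profile is not None:
        cp_of = dict(zip(cp_profile.residue_numbers, cp_profile.cp))
    hops: list[Hop] = []
    for a, b in zip(path.residues, path.residues[1:]):
        if a not in member or b not in member:
            raise InputError(f"partition does not cover path residues {a}/{b}")
        ca_, cb_ = member[a], member[b]
        if ca_ != cb_:
            hops.append(
                Hop(
                    from_residue=a,
                    to_residue=b,
                    from_community=ca_,
                    to_community=cb_,
                    cp_from=cp_of.get(a),
                    cp_to=cp_of.get(b),
                )
            )
    path.hops = hops
    return path
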