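from __future__ import annotations

import warnings

import numpy as np
import pytest

from allonet.alignment import MultipleAlignment, encode_sequence
from allonet.ensemble import ConformationalEnsemble, Residue, StructureModel
from allonet.network import ResidueGraph

import networkx as nx

# low-effective-sequence warnings are expected on tiny test alignments
warnings.filterwarnings(
    "ignore", message="only .* sequence clusters", category=UserWarning
)


def make_alignment(rows: list[str], ids: list[str] | None = None,
                   reference_id: str | None = None) -> MultipleAlignment:
    ids = ids or [f"s{i}" for i in range(len(rows))]
    matrix = np.vstack([encode_sequence(r) for r in rows])
    return MultipleAlignment(
        sequence_ids=ids,
        matrix=matrix,
        column_index=np.arange(matrix.shape[1]),
        reference_id=reference_id,
    )


def make_bead_structure(coords: np.ndarray, names: list[str] | None = None) -> StructureModel:
    """One CA pseudo-atom per residue at the given coordinates."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    names = names or ["ALA"] * n
    residues = [
        Residue(number=i + 1, chain="A", name=names[i], letter="A",
                atom_names=["CA"], atom_start=i, atom_stop=i + 1)
        for i in range(n)
    ]
    return StructureModel(residues=residues, coords=coords)


def make_bead_ensemble(frames: np.ndarray) -> ConformationalEnsemble:
    frames = np.asarray(frames, dtype=float)
    structure = make_bead_structure(frames[0])
    return ConformationalEnsemble(structure=structure, frames=frames)


def graph_from_edges(n: int, edges: dict[tuple[int, int], float]) -> ResidueGraph:
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for (u, v), w in edges.items():
        g.add_edge(u, v, length=float(w), strength=100.0)
    return ResidueGraph(g=g)


def zero_pmi(ens):
    """All-zero pMI profile congruent with an ensemble."""
    from allonet.coupling import PMIProfile

    n = ens.structure.n_residues
    return PMIProfile(
        mean=np.zeros(n),
        per_frame=np.zeros((ens.frame_count, n)),
        residue_numbers=ens.structure.residue_numbers,
        threshold=5.0,
        aggregate="mean",
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
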