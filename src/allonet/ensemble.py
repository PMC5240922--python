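"""Structures and conformational ensembles.

A :class:`StructureModel` is a flat heavy-atom table with residue
bookkeeping (contiguous atom slices per residue); a
:class:`ConformationalEnsemble` stacks per-frame coordinates congruent
with one model. Multi-model PDB is the interchange format; hydrogens are
ignored and disordered atoms resolve to their highest-occupancy
location.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data.PDBData import protein_letters_3to1
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import EnsembleError, InputError


@dataclass
class Residue:
    number: int
    chain: str
    name: str          # 3-letter code
    letter: str        # 1-letter code ('X' if unknown)
    atom_names: list[str]
    atom_start: int    # slice [atom_start, atom_stop) into the atom table
    atom_stop: int

    @property
    def n_atoms(self) -> int:
        return self.atom_stop - self.atom_start


@dataclass
class StructureModel:
    """Heavy-atom model: residue table plus an (n_atoms, 3) coordinate array."""

    residues: list[Residue]
    coords: np.ndarray
    atom_residue_index: np.ndarray = field(init=False)
    ca_indices: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InputError("coords must be (n_atoms, 3)")
        seen: set[tuple[str, int]] = set()
        idx = np.empty(self.coords.shape[0], dtype=np.int64)
        ca = np.full(len(self.residues), -1, dtype=np.int64)
        for r_i, res in enumerate(self.residues):
            if res.n_atoms < 1:
                raise InputError(f"residue {res.chain}:{res.number} has no heavy atoms")
            key = (res.chain, res.number)
            if key in seen:
                raise InputError(f"duplicate residue number {res.number} in chain {res.chain}")
            seen.add(key)
            idx[res.atom_start:res.atom_stop] = r_i
            for a in range(res.atom_start, res.atom_stop):
                if res.atom_names[a - res.atom_start] == "CA":
                    ca[r_i] = a
        self.atom_residue_index = idx
        self.ca_indices = ca

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def residue_numbers(self) -> list[int]:
        return [r.number for r in self.residues]

    @property
    def sequence(self) -> str:
        return "".join(r.letter for r in self.residues)

    def ca_coords(self, coords: np.ndarray | None = None) -> np.ndarray:
        """Cα coordinates (rows of residues lacking a Cα are NaN)."""
        c = self.coords if coords is None else coords
        out = np.full((self.n_residues, 3), np.nan)
        ok = self.ca_indices >= 0
        out[ok] = c[self.ca_indices[ok]]
        return out


@dataclass
class ConformationalEnsemble:
    """Ordered frames over one structure's atom bookkeeping."""

    structure: StructureModel
    frames: np.ndarray   # (n_frames, n_atoms, 3)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (self.structure.n_atoms, 3):
            raise EnsembleError("frames must be (n_frames, n_atoms, 3) congruent with the structure")

    @property
    def frame_count(self) -> int:
        return self.frames.shape[0]


def _model_to_structure(model) -> StructureModel:
    residues: list[Residue] = []
    coords: list[np.ndarray] = []
    for chain in model:
        for res in chain:
            if res.id[0].strip():      # skip waters / hetero records
                continue
            names, xyz = [], []
            for atom in res:
                if (atom.element or "").upper() == "H":
                    continue
                names.append(atom.get_name())
                xyz.append(atom.get_coord())
            if not names:
                continue
            letter = protein_letters_3to1.get(res.get_resname(), "X")
            start = len(coords)
            coords.extend(xyz)
            residues.append(
                Residue(
                    number=res.id[1],
                    chain=chain.id,
                    name=res.get_resname(),
                    letter=letter,
                    atom_names=names,
                    atom_start=start,
                    atom_stop=len(coords),
                )
            )
    if not residues:
        raise InputError("no protein residues with heavy atoms found")
    return StructureModel(residues=residues, coords=np.asarray(coords, dtype=float))


def read_structure(path: str | Path) -> StructureModel:
    """Read the first model of a PDB file (heavy atoms only)."""
    return read_ensemble(path).structure


def read_ensemble(path: str | Path) -> ConformationalEnsemble:
    """Read a (multi-model) PDB file as a conformational ensemble.

    All models must share atom bookkeeping; a model with a differing atom
    count raises :class:`EnsembleError` naming the model and first
    offending residue.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"structure file not found: {path}")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    models = list(structure)
    if not models:
        raise InputError(f"no models in {path}")
    ref = _model_to_structure(models[0])
    missing_ca = [r.number for r in ref.residues if "CA" not in r.atom_names]
    if missing_ca:
        warnings.warn(
            f"{len(missing_ca)} residue(s) lack a CA atom and are excluded "
            f"from elastic-network models: {missing_ca[:10]}",
            stacklevel=2,
        )
    frames = [ref.coords]
    for m_i, model in enumerate(models[1:], start=2):
        other = _model_to_structure(model)
        if other.n_atoms != ref.n_atoms or other.n_residues != ref.n_residues:
            bad = _first_incongruent_residue(ref, other)
            raise EnsembleError(
                f"model {m_i} of {path.name} is not congruent with model 1 "
                f"(first differing residue: {bad})"
            )
        for r1, r2 in zip(ref.residues, other.residues):
            if r1.atom_names != r2.atom_names:
                raise EnsembleError(
                    f"model {m_i} of {path.name}: residue {r1.chain}:{r1.number} "
                    f"atom records differ from model 1"
                )
        frames.append(other.coords)
    return ConformationalEnsemble(structure=ref, frames=np.stack(frames))


def _first_incongruent_residue(ref: StructureModel, other: StructureModel) -> str:
    for r1, r2 in zip(ref.residues, other.residues):
        if (r1.number, r1.chain, r1.n_atoms) != (r2.number, r2.chain, r2.n_atoms):
            return f"{r1.chain}:{r1.number}"
    return "residue table length differs"


def superpose(ensemble: ConformationalEnsemble, passes: int = 2) -> ConformationalEnsemble:
    """Least-squares fit of every frame onto the ensemble mean (Kabsch),
    iterated ``passes`` times so the mean itself stabilizes.

    Removes rigid-body motion that would otherwise masquerade as
    correlated internal dynamics.
    """
    frames = ensemble.frames.copy()
    for _ in range(passes):
        mean = frames.mean(axis=0)
        mean_c = mean - mean.mean(axis=0)
        for f in range(frames.shape[0]):
            x = frames[f] - frames[f].mean(axis=0)
            rot = _kabsch(x, mean_c)
            frames[f] = x @ rot
        # re-centre the running mean at the origin
    return ConformationalEnsemble(structure=ensemble.structure, frames=frames)


def _kabsch(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation matrix minimizing RMSD of centred ``x`` onto centred ``target``."""
    h = x.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


@dataclass
class FluctuationProfile:
    """Per-residue nonnegative fluctuation amplitudes.

    ``mode_set`` names the source ("rmsf" or the elastic-network modes
    averaged); ``hinges`` optionally flags local minima, the usual hinge
    candidates.
    """

    values: np.ndarray
    residue_numbers: list[int]
    mode_set: str
    hinges: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise InputError("fluctuation values must be nonnegative")


def rmsf(ensemble: ConformationalEnsemble, superposed: bool = False) -> FluctuationProfile:
    """Per-residue Cα root-mean-square fluctuation about the mean (Å).

    Frames are superposed first unless ``superposed`` says they already are.
    """
    if ensemble.frame_count < 2:
        raise EnsembleError("RMSF needs at least 2 frames")
    ens = ensemble if superposed else superpose(ensemble)
    s = ens.structure
    ok = s.ca_indices >= 0
    ca = ens.frames[:, s.ca_indices[ok], :]
    mean = ca.mean(axis=0)
    vals = np.sqrt(((ca - mean) ** 2).sum(axis=2).mean(axis=0))
    out = np.zeros(s.n_residues)
    out[ok] = vals
    return FluctuationProfile(
        values=out, residue_numbers=s.residue_numbers, mode_set="rmsf"
    )


def min_heavy_atom_distances(
    structure: StructureModel, coords: np.ndarray | None = None
) -> np.ndarray:
    """Symmetric matrix of minimum inter-heavy-atom distances (Å), diagonal 0."""
    c = structure.coords if coords is None else np.asarray(coords, dtype=float)
    d_atoms = cdist(c, c)
    starts = np.array([r.atom_start for r in structure.residues])
    red_rows = np.minimum.reduceat(d_atoms, starts, axis=0)
    red = np.minimum.reduceat(red_rows, starts, axis=1)
    np.fill_diagonal(red, 0.0)
    return red


def residue_pair_contacts(
    structure: StructureModel,
    coords: np.ndarray,
    cutoff: float,
) -> dict[tuple[int, int], int]:
    """Count heavy-atom pairs within ``cutoff`` for every residue pair.

    KD-tree based; identical to the brute-force all-pairs count. Keys are
    (i, j) residue *indices* with i < j; intra-residue pairs are skipped.
    """
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    out: dict[tuple[int, int], int] = {}
    if pairs.size == 0:
        return out
    ri = structure.atom_residue_index[pairs[:, 0]]
    rj = structure.atom_residue_index[pairs[:, 1]]
    mask = ri != rj
    lo = np.minimum(ri[mask], rj[mask])
    hi = np.maximum(ri[mask], rj[mask])
    codes, counts = np.unique(lo * structure.n_residues + hi, return_counts=True)
    n = structure.n_residues
    for code, cnt in zip(codes, counts):
        out[(int(code // n), int(code % n))] = int(cnt)
    return out
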