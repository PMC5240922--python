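"""Ground-truth-bearing synthetic alignments and ensembles.

Every stage of the pipeline is testable without downloads: alignments
carry planted covarying column pairs generated by copying a latent state
through a noisy channel, and bead-polymer ensembles carry planted
correlation blocks and inter-block bridge pairs whose displacements
co-move. The paired fixture couples the two — planted coevolving column
pairs coincide with planted structural bridges — emulating the empirical
tendency of coevolving residues to sit close in space and to carry the
allosteric cross-talk between modules.

All generators are pure functions of their spec (seed included): the
same spec reproduces bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import AA_ALPHABET, GAP, N_AA, MultipleAlignment
from .coevolution import load_background
from .ensemble import ConformationalEnsemble, Residue, StructureModel
from .errors import InputError

_AA_3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
BEAD_SPACING = 3.8      # Å, Cα–Cα virtual bond (chain/stalk/bridge spacing)
CLUSTER_SPACING = 3.1   # Å, block lattice constant (sqrt(2)·3.1 < 4.5 contact)


@dataclass
class MSASpec:
    """Recipe for a synthetic alignment.

    ``planted_pairs`` couples column pairs at the given strength: with
    probability ``coupling`` both columns copy one latent letter drawn
    uniformly from ``latent_states`` letters, otherwise each column draws
    independently from the background.
    """

    seed: int = 0
    n_sequences: int = 400
    n_columns: int = 60
    planted_pairs: list[tuple[int, int]] = field(default_factory=list)
    coupling: float = 0.9
    latent_states: int = 8
    conservation: np.ndarray | float = 0.0
    gap_rate: float = 0.05

    def validate(self) -> None:
        if not 0 <= self.coupling <= 1:
            raise InputError("coupling must be in [0, 1]")
        if self.coupling == 1 and self.latent_states < 2:
            raise InputError("perfect coupling needs >= 2 latent states")
        if not 2 <= self.latent_states <= N_AA:
            raise InputError("latent_states must be in [2, 20]")
        flat = [c for p in self.planted_pairs for c in p]
        if len(set(flat)) != len(flat):
            raise InputError("planted pairs must not share columns")
        if any(not 0 <= c < self.n_columns for c in flat):
            raise InputError("planted column index out of range")
        if not 0 <= self.gap_rate < 1:
            raise InputError("gap_rate must be in [0, 1)")


@dataclass
class EnsembleSpec:
    """Recipe for a block-correlated bead-polymer ensemble.

    Residues are one pseudo-heavy-atom beads grouped into compact
    lattice blocks joined by bridge stalks. Per frame each block
    breathes: a shared scalar latent drives every member along its fixed
    radial direction from the block centre (weight sqrt(rho)), on top of
    independent bead noise. A breathing mode carries no net translation
    or rotation, so least-squares superposition cannot alias one block's
    motion into another. Each planted bridge pair shares a 3-D latent
    displacement (weight sqrt(bridge_rho)); the remaining bridge-bead
    variance follows the own-block breathing, keeping bridge beads
    dynamically tied to their modules as well as to each other.
    """

    seed: int = 0
    blocks: list[tuple[int, int]] = field(default_factory=lambda: [(0, 30), (30, 60)])
    n_frames: int = 500
    rho: float = 0.6
    bridge_rho: float = 0.6
    bridges: list[tuple[int, int]] = field(default_factory=lambda: [(29, 30)])
    noise_sd: float = 0.5
    sequence: str | None = None
    #: plant a low-weight communication corridor: a contact chain of
    #: beads from the first block's far side, through every bridge, to
    #: the last block's far side, all sharing one strong 3-D latent
    #: (weight sqrt(corridor_rho)) so their mutual coupling dominates.
    corridor: bool = False
    corridor_rho: float = 0.85

    @property
    def n_residues(self) -> int:
        return max(stop for _, stop in self.blocks)

    def validate(self) -> None:
        prev = 0
        for start, stop in self.blocks:
            if start != prev or stop <= start:
                raise InputError("blocks must be contiguous, ordered and non-overlapping")
            prev = stop
        if not 0 <= self.rho < 1 or not 0 <= self.bridge_rho < 1:
            raise InputError("rho values must be in [0, 1)")
        if any(stop - start < 10 for start, stop in self.blocks):
            raise InputError("blocks need at least 10 residues each")
        seen_pairs: set[tuple[int, int]] = set()
        for i, j in self.bridges:
            bi = self._block_of(i)
            bj = self._block_of(j)
            if bi is None or bj is None or bi == bj:
                raise InputError(f"bridge ({i}, {j}) must join two distinct blocks")
            if abs(bi - bj) != 1:
                raise InputError("bridges must join adjacent blocks")
            key = (min(bi, bj), max(bi, bj))
            if key in seen_pairs:
                raise InputError("at most one bridge per adjacent block pair")
            seen_pairs.add(key)
        if self.sequence is not None and len(self.sequence) != self.n_residues:
            raise InputError("sequence length must equal residue count")
        if self.noise_sd <= 0:
            raise InputError("noise_sd must be positive")
        if self.corridor:
            if not 0 <= self.corridor_rho < 1:
                raise InputError("corridor_rho must be in [0, 1)")
            if len(self.bridges) != len(self.blocks) - 1:
                raise InputError("a corridor needs a bridge between every adjacent block pair")

    def _block_of(self, residue: int) -> int | None:
        for b, (start, stop) in enumerate(self.blocks):
            if start <= residue < stop:
                return b
        return None


@dataclass
class PairedSpec:
    """End-to-end fixture: one alignment column per structure residue,
    with planted covarying pairs placed on the structural bridge pairs."""

    seed: int = 0
    n_sequences: int = 400
    n_residues: int = 60
    n_frames: int = 500
    blocks: list[tuple[int, int]] = field(default_factory=lambda: [(0, 30), (30, 60)])
    bridges: list[tuple[int, int]] = field(default_factory=lambda: [(29, 30)])
    coupling: float = 0.9
    rho: float = 0.6
    bridge_rho: float = 0.6
    noise_sd: float = 0.5
    gap_rate: float = 0.05
    corridor: bool = True
    corridor_rho: float = 0.85


def synth_msa(spec: MSASpec) -> tuple[MultipleAlignment, dict]:
    """Generate an alignment with planted covarying column pairs.

    Background columns are i.i.d. draws from the bundled background
    frequencies; planted pairs copy a shared latent letter with
    probability ``coupling``. Gaps are injected uniformly at
    ``gap_rate``. Returns the alignment plus a truth record.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    q = load_background().q
    n_seq, n_col = spec.n_sequences, spec.n_columns
    matrix = rng.choice(N_AA, size=(n_seq, n_col), p=q).astype(np.int8)
    cons = np.broadcast_to(np.asarray(spec.conservation, dtype=float), (n_col,))
    consensus = rng.integers(0, N_AA, size=n_col)
    for c in range(n_col):
        if cons[c] > 0:
            take = rng.random(n_seq) < cons[c]
            matrix[take, c] = consensus[c]
    latent_letters = rng.choice(N_AA, size=spec.latent_states, replace=False)
    for ci, cj in spec.planted_pairs:
        latent = latent_letters[rng.integers(0, spec.latent_states, size=n_seq)]
        copy = rng.random(n_seq) < spec.coupling
        matrix[copy, ci] = latent[copy]
        matrix[copy, cj] = latent[copy]
    if spec.gap_rate > 0:
        gaps = rng.random((n_seq, n_col)) < spec.gap_rate
        matrix[gaps] = GAP
    ids = [f"seq{i:05d}" for i in range(n_seq)]
    # reference row: the consensus-free background consensus of column
    # majorities, appended ungapped so every column maps to a residue
    ref = np.array(
        [np.bincount(matrix[matrix[:, c] != GAP, c], minlength=N_AA)[:N_AA].argmax()
         if np.any(matrix[:, c] != GAP) else 0
         for c in range(n_col)],
        dtype=np.int8,
    )
    ids.append("reference")
    matrix = np.vstack([matrix, ref])
    aln = MultipleAlignment(
        sequence_ids=ids,
        matrix=matrix,
        column_index=np.arange(n_col),
        reference_id="reference",
    )
    truth = {
        "planted_pairs": [list(p) for p in spec.planted_pairs],
        "coupling": spec.coupling,
        "latent_letters": [AA_ALPHABET[i] for i in latent_letters],
        "seed": spec.seed,
    }
    return aln, truth


def _block_geometry(spec: EnsembleSpec) -> tuple[np.ndarray, dict]:
    """Mean bead coordinates: compact lattice blocks joined by stalks.

    Each block occupies sites of a cubic lattice (spacing = bead spacing)
    taken in distance-from-centre order, so blocks are dense clumps with
    every interior bead within contact range of several block-mates.
    Bridge beads are pulled out onto a stalk toward the partner block so
    that exactly the bridge pair sits within contact distance across the
    gap; all other cross-block pairs stay well separated.
    """
    a = BEAD_SPACING
    s = CLUSTER_SPACING
    n_blocks = len(spec.blocks)
    # consecutive centres: block surface (|x| <= s) + stalk (a beyond the
    # surface) + bridge gap (a) + stalk + surface
    sep = 2 * (s + a) + a
    block_centers = np.array([[b * sep, 0.0, 0.0] for b in range(n_blocks)])
    # lattice offsets sorted by radius; x restricted to {-s, 0, s} so the
    # block's x-extent is fixed regardless of block size. The lattice
    # constant sits below sqrt(2)-shell contact range, so interior beads
    # touch up to 18 neighbors and blocks are dense modules.
    offsets = np.array(
        [[x, y, z] for x in (-1, 0, 1) for y in range(-3, 4) for z in range(-3, 4)],
        dtype=float,
    )
    order = np.lexsort((offsets[:, 2], offsets[:, 1], offsets[:, 0],
                        (offsets**2).sum(axis=1)))
    offsets = offsets[order] * s
    coords = np.zeros((spec.n_residues, 3))
    stalk_of: dict[int, int] = {}
    for i, j in spec.bridges:
        bi, bj = spec._block_of(i), spec._block_of(j)
        stalk_of[i] = bj
        stalk_of[j] = bi
    site_members: list[list[int]] = []
    for b, (start, stop) in enumerate(spec.blocks):
        members = [r for r in range(start, stop) if r not in stalk_of]
        if len(members) > len(offsets):
            raise InputError("block too large for the lattice template")
        site_members.append(members)
        for k, r in enumerate(members):
            coords[r] = block_centers[b] + offsets[k]
    # stalks: each bridge bead sits between its block centre and the
    # partner block centre, one spacing beyond the block surface; the two
    # beads of a bridge end up ~one spacing apart across the midline.
    for (i, j) in spec.bridges:
        bi, bj = spec._block_of(i), spec._block_of(j)
        ci, cj = block_centers[bi], block_centers[bj]
        mid = 0.5 * (ci + cj)
        direction = (cj - ci) / np.linalg.norm(cj - ci)
        coords[i] = mid - 0.5 * a * direction
        coords[j] = mid + 0.5 * a * direction
    layout = {"site_members": site_members, "stalk_of": stalk_of}
    return coords, layout


# site-order positions of the x-axis lattice line (see offsets ordering):
# site 0 = centre, site 1 = (-s,0,0), site 6 = (+s,0,0)
_ENTRY_SITE, _CENTER_SITE, _EXIT_SITE = 1, 0, 6


def _corridor_indices(spec: EnsembleSpec, layout: dict) -> list[int]:
    """Residue indices of the planted corridor, source end to sink end.

    Per block: the (-x) surface bead, the centre bead, the (+x) surface
    bead; stalk beads are interleaved between blocks. Consecutive
    corridor beads are in contact (lattice or stalk spacing), so the
    corridor is a connected chain through every bridge.
    """
    stalk_pairs = sorted(
        spec.bridges, key=lambda p: min(spec._block_of(p[0]), spec._block_of(p[1]))
    )
    corridor: list[int] = []
    for b in range(len(spec.blocks)):
        members = layout["site_members"][b]
        if len(members) <= _EXIT_SITE:
            raise InputError("block too small to host a corridor")
        corridor.extend(
            [members[_ENTRY_SITE], members[_CENTER_SITE], members[_EXIT_SITE]]
        )
        if b < len(spec.blocks) - 1:
            i, j = stalk_pairs[b]
            lo = i if spec._block_of(i) == b else j
            hi = j if lo == i else i
            corridor.extend([lo, hi])
    return corridor


def synth_ensemble(spec: EnsembleSpec) -> tuple[ConformationalEnsemble, dict]:
    """Generate a block-correlated Gaussian bead ensemble.

    Per frame, residue r of block b moves as
    sd·(sqrt(rho)·s_b·û_r + sqrt(1-rho)·e_r) where s_b is the block's
    scalar breathing latent and û_r the bead's fixed radial unit vector
    from the block centre. Bridge beads replace a (1 - bridge_rho)
    share of their variance budget with the block breathing/noise split
    and put sqrt(bridge_rho) on a 3-D latent shared by the pair, so the
    pair co-moves across the gap while staying tied to its own block.
    Returns the ensemble plus a truth record.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mean, layout = _block_geometry(spec)
    corridor = _corridor_indices(spec, layout) if spec.corridor else []
    n = spec.n_residues
    seq = spec.sequence or "".join(
        AA_ALPHABET[i] for i in rng.integers(0, N_AA, size=n)
    )
    block_of = np.empty(n, dtype=np.int64)
    centers = np.empty((n, 3))
    for b, (start, stop) in enumerate(spec.blocks):
        block_of[start:stop] = b
        centers[start:stop] = mean[start:stop].mean(axis=0)
    radial = mean - centers
    norms = np.linalg.norm(radial, axis=1)
    radial = np.where(norms[:, None] > 1e-9, radial / np.maximum(norms, 1e-9)[:, None],
                      np.array([1.0, 0.0, 0.0]))
    bridge_members: dict[int, int] = {}
    for p, (i, j) in enumerate(spec.bridges):
        bridge_members[i] = p
        bridge_members[j] = p
    sq_r, sq_1r = np.sqrt(spec.rho), np.sqrt(1 - spec.rho)
    sq_br, sq_1br = np.sqrt(spec.bridge_rho), np.sqrt(1 - spec.bridge_rho)
    sq_cr, sq_1cr = np.sqrt(spec.corridor_rho), np.sqrt(1 - spec.corridor_rho)
    frames = np.empty((spec.n_frames, n, 3))
    for f in range(spec.n_frames):
        s_block = rng.standard_normal(len(spec.blocks))
        g_pair = rng.standard_normal((len(spec.bridges), 3))
        g_corr = rng.standard_normal(3)
        noise = rng.standard_normal((n, 3))
        disp = sq_r * s_block[block_of, None] * radial + sq_1r * noise
        for r, p in bridge_members.items():
            if r not in corridor:
                disp[r] = sq_br * g_pair[p] + sq_1br * disp[r]
        for r in corridor:
            disp[r] = sq_cr * g_corr + sq_1cr * disp[r]
        frames[f] = mean + spec.noise_sd * disp
    residues = [
        Residue(
            number=r + 1,
            chain="A",
            name=_AA_3[seq[r]],
            letter=seq[r],
            atom_names=["CA"],
            atom_start=r,
            atom_stop=r + 1,
        )
        for r in range(n)
    ]
    structure = StructureModel(residues=residues, coords=mean.copy())
    ensemble = ConformationalEnsemble(structure=structure, frames=frames)
    truth = {
        "blocks": [list(b) for b in spec.blocks],
        "bridges": [list(b) for b in spec.bridges],
        "bridge_residue_numbers": [[i + 1, j + 1] for i, j in spec.bridges],
        "rho": spec.rho,
        "bridge_rho": spec.bridge_rho,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    if spec.corridor:
        truth["corridor"] = corridor
        truth["corridor_residue_numbers"] = [r + 1 for r in corridor]
        truth["source_residue"] = corridor[0] + 1
        truth["sink_residue"] = corridor[-1] + 1
    return ensemble, truth


def paired_fixture(
    spec: PairedSpec,
) -> tuple[MultipleAlignment, ConformationalEnsemble, dict]:
    """End-to-end fixture: alignment and ensemble over the same residues.

    Column c of the alignment corresponds to residue c+1 of the
    structure; the reference row equals the structure sequence, so the
    column→residue mapping is the identity. Planted covarying column
    pairs sit exactly on the planted structural bridges.
    """
    ens_spec = EnsembleSpec(
        seed=spec.seed,
        blocks=spec.blocks,
        n_frames=spec.n_frames,
        rho=spec.rho,
        bridge_rho=spec.bridge_rho,
        bridges=spec.bridges,
        noise_sd=spec.noise_sd,
        corridor=spec.corridor,
        corridor_rho=spec.corridor_rho,
    )
    if ens_spec.n_residues != spec.n_residues:
        raise InputError("blocks must cover exactly n_residues")
    ensemble, ens_truth = synth_ensemble(ens_spec)
    msa_spec = MSASpec(
        seed=spec.seed + 1,
        n_sequences=spec.n_sequences,
        n_columns=spec.n_residues,
        planted_pairs=spec.bridges,
        coupling=spec.coupling,
        gap_rate=spec.gap_rate,
    )
    aln, msa_truth = synth_msa(msa_spec)
    # align the reference row with the structure sequence so the mapping
    # is the identity (offset by the first residue number)
    ref_idx = aln.sequence_ids.index(aln.reference_id)
    aln.matrix[ref_idx] = np.array(
        [AA_ALPHABET.index(c) for c in ensemble.structure.sequence], dtype=np.int8
    )
    truth = {**ens_truth, **msa_truth, "n_residues": spec.n_residues}
    return aln, ensemble, truth


def synth_multiatom_structure(
    seed: int = 0, n_residues: int = 40, atoms_per_residue: int = 5
) -> StructureModel:
    """Compact multi-atom structure for distance-matrix oracles and the
    contact-normalization recipe.

    Residues follow a coarse helical backbone; each carries a small
    cluster of pseudo-side-chain heavy atoms. Residue types cycle through
    the 20 amino acids.
    """
    rng = np.random.default_rng(seed)
    residues: list[Residue] = []
    coords: list[np.ndarray] = []
    t = np.arange(n_residues) * 100.0 * np.pi / 180.0
    backbone = np.stack(
        [2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n_residues)], axis=1
    )
    for r in range(n_residues):
        letter = AA_ALPHABET[r % N_AA]
        names = ["CA"] + [f"X{k}" for k in range(1, atoms_per_residue)]
        start = len(coords)
        coords.append(backbone[r])
        side = backbone[r] + rng.normal(scale=1.2, size=(atoms_per_residue - 1, 3))
        coords.extend(side)
        residues.append(
            Residue(
                number=r + 1,
                chain="A",
                name=_AA_3[letter],
                letter=letter,
                atom_names=names,
                atom_start=start,
                atom_stop=len(coords),
            )
        )
    return StructureModel(residues=residues, coords=np.asarray(coords))


def write_fasta(aln: MultipleAlignment, path: str | Path) -> None:
    """Write the alignment as aligned FASTA (gaps as '-')."""
    from .alignment import decode_row

    with open(path, "w") as fh:
        for sid, row in zip(aln.sequence_ids, aln.matrix):
            fh.write(f">{sid}\n{decode_row(row)}\n")


def write_multimodel_pdb(ensemble: ConformationalEnsemble, path: str | Path) -> None:
    """Write the ensemble as a multi-model PDB file."""
    s = ensemble.structure
    with open(path, "w") as fh:
        for f in range(ensemble.frame_count):
            fh.write(f"MODEL     {f + 1:4d}\n")
            serial = 1
            for res in s.residues:
                for k, name in enumerate(res.atom_names):
                    x, y, z = ensemble.frames[f, res.atom_start + k]
                    element = "C"
                    fh.write(
                        f"ATOM  {serial:5d} {name:^4s}{res.name:>4s} "
                        f"{res.chain}{res.number:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                        f"          {element:>2s}\n"
                    )
                    serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")
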