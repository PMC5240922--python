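"""Gaussian network model (GNM) of residue fluctuations.

The GNM places a harmonic spring between every Cα pair within a cutoff
(7.3 Å by default, the usual single-parameter choice) and reads
collective dynamics off the Kirchhoff (graph Laplacian) matrix: slow
(low-eigenvalue) modes describe large-scale collective motions, and
local minima of the slow-mode fluctuation profile mark hinge residues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

from .ensemble import FluctuationProfile, StructureModel
from .errors import GraphError, InputError

DEFAULT_CUTOFF = 7.3
_ZERO_TOL = 1e-9


@dataclass
class GNMModel:
    """Kirchhoff matrix with its full eigendecomposition (ascending)."""

    kirchhoff: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray   # column k is mode k
    residue_numbers: list[int]
    cutoff: float

    @property
    def n_residues(self) -> int:
        return self.kirchhoff.shape[0]


def build_gnm(
    structure: StructureModel | np.ndarray, cutoff: float = DEFAULT_CUTOFF
) -> GNMModel:
    """Build the Kirchhoff matrix from Cα contacts and diagonalize it.

    Γ_ij = -1 for distinct residues within ``cutoff``; the diagonal is
    minus the row sum, so row sums are exactly 0. Residues without a Cα
    are excluded. A contact network with more than one (near-)zero
    eigenvalue is disconnected and raises :class:`GraphError`.
    """
    if cutoff <= 0:
        raise InputError("cutoff must be positive")
    if isinstance(structure, StructureModel):
        ca = structure.ca_coords()
        ok = ~np.isnan(ca[:, 0])
        coords = ca[ok]
        numbers = [n for n, keep in zip(structure.residue_numbers, ok) if keep]
    else:
        coords = np.asarray(structure, dtype=float)
        numbers = list(range(1, coords.shape[0] + 1))
    n = coords.shape[0]
    if n < 3:
        raise InputError("GNM needs at least 3 residues with Cα")
    contact = squareform(pdist(coords) <= cutoff).astype(np.int64)
    np.fill_diagonal(contact, 0)
    kirchhoff = (-contact).astype(float)
    np.fill_diagonal(kirchhoff, contact.sum(axis=1).astype(float))
    evals, evecs = eigh(kirchhoff)
    evals = np.where(np.abs(evals) < _ZERO_TOL, 0.0, evals)
    if np.any(evals < 0):
        raise GraphError("Kirchhoff matrix has a negative eigenvalue beyond tolerance")
    scale = max(evals.max(), 1.0)
    n_zero = int((evals < _ZERO_TOL * scale).sum())
    if n_zero != 1:
        raise GraphError(
            f"contact network is disconnected ({n_zero} zero modes); "
            f"raise the cutoff or check the structure"
        )
    return GNMModel(
        kirchhoff=kirchhoff,
        eigenvalues=evals,
        eigenvectors=evecs,
        residue_numbers=numbers,
        cutoff=cutoff,
    )


def slow_mode_fluctuations(gnm: GNMModel, n_modes: int = 3) -> FluctuationProfile:
    """Residue fluctuations from the lowest nonzero modes.

    fluctuation_i = Σ_{k=1..n_modes} u_ik² / λ_k over the slowest
    internal modes (default 3). Strict local minima of the profile are
    flagged as hinge candidates.
    """
    n_nonzero = gnm.n_residues - 1
    if not 1 <= n_modes < gnm.n_residues:
        raise InputError(f"n_modes must be in [1, {n_nonzero}]")
    modes = slice(1, 1 + n_modes)
    u = gnm.eigenvectors[:, modes]
    lam = gnm.eigenvalues[modes]
    vals = (u * u / lam).sum(axis=1)
    hinges = np.zeros(gnm.n_residues, dtype=bool)
    interior = np.arange(1, gnm.n_residues - 1)
    if interior.size:
        hinges[interior] = (vals[interior] < vals[interior - 1]) & (
            vals[interior] < vals[interior + 1]
        )
    return FluctuationProfile(
        values=vals,
        residue_numbers=gnm.residue_numbers,
        mode_set=f"gnm:1-{n_modes}",
        hinges=hinges,
    )
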