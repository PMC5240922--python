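"""Column-pair coevolution statistics on a weighted alignment.

The pipeline is: plug-in mutual information from cluster-weighted joint
frequencies (pairwise-complete over gaps), average product correction
(APC) to strip broad phylogenetic/compositional signal, and a Z-score
against a within-column shuffle null. Per-residue summaries are the KL
conservation score and the cumulative MI (cMI) profile.

MI is reported in nats by default (``base=2`` gives bits). Gap handling
is pairwise-complete: a sequence gapped in either column of a pair is
dropped from that pair's counts, which avoids treating the gap as a 21st
residue state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .alignment import GAP, N_AA, AA_ALPHABET, MultipleAlignment, SequenceWeights
from .errors import InputError

#: Default Z-score threshold above which a pair contributes to cMI.
CMI_THRESHOLD = 6.5


@dataclass
class BackgroundFrequencies:
    """Background amino-acid probabilities Q, in AA_ALPHABET order."""

    q: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (N_AA,):
            raise InputError("background must have 20 entries")
        if np.any(self.q < 0):
            raise InputError("background frequencies must be nonnegative")
        s = self.q.sum()
        if not np.isclose(s, 1.0, atol=1e-2):
            raise InputError(f"background frequencies sum to {s}, not 1")
        self.q = self.q / s  # renormalize away table rounding

    def __getitem__(self, aa: str) -> float:
        return float(self.q[AA_ALPHABET.index(aa)])


def load_background(path: str | Path | None = None) -> BackgroundFrequencies:
    """Load background frequencies from a 2-column TSV (default: bundled
    proteome-wide composition table)."""
    if path is None:
        ref = resources.files("allonet.data") / "background_frequencies.tsv"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    q = np.zeros(N_AA)
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, freq = line.split("\t")
        q[AA_ALPHABET.index(aa)] = float(freq)
    return BackgroundFrequencies(q=q)


@dataclass
class CoevolutionMatrix:
    """Symmetric column-pair matrices: raw MI, APC-corrected MI, Z-scored MI.

    ``column_index`` carries the original column numbers of the source
    alignment; ``flagged`` marks pairs whose statistic is degenerate
    (< 2 effective sequences, or zero null spread for the Z-score).
    Diagonals are zero by convention.
    """

    raw_mi: np.ndarray
    column_index: np.ndarray
    apc_mi: np.ndarray | None = None
    z_mi: np.ndarray | None = None
    flagged: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw_mi = np.asarray(self.raw_mi, dtype=float)
        n = self.raw_mi.shape[0]
        if self.raw_mi.shape != (n, n):
            raise InputError("raw_mi must be square")
        if self.flagged is None:
            self.flagged = np.zeros((n, n), dtype=bool)

    @property
    def n_columns(self) -> int:
        return self.raw_mi.shape[0]


@dataclass
class ConservationProfile:
    """Per-column KL conservation scores (nats); gap-only columns are
    flagged and scored 0."""

    scores: np.ndarray
    column_index: np.ndarray
    flagged: np.ndarray


@dataclass
class CMIProfile:
    """Per-column cumulative MI: the sum of partner scores above the
    threshold ``t`` in the chosen matrix (Z-scored MI by default)."""

    cmi: np.ndarray
    column_index: np.ndarray
    threshold: float


def _entropy(p: np.ndarray, base: float | None) -> float:
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    return h / np.log(base) if base else h


def _pair_mi(
    joint: np.ndarray, base: float | None
) -> float:
    """Plug-in MI of a normalized 20x20 joint table, in nats (or ``base``)."""
    pi = joint.sum(axis=1)
    pj = joint.sum(axis=0)
    return _entropy(pi, base) + _entropy(pj, base) - _entropy(joint.ravel(), base)


def mi_matrix(
    aln: MultipleAlignment,
    weights: SequenceWeights | None = None,
    pseudocount: float = 0.05,
    base: float | None = None,
) -> CoevolutionMatrix:
    """Weighted plug-in mutual information for every column pair.

    Counts are cluster weights summed per (aa_i, aa_j) cell over sequences
    ungapped in both columns; ``pseudocount`` is spread uniformly over the
    20x20 joint table (each cell gains ``pseudocount / 400``) before
    normalization, stabilizing sparsely observed pairs. Marginals are the
    joint's row/column sums, so MI is always >= 0 up to rounding. Pairs
    with fewer than 2 effective (weighted) sequences are set to 0 and
    flagged.
    """
    if pseudocount < 0:
        raise InputError("pseudocount must be nonnegative")
    m = aln.matrix
    n_seq, n_col = m.shape
    w = np.ones(n_seq) if weights is None else weights.weights
    if w.shape != (n_seq,):
        raise InputError("weights not aligned to alignment rows")
    raw = np.zeros((n_col, n_col))
    flagged = np.zeros((n_col, n_col), dtype=bool)
    ungapped = m != GAP
    cell_pc = pseudocount / (N_AA * N_AA)
    for i in range(n_col):
        for j in range(i + 1, n_col):
            both = ungapped[:, i] & ungapped[:, j]
            wv = w[both]
            n_eff = wv.sum()
            if n_eff < 2:
                flagged[i, j] = flagged[j, i] = True
                continue
            codes = m[both, i].astype(np.int64) * N_AA + m[both, j]
            joint = np.bincount(codes, weights=wv, minlength=N_AA * N_AA)
            joint = joint.reshape(N_AA, N_AA) + cell_pc
            joint /= joint.sum()
            mi = max(_pair_mi(joint, base), 0.0)
            raw[i, j] = raw[j, i] = mi
    return CoevolutionMatrix(raw_mi=raw, column_index=aln.column_index, flagged=flagged)


def apc_correct(coevo: CoevolutionMatrix) -> CoevolutionMatrix:
    """Average product correction: apc(i,j) = mi(i,j) - mean_i * mean_j / mean.

    Row means and the overall mean exclude the diagonal. With an all-zero
    matrix the correction is zero. For a 2-column alignment APC exactly
    cancels the single off-diagonal value.
    """
    mi = coevo.raw_mi
    n = mi.shape[0]
    if n < 2:
        coevo.apc_mi = np.zeros_like(mi)
        return coevo
    row_mean = (mi.sum(axis=1) - np.diag(mi)) / (n - 1)
    total = row_mean.mean()
    if total == 0:
        apc = mi.copy()
    else:
        # dividing first keeps apc exactly 0 when row means equal the
        # overall mean (e.g. any 2-column alignment)
        apc = mi - np.outer(row_mean / total, row_mean)
    np.fill_diagonal(apc, 0.0)
    coevo.apc_mi = apc
    return coevo


def zscore_mi(
    aln: MultipleAlignment,
    weights: SequenceWeights | None = None,
    n_shuffles: int = 100,
    seed: int | np.random.Generator = 0,
    pseudocount: float = 0.05,
    base: float | None = None,
) -> CoevolutionMatrix:
    """APC-corrected MI standardized against a within-column shuffle null.

    Each of ``n_shuffles`` replicates permutes every column independently
    among the sequences (column compositions, and hence conservation, are
    preserved while inter-column dependence is destroyed), recomputes the
    weighted MI matrix and its APC correction, and the observed APC value
    is standardized by the per-pair null mean and standard deviation.
    Pairs whose null spread is 0 get z = 0 and are flagged. Deterministic
    for a fixed seed.
    """
    if n_shuffles < 10:
        raise InputError("n_shuffles must be >= 10")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coevo = apc_correct(mi_matrix(aln, weights, pseudocount, base))
    obs = coevo.apc_mi
    n_seq, n_col = aln.matrix.shape
    acc = np.zeros_like(obs)
    acc2 = np.zeros_like(obs)
    shuffled = MultipleAlignment(
        sequence_ids=list(aln.sequence_ids),
        matrix=aln.matrix.copy(),
        column_index=aln.column_index,
        reference_id=None,
    )
    for _ in range(n_shuffles):
        for c in range(n_col):
            shuffled.matrix[:, c] = aln.matrix[rng.permutation(n_seq), c]
        null = apc_correct(mi_matrix(shuffled, weights, pseudocount, base)).apc_mi
        acc += null
        acc2 += null * null
    mean = acc / n_shuffles
    var = np.maximum(acc2 / n_shuffles - mean * mean, 0.0)
    sd = np.sqrt(var)
    z = np.zeros_like(obs)
    ok = sd > 0
    z[ok] = (obs[ok] - mean[ok]) / sd[ok]
    coevo.flagged = coevo.flagged | (~ok & ~np.eye(n_col, dtype=bool))
    np.fill_diagonal(z, 0.0)
    coevo.z_mi = z
    return coevo


def kl_conservation(
    aln: MultipleAlignment,
    weights: SequenceWeights | None = None,
    background: BackgroundFrequencies | None = None,
) -> ConservationProfile:
    """Per-column KL divergence of observed residue frequencies from the
    background: sum_a P(a) ln(P(a)/Q(a)) over residues with P(a) > 0.

    P comes from cluster-weighted non-gap counts. Columns with no
    ungapped residue are scored 0 and flagged.
    """
    if background is None:
        background = load_background()
    m = aln.matrix
    n_seq, n_col = m.shape
    w = np.ones(n_seq) if weights is None else weights.weights
    scores = np.zeros(n_col)
    flagged = np.zeros(n_col, dtype=bool)
    for c in range(n_col):
        ok = m[:, c] != GAP
        if not ok.any():
            flagged[c] = True
            continue
        counts = np.bincount(m[ok, c], weights=w[ok], minlength=N_AA)[:N_AA]
        p = counts / counts.sum()
        nz = p > 0
        scores[c] = float((p[nz] * np.log(p[nz] / background.q[nz])).sum())
    return ConservationProfile(scores=scores, column_index=aln.column_index, flagged=flagged)


def cmi_profile(
    coevo: CoevolutionMatrix,
    t: float = CMI_THRESHOLD,
    matrix: str = "z",
) -> CMIProfile:
    """Cumulative MI per column: sum of partner values strictly above ``t``.

    Applied to the Z-scored matrix by default (``matrix`` may also be
    ``"apc"`` or ``"raw"``), since the threshold is calibrated on
    standardized scores.
    """
    source = {"z": coevo.z_mi, "apc": coevo.apc_mi, "raw": coevo.raw_mi}[matrix]
    if source is None:
        raise InputError(f"{matrix} matrix not computed yet")
    vals = np.where(source > t, source, 0.0).copy()
    np.fill_diagonal(vals, 0.0)
    return CMIProfile(cmi=vals.sum(axis=1), column_index=coevo.column_index, threshold=t)
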