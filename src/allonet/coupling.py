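"""Fusing coevolution with ensemble dynamics.

Three stages live here:

* the proximity MI profile (pMI): per frame, the mean cMI of a residue's
  heavy-atom neighbors within 5 Å, averaged over the ensemble — a
  structural-proximity coevolution score;
* composite per-residue time series: superposed Cα position (3 channels)
  plus the per-frame pMI (1 channel), each channel standardized;
* the generalized correlation coefficient r_MI between two residues'
  composite series, and the network edge length w = -ln r_MI.

r_MI = sqrt(1 - exp(-2 I / d)) maps the mutual information I between two
d-dimensional signals onto a [0, 1] correlation-like scale; for
1-dimensional Gaussian signals it equals |ρ| exactly. The default I
estimator is the Gaussian (log-determinant) form — deterministic and
exact in the Gaussian regime; a k-nearest-neighbor estimator is
available for non-Gaussian signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

from .ensemble import ConformationalEnsemble, superpose
from .errors import InputError

PMI_DISTANCE_THRESHOLD = 5.0
_R_CLIP = 1.0 - 1e-12


@dataclass
class PMIProfile:
    """Ensemble pMI: per-frame series and the over-frames mean per residue."""

    mean: np.ndarray               # (n_residues,)
    per_frame: np.ndarray          # (n_frames, n_residues)
    residue_numbers: list[int]
    threshold: float
    aggregate: str


def pmi_profile(
    ensemble: ConformationalEnsemble,
    cmi_by_residue: np.ndarray,
    threshold: float = PMI_DISTANCE_THRESHOLD,
    aggregate: str = "mean",
) -> PMIProfile:
    """Proximity MI of every residue, averaged over the ensemble.

    In each frame, pMI_i aggregates the cMI of residues j ≠ i whose
    minimum heavy-atom distance to i is within ``threshold`` (5 Å by
    default); a residue with no neighbor in a frame scores 0 there.
    ``aggregate`` selects the neighborhood mean (default) or sum.
    """
    if aggregate not in ("mean", "sum"):
        raise InputError("aggregate must be 'mean' or 'sum'")
    cmi = np.asarray(cmi_by_residue, dtype=float)
    s = ensemble.structure
    if cmi.shape != (s.n_residues,):
        raise InputError("cmi_by_residue must have one value per residue")
    if not np.any(np.isfinite(cmi)):
        raise InputError("no mapped cMI values available")
    n_frames = ensemble.frame_count
    out = np.zeros((n_frames, s.n_residues))
    res_of_atom = s.atom_residue_index
    for f in range(n_frames):
        tree = cKDTree(ensemble.frames[f])
        pairs = tree.query_pairs(threshold, output_type="ndarray")
        if pairs.size == 0:
            continue
        ri = res_of_atom[pairs[:, 0]]
        rj = res_of_atom[pairs[:, 1]]
        mask = ri != rj
        lo, hi = ri[mask], rj[mask]
        codes = np.unique(
            np.minimum(lo, hi) * s.n_residues + np.maximum(lo, hi)
        )
        a, b = codes // s.n_residues, codes % s.n_residues
        sums = np.zeros(s.n_residues)
        counts = np.zeros(s.n_residues)
        np.add.at(sums, a, cmi[b])
        np.add.at(sums, b, cmi[a])
        np.add.at(counts, a, 1)
        np.add.at(counts, b, 1)
        if aggregate == "mean":
            nz = counts > 0
            out[f, nz] = sums[nz] / counts[nz]
        else:
            out[f] = sums
    return PMIProfile(
        mean=out.mean(axis=0),
        per_frame=out,
        residue_numbers=s.residue_numbers,
        threshold=threshold,
        aggregate=aggregate,
    )


@dataclass
class CompositeSeries:
    """Standardized per-residue channel series over frames.

    ``data`` is (n_residues, 4, n_frames): superposed Cα x/y/z plus
    per-frame pMI. ``active`` marks channels with nonzero variance;
    constant channels are zeroed and excluded from correlation
    estimation.
    """

    data: np.ndarray
    active: np.ndarray             # (n_residues, 4) bool
    residue_numbers: list[int]


def composite_series(
    ensemble: ConformationalEnsemble,
    pmi: PMIProfile,
    superposed: bool = False,
) -> CompositeSeries:
    ens = ensemble if superposed else superpose(ensemble)
    s = ens.structure
    n_frames = ens.frame_count
    if pmi.per_frame.shape != (n_frames, s.n_residues):
        raise InputError("pMI series not congruent with the ensemble")
    data = np.zeros((s.n_residues, 4, n_frames))
    ok = s.ca_indices >= 0
    data[ok, :3, :] = np.transpose(ens.frames[:, s.ca_indices[ok], :], (1, 2, 0))
    data[:, 3, :] = pmi.per_frame.T
    mean = data.mean(axis=2, keepdims=True)
    sd = data.std(axis=2, keepdims=True)
    active = sd[:, :, 0] > 1e-12
    data = np.where(sd > 1e-12, (data - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return CompositeSeries(data=data, active=active, residue_numbers=s.residue_numbers)


def _gaussian_mi(x: np.ndarray, y: np.ndarray, ridge: float = 1e-8) -> float:
    """MI (nats) of jointly Gaussian signals from covariance log-determinants."""
    n = x.shape[1]
    joint = np.vstack([x, y])
    cov = joint @ joint.T / n
    dx = x.shape[0]
    sx, sy, sj = (cov[:dx, :dx], cov[dx:, dx:], cov)
    def _slogdet(m: np.ndarray) -> float:
        sign, ld = np.linalg.slogdet(m)
        if sign <= 0:
            sign, ld = np.linalg.slogdet(m + ridge * np.eye(m.shape[0]))
        return ld
    return max(0.5 * (_slogdet(sx) + _slogdet(sy) - _slogdet(sj)), 0.0)


def _knn_mi(x: np.ndarray, y: np.ndarray, k: int = 4) -> float:
    """Kraskov–Stögbauer–Grassberger (type 1) MI estimate, nats."""
    n = x.shape[1]
    xt, yt = x.T, y.T
    joint = np.hstack([xt, yt])
    tree = cKDTree(joint)
    eps = tree.query(joint, k=k + 1, p=np.inf)[0][:, -1]
    tx, ty = cKDTree(xt), cKDTree(yt)
    nx = np.array([len(tx.query_ball_point(xt[i], eps[i] - 1e-12, p=np.inf)) - 1 for i in range(n)])
    ny = np.array([len(ty.query_ball_point(yt[i], eps[i] - 1e-12, p=np.inf)) - 1 for i in range(n)])
    return max(
        digamma(k) + digamma(n) - float(np.mean(digamma(nx + 1) + digamma(ny + 1))), 0.0
    )


def mi_to_r(mi: float, d: float) -> float:
    """Map mutual information to the generalized correlation scale [0, 1]."""
    return float(np.clip(np.sqrt(1.0 - np.exp(-2.0 * mi / d)), 0.0, _R_CLIP))


def generalized_correlation(
    series_i: np.ndarray,
    series_j: np.ndarray,
    estimator: str = "gaussian",
) -> float:
    """Generalized correlation r_MI between two multichannel series.

    Inputs are (d, n_frames) arrays; channels are standardized and
    constant channels dropped. The information dimension d in the
    exponential map is the mean active channel count of the two residues.
    """
    xi = _standardize(np.atleast_2d(np.asarray(series_i, dtype=float)))
    xj = _standardize(np.atleast_2d(np.asarray(series_j, dtype=float)))
    if xi.shape[1] != xj.shape[1]:
        raise InputError("series must share the frame axis")
    if xi.shape[1] < 50:
        raise InputError("need at least 50 frames for a stable r_MI estimate")
    if xi.shape[0] == 0 or xj.shape[0] == 0:
        return 0.0
    if estimator == "gaussian":
        mi = _gaussian_mi(xi, xj)
    elif estimator == "knn":
        mi = _knn_mi(xi, xj)
    else:
        raise InputError(f"unknown estimator {estimator!r}")
    d = 0.5 * (xi.shape[0] + xj.shape[0])
    return mi_to_r(mi, d)


def _standardize(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 1e-12
    return (x[keep] - mean[keep]) / sd[keep]


@dataclass
class CouplingMatrix:
    """r_MI in [0, 1] and edge lengths w = -ln r_MI per residue pair.

    ``w`` is +inf where r_MI = 0 (edge unusable; such edges are excluded
    from path searches rather than capped). ``flagged`` marks pairs where
    a constant channel was dropped or a covariance needed ridging.
    """

    r_mi: np.ndarray
    w: np.ndarray
    residue_numbers: list[int]
    flagged: np.ndarray

    @property
    def n_residues(self) -> int:
        return self.r_mi.shape[0]


def coupling_matrix(
    ensemble: ConformationalEnsemble,
    pmi: PMIProfile,
    estimator: str = "gaussian",
    superposed: bool = False,
) -> CouplingMatrix:
    """Full symmetric r_MI / w matrices over all residue pairs."""
    series = composite_series(ensemble, pmi, superposed=superposed)
    n = series.data.shape[0]
    n_frames = series.data.shape[2]
    if n_frames < 50:
        raise InputError("need at least 50 frames for a stable r_MI estimate")
    r = np.zeros((n, n))
    flagged = np.zeros((n, n), dtype=bool)
    if estimator == "gaussian":
        # One flattened covariance of all active channels, then per-pair
        # log-determinants of small sub-blocks.
        act = series.active
        idx_of = []
        flat = []
        for i in range(n):
            idx_of.append(np.arange(len(flat), len(flat) + act[i].sum()))
            flat.extend(series.data[i][act[i]])
        x = np.asarray(flat)
        cov = x @ x.T / n_frames
        for i in range(n):
            ii = idx_of[i]
            di = len(ii)
            if di == 0:
                flagged[i, :] = flagged[:, i] = True
                continue
            si = cov[np.ix_(ii, ii)]
            _, ld_i = np.linalg.slogdet(si)
            for j in range(i + 1, n):
                jj = idx_of[j]
                dj = len(jj)
                if dj == 0:
                    continue
                sj = cov[np.ix_(jj, jj)]
                _, ld_j = np.linalg.slogdet(sj)
                kk = np.concatenate([ii, jj])
                sjoint = cov[np.ix_(kk, kk)]
                sign, ld = np.linalg.slogdet(sjoint)
                if sign <= 0:
                    sjoint = sjoint + 1e-8 * np.eye(len(kk))
                    _, ld = np.linalg.slogdet(sjoint)
                    flagged[i, j] = flagged[j, i] = True
                mi = max(0.5 * (ld_i + ld_j - ld), 0.0)
                if di < 4 or dj < 4:
                    flagged[i, j] = flagged[j, i] = True
                r[i, j] = r[j, i] = mi_to_r(mi, 0.5 * (di + dj))
    else:
        for i in range(n):
            xi = series.data[i][series.active[i]]
            for j in range(i + 1, n):
                xj = series.data[j][series.active[j]]
                if xi.shape[0] == 0 or xj.shape[0] == 0:
                    flagged[i, j] = flagged[j, i] = True
                    continue
                r[i, j] = r[j, i] = generalized_correlation(xi, xj, estimator=estimator)
    with np.errstate(divide="ignore"):
        w = np.where(r > 0, -np.log(np.minimum(r, _R_CLIP)), np.inf)
    np.fill_diagonal(w, 0.0)
    return CouplingMatrix(
        r_mi=r, w=w, residue_numbers=ensemble.structure.residue_numbers, flagged=flagged
    )
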