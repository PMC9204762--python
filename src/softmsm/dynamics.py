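"""Local-dynamics metrics: dihedral entropies and circular autocorrelation.

Ramachandran entropy summarizes per-residue backbone flexibility as the
information entropy (in nats) of the weighted 2D histogram of (phi, psi)
over [-pi, pi)^2. State entropy measures how decisively frames are
assigned to metastable states. The chi1 circular autocorrelation at a
fixed lag probes side-chain rotamer dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import FeatureSeries, StateAssignment, lagged_pairs
from .observables import FrameWeights

logger = logging.getLogger(__name__)

__all__ = [
    "EntropyProfile",
    "ramachandran_entropy",
    "state_entropy",
    "circular_autocorrelation",
]


@dataclass
class EntropyProfile:
    """Per-residue dihedral entropies (nats) and their sum."""

    residues: list
    per_residue: np.ndarray
    n_bins_per_axis: int
    provenance: str = ""

    def __post_init__(self) -> None:
        if np.any(self.per_residue < -1e-12):
            raise ValueError("entropy cannot be negative")

    @property
    def total(self) -> float:
        return float(self.per_residue.sum())


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _get_weights(weights, n: int) -> np.ndarray:
    if weights is None:
        return np.full(n, 1.0 / n)
    w = weights.w if isinstance(weights, FrameWeights) else np.asarray(weights, float)
    if len(w) != n:
        raise ValueError("weight length does not match frame count")
    return w


def ramachandran_entropy(
    phi: FeatureSeries,
    psi: FeatureSeries,
    weights=None,
    n_bins: int = 100,
    per_axis: bool = True,
) -> EntropyProfile:
    """Entropy of each residue's weighted (phi, psi) histogram.

    ``n_bins`` counts bins per axis by default (n_bins^2 cells); with
    ``per_axis=False`` it is the total cell count and the grid is
    sqrt(n_bins) x sqrt(n_bins). Residues whose angles are all missing
    are skipped with a log message; frames with a missing angle are
    dropped for that residue and the weights renormalized.
    """
    if phi.n_features != psi.n_features:
        raise ValueError("phi and psi must cover the same residues")
    bins = n_bins if per_axis else max(1, int(round(np.sqrt(n_bins))))
    edges = np.linspace(-np.pi, np.pi, bins + 1)
    xphi, xpsi = phi.stacked, psi.stacked
    w = _get_weights(weights, len(xphi))
    residues, ent = [], []
    for r in range(phi.n_features):
        a, b = xphi[:, r], xpsi[:, r]
        ok = np.isfinite(a) & np.isfinite(b)
        if not ok.any():
            logger.info("residue %s: all angles missing, skipped", phi.labels[r])
            continue
        wr = w[ok]
        wr = wr / wr.sum()
        hist, _, _ = np.histogram2d(a[ok], b[ok], bins=[edges, edges], weights=wr)
        residues.append(phi.labels[r])
        ent.append(_entropy(hist.ravel()))
    return EntropyProfile(residues, np.array(ent), bins)


def state_entropy(assign: StateAssignment | np.ndarray, weights=None) -> float:
    """Weighted mean assignment entropy sum_t w_t H(chi(x_t)) in nats.

    Zero for hard assignments, ln k for uniformly ambiguous ones.
    """
    chi = assign.stacked if isinstance(assign, StateAssignment) else np.asarray(assign)
    w = _get_weights(weights, len(chi))
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(chi > 0, chi * np.log(chi), 0.0).sum(axis=1)
    return float(w @ h)


def circular_autocorrelation(
    theta: FeatureSeries,
    lag_frames: int,
    linear: bool = False,
) -> np.ndarray:
    """Per-column circular autocorrelation at a fixed lag.

    Angles are embedded as unit vectors u = (cos th, sin th) and

        rho(tau) = (<u_t . u_{t+tau}> - |<u>|^2) / (1 - |<u>|^2),

    with pairs taken within trajectories only. A constant series (the
    denominator vanishes) is defined to have rho = 1 and flagged. With
    ``linear=True`` a plain Pearson autocorrelation on the raw angle
    values is returned instead.
    """
    if lag_frames < 1:
        raise ValueError("lag must be >= 1 frame")
    t0, t1 = lagged_pairs(theta.arrays, lag_frames)
    allx = theta.stacked
    out = np.empty(theta.n_features)
    for c in range(theta.n_features):
        a0, a1, aa = t0[:, c], t1[:, c], allx[:, c]
        ok = np.isfinite(a0) & np.isfinite(a1)
        okc = np.isfinite(aa)
        if not ok.any():
            out[c] = np.nan
            continue
        if linear:
            m = aa[okc].mean()
            var = aa[okc].var()
            if var < 1e-15:
                logger.warning("column %s constant; autocorrelation set to 1",
                               theta.labels[c])
                out[c] = 1.0
                continue
            out[c] = float(np.mean((a0[ok] - m) * (a1[ok] - m)) / var)
            continue
        u_mean = np.array([np.cos(aa[okc]).mean(), np.sin(aa[okc]).mean()])
        r2 = float(u_mean @ u_mean)
        num = float(np.mean(np.cos(a0[ok] - a1[ok])))  # <u_t . u_{t+tau}>
        if 1.0 - r2 < 1e-12:
            logger.warning("column %s constant; autocorrelation set to 1",
                           theta.labels[c])
            out[c] = 1.0
        else:
            out[c] = (num - r2) / (1.0 - r2)
    return out
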