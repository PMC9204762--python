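"""Kinetic and thermodynamic observables from (chi, K, pi).

State averages weight frames by their soft state membership; ensemble
averages reweight frames so that the model's equilibrium distribution pi
replaces the empirical state frequencies:

    <A_i> = sum_t chi_i(x_t) A(x_t) / sum_t chi_i(x_t)
    w_t  ∝ sum_i pi_i chi_i(x_t) / N_i,   N_i = sum_t chi_i(x_t)
    <A>  = sum_t w_t A(x_t)

With hard assignments and pi equal to the empirical state frequencies
the weights are exactly uniform, recovering the plain trajectory mean.

Timescales and lifetimes follow the standard lag-time relations
t_i = -tau/ln|lambda_i| (non-unit eigenvalues of K) and
t̄_i = -tau/ln K_ii. Multi-model uncertainty is summarized either by the
95th-percentile interval of the bootstrap distribution of the mean over
models (default) or by its bootstrap standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import KoopmanModel, StateAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "FrameWeights",
    "ModelEnsembleStat",
    "state_average",
    "frame_weights",
    "ensemble_average",
    "relaxation_timescales",
    "state_lifetimes",
    "transition_rates",
    "state_populations",
    "model_ensemble_stats",
]


@dataclass
class FrameWeights:
    """Normalized per-frame weights (stacked over trajectories)."""

    w: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.w < 0):
            raise ValueError("weights must be non-negative")
        if abs(self.w.sum() - 1.0) > 1e-10:
            raise ValueError("weights must sum to 1 within 1e-10")


@dataclass
class ModelEnsembleStat:
    """Mean and uncertainty interval of an observable over trained models."""

    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_models: int

    def __post_init__(self) -> None:
        if np.any(self.lower > self.mean + 1e-12) or np.any(self.upper < self.mean - 1e-12):
            raise ValueError("interval must contain the mean")


def _stacked_chi(assign: StateAssignment | np.ndarray) -> np.ndarray:
    if isinstance(assign, StateAssignment):
        return assign.stacked
    return np.asarray(assign, dtype=float)


def state_average(A: np.ndarray, assign: StateAssignment | np.ndarray,
                  state: int) -> float | np.ndarray:
    """chi-weighted average of a per-frame observable in one state."""
    chi = _stacked_chi(assign)
    A = np.asarray(A, dtype=float)
    if len(A) != len(chi):
        raise ValueError("observable and assignment lengths differ")
    if not np.all(np.isfinite(A)):
        raise ValueError("observable contains non-finite values")
    ci = chi[:, state]
    mass = ci.sum()
    if mass <= 0:
        raise ValueError(f"state {state} has zero probability mass")
    return np.tensordot(ci, A, axes=(0, 0)) / mass


def frame_weights(assign: StateAssignment | np.ndarray, pi: np.ndarray,
                  provenance: str = "") -> FrameWeights:
    """Equilibrium reweighting of frames by the model distribution pi."""
    chi = _stacked_chi(assign)
    pi = np.asarray(pi, dtype=float)
    N = chi.sum(axis=0)
    if np.any(N <= 0):
        bad = np.where(N <= 0)[0].tolist()
        raise ValueError(f"state(s) {bad} have zero total soft mass")
    w = chi @ (pi / N)
    return FrameWeights(w / w.sum(), provenance)


def ensemble_average(A: np.ndarray, weights: FrameWeights | np.ndarray):
    """Weighted ensemble average sum_t w_t A(x_t)."""
    w = weights.w if isinstance(weights, FrameWeights) else np.asarray(weights, float)
    A = np.asarray(A, dtype=float)
    if len(A) != len(w):
        raise ValueError("observable and weight lengths differ")
    return np.tensordot(w, A, axes=(0, 0))


def _nonstationary_eigvals(K: np.ndarray) -> np.ndarray:
    w = np.linalg.eigvals(K)
    drop = int(np.argmin(np.abs(w - 1.0)))
    return np.delete(w, drop)


def relaxation_timescales(model: KoopmanModel, tol: float = 1e-12) -> np.ndarray:
    """Relaxation times -tau/ln|lambda_i| for non-unit eigenvalues (ns).

    Complex eigenvalues contribute through their modulus; a non-stationary
    mode with |lambda| >= 1 is flagged and reported as infinite.
    """
    lam = np.abs(_nonstationary_eigvals(model.K))
    out = np.empty(len(lam))
    for i, l in enumerate(lam):
        if l >= 1.0 - tol:
            logger.warning("non-stationary eigenvalue modulus %.6f; "
                           "timescale reported as infinite", l)
            out[i] = np.inf
        elif l <= 0:
            out[i] = 0.0
        else:
            out[i] = -model.tau_ns / np.log(l)
    return np.sort(out)[::-1]


def state_lifetimes(model: KoopmanModel) -> np.ndarray:
    """Mean state dwell times -tau/ln K_ii in ns."""
    d = np.diag(model.K)
    if np.any(d <= 0):
        raise ValueError("diagonal element <= 0; lifetime undefined")
    out = np.empty(len(d))
    for i, dii in enumerate(d):
        if dii >= 1.0:
            logger.warning("state %d never leaves at this lag; infinite lifetime", i)
            out[i] = np.inf
        else:
            out[i] = -model.tau_ns / np.log(dii)
    return out


def transition_rates(model: KoopmanModel, mfpt: bool = False) -> np.ndarray:
    """Pairwise transition rates in 1/us.

    Default definition: rate_{i->j} = K_ij(tau)/tau for i != j (zero
    diagonal). With ``mfpt=True`` rates are inverse mean first-passage
    times of the embedded jump chain instead.
    """
    k = model.k
    tau_us = model.tau_ns / 1000.0
    if not mfpt:
        R = model.K / tau_us
        np.fill_diagonal(R, 0.0)
        return R
    # MFPT via the fundamental-matrix relation on the discrete chain
    R = np.zeros((k, k))
    for j in range(k):
        idx = [i for i in range(k) if i != j]
        Q = model.K[np.ix_(idx, idx)]
        m = np.linalg.solve(np.eye(k - 1) - Q, np.ones(k - 1))  # in lag steps
        for row, i in enumerate(idx):
            R[i, j] = 1.0 / (m[row] * model.tau_ns / 1000.0)
    np.fill_diagonal(R, 0.0)
    return R


def state_populations(model: KoopmanModel) -> np.ndarray:
    """Equilibrium state populations (the stationary distribution pi)."""
    return model.pi.copy()


def model_ensemble_stats(values, mode: str = "percentile", n_boot: int = 1000,
                         seed: int = 0) -> ModelEnsembleStat:
    """Mean over models with a bootstrap uncertainty of that mean.

    values has shape (n_models, ...). mode="percentile" reports the
    2.5th/97.5th percentiles of the bootstrap distribution of the mean;
    mode="sd" reports mean ± one bootstrap standard deviation.
    """
    vals = np.asarray(values, dtype=float)
    if vals.shape[0] < 2:
        raise ValueError("need at least two models")
    rng = np.random.default_rng(seed)
    n = vals.shape[0]
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = vals[idx].mean(axis=1)
    mean = vals.mean(axis=0)
    if mode == "percentile":
        lower = np.percentile(boot_means, 2.5, axis=0)
        upper = np.percentile(boot_means, 97.5, axis=0)
    elif mode == "sd":
        sd = boot_means.std(axis=0)
        lower, upper = mean - sd, mean + sd
    else:
        raise ValueError("mode must be 'percentile' or 'sd'")
    lower = np.minimum(lower, mean)
    upper = np.maximum(upper, mean)
    return ModelEnsembleStat(mean, lower, upper, n)
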