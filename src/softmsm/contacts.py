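"""Contact probabilities, per-contact lifetimes, and conditional contacts.

Each ligand-residue (or ring-ring) contact is a binary time series. Its
probability is the (optionally frame-weighted) on-fraction; its lifetime
comes from a tiny two-state Markov model counted at a fixed lag, with
the on-state dwell time -tau/ln T_on,on. Contacts with too little data
for a lifetime are flagged rather than smoothed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ContactSeries, lagged_pairs
from .observables import FrameWeights

logger = logging.getLogger(__name__)

__all__ = [
    "ContactKinetics",
    "contact_probability",
    "contact_lifetime",
    "conditional_contact_probability",
]

#: status flags for per-contact lifetime estimates
OK = "ok"
NEVER_ON = "never-on"
NEVER_OFF = "never-off"
BELOW_RESOLUTION = "below-resolution"


@dataclass
class ContactKinetics:
    """Per-contact probabilities and MSM lifetimes at a fixed lag."""

    labels: list
    probability: np.ndarray
    lifetime_ns: np.ndarray
    status: list
    lag_ns: float

    def __post_init__(self) -> None:
        if np.any((self.probability < -1e-12) | (self.probability > 1 + 1e-12)):
            raise ValueError("contact probability must lie in [0, 1]")
        self.probability = np.clip(self.probability, 0.0, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "contact": [str(l) for l in self.labels],
            "probability": self.probability,
            "lifetime_ns": self.lifetime_ns,
            "status": self.status,
        })


def _get_weights(weights, n: int) -> np.ndarray:
    if weights is None:
        return np.full(n, 1.0 / n)
    w = weights.w if isinstance(weights, FrameWeights) else np.asarray(weights, float)
    if len(w) != n:
        raise ValueError("weight length does not match frame count")
    return w / w.sum()


def contact_probability(series: ContactSeries, weights=None) -> np.ndarray:
    """Weighted fraction of frames in which each contact is formed."""
    x = series.stacked
    w = _get_weights(weights, len(x))
    return w @ x


def contact_lifetime(series: ContactSeries, lag_frames: int) -> ContactKinetics:
    """Lifetime of each contact from a per-contact 2x2 MSM at the lag.

    Pairs are counted within trajectories; lifetime = -tau/ln T_on,on.
    Contacts that are never on, never leave the on state, or whose
    on-state survival at the lag is zero (dwell below the lag
    resolution) carry a status flag and a NaN (or inf) lifetime.
    """
    if lag_frames < 1:
        raise ValueError("lag must be >= 1 frame")
    x0, x1 = lagged_pairs([a.astype(float) for a in series.arrays], lag_frames)
    tau_ns = lag_frames * series.frame_interval_ps / 1000.0
    n = series.n_features
    prob = contact_probability(series)
    lifetimes = np.full(n, np.nan)
    status = []
    for c in range(n):
        on0 = x0[:, c] > 0.5
        n_on = int(on0.sum())
        if n_on == 0:
            status.append(NEVER_ON)
            continue
        t_on_on = float(x1[on0, c].mean())
        if t_on_on >= 1.0:
            status.append(NEVER_OFF)
            lifetimes[c] = np.inf
            logger.warning("contact %s never breaks at lag %.3g ns",
                           series.labels[c], tau_ns)
        elif t_on_on <= 0.0:
            status.append(BELOW_RESOLUTION)
            logger.warning("contact %s: on-dwell below the lag resolution",
                           series.labels[c])
        else:
            status.append(OK)
            lifetimes[c] = -tau_ns / np.log(t_on_on)
    return ContactKinetics(list(series.labels), np.asarray(prob, float),
                           lifetimes, status, tau_ns)


def conditional_contact_probability(
    series: ContactSeries,
    condition: int | str,
    target: int | str,
    weights=None,
) -> float:
    """P(target contact | condition contact) under optional frame weights."""
    def _col(key):
        if isinstance(key, str):
            names = [str(l) for l in series.labels]
            if key not in names:
                raise KeyError(f"unknown contact {key!r}")
            return names.index(key)
        return int(key)

    i, j = _col(condition), _col(target)
    x = series.stacked
    w = _get_weights(weights, len(x))
    p_i = float(w @ x[:, i])
    if p_i <= 0:
        raise ValueError(f"conditioning contact {series.labels[i]} never occurs")
    p_ij = float(w @ (x[:, i] & x[:, j]))
    return p_ij / p_i
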