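"""Model validation: implied timescales, Chapman-Kolmogorov, convergence.

A kinetic model estimated at lag tau is trustworthy only if (i) its
implied timescales are flat in tau, (ii) propagating it n times matches
a model estimated directly at n*tau (Chapman-Kolmogorov), and (iii) its
timescales are converged in the amount of data. All three checks operate
on a soft state assignment and re-estimate Koopman models as needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import KoopmanModel, StateAssignment
from .msm import estimate_koopman
from .observables import relaxation_timescales

logger = logging.getLogger(__name__)

__all__ = [
    "CKReport",
    "implied_timescales",
    "chapman_kolmogorov",
    "timescale_convergence",
]


def implied_timescales(
    assign: StateAssignment,
    lag_grid_frames: list[int],
) -> pd.DataFrame:
    """Implied (relaxation) timescales re-estimated at each lag.

    Returns a tidy frame with columns (lag_ns, process, timescale_ns);
    process 1 is the slowest. For data generated by an exact Markov
    chain the curves are flat in the lag up to sampling error.
    """
    rows = []
    for lag in lag_grid_frames:
        model = estimate_koopman(assign, lag)
        ts = relaxation_timescales(model)
        for p, t in enumerate(ts, start=1):
            rows.append({"lag_ns": model.tau_ns, "process": p, "timescale_ns": t})
    return pd.DataFrame(rows)


@dataclass
class CKReport:
    """Chapman-Kolmogorov comparison K(tau)^n vs K(n tau).

    ``band_lower``/``band_upper`` bound the bootstrap (over trajectories)
    confidence band of the directly estimated K(n tau); ``passed`` marks
    the multiples where every predicted entry falls inside its band
    (widened by ``tolerance``).
    """

    tau_ns: float
    multiples: list[int]
    predicted: dict
    estimated: dict
    deviations: dict
    max_deviation: dict
    band_lower: dict
    band_upper: dict
    passed: dict
    tolerance: float

    def all_passed(self, n_max: int | None = None) -> bool:
        ns = [n for n in self.multiples if n_max is None or n <= n_max]
        return all(self.passed[n] for n in ns)


def chapman_kolmogorov(
    assign: StateAssignment,
    lag_frames: int,
    n_max: int = 5,
    n_boot: int = 20,
    tolerance: float = 0.0,
    seed: int = 0,
) -> CKReport:
    """Chapman-Kolmogorov test at integer multiples of the lag.

    For each n in 1..n_max, compares K(tau)^n with a Koopman model
    estimated directly at n*tau. Per-entry deviations are reported along
    with a bootstrap band (resampling trajectories with replacement,
    ``n_boot`` resamples); the pass criterion is that every predicted
    entry lies within its band, optionally widened by ``tolerance``.
    """
    base = estimate_koopman(assign, lag_frames)
    rng = np.random.default_rng(seed)
    n_traj = len(assign.chi)
    report = CKReport(base.tau_ns, list(range(1, n_max + 1)), {}, {}, {}, {},
                      {}, {}, {}, tolerance)
    for n in report.multiples:
        lag_n = n * lag_frames
        try:
            est = estimate_koopman(assign, lag_n)
        except ValueError as exc:
            raise ValueError(
                f"insufficient lagged pairs at multiple n={n} "
                f"(lag {lag_n} frames): {exc}") from exc
        pred = np.linalg.matrix_power(base.K, n)
        boots = []
        for _ in range(n_boot):
            pick = rng.integers(0, n_traj, size=n_traj)
            chi_b = [assign.chi[i] for i in pick]
            try:
                kb = estimate_koopman(
                    StateAssignment(chi_b, assign.frame_interval_ps), lag_n)
                boots.append(kb.K)
            except ValueError:
                continue
        if boots:
            boots = np.array(boots)
            lower = np.percentile(boots, 2.5, axis=0)
            upper = np.percentile(boots, 97.5, axis=0)
        else:  # pragma: no cover - degenerate resampling
            lower = upper = est.K
        dev = np.abs(pred - est.K)
        report.predicted[n] = pred
        report.estimated[n] = est.K
        report.deviations[n] = dev
        report.max_deviation[n] = float(dev.max())
        report.band_lower[n] = lower
        report.band_upper[n] = upper
        report.passed[n] = bool(
            np.all(pred >= lower - tolerance) and np.all(pred <= upper + tolerance))
    return report


def timescale_convergence(
    assign: StateAssignment,
    trajectory_counts: list[int],
    lag_frames: int,
    n_resamples: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Slowest implied timescale vs the number of trajectories used.

    For each count, trajectories are resampled without replacement
    ``n_resamples`` times and the slowest timescale re-estimated; the
    full count uses all data once (no resampling). Returns columns
    (n_trajectories, mean_ns, lower_ns, upper_ns).
    """
    n_traj = len(assign.chi)
    rng = np.random.default_rng(seed)
    rows = []
    for count in trajectory_counts:
        if count < 2:
            raise ValueError("need at least 2 trajectories per subsample")
        if count > n_traj:
            raise ValueError(f"count {count} exceeds available {n_traj} trajectories")
        if count == n_traj:
            t = relaxation_timescales(estimate_koopman(assign, lag_frames))[0]
            rows.append({"n_trajectories": count, "mean_ns": t,
                         "lower_ns": t, "upper_ns": t})
            continue
        vals = []
        for _ in range(n_resamples):
            pick = rng.choice(n_traj, size=count, replace=False)
            sub = StateAssignment([assign.chi[i] for i in pick],
                                  assign.frame_interval_ps)
            try:
                vals.append(relaxation_timescales(
                    estimate_koopman(sub, lag_frames))[0])
            except ValueError:
                continue
        vals = np.array(vals)
        vals = vals[np.isfinite(vals)]
        rows.append({
            "n_trajectories": count,
            "mean_ns": float(vals.mean()),
            "lower_ns": float(np.percentile(vals, 2.5)),
            "upper_ns": float(np.percentile(vals, 97.5)),
        })
    return pd.DataFrame(rows)
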