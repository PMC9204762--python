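"""Shared in-memory containers for multi-trajectory time series.

All containers keep one array per trajectory so that time-lagged frame
pairs never span a trajectory boundary. Angles are stored in radians in
the open interval [-pi, pi); distances in nanometres; frame spacing in
picoseconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryEnsemble",
    "FeatureSeries",
    "ContactSeries",
    "StateAssignment",
    "KoopmanModel",
    "lagged_pairs",
]


@dataclass
class TrajectoryEnsemble:
    """A set of trajectories (mdtraj.Trajectory) sharing one topology.

    Parameters
    ----------
    trajectories : list of mdtraj.Trajectory
        Coordinate trajectories, one per independent run.
    frame_interval_ps : float
        Time between stored frames in picoseconds.
    ligand_resname : str or None
        Residue name selecting the ligand atom group, if present.
    """

    trajectories: list
    frame_interval_ps: float
    ligand_resname: str | None = None

    def __post_init__(self) -> None:
        if self.frame_interval_ps <= 0:
            raise ValueError("frame_interval_ps must be positive")
        if not self.trajectories:
            raise ValueError("ensemble contains no trajectories")

    @property
    def n_trajectories(self) -> int:
        return len(self.trajectories)

    @property
    def topology(self):
        return self.trajectories[0].topology

    def save(self, out_dir: str | Path, prefix: str = "traj") -> None:
        """Write topology as PDB and each trajectory as DCD."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        try:
            self.trajectories[0][0].save_pdb(str(out / "topology.pdb"))
            for i, t in enumerate(self.trajectories):
                t.save_dcd(str(out / f"{prefix}_{i:04d}.dcd"))
        except OSError as exc:  # pragma: no cover - passthrough with context
            raise OSError(f"failed writing trajectories under {out}: {exc}") from exc


class _PerTrajectorySeries:
    """Base for per-trajectory (frames x columns) array stacks."""

    arrays: list[np.ndarray]
    labels: list
    frame_interval_ps: float

    @property
    def n_trajectories(self) -> int:
        return len(self.arrays)

    @property
    def n_features(self) -> int:
        return len(self.labels)

    @property
    def traj_lengths(self) -> np.ndarray:
        return np.array([len(a) for a in self.arrays])

    @property
    def n_frames(self) -> int:
        return int(self.traj_lengths.sum())

    @property
    def stacked(self) -> np.ndarray:
        return np.concatenate(self.arrays, axis=0)

    def _check(self) -> None:
        if self.frame_interval_ps <= 0:
            raise ValueError("frame_interval_ps must be positive")
        for a in self.arrays:
            if a.ndim != 2 or a.shape[1] != len(self.labels):
                raise ValueError(
                    f"array shape {a.shape} inconsistent with {len(self.labels)} labels"
                )


@dataclass
class FeatureSeries(_PerTrajectorySeries):
    """Per-frame feature matrix with ordered labels.

    ``units`` is ``"nm"`` for distances or ``"rad"`` for angles; CSV
    exports convert radians to degrees.
    """

    arrays: list[np.ndarray]
    labels: list
    frame_interval_ps: float
    units: str = "nm"

    def __post_init__(self) -> None:
        self._check()
        if self.units not in ("nm", "rad", "dimensionless"):
            raise ValueError(f"unknown units {self.units!r}")

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        frames = []
        for i, a in enumerate(self.arrays):
            vals = np.degrees(a) if self.units == "rad" else a
            df = pd.DataFrame(vals, columns=[str(l) for l in self.labels])
            df.insert(0, "frame", np.arange(len(a)))
            df.insert(0, "trajectory_id", i)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        meta = {
            "labels": [list(l) if isinstance(l, tuple) else l for l in self.labels],
            "units": "deg" if self.units == "rad" else self.units,
            "frame_interval_ps": self.frame_interval_ps,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureSeries":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cols = [c for c in df.columns if c not in ("trajectory_id", "frame")]
        arrays = []
        for _, grp in df.groupby("trajectory_id", sort=True):
            a = grp.sort_values("frame")[cols].to_numpy(float)
            arrays.append(a)
        units = meta.get("units", "nm")
        if units == "deg":
            arrays = [np.radians(a) for a in arrays]
            units = "rad"
        labels = [tuple(l) if isinstance(l, list) else l for l in meta["labels"]]
        return cls(arrays, labels, float(meta["frame_interval_ps"]), units)

    def select(self, columns: Sequence[int]) -> "FeatureSeries":
        cols = list(columns)
        return FeatureSeries(
            [a[:, cols] for a in self.arrays],
            [self.labels[c] for c in cols],
            self.frame_interval_ps,
            self.units,
        )


# A DistanceSeries is a FeatureSeries in nm with one column per entity.
DistanceSeries = FeatureSeries


@dataclass
class ContactSeries(_PerTrajectorySeries):
    """Boolean on/off series, one column per labelled contact."""

    arrays: list[np.ndarray]
    labels: list
    frame_interval_ps: float
    cutoff_nm: float | None = None

    def __post_init__(self) -> None:
        self.arrays = [np.asarray(a, dtype=bool) for a in self.arrays]
        self._check()
        if len(set(map(str, self.labels))) != len(self.labels):
            raise ValueError("contact labels must be unique")

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        frames = []
        for i, a in enumerate(self.arrays):
            df = pd.DataFrame(a.astype(int), columns=[str(l) for l in self.labels])
            df.insert(0, "frame", np.arange(len(a)))
            df.insert(0, "trajectory_id", i)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        meta = {
            "labels": [str(l) for l in self.labels],
            "cutoff_nm": self.cutoff_nm,
            "frame_interval_ps": self.frame_interval_ps,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ContactSeries":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cols = [c for c in df.columns if c not in ("trajectory_id", "frame")]
        arrays = [
            grp.sort_values("frame")[cols].to_numpy() > 0
            for _, grp in df.groupby("trajectory_id", sort=True)
        ]
        return cls(arrays, meta["labels"], float(meta["frame_interval_ps"]),
                   meta.get("cutoff_nm"))


@dataclass
class StateAssignment:
    """Soft per-frame state probabilities chi(x_t) over k states.

    Each row of every per-trajectory array is a probability vector; rows
    must sum to 1 within 1e-6.
    """

    chi: list[np.ndarray]
    frame_interval_ps: float

    def __post_init__(self) -> None:
        if self.frame_interval_ps <= 0:
            raise ValueError("frame_interval_ps must be positive")
        k = self.chi[0].shape[1]
        for a in self.chi:
            if a.shape[1] != k:
                raise ValueError("inconsistent state count across trajectories")
            if np.any(a < -1e-12):
                raise ValueError("state probabilities must be non-negative")
            if not np.allclose(a.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError("state probability rows must sum to 1 within 1e-6")

    @property
    def k(self) -> int:
        return self.chi[0].shape[1]

    @property
    def n_frames(self) -> int:
        return int(sum(len(a) for a in self.chi))

    @property
    def stacked(self) -> np.ndarray:
        return np.concatenate(self.chi, axis=0)

    def permute(self, perm: Sequence[int]) -> "StateAssignment":
        """Relabel states so that new state i is old state perm[i]."""
        p = list(perm)
        return StateAssignment([a[:, p] for a in self.chi], self.frame_interval_ps)

    @classmethod
    def from_labels(cls, labels: list[np.ndarray], k: int,
                    frame_interval_ps: float) -> "StateAssignment":
        """Hard (0/1) assignment from integer state paths."""
        chi = [np.eye(k)[np.asarray(l, dtype=int)] for l in labels]
        return cls(chi, frame_interval_ps)


@dataclass
class KoopmanModel:
    """Row-stochastic transition operator K(tau) with stationary pi.

    ``lag_frames`` times ``frame_interval_ps`` gives the lag time tau.
    """

    K: np.ndarray
    pi: np.ndarray
    lag_frames: int
    frame_interval_ps: float

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        k = self.K.shape[0]
        if self.K.shape != (k, k) or self.pi.shape != (k,):
            raise ValueError("K must be square and pi of matching length")
        if np.any(self.K < -1e-12):
            raise ValueError("K entries must be non-negative")
        if not np.allclose(self.K.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("K rows must sum to 1 within 1e-8")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must sum to 1")
        if not np.allclose(self.pi @ self.K, self.pi, atol=1e-6):
            raise ValueError("pi is not stationary under K within 1e-6")

    @property
    def k(self) -> int:
        return self.K.shape[0]

    @property
    def tau_ns(self) -> float:
        return self.lag_frames * self.frame_interval_ps / 1000.0

    def permute(self, perm: Sequence[int]) -> "KoopmanModel":
        p = np.asarray(perm, dtype=int)
        return KoopmanModel(self.K[np.ix_(p, p)], self.pi[p],
                            self.lag_frames, self.frame_interval_ps)


def lagged_pairs(arrays: list[np.ndarray], lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack (x_t, x_{t+lag}) pairs taken within each trajectory only.

    Returns two aligned arrays; raises if no trajectory is longer than
    the lag.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    x0, xt = [], []
    for a in arrays:
        if len(a) > lag:
            x0.append(a[:-lag])
            xt.append(a[lag:])
    if not x0:
        raise ValueError(f"no trajectory longer than lag {lag}; no lagged pairs exist")
    return np.concatenate(x0, axis=0), np.concatenate(xt, axis=0)
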