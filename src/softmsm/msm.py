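"""Soft state assignment and Koopman-model estimation.

The state-assignment function chi maps per-frame features onto the
probability simplex over k metastable states. It is a small
self-normalizing feed-forward network (SELU activations, LeCun-normal
initialization, softmax output) trained by stochastic gradient ascent on
the VAMP-2 score of time-lagged frame pairs; gradients of the score with
respect to the network outputs are computed in closed form, so no
autodiff framework is needed.

Given chi, the Koopman operator is estimated from soft transition counts

    C_ij = sum_t chi_i(x_t) chi_j(x_{t+tau}),    K = diag(C 1)^(-1) C,

with the equilibrium distribution pi taken as the leading left
eigenvector of K. With hard (0/1) assignments this reduces exactly to
the classical count-based Markov state model.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg

from .containers import (DistanceSeries, FeatureSeries, KoopmanModel,
                         StateAssignment, lagged_pairs)

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "TrainingConfig",
    "PRESETS",
    "SoftmaxNet",
    "TrainedModel",
    "make_splits",
    "filter_bound_frames",
    "train_assignment_model",
    "estimate_koopman",
    "vamp2_score",
    "vamp2_from_chi",
    "align_states_across_models",
    "state_averaged_map",
]

_SELU_LAMBDA = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


# ---------------------------------------------------------------------------
# Splits and frame filtering
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Frame-level test hold-out plus repeated train/validation splits."""

    test_idx: np.ndarray
    splits: list[tuple[np.ndarray, np.ndarray]]
    seed: int

    @property
    def n_splits(self) -> int:
        return len(self.splits)


def make_splits(n_frames: int, test_fraction: float = 0.1, n_splits: int = 20,
                val_fraction: float = 0.1, seed: int = 0) -> SplitPlan:
    """Hold out a test fraction, then make repeated 9:1 train/val splits.

    All splits partition the frames: test is disjoint from every
    train/validation pair, and each pair partitions the remainder.
    """
    if n_frames < 20:
        raise ValueError(f"need at least 20 frames, got {n_frames}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_frames)
    n_test = int(round(test_fraction * n_frames))
    test = np.sort(perm[:n_test])
    rest = perm[n_test:]
    n_val = int(round(val_fraction * len(rest)))
    splits = []
    for _ in range(n_splits):
        p = rng.permutation(rest)
        splits.append((np.sort(p[n_val:]), np.sort(p[:n_val])))
    return SplitPlan(test, splits, seed)


def filter_bound_frames(distances: DistanceSeries, cutoff: float = 0.5) -> list[np.ndarray]:
    """Mask of frames where the ligand is within cutoff of any residue.

    Returns one boolean array per trajectory; True marks bound frames
    (minimum ligand-residue distance <= cutoff in nm).
    """
    return [a.min(axis=1) <= cutoff for a in distances.arrays]


# ---------------------------------------------------------------------------
# VAMP-2 score
# ---------------------------------------------------------------------------

def _vamp2_matrices(chi0: np.ndarray, chit: np.ndarray, ridge: float):
    n = len(chi0)
    k = chi0.shape[1]
    c00 = chi0.T @ chi0 / n + ridge * np.eye(k)
    ctt = chit.T @ chit / n + ridge * np.eye(k)
    c0t = chi0.T @ chit / n
    return c00, c0t, ctt


def vamp2_from_chi(chi0: np.ndarray, chit: np.ndarray, ridge: float = 1e-10) -> float:
    """VAMP-2 score of paired (t, t+tau) assignment matrices.

    Sum of squared singular values of C00^{-1/2} C0t Ctt^{-1/2}; lies in
    [1, k] for probability-simplex features. Near-singular correlation
    matrices are regularized by a small ridge (logged).
    """
    c00, c0t, ctt = _vamp2_matrices(chi0, chit, ridge)
    try:
        a = scipy.linalg.solve(c00, c0t, assume_a="pos")
        b = scipy.linalg.solve(ctt, c0t.T, assume_a="pos")
    except scipy.linalg.LinAlgError:
        logger.warning("rank-deficient correlation matrix; ridge raised to 1e-6")
        c00, c0t, ctt = _vamp2_matrices(chi0, chit, 1e-6)
        a = scipy.linalg.solve(c00, c0t, assume_a="pos")
        b = scipy.linalg.solve(ctt, c0t.T, assume_a="pos")
    return float(np.trace(a @ b))


def vamp2_score(assign: StateAssignment, lag_frames: int, ridge: float = 1e-10) -> float:
    """VAMP-2 score of a state assignment at the given lag."""
    chi0, chit = lagged_pairs(assign.chi, lag_frames)
    return vamp2_from_chi(chi0, chit, ridge)


def _vamp2_grad(chi0: np.ndarray, chit: np.ndarray, ridge: float):
    """Score and its gradients with respect to chi0 and chit."""
    n = len(chi0)
    c00, c0t, ctt = _vamp2_matrices(chi0, chit, ridge)
    a = np.linalg.inv(c00)
    b = np.linalg.inv(ctt)
    score = float(np.trace(a @ c0t @ b @ c0t.T))
    g_c0t = 2.0 * a @ c0t @ b
    m = c0t @ b @ c0t.T
    g_c00 = -a @ m @ a
    g_ctt = -b @ c0t.T @ a @ c0t @ b
    d_chi0 = (2.0 * chi0 @ g_c00 + chit @ g_c0t.T) / n
    d_chit = (2.0 * chit @ g_ctt + chi0 @ g_c0t) / n
    return score, d_chi0, d_chit


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

def _selu(x: np.ndarray) -> np.ndarray:
    return _SELU_LAMBDA * np.where(x > 0, x, _SELU_ALPHA * (np.exp(x) - 1.0))


def _selu_grad(x: np.ndarray) -> np.ndarray:
    return _SELU_LAMBDA * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(x))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SoftmaxNet:
    """Feed-forward SELU network with a softmax output over k states."""

    def __init__(self, n_in: int, k: int, width: int, depth: int,
                 rng: np.random.Generator):
        dims = [n_in] + [width] * depth + [k]
        self.W = [rng.normal(0.0, 1.0 / np.sqrt(dims[i]), (dims[i], dims[i + 1]))
                  for i in range(len(dims) - 1)]
        self.b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        self.mean = np.zeros(n_in)
        self.std = np.ones(n_in)

    def set_standardization(self, x: np.ndarray) -> None:
        self.mean = x.mean(axis=0)
        self.std = x.std(axis=0)
        self.std[self.std < 1e-12] = 1.0

    def forward(self, x: np.ndarray, dropout: float = 0.0,
                rng: np.random.Generator | None = None):
        h = (x - self.mean) / self.std
        cache = [("input", h, None)]
        n_layers = len(self.W)
        for i in range(n_layers):
            z = h @ self.W[i] + self.b[i]
            if i < n_layers - 1:
                h = _selu(z)
                mask = None
                if dropout > 0.0 and rng is not None:
                    mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
                    h = h * mask
                cache.append(("hidden", z, mask))
            else:
                h = _softmax(z)
                cache.append(("output", z, None))
        return h, cache

    def predict(self, x: np.ndarray) -> np.ndarray:
        chi, _ = self.forward(x)
        return chi

    def backward(self, cache, chi: np.ndarray, d_chi: np.ndarray):
        """Gradients of a scalar loss given d(loss)/d(chi)."""
        s = (d_chi * chi).sum(axis=1, keepdims=True)
        delta = chi * (d_chi - s)  # softmax backprop
        gW = [None] * len(self.W)
        gb = [None] * len(self.W)
        for i in range(len(self.W) - 1, -1, -1):
            kind, z, mask = cache[i]
            h_in = z if kind == "input" else _selu(z)
            if kind == "hidden" and mask is not None:
                h_in = h_in * mask
            gW[i] = h_in.T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.W[i].T
                kind_prev, z_prev, mask_prev = cache[i]
                if kind_prev == "hidden":
                    if mask_prev is not None:
                        delta = delta * mask_prev
                    delta = delta * _selu_grad(z_prev)
        return gW, gb

    def save(self, path) -> None:
        np.savez(path, n_layers=len(self.W), mean=self.mean, std=self.std,
                 **{f"W{i}": w for i, w in enumerate(self.W)},
                 **{f"b{i}": b for i, b in enumerate(self.b)})

    @classmethod
    def load(cls, path) -> "SoftmaxNet":
        data = np.load(path)
        net = cls.__new__(cls)
        n = int(data["n_layers"])
        net.W = [data[f"W{i}"] for i in range(n)]
        net.b = [data[f"b{i}"] for i in range(n)]
        net.mean = data["mean"]
        net.std = data["std"]
        return net

    def params(self):
        return self.W + self.b

    def clone_weights(self):
        return [w.copy() for w in self.W], [b.copy() for b in self.b]

    def load_weights(self, weights):
        W, b = weights
        self.W = [w.copy() for w in W]
        self.b = [x.copy() for x in b]


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    """Hyperparameters of the assignment-network trainer.

    The ``paper`` preset mirrors the published protocol (512-wide,
    2-layer network, L2 1e-7, dropout 0.05, Adam with learning rate
    0.05, beta2 0.99, epsilon 1e-4, batches of 10,000 frame pairs, early
    stopping on a minimum validation-score improvement of 1e-3 over the
    last five epochs). The ``desk`` preset is a smaller network for
    laptop-scale ensembles.
    """

    width: int = 64
    depth: int = 2
    learning_rate: float = 0.02
    beta1: float = 0.9
    beta2: float = 0.99
    eps: float = 1e-4
    l2: float = 0.0
    dropout: float = 0.0
    batch_pairs: int = 2000
    max_epochs: int = 60
    patience: int = 5
    min_improvement: float = 1e-3
    n_trials: int = 3
    ridge: float = 1e-8


PRESETS = {
    "desk": TrainingConfig(),
    "paper": TrainingConfig(width=512, depth=2, learning_rate=0.05, beta2=0.99,
                            eps=1e-4, l2=1e-7, dropout=0.05, batch_pairs=10_000,
                            max_epochs=200),
}


@dataclass
class TrainedModel:
    """A trained assignment function with its Koopman model and metadata."""

    net: SoftmaxNet
    assignment: StateAssignment
    koopman: KoopmanModel
    metadata: dict = field(default_factory=dict)

    def permute(self, perm) -> "TrainedModel":
        return TrainedModel(self.net, self.assignment.permute(perm),
                            self.koopman.permute(perm), dict(self.metadata))


def _pair_indices(traj_lengths: np.ndarray, lag: int):
    """Global frame indices (t, t+lag) of all within-trajectory pairs."""
    starts = np.concatenate([[0], np.cumsum(traj_lengths)[:-1]])
    t0, t1 = [], []
    for s, n in zip(starts, traj_lengths):
        if n > lag:
            idx = np.arange(s, s + n - lag)
            t0.append(idx)
            t1.append(idx + lag)
    if not t0:
        raise ValueError(f"no trajectory longer than lag {lag}")
    return np.concatenate(t0), np.concatenate(t1)


def _adam_step(params, grads, m, v, t, cfg: TrainingConfig):
    for p, g, mi, vi in zip(params, grads, m, v):
        mi *= cfg.beta1
        mi += (1 - cfg.beta1) * g
        vi *= cfg.beta2
        vi += (1 - cfg.beta2) * g * g
        mhat = mi / (1 - cfg.beta1 ** t)
        vhat = vi / (1 - cfg.beta2 ** t)
        p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + cfg.eps)


def _train_one(x: np.ndarray, pair0: np.ndarray, pair1: np.ndarray,
               val0: np.ndarray, val1: np.ndarray, k: int,
               cfg: TrainingConfig, seed: int) -> tuple[SoftmaxNet, float]:
    rng = np.random.default_rng(seed)
    net = SoftmaxNet(x.shape[1], k, cfg.width, cfg.depth, rng)
    net.set_standardization(x)
    m = [np.zeros_like(p) for p in net.params()]
    v = [np.zeros_like(p) for p in net.params()]
    best_val = -np.inf
    best_weights = net.clone_weights()
    history: list[float] = []
    step = 0
    n_pairs = len(pair0)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, cfg.batch_pairs):
            sel = order[lo:lo + cfg.batch_pairs]
            if len(sel) < 2 * k:
                continue
            chi0, cache0 = net.forward(x[pair0[sel]], cfg.dropout, rng)
            chit, cachet = net.forward(x[pair1[sel]], cfg.dropout, rng)
            _, d0, dt = _vamp2_grad(chi0, chit, cfg.ridge)
            gW0, gb0 = net.backward(cache0, chi0, -d0)  # maximize score
            gW1, gb1 = net.backward(cachet, chit, -dt)
            gW = [a + b for a, b in zip(gW0, gW1)]
            gb = [a + b for a, b in zip(gb0, gb1)]
            if cfg.l2 > 0:
                gW = [g + cfg.l2 * w for g, w in zip(gW, net.W)]
            step += 1
            _adam_step(net.params(), gW + gb, m, v, step, cfg)
        chi_v0 = net.predict(x[val0])
        chi_v1 = net.predict(x[val1])
        val = vamp2_from_chi(chi_v0, chi_v1, cfg.ridge)
        history.append(val)
        if val > best_val:
            best_val = val
            best_weights = net.clone_weights()
        if len(history) > cfg.patience and \
                max(history[-cfg.patience:]) - max(history[:-cfg.patience]) \
                < cfg.min_improvement:
            break
    net.load_weights(best_weights)
    return net, best_val


def train_assignment_model(
    features: FeatureSeries,
    k: int = 2,
    lag_frames: int = 20,
    config: TrainingConfig | str = "desk",
    split: tuple[np.ndarray, np.ndarray] | None = None,
    test_idx: np.ndarray | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Train the soft state-assignment network for one train/val split.

    Three independently initialized trials are trained per call and the
    best kept by its VAMP-2 score on the held-out test frames. Frame
    pairs are attributed to a split by their start frame; pairs never
    cross trajectory boundaries. Returns the trained network, the soft
    assignment over *all* frames and the Koopman model estimated from it.
    """
    cfg = PRESETS[config] if isinstance(config, str) else config
    x = features.stacked
    if not np.all(np.isfinite(x)):
        raise ValueError("features contain non-finite values")
    if lag_frames < 1:
        raise ValueError("lag must be >= 1 frame")
    pair0, pair1 = _pair_indices(features.traj_lengths, lag_frames)
    n_frames = features.n_frames
    if split is None:
        plan = make_splits(n_frames, n_splits=1, seed=seed)
        split = plan.splits[0]
        test_idx = plan.test_idx if test_idx is None else test_idx
    train_idx, val_idx = split
    in_train = np.zeros(n_frames, dtype=bool)
    in_train[train_idx] = True
    in_val = np.zeros(n_frames, dtype=bool)
    in_val[val_idx] = True
    tr = in_train[pair0]
    va = in_val[pair0]
    if test_idx is not None and len(test_idx):
        in_test = np.zeros(n_frames, dtype=bool)
        in_test[test_idx] = True
        te = in_test[pair0]
    else:
        te = va
    trials = []
    ss = np.random.SeedSequence(seed).spawn(cfg.n_trials)
    for t, child in enumerate(ss):
        trial_seed = int(child.generate_state(1)[0] % (2**31))
        net, val_score = _train_one(
            x, pair0[tr], pair1[tr], pair0[va], pair1[va], k, cfg, trial_seed)
        test_score = vamp2_from_chi(net.predict(x[pair0[te]]),
                                    net.predict(x[pair1[te]]), cfg.ridge)
        trials.append((test_score, val_score, net))
        logger.info("trial %d: val VAMP2 %.4f, test VAMP2 %.4f",
                    t, val_score, test_score)
    test_score, val_score, net = max(trials, key=lambda t: t[0])
    chi = [net.predict(a) for a in features.arrays]
    assignment = StateAssignment(chi, features.frame_interval_ps)
    koopman = estimate_koopman(assignment, lag_frames)
    stacked = assignment.stacked
    collapse = bool(np.any(stacked.max(axis=0) < 0.5))
    if collapse:
        logger.warning("degenerate state collapse: some state never dominates")
    meta = {"k": k, "lag_frames": lag_frames, "seed": seed,
            "vamp2_test": test_score, "vamp2_val": val_score,
            "degenerate_collapse": collapse,
            "config": {kk: vv for kk, vv in cfg.__dict__.items()}}
    return TrainedModel(net, assignment, koopman, meta)


# ---------------------------------------------------------------------------
# Koopman estimation
# ---------------------------------------------------------------------------

def estimate_koopman(assign: StateAssignment, lag_frames: int) -> KoopmanModel:
    """Soft-count Koopman operator and its stationary distribution.

    C_ij = sum over within-trajectory pairs of chi_i(x_t) chi_j(x_{t+tau});
    K is C row-normalized and pi the leading left eigenvector of K scaled
    to sum 1.
    """
    chi0, chit = lagged_pairs(assign.chi, lag_frames)
    counts = chi0.T @ chit
    mass = counts.sum(axis=1)
    empty = np.where(mass <= 0)[0]
    if len(empty):
        raise ValueError(f"state(s) {empty.tolist()} have zero transition mass")
    K = counts / mass[:, None]
    w, v = scipy.linalg.eig(K, left=True, right=False)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    pi = pi / pi.sum()
    # one power-iteration refinement keeps pi stationary to tight tolerance
    for _ in range(50):
        nxt = pi @ K
        if np.max(np.abs(nxt - pi)) < 1e-14:
            break
        pi = nxt / nxt.sum()
    return KoopmanModel(K, pi, lag_frames, assign.frame_interval_ps)


# ---------------------------------------------------------------------------
# State alignment across models
# ---------------------------------------------------------------------------

def state_averaged_map(assign: StateAssignment, features: FeatureSeries) -> np.ndarray:
    """chi-weighted mean feature map per state, shape (k, n_features)."""
    chi = assign.stacked
    x = features.stacked
    mass = chi.sum(axis=0)
    if np.any(mass <= 0):
        raise ValueError("state with zero mass")
    return (chi.T @ x) / mass[:, None]


def align_states_across_models(
    models: list[TrainedModel],
    contact_maps: list[np.ndarray],
) -> list[tuple[int, ...]]:
    """Per-model state permutation matching states to the first model.

    States are matched by minimizing the total root-mean-square deviation
    between state-averaged contact maps; exact search over permutations
    (k is small). Ties are broken by ordering states by population,
    descending.
    """
    if len(models) < 2:
        raise ValueError("need at least two models to align")
    ref = contact_maps[0]
    k = ref.shape[0]
    perms = []
    for model, cmap in zip(models, contact_maps):
        best = None
        for p in itertools.permutations(range(k)):
            rmsd = sum(
                float(np.sqrt(np.mean((cmap[p[i]] - ref[i]) ** 2)))
                for i in range(k)
            )
            pops = tuple(-model.koopman.pi[list(p)])
            key = (round(rmsd, 12), pops)
            if best is None or key < best[0]:
                best = (key, p)
        perms.append(best[1])
    return perms
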