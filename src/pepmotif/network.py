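"""Single feed-forward network with simultaneous core alignment.

Each network has one sigmoid hidden layer and one sigmoid output and is
trained online: for every training peptide, the best-scoring core offset
under the *current* weights is located by exhaustive scan, then one
gradient step on the squared error at that core is taken.  Re-selecting
the core per example (with the freshest weights) is what lets the model
align the peptides and learn the quantitative motif at the same time.

The inner loop is numba-compiled; the jitted kernels are also called
directly by the test-suite's finite-difference gradient oracle so the
verified arithmetic is exactly the production path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .encoding import BatchEncoding, EncodingConfig, encode_instance, encode_peptides

WEIGHT_INIT_RANGE = 0.05


@dataclass
class TrainSchedule:
    n_iterations: int = 500      # epochs over the training set
    learning_rate: float = 0.05
    stop_on_best_test: bool = False

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")

    def to_dict(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "learning_rate": self.learning_rate,
            "stop_on_best_test": self.stop_on_best_test,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainSchedule":
        return cls(**d)


@dataclass
class TrainedNetwork:
    """One network's weights, with the bias folded in as the last column.

    ``weights_in`` has shape (n_hidden, input_dim + 1): column ``input_dim``
    is the hidden bias.  ``weights_out`` has length n_hidden + 1: the last
    element is the output bias.  ``logo_offset`` is the register shift
    assigned later by the logo offset correction (0 until then).
    """

    weights_in: np.ndarray
    weights_out: np.ndarray
    config: EncodingConfig
    n_hidden: int
    seed: int
    logo_offset: int = 0
    stop_rmse: Optional[float] = None
    fold: Optional[int] = None

    def __post_init__(self) -> None:
        self.weights_in = np.asarray(self.weights_in, dtype=np.float64)
        self.weights_out = np.asarray(self.weights_out, dtype=np.float64)
        D = self.config.input_dim
        if self.weights_in.shape != (self.n_hidden, D + 1):
            raise ValueError(
                f"weights_in shape {self.weights_in.shape} inconsistent with "
                f"n_hidden={self.n_hidden}, input_dim={D}"
            )
        if self.weights_out.shape != (self.n_hidden + 1,):
            raise ValueError("weights_out length must be n_hidden + 1")

    def to_dict(self) -> dict:
        return {
            "weights_in": self.weights_in.tolist(),
            "weights_out": self.weights_out.tolist(),
            "config": self.config.to_dict(),
            "n_hidden": self.n_hidden,
            "seed": self.seed,
            "logo_offset": self.logo_offset,
            "stop_rmse": self.stop_rmse,
            "fold": self.fold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedNetwork":
        d = dict(d)
        d["config"] = EncodingConfig.from_dict(d["config"])
        d["weights_in"] = np.array(d["weights_in"], dtype=np.float64)
        d["weights_out"] = np.array(d["weights_out"], dtype=np.float64)
        return cls(**d)


# ---------------------------------------------------------------------------
# jitted kernels


@njit(cache=False)
def _forward_rows(W1, w2, X):
    """Scores for each row of X.  W1: (H, D+1) with bias col, w2: (H+1,)."""
    n, D = X.shape
    H = W1.shape[0]
    out = np.empty(n)
    for r in range(n):
        acc_out = w2[H]
        for h in range(H):
            acc = W1[h, D]
            for d in range(D):
                acc += W1[h, d] * X[r, d]
            acc_out += w2[h] * (1.0 / (1.0 + np.exp(-acc)))
        out[r] = 1.0 / (1.0 + np.exp(-acc_out))
    return out


@njit(cache=False)
def _best_core_scores(W1, w2, X, start):
    """Per-peptide (best offset, best score) over contiguous offset blocks.

    Ties broken by the smallest offset (strict > while scanning in order).
    """
    n_pep = start.shape[0] - 1
    offsets = np.empty(n_pep, dtype=np.int64)
    scores = np.empty(n_pep)
    for p in range(n_pep):
        lo, hi = start[p], start[p + 1]
        vals = _forward_rows(W1, w2, X[lo:hi])
        best = 0
        for o in range(1, hi - lo):
            if vals[o] > vals[best]:
                best = o
        offsets[p] = best
        scores[p] = vals[best]
    return offsets, scores


@njit(cache=False)
def _gradient_step(W1, w2, x, target, lr):
    """One online backprop step on E = 0.5*(o - t)^2 at input row x.

    Updates W1 and w2 in place and returns the pre-update output.
    """
    D = x.shape[0]
    H = W1.shape[0]
    hidden = np.empty(H)
    acc_out = w2[H]
    for h in range(H):
        acc = W1[h, D]
        for d in range(D):
            acc += W1[h, d] * x[d]
        hidden[h] = 1.0 / (1.0 + np.exp(-acc))
        acc_out += w2[h] * hidden[h]
    out = 1.0 / (1.0 + np.exp(-acc_out))
    delta_o = (out - target) * out * (1.0 - out)
    for h in range(H):
        delta_h = delta_o * w2[h] * hidden[h] * (1.0 - hidden[h])
        w2[h] -= lr * delta_o * hidden[h]
        for d in range(D):
            W1[h, d] -= lr * delta_h * x[d]
        W1[h, D] -= lr * delta_h
    w2[H] -= lr * delta_o
    return out


@njit(cache=False)
def _train_epoch(W1, w2, X, start, targets, order, lr):
    """One epoch: per peptide (in ``order``), re-select the best core under
    the current weights, then one gradient step on it."""
    for k in range(order.shape[0]):
        p = order[k]
        lo, hi = start[p], start[p + 1]
        vals = _forward_rows(W1, w2, X[lo:hi])
        best = 0
        for o in range(1, hi - lo):
            if vals[o] > vals[best]:
                best = o
        _gradient_step(W1, w2, X[lo + best], targets[p], lr)


# ---------------------------------------------------------------------------
# public API


def forward(network: TrainedNetwork, vector: np.ndarray) -> float:
    """Network output for one encoded input vector; strictly in (0, 1)."""
    vec = np.asarray(vector, dtype=np.float64)
    if vec.shape != (network.config.input_dim,):
        raise ValueError(
            f"input vector length {vec.shape} does not match "
            f"input_dim {network.config.input_dim}"
        )
    return float(
        _forward_rows(network.weights_in, network.weights_out, vec[None, :])[0]
    )


def best_core(network: TrainedNetwork, peptide: str) -> tuple[int, float]:
    """Exhaustive scan of all core offsets; returns (offset, score).

    Ties are broken by the smallest offset.
    """
    m = network.config.motif_len
    if len(peptide) < m:
        raise ValueError(f"peptide {peptide!r} shorter than motif length {m}")
    enc = encode_peptides([peptide], network.config)
    offs, scores = _best_core_scores(
        network.weights_in, network.weights_out, enc.X, enc.start
    )
    return int(offs[0]), float(scores[0])


def score_batch(network: TrainedNetwork, enc: BatchEncoding) -> tuple[np.ndarray, np.ndarray]:
    """Best-core offsets and scores for every peptide in a batch encoding."""
    offs, scores = _best_core_scores(
        network.weights_in, network.weights_out, enc.X, enc.start
    )
    return offs, scores


def init_weights(n_hidden: int, input_dim: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Uniform ±0.05 initial weights; W_in drawn first, then w_out."""
    rng = np.random.default_rng(seed)
    W1 = rng.uniform(-WEIGHT_INIT_RANGE, WEIGHT_INIT_RANGE, size=(n_hidden, input_dim + 1))
    w2 = rng.uniform(-WEIGHT_INIT_RANGE, WEIGHT_INIT_RANGE, size=n_hidden + 1)
    return W1, w2


def train_network(
    train_peptides: list[str],
    train_targets,
    schedule: TrainSchedule,
    encoding: EncodingConfig,
    n_hidden: int,
    seed: int,
    stop_peptides: Optional[list[str]] = None,
    stop_targets=None,
    train_encoding: Optional[BatchEncoding] = None,
    stop_encoding: Optional[BatchEncoding] = None,
) -> TrainedNetwork:
    """Train one network; fully deterministic given ``seed``.

    Targets must already be rescaled to [0, 1].  When
    ``schedule.stop_on_best_test`` is set and a stop set is given, the
    returned weights are those with minimal stop-set RMSE over epochs;
    otherwise the final-epoch weights.  The stop set is only ever read to
    compute that RMSE.  Pre-computed batch encodings may be passed to
    avoid re-encoding across seeds/architectures.
    """
    if len(train_peptides) == 0:
        raise ValueError("empty training set")
    targets = np.asarray(list(train_targets), dtype=np.float64)
    if targets.shape != (len(train_peptides),):
        raise ValueError("one target per training peptide required")
    if targets.min() < 0 or targets.max() > 1:
        raise ValueError("training targets must be rescaled to [0, 1]")
    enc = train_encoding or encode_peptides(train_peptides, encoding)
    senc = None
    s_targets = None
    if stop_peptides is not None and len(stop_peptides):
        senc = stop_encoding or encode_peptides(stop_peptides, encoding)
        s_targets = np.asarray(list(stop_targets), dtype=np.float64)

    W1, w2 = init_weights(n_hidden, encoding.input_dim, seed)
    rng = np.random.default_rng(seed + 1)
    lr = schedule.learning_rate
    best_rmse = np.inf
    best_W1, best_w2 = None, None
    last_rmse = None
    for _ in range(schedule.n_iterations):
        order = rng.permutation(len(train_peptides)).astype(np.int64)
        _train_epoch(W1, w2, enc.X, enc.start, targets, order, lr)
        if senc is not None:
            _, preds = _best_core_scores(W1, w2, senc.X, senc.start)
            last_rmse = float(np.sqrt(np.mean((preds - s_targets) ** 2)))
            if schedule.stop_on_best_test and last_rmse < best_rmse:
                best_rmse = last_rmse
                best_W1, best_w2 = W1.copy(), w2.copy()
    if schedule.stop_on_best_test and best_W1 is not None:
        W1, w2, stop_rmse = best_W1, best_w2, best_rmse
    else:
        stop_rmse = last_rmse
    return TrainedNetwork(
        weights_in=W1,
        weights_out=w2,
        config=encoding,
        n_hidden=n_hidden,
        seed=seed,
        stop_rmse=stop_rmse,
    )
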