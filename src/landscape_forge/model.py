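"""Neural-network fitness models on one-hot encoded protein genotypes.

Four model families over position/state indicator features:

* a **linear** model (single linear output node) whose prediction is the
  *fitness potential* — the summed contribution of weighted mutations;
* the linear model with a single **sigmoid** node appended (plus an affine
  output rescale, since fluorescence is not confined to (0, 1));
* a **two-layer** network — linear hidden layer → dropout → sigmoid hidden
  layer → dropout → linear output — with Monte Carlo dropout (rate 0.1,
  active at inference) giving per-genotype prediction medians and sds;
* an independent **a-posteriori** model with 10, 100 and 1 leaky-ReLU nodes
  used only to double-check design candidates.

The networks are small (≤ a few hundred units), so they are implemented
directly in numpy: manual backpropagation, Adam, mini-batches, MSE loss, and
early stopping on validation loss with best-weight restoration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import parse_mutation_set, format_mutation_set

WIDTH_GRID = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 20, 50, 100, 200)
LEAKY_ALPHA = 0.1


# ---------------------------------------------------------------------------
# encoding

@dataclass
class OneHotDataset:
    X: np.ndarray  # (n, p) float32 indicators
    y: np.ndarray  # (n,) float64 log10 fluorescence
    columns: list[tuple[int, str]]  # (site, state) per indicator column
    mutation_sets: list[frozenset]
    wildtype: str
    labels: np.ndarray | None = None  # 'train' | 'val' | 'test'

    @property
    def col_index(self) -> dict[tuple[int, str], int]:
        return {c: i for i, c in enumerate(self.columns)}

    def subset(self, mask: np.ndarray) -> "OneHotDataset":
        idx = np.flatnonzero(mask)
        return OneHotDataset(
            X=self.X[idx],
            y=self.y[idx],
            columns=self.columns,
            mutation_sets=[self.mutation_sets[i] for i in idx],
            wildtype=self.wildtype,
            labels=self.labels[idx] if self.labels is not None else None,
        )


def encode(dataset: pd.DataFrame, wildtype: str, full_alphabet: bool = False) -> OneHotDataset:
    """One-hot encode protein genotypes: one indicator per observed (site, state).

    Each position contributes a column for its wildtype state plus one per
    state observed in the dataset at that position (all 20 states with
    ``full_alphabet``).  Every row has exactly one active state per position.
    Genotypes with negative fluorescence are the caller's responsibility to
    exclude beforehand.
    """
    from .genotypes import AMINO_ACIDS, STOP

    mut_sets = [parse_mutation_set(m) for m in dataset["mutations"]]
    states: dict[int, set[str]] = {s + 1: {wildtype[s]} for s in range(len(wildtype))}
    if full_alphabet:
        for site in states:
            states[site] |= set(AMINO_ACIDS) | {STOP}
    else:
        valid = set(AMINO_ACIDS) | {STOP}
        for ms in mut_sets:
            for site, alt in ms:
                if alt not in valid:
                    raise ValueError(f"unknown amino-acid state {alt!r} at site {site}")
                states[site].add(alt)
    columns = [(site, st) for site in sorted(states) for st in sorted(states[site])]
    col_index = {c: i for i, c in enumerate(columns)}

    wt_cols = np.array([col_index[(s + 1, wildtype[s])] for s in range(len(wildtype))])
    X = np.zeros((len(mut_sets), len(columns)), dtype=np.float32)
    X[:, wt_cols] = 1.0
    for i, ms in enumerate(mut_sets):
        for site, alt in ms:
            key = (site, alt)
            if key not in col_index:
                raise ValueError(f"state {alt!r} at site {site} not in encoding alphabet")
            X[i, col_index[(site, wildtype[site - 1])]] = 0.0
            X[i, col_index[key]] = 1.0
    return OneHotDataset(
        X=X,
        y=dataset["fluorescence"].to_numpy(dtype=float),
        columns=columns,
        mutation_sets=mut_sets,
        wildtype=wildtype,
    )


def decode(ds: OneHotDataset, row: int) -> str:
    """Mutation string of an encoded row (inverse of encode)."""
    active = np.flatnonzero(ds.X[row] == 1.0)
    muts = []
    for i in active:
        site, state = ds.columns[i]
        if state != ds.wildtype[site - 1]:
            muts.append((site, state))
    return format_mutation_set(ds.wildtype, muts)


def split(n: int, fractions: tuple[float, float, float] = (0.6, 0.2, 0.2), seed: int = 0) -> np.ndarray:
    """Random disjoint train/val/test labels covering all n rows."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    labels = np.empty(n, dtype=object)
    labels[order[:n_train]] = "train"
    labels[order[n_train : n_train + n_val]] = "val"
    labels[order[n_train + n_val :]] = "test"
    return labels


def filter_for_training(
    train_sets: list[frozenset],
    val_sets: list[frozenset],
    min_genotypes: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively drop training genotypes with under-observed mutations.

    Training genotypes containing a mutation present in fewer than
    ``min_genotypes`` distinct training genotypes are removed; removal lowers
    other mutations' counts, so the rule is iterated to its fixed point.
    Validation genotypes containing mutations absent from the final training
    set are removed.  Returns boolean keep-masks (train, val).
    """
    keep = np.ones(len(train_sets), dtype=bool)
    while True:
        counts: dict = {}
        for i in np.flatnonzero(keep):
            for m in train_sets[i]:
                counts[m] = counts.get(m, 0) + 1
        bad = {m for m, c in counts.items() if c < min_genotypes}
        drop = [i for i in np.flatnonzero(keep) if train_sets[i] & bad]
        if not drop:
            break
        keep[drop] = False
    if not keep.any():
        raise ValueError("training set empty after mutation-frequency filtering")
    train_muts = set().union(*(train_sets[i] for i in np.flatnonzero(keep))) if keep.any() else set()
    keep_val = np.array([not (ms - train_muts) for ms in val_sets], dtype=bool)
    return keep, keep_val


# ---------------------------------------------------------------------------
# network

def _act(name, z):
    if name == "identity":
        return z
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    if name == "leaky_relu":
        return np.where(z > 0, z, LEAKY_ALPHA * z)
    raise ValueError(name)


def _act_grad(name, z, a):
    if name == "identity":
        return np.ones_like(z)
    if name == "sigmoid":
        return a * (1.0 - a)
    if name == "leaky_relu":
        return np.where(z > 0, 1.0, LEAKY_ALPHA)
    raise ValueError(name)


@dataclass
class ModelArchitecture:
    """Layer plan: (width, activation, dropout_after) triples plus metadata."""

    layers: tuple[tuple[int, str, bool], ...]
    dropout_rate: float = 0.1
    name: str = "custom"


def linear_architecture() -> ModelArchitecture:
    return ModelArchitecture(((1, "identity", False),), 0.0, "linear")


def sigmoid_architecture() -> ModelArchitecture:
    return ModelArchitecture(
        ((1, "identity", False), (1, "sigmoid", False), (1, "identity", False)), 0.0, "sigmoid"
    )


def sigmoid_model_from_linear(linear_net: "Network") -> "Network":
    """Append a sigmoid node to a trained linear model (warm start).

    The sigmoid layer is initialized in its linear regime and the output layer
    undoes that scaling, so the new model starts as the linear model's
    prediction and retraining can bend the threshold.
    """
    net = Network(linear_net.W[0].shape[0], sigmoid_architecture())
    net.W[0] = linear_net.W[0].copy()
    net.b[0] = linear_net.b[0].copy()
    net.W[1] = np.array([[0.5]])
    net.b[1] = np.zeros(1)
    net.W[2] = np.array([[8.0]])
    net.b[2] = np.array([-4.0])
    net.y_center = linear_net.y_center
    net.y_scale = linear_net.y_scale
    return net


def two_layer_architecture(w1: int, w2: int, dropout: float = 0.1) -> ModelArchitecture:
    return ModelArchitecture(
        ((w1, "identity", True), (w2, "sigmoid", True), (1, "identity", False)),
        dropout,
        f"two_layer_{w1}x{w2}",
    )


def transform_architecture() -> ModelArchitecture:
    """1 linear node → 10 sigmoid nodes → linear output (transform visualization)."""
    return ModelArchitecture(
        ((1, "identity", False), (10, "sigmoid", False), (1, "identity", False)),
        0.0,
        "transform",
    )


def posterior_architecture() -> ModelArchitecture:
    return ModelArchitecture(
        ((10, "leaky_relu", False), (100, "leaky_relu", False), (1, "leaky_relu", False)),
        0.0,
        "posterior",
    )


class Network:
    """Dense feed-forward regressor with optional MC dropout."""

    def __init__(self, n_inputs: int, architecture: ModelArchitecture, seed: int = 0):
        self.architecture = architecture
        self.dropout_rate = architecture.dropout_rate
        rng = np.random.default_rng(seed)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        self.acts: list[str] = []
        self.drop_after: list[bool] = []
        fan_in = n_inputs
        for width, act, drop in architecture.layers:
            limit = np.sqrt(6.0 / (fan_in + width))  # Glorot uniform
            self.W.append(rng.uniform(-limit, limit, size=(fan_in, width)))
            self.b.append(np.zeros(width))
            self.acts.append(act)
            self.drop_after.append(drop)
            fan_in = width
        if self.W[-1].shape[1] != 1:
            raise ValueError("output layer must have a single node")
        # target normalization (set by train)
        self.y_center = 0.0
        self.y_scale = 1.0

    # -- forward ------------------------------------------------------------

    def _forward(self, X, rng=None, dropout=False):
        a = X
        zs, as_, masks = [], [a], []
        for W, b, act, drop in zip(self.W, self.b, self.acts, self.drop_after):
            z = a @ W + b
            a = _act(act, z)
            mask = None
            if dropout and drop and self.dropout_rate > 0:
                mask = (rng.random(a.shape) >= self.dropout_rate) / (1.0 - self.dropout_rate)
                a = a * mask
            zs.append(z)
            as_.append(a)
            masks.append(mask)
        return zs, as_, masks

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic prediction (dropout off), on the fluorescence scale."""
        _, as_, _ = self._forward(np.asarray(X, dtype=float))
        return as_[-1][:, 0] * self.y_scale + self.y_center

    def predict_stochastic(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        _, as_, _ = self._forward(np.asarray(X, dtype=float), rng=rng, dropout=True)
        return as_[-1][:, 0] * self.y_scale + self.y_center

    # -- persistence ---------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "layers": [list(t) for t in self.architecture.layers],
                "dropout_rate": self.dropout_rate,
                "name": self.architecture.name,
                "y_center": self.y_center,
                "y_scale": self.y_scale,
                "W": [w.tolist() for w in self.W],
                "b": [b.tolist() for b in self.b],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Network":
        d = json.loads(text)
        arch = ModelArchitecture(
            tuple(tuple(t) for t in d["layers"]), d["dropout_rate"], d["name"]
        )
        net = cls(len(d["W"][0]), arch)
        net.W = [np.array(w) for w in d["W"]]
        net.b = [np.array(b) for b in d["b"]]
        net.y_center = d["y_center"]
        net.y_scale = d["y_scale"]
        return net


def train(
    net: Network,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    max_epochs: int = 30,
    patience: int = 10,
    learning_rate: float = 1e-3,
    batch_size: int = 64,
    seed: int = 0,
    center_targets: bool = True,
) -> dict:
    """Mini-batch Adam on MSE with early stopping on validation loss.

    Targets are normalized internally (z-score by default; scale-only for
    networks whose output activation is one-sided).  For networks with MC
    dropout the validation loss is computed with dropout active (averaged
    over several stochastic passes), mirroring inference-time behavior and
    penalizing architectures whose predictions destabilize under dropout;
    dropout-free networks use a deterministic pass.  The best-epoch weights
    are restored.  Returns the per-epoch training history.
    """
    rng = np.random.default_rng(seed)
    X_train = np.asarray(X_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    net.y_center = float(np.mean(y_train)) if center_targets else 0.0
    net.y_scale = float(np.std(y_train)) or 1.0
    yt = (np.asarray(y_train, dtype=float) - net.y_center) / net.y_scale
    yv = (np.asarray(y_val, dtype=float) - net.y_center) / net.y_scale

    mW = [np.zeros_like(w) for w in net.W]
    vW = [np.zeros_like(w) for w in net.W]
    mb = [np.zeros_like(b) for b in net.b]
    vb = [np.zeros_like(b) for b in net.b]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    has_dropout = net.dropout_rate > 0 and any(net.drop_after)
    val_rng = np.random.default_rng(seed + 1)

    def val_loss():
        if has_dropout:
            losses = [
                float(np.mean((net._forward(X_val, rng=val_rng, dropout=True)[1][-1][:, 0] - yv) ** 2))
                for _ in range(8)
            ]
            return float(np.mean(losses))
        _, as_, _ = net._forward(X_val)
        return float(np.mean((as_[-1][:, 0] - yv) ** 2))

    best = (np.inf, None, None)
    history = {"train_loss": [], "val_loss": []}
    since_best = 0
    n = len(X_train)

    for epoch in range(max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = X_train[idx], yt[idx]
            zs, as_, masks = net._forward(xb, rng=rng, dropout=True)
            pred = as_[-1][:, 0]
            err = pred - yb
            epoch_loss += float(np.sum(err**2))
            da = (2.0 / len(idx)) * err[:, None]
            for l in range(len(net.W) - 1, -1, -1):
                if masks[l] is not None:
                    da = da * masks[l]
                dz = da * _act_grad(net.acts[l], zs[l], as_[l + 1])
                dW = as_[l].T @ dz
                db = dz.sum(axis=0)
                da = dz @ net.W[l].T
                step_l = step + 1
                mW[l] = beta1 * mW[l] + (1 - beta1) * dW
                vW[l] = beta2 * vW[l] + (1 - beta2) * dW**2
                mb[l] = beta1 * mb[l] + (1 - beta1) * db
                vb[l] = beta2 * vb[l] + (1 - beta2) * db**2
                mhW = mW[l] / (1 - beta1**step_l)
                vhW = vW[l] / (1 - beta2**step_l)
                mhb = mb[l] / (1 - beta1**step_l)
                vhb = vb[l] / (1 - beta2**step_l)
                net.W[l] -= learning_rate * mhW / (np.sqrt(vhW) + eps)
                net.b[l] -= learning_rate * mhb / (np.sqrt(vhb) + eps)
            step += 1
        tl = epoch_loss / n
        vl = val_loss()
        if not np.isfinite(tl) or not np.isfinite(vl):
            raise RuntimeError(f"training diverged at epoch {epoch}: loss not finite")
        history["train_loss"].append(tl)
        history["val_loss"].append(vl)
        if vl < best[0] - 1e-12:
            best = (vl, [w.copy() for w in net.W], [b.copy() for b in net.b])
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    if best[1] is not None:
        net.W = best[1]
        net.b = best[2]
    history["best_val_loss"] = best[0]
    return history


def predict_mc(
    net: Network, X: np.ndarray, n_samples: int = 20, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Median and sd over stochastic forward passes with dropout active."""
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    samples = np.stack([net.predict_stochastic(X, rng) for _ in range(n_samples)])
    return np.median(samples, axis=0), np.std(samples, axis=0)


def r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination; undefined (raises) for zero-variance labels."""
    y_true = np.asarray(y_true, dtype=float)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("coefficient of determination undefined: labels have zero variance")
    ss_res = float(np.sum((y_true - np.asarray(y_pred, dtype=float)) ** 2))
    return 1.0 - ss_res / ss_tot


def grid_search(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    width_grid: tuple[int, ...] = WIDTH_GRID,
    n_architectures: int = 10,
    search_epochs: int = 10,
    final_epochs: int = 30,
    dropout: float = 0.1,
    seed: int = 0,
) -> tuple[ModelArchitecture, Network, dict]:
    """Random search over (linear width, sigmoid width) pairs.

    Each sampled architecture is trained briefly and scored by validation MSE;
    the best is retrained from scratch for the full epoch budget.
    """
    rng = np.random.default_rng(seed)
    pairs = [(w1, w2) for w1 in width_grid for w2 in width_grid]
    order = rng.permutation(len(pairs))[: max(1, n_architectures)]
    results = []
    for rank, k in enumerate(order):
        w1, w2 = pairs[k]
        arch = two_layer_architecture(w1, w2, dropout)
        net = Network(X_train.shape[1], arch, seed=seed + rank)
        hist = train(
            net, X_train, y_train, X_val, y_val, max_epochs=search_epochs, seed=seed + rank
        )
        results.append(((w1, w2), hist["best_val_loss"]))
    best_pair = min(results, key=lambda t: t[1])[0]
    arch = two_layer_architecture(*best_pair, dropout)
    net = Network(X_train.shape[1], arch, seed=seed)
    history = train(net, X_train, y_train, X_val, y_val, max_epochs=final_epochs, seed=seed)
    history["search_results"] = results
    return arch, net, history


def train_posterior(
    X: np.ndarray,
    y: np.ndarray,
    split_fractions: tuple[float, float] = (0.9, 0.1),
    max_epochs: int = 500,
    patience: int = 10,
    seed: int = 0,
) -> tuple[Network, dict]:
    """Independent 10/100/1 leaky-ReLU filter model on a fresh 90/10 split.

    Targets are normalized by scale only (no centering) so the one-sided
    output activation sees positive targets; deterministic at inference.
    """
    rng = np.random.default_rng(seed)
    n = len(X)
    order = rng.permutation(n)
    n_train = int(round(split_fractions[0] * n))
    tr, va = order[:n_train], order[n_train:]
    net = Network(X.shape[1], posterior_architecture(), seed=seed)
    history = train(
        net,
        X[tr],
        y[tr],
        X[va],
        y[va],
        max_epochs=max_epochs,
        patience=patience,
        seed=seed,
        center_targets=False,
    )
    return net, history


def transform_curve(net: Network, potentials: np.ndarray) -> np.ndarray:
    """Learned 1-D transform of a transform-visualization network.

    Evaluates the post-potential layers on a grid of fitness-potential values,
    exposing the threshold function the network learned.
    """
    a = np.asarray(potentials, dtype=float)[:, None]
    for W, b, act in list(zip(net.W, net.b, net.acts))[1:]:
        a = _act(act, a @ W + b)
    return a[:, 0] * net.y_scale + net.y_center
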