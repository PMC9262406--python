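"""Linear-activation feedforward network models of region dependence.

Two architectures are provided, both purely linear (affine layers, no
nonlinear activation functions):

* ``standard`` — a plain chain input -> hidden -> ... -> hidden -> output.
* ``dense`` — densely connected: every hidden layer receives the raw input
  concatenated with the outputs of all earlier hidden layers, so with L
  hidden layers of width ``h`` the ℓ-th hidden layer's input width is
  ``input_dim + (ℓ-1)·h`` and the output layer sees ``input_dim + L·h``
  features.

Because all activations are linear, each trained network collapses
algebraically to a single affine map; the architectures differ only in how
SGD parameterizes and traverses that space, which is exactly what makes them
interesting as models of between-region dependence.

Training is plain stochastic gradient descent with classical momentum and an
L2 weight-decay gradient term, minimizing squared error. The optimized
objective sums squared residuals over target voxels and averages over the
timepoints in the batch, so the gradient magnitude seen by each output unit
does not shrink as the target region grows (averaging over voxels as well
would scale the effective learning rate by 1/n_Y, making wide targets
untrainable at standard learning rates); the recorded ``loss_history`` is
nevertheless the per-element mean squared error, which is the same quantity
up to the constant factor n_Y and comparable across region sizes. Batch
normalization (non-affine: standardization to batch mean 0 / variance 1) is
applied to the inputs of every affine layer, including the first, so raw
BOLD-scale inputs train at small learning rates; the scale and shift a
learnable BN would add are absorbed by the following affine layer, which is
exact here since no nonlinearity intervenes. During training BN uses batch
statistics and accumulates running estimates; prediction uses the frozen
running estimates, so a column's output never depends on which other columns
share the call.

Mini-batches are composed of randomly permuted timepoints (a replay-memory
style scheme): each epoch draws a seeded permutation of all training
timepoints and slices it into consecutive chunks, so batches mix timepoints
from across runs and are non-consecutive in acquisition time, weakening the
temporal autocorrelation within a batch. Sampling with replacement is
available as an option.

The whole stack is implemented in numpy with explicit forward/backward
passes; everything is seeded, so identical seeds and data give bitwise
identical trained parameters.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NNArchitectureSpec",
    "TrainingConfig",
    "NNArtifact",
    "layer_widths",
    "n_affine_parameters",
    "build_network",
    "sample_batch_schedule",
    "train_network",
    "predict_network",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1  # running = (1-mom)*running + mom*batch statistic


@dataclass(frozen=True)
class NNArchitectureSpec:
    """Architecture of a linear-activation network.

    kind : {"standard", "dense"}; n_hidden_layers >= 1; hidden_units is the
    width of every hidden layer; batch_norm toggles the normalization stage
    before each affine layer (on by default, including before the first).
    """

    kind: str
    n_hidden_layers: int
    hidden_units: int
    input_dim: int
    output_dim: int
    batch_norm: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("standard", "dense"):
            raise ValueError(f"kind must be 'standard' or 'dense', got {self.kind!r}")
        if self.n_hidden_layers < 1:
            raise ValueError("need at least one hidden layer")
        if min(self.hidden_units, self.input_dim, self.output_dim) < 1:
            raise ValueError("layer widths must be positive")


@dataclass(frozen=True)
class TrainingConfig:
    """SGD hyperparameters. Defaults follow common MVPD practice:
    batch size 32, learning rate 1e-3, momentum 0.9, no weight decay,
    100 epochs."""

    learning_rate: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.0
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0
    sample_with_replacement: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


def layer_widths(spec: NNArchitectureSpec) -> list[tuple[int, int]]:
    """(input_width, output_width) of each affine layer, in order."""
    L, h = spec.n_hidden_layers, spec.hidden_units
    if spec.kind == "standard":
        ins = [spec.input_dim] + [h] * (L - 1) + [h]
        outs = [h] * L + [spec.output_dim]
        return list(zip(ins, outs))
    # dense: layer ℓ sees the input plus all ℓ-1 earlier hidden outputs
    widths = [(spec.input_dim + (ell - 1) * h, h) for ell in range(1, L + 1)]
    widths.append((spec.input_dim + L * h, spec.output_dim))
    return widths


def n_affine_parameters(spec: NNArchitectureSpec) -> int:
    """Total weight + bias count, excluding normalization statistics."""
    return sum(din * dout + dout for din, dout in layer_widths(spec))


@dataclass
class NNArtifact:
    """A (possibly trained) network: spec, parameters, BN statistics, trace."""

    spec: NNArchitectureSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    bn_mean: list[np.ndarray] | None
    bn_var: list[np.ndarray] | None
    loss_history: list[float] = field(default_factory=list)
    trained: bool = False
    init_seed: int = 0

    def copy(self) -> "NNArtifact":
        return copy.deepcopy(self)

    def save(self, path) -> None:
        """Checkpoint to a single .npz file (spec fields + arrays)."""
        arrays = {f"W{i}": w for i, w in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases)})
        if self.bn_mean is not None:
            arrays.update({f"bn_mean{i}": m for i, m in enumerate(self.bn_mean)})
            arrays.update({f"bn_var{i}": v for i, v in enumerate(self.bn_var)})
        np.savez(
            path,
            kind=self.spec.kind,
            n_hidden_layers=self.spec.n_hidden_layers,
            hidden_units=self.spec.hidden_units,
            input_dim=self.spec.input_dim,
            output_dim=self.spec.output_dim,
            batch_norm=self.spec.batch_norm,
            trained=self.trained,
            init_seed=self.init_seed,
            loss_history=np.asarray(self.loss_history, dtype=float),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "NNArtifact":
        with np.load(path) as z:
            spec = NNArchitectureSpec(
                kind=str(z["kind"]),
                n_hidden_layers=int(z["n_hidden_layers"]),
                hidden_units=int(z["hidden_units"]),
                input_dim=int(z["input_dim"]),
                output_dim=int(z["output_dim"]),
                batch_norm=bool(z["batch_norm"]),
            )
            n_layers = len(layer_widths(spec))
            weights = [z[f"W{i}"] for i in range(n_layers)]
            biases = [z[f"b{i}"] for i in range(n_layers)]
            bn_mean = bn_var = None
            if spec.batch_norm:
                bn_mean = [z[f"bn_mean{i}"] for i in range(n_layers)]
                bn_var = [z[f"bn_var{i}"] for i in range(n_layers)]
            return cls(
                spec=spec,
                weights=weights,
                biases=biases,
                bn_mean=bn_mean,
                bn_var=bn_var,
                loss_history=list(z["loss_history"]),
                trained=bool(z["trained"]),
                init_seed=int(z["init_seed"]),
            )


def build_network(spec: NNArchitectureSpec, seed: int = 0) -> NNArtifact:
    """Initialize an untrained network with seeded uniform fan-in weights.

    Each affine layer's weights and bias are drawn i.i.d. from
    ``U(-1/sqrt(fan_in), 1/sqrt(fan_in))``, layer by layer in order, from a
    single generator seeded with ``seed`` — so the same seed gives bitwise
    identical initial parameters. BN running statistics start at mean 0 /
    variance 1 but are flagged untrained until :func:`train_network` runs.
    """
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for din, dout in layer_widths(spec):
        bound = 1.0 / np.sqrt(din)
        weights.append(rng.uniform(-bound, bound, size=(dout, din)))
        biases.append(rng.uniform(-bound, bound, size=dout))
    bn_mean = bn_var = None
    if spec.batch_norm:
        bn_mean = [np.zeros(din) for din, _ in layer_widths(spec)]
        bn_var = [np.ones(din) for din, _ in layer_widths(spec)]
    return NNArtifact(
        spec=spec, weights=weights, biases=biases,
        bn_mean=bn_mean, bn_var=bn_var, init_seed=seed,
    )


def sample_batch_schedule(
    T: int, batch_size: int, epoch_seed: int, with_replacement: bool = False
) -> list[np.ndarray]:
    """Timepoint index batches for one epoch.

    Default: a seeded random permutation of ``0..T-1`` cut into
    ``ceil(T/batch_size)`` consecutive chunks (last possibly short), so every
    timepoint is visited exactly once per epoch but batches are
    non-consecutive in acquisition time. With ``with_replacement`` the same
    number of batches is drawn uniformly with replacement instead.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(epoch_seed)
    n_batches = -(-T // batch_size)
    if with_replacement:
        return [rng.integers(0, T, size=min(batch_size, T)) for _ in range(n_batches)]
    perm = rng.permutation(T)
    return [perm[i * batch_size:(i + 1) * batch_size] for i in range(n_batches)]


# ---------------------------------------------------------------------------
# forward / backward machinery (x layouts are batch x features)

def _bn_forward_train(x, run_mean, run_var):
    mu = x.mean(axis=0)
    var = x.var(axis=0)
    inv = 1.0 / np.sqrt(var + _BN_EPS)
    xhat = (x - mu) * inv
    run_mean *= 1.0 - _BN_MOMENTUM
    run_mean += _BN_MOMENTUM * mu
    run_var *= 1.0 - _BN_MOMENTUM
    run_var += _BN_MOMENTUM * var
    return xhat, (x, mu, inv)


def _bn_backward(dxhat, cache):
    x, mu, inv = cache
    B = x.shape[0]
    xc = x - mu
    dvar = np.sum(dxhat * xc, axis=0) * (-0.5) * inv**3
    dmu = -inv * np.sum(dxhat, axis=0)
    return dxhat * inv + dvar * 2.0 * xc / B + dmu / B


def _forward_train(net: NNArtifact, x: np.ndarray):
    """Forward pass in training mode; returns output and caches."""
    spec = net.spec
    caches = []
    if spec.kind == "standard":
        h = x
        for i, (W, b) in enumerate(zip(net.weights, net.biases)):
            if spec.batch_norm:
                h_in, bn_cache = _bn_forward_train(h, net.bn_mean[i], net.bn_var[i])
            else:
                h_in, bn_cache = h, None
            caches.append((h_in, bn_cache))
            h = h_in @ W.T + b
        return h, caches
    # dense
    hs = []
    for i, (W, b) in enumerate(zip(net.weights, net.biases)):
        inp = np.concatenate([x] + hs[: i], axis=1) if i > 0 else x
        if i == len(net.weights) - 1:
            inp = np.concatenate([x] + hs, axis=1)
        if spec.batch_norm:
            h_in, bn_cache = _bn_forward_train(inp, net.bn_mean[i], net.bn_var[i])
        else:
            h_in, bn_cache = inp, None
        caches.append((h_in, bn_cache))
        out = h_in @ W.T + b
        if i < len(net.weights) - 1:
            hs.append(out)
    return out, caches


def _backward(net: NNArtifact, caches, dout):
    """Gradients of the loss w.r.t. every weight and bias."""
    spec = net.spec
    n_layers = len(net.weights)
    dW = [None] * n_layers
    db = [None] * n_layers
    if spec.kind == "standard":
        d = dout
        for i in range(n_layers - 1, -1, -1):
            h_in, bn_cache = caches[i]
            dW[i] = d.T @ h_in
            db[i] = d.sum(axis=0)
            d_in = d @ net.weights[i]
            if bn_cache is not None:
                d_in = _bn_backward(d_in, bn_cache)
            d = d_in
        return dW, db
    # dense: accumulate gradients flowing into each hidden output and into x
    nx = spec.input_dim
    h = spec.hidden_units
    dh = [np.zeros((dout.shape[0], h)) for _ in range(n_layers - 1)]

    def split(d_concat, n_hidden_blocks, i_layer):
        # layer i's input = [x | h_1 ... h_{n_hidden_blocks}]
        for j in range(n_hidden_blocks):
            dh[j] += d_concat[:, nx + j * h: nx + (j + 1) * h]

    # output layer first
    h_in, bn_cache = caches[-1]
    dW[-1] = dout.T @ h_in
    db[-1] = dout.sum(axis=0)
    d_in = dout @ net.weights[-1]
    if bn_cache is not None:
        d_in = _bn_backward(d_in, bn_cache)
    split(d_in, n_layers - 1, n_layers - 1)
    # hidden layers in reverse
    for i in range(n_layers - 2, -1, -1):
        d = dh[i]
        h_in, bn_cache = caches[i]
        dW[i] = d.T @ h_in
        db[i] = d.sum(axis=0)
        d_in = d @ net.weights[i]
        if bn_cache is not None:
            d_in = _bn_backward(d_in, bn_cache)
        split(d_in, i, i)
    return dW, db


def _epoch_seed(base_seed: int, epoch: int) -> int:
    # documented derivation: a fixed multiplicative hash, kept below 2**31
    return int((base_seed * 2654435761 + epoch) % (2**31))


def train_network(
    net: NNArtifact, X_train: np.ndarray, Y_train: np.ndarray, cfg: TrainingConfig
) -> NNArtifact:
    """Train a copy of ``net`` by SGD on MSE; the input artifact is untouched.

    ``X_train``/``Y_train`` are voxels x timepoints. Per epoch, batches come
    from :func:`sample_batch_schedule`; the loss history records the mean
    batch MSE per epoch. A non-finite loss aborts with a diagnostic (usually
    the learning rate is too large for unnormalized inputs).
    """
    X_train = np.atleast_2d(np.asarray(X_train, float))
    Y_train = np.atleast_2d(np.asarray(Y_train, float))
    if X_train.shape[1] != Y_train.shape[1]:
        raise ValueError("X_train and Y_train must share timepoints (columns)")
    if X_train.shape[0] != net.spec.input_dim or Y_train.shape[0] != net.spec.output_dim:
        raise ValueError(
            f"data dims ({X_train.shape[0]} -> {Y_train.shape[0]}) do not match "
            f"spec ({net.spec.input_dim} -> {net.spec.output_dim})"
        )
    out = net.copy()
    if cfg.epochs == 0:
        return out
    T = X_train.shape[1]
    Xs, Ys = X_train.T, Y_train.T  # batch-major
    vel_W = [np.zeros_like(w) for w in out.weights]
    vel_b = [np.zeros_like(b) for b in out.biases]
    out.loss_history = []
    for epoch in range(cfg.epochs):
        batches = sample_batch_schedule(
            T, cfg.batch_size, _epoch_seed(cfg.seed, epoch),
            with_replacement=cfg.sample_with_replacement,
        )
        epoch_losses = []
        for idx in batches:
            xb, yb = Xs[idx], Ys[idx]
            yhat, caches = _forward_train(out, xb)
            resid = yhat - yb
            with np.errstate(over="ignore"):  # inf loss is caught below
                loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    f"try a smaller learning rate (current {cfg.learning_rate}) "
                    f"or enable batch normalization"
                )
            epoch_losses.append(loss)
            # sum over voxels, mean over batch timepoints (see module docs)
            dout = 2.0 * resid / resid.shape[0]
            dW, db = _backward(out, caches, dout)
            for i in range(len(out.weights)):
                gw = dW[i] + cfg.weight_decay * out.weights[i]
                gb = db[i] + cfg.weight_decay * out.biases[i]
                vel_W[i] = cfg.momentum * vel_W[i] + gw
                vel_b[i] = cfg.momentum * vel_b[i] + gb
                out.weights[i] -= cfg.learning_rate * vel_W[i]
                out.biases[i] -= cfg.learning_rate * vel_b[i]
        out.loss_history.append(float(np.mean(epoch_losses)))
    out.trained = True
    return out


def predict_network(net: NNArtifact, X_test: np.ndarray) -> np.ndarray:
    """Deterministic forward pass in evaluation mode.

    Batch normalization uses the frozen running statistics, so each column's
    prediction is independent of the other columns in the call. Raises if
    the network uses BN but has never been trained (running statistics would
    be meaningless).
    """
    X_test = np.atleast_2d(np.asarray(X_test, float))
    if X_test.shape[0] != net.spec.input_dim:
        raise ValueError(
            f"predictor has {X_test.shape[0]} rows, spec expects {net.spec.input_dim}"
        )
    if net.spec.batch_norm and not net.trained:
        raise RuntimeError(
            "network has batch normalization but was never trained; "
            "running statistics are uninitialized"
        )
    x = X_test.T
    spec = net.spec

    def bn_eval(v, i):
        if not spec.batch_norm:
            return v
        return (v - net.bn_mean[i]) / np.sqrt(net.bn_var[i] + _BN_EPS)

    if spec.kind == "standard":
        h = x
        for i, (W, b) in enumerate(zip(net.weights, net.biases)):
            h = bn_eval(h, i) @ W.T + b
        return h.T
    hs = []
    for i, (W, b) in enumerate(zip(net.weights, net.biases)):
        if i == len(net.weights) - 1:
            inp = np.concatenate([x] + hs, axis=1)
        else:
            inp = np.concatenate([x] + hs[: i], axis=1) if i > 0 else x
        out = bn_eval(inp, i) @ W.T + b
        if i < len(net.weights) - 1:
            hs.append(out)
    return out.T
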