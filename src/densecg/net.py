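"""The dense (fully connected) rhythm classifier.

Architecture: a batch-normalization layer over the raw feature inputs,
up to three hidden dense layers with ReLU activation and (train-time)
inverted dropout, and a 4-node softmax output over the rhythm classes
(N, AF, O, X).  Training minimizes weighted categorical cross-entropy

    Loss = -(1/N) sum_i ClassWeights(C_{y_i}) * log P_{i,y_i}

with mini-batch Adam, uniform random weight initialization, and early
stopping on the monitored loss; the parameter snapshot with minimal
monitored loss is returned.

All linear algebra is plain NumPy; gradients are computed analytically
(they are verified against central finite differences in the test
suite).  The trainable-parameter count of a topology with D dense layers
and ``NodesBN`` batch-normalized inputs is

    Params = 2*NodesBN + sum_{i=1..D} Nodes_i * (Nodes_{i-1} + 1).
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from densecg.errors import FormatError, InvalidSpecError, ShapeError
from densecg.types import CLASSES

__all__ = [
    "CLASSES", "BN_EPS", "BN_MOMENTUM",
    "Topology", "BNParams", "DenseParams", "TrainingConfig", "TrainedModel",
    "ForwardResult", "param_count", "forward", "loss", "loss_and_gradients",
    "train", "predict", "save_model", "load_model",
]

BN_EPS = 1e-3        # variance floor inside the BN scale factor
BN_MOMENTUM = 0.99   # EMA momentum of the running BN statistics
PROB_FLOOR = 1e-12   # clip for log-probabilities in the loss


@dataclass(frozen=True)
class Topology:
    """Layer widths of a DenseNet-D model (D = hidden layers + output)."""

    n_inputs: int
    hidden_widths: tuple = ()
    n_classes: int = 4

    def __post_init__(self):
        object.__setattr__(self, "hidden_widths",
                           tuple(int(w) for w in self.hidden_widths))
        if self.n_inputs < 1 or self.n_classes < 1:
            raise InvalidSpecError("layer widths must be >= 1")
        if any(w < 1 for w in self.hidden_widths):
            raise InvalidSpecError("hidden widths must be >= 1")
        if not 1 <= self.depth <= 4:
            raise InvalidSpecError("1 to 4 dense layers supported")

    @property
    def depth(self) -> int:
        """Total number of dense layers D, output layer included."""
        return len(self.hidden_widths) + 1

    @property
    def widths(self) -> tuple:
        """Full width chain: input, hidden..., output."""
        return (self.n_inputs, *self.hidden_widths, self.n_classes)

    def __str__(self):
        return "DenseNet-{}@{}".format(
            self.depth, "-".join(str(w) for w in self.widths[1:]))


def param_count(topology: Topology) -> int:
    """Trainable parameters: 2 per BN input + weights and biases per layer."""
    w = topology.widths
    return 2 * topology.n_inputs + sum(
        w[i + 1] * (w[i] + 1) for i in range(topology.depth))


@dataclass
class BNParams:
    gamma: np.ndarray
    beta: np.ndarray
    mean: np.ndarray   # running mean used at inference
    var: np.ndarray    # running variance used at inference

    def __post_init__(self):
        for name in ("gamma", "beta", "mean", "var"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.var < 0):
            raise InvalidSpecError("running variance must be >= 0")


@dataclass
class DenseParams:
    W: list
    b: list

    def __post_init__(self):
        self.W = [np.asarray(w, dtype=float) for w in self.W]
        self.b = [np.asarray(x, dtype=float) for x in self.b]


@dataclass
class TrainedModel:
    topology: Topology
    bn: BNParams
    dense: DenseParams
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        w = self.topology.widths
        if len(self.dense.W) != self.topology.depth:
            raise ShapeError("number of weight matrices != topology depth")
        for i, (Wi, bi) in enumerate(zip(self.dense.W, self.dense.b)):
            if Wi.shape != (w[i], w[i + 1]) or bi.shape != (w[i + 1],):
                raise ShapeError(
                    f"layer {i + 1}: W{Wi.shape}/b{bi.shape} inconsistent "
                    f"with widths {w}")
        for arr in (self.bn.gamma, self.bn.beta, self.bn.mean, self.bn.var):
            if arr.shape != (self.topology.n_inputs,):
                raise ShapeError("BN parameter length != n_inputs")

    def n_params(self) -> int:
        """Literal number of scalars in (gamma, beta, all W_i, all b_i)."""
        return (self.bn.gamma.size + self.bn.beta.size
                + sum(w.size for w in self.dense.W)
                + sum(b.size for b in self.dense.b))


@dataclass
class TrainingConfig:
    class_weights: tuple = (0.25, 0.25, 0.25, 0.25)
    batch_size: int = 128
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    dropout_rate: float = 0.3
    patience: int = 10
    max_epochs: int = 200
    seed: int = 0
    init_bound: float = 0.05  # uniform initializer bounds +-init_bound

    def __post_init__(self):
        cw = np.asarray(self.class_weights, dtype=float)
        if np.any(cw < 0) or abs(cw.sum() - 1.0) > 1e-8:
            raise InvalidSpecError("class weights must be >= 0 and sum to 1")
        if not 0 <= self.dropout_rate < 1:
            raise InvalidSpecError("dropout rate must lie in [0, 1)")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise InvalidSpecError("batch size and epochs must be >= 1")


@dataclass
class ForwardResult:
    z: np.ndarray            # BN outputs (the network's receptive field)
    hidden: list             # post-activation maps per hidden layer
    logits: np.ndarray
    probs: np.ndarray
    activations: list        # Boolean ReLU masks (pre-activation > 0)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _bn_apply(bn: BNParams, X, mean, var):
    xhat = (X - mean) / np.sqrt(var + BN_EPS)
    return bn.gamma * xhat + bn.beta, xhat


def forward(model: TrainedModel, X, mode: str = "infer",
            dropout_rate: float = 0.0, dropout_masks=None,
            rng: np.random.Generator | None = None) -> ForwardResult:
    """Run the network on a batch (or single vector) of features.

    ``mode='train'`` standardizes with the statistics of the given batch
    and applies inverted dropout (if a positive rate and masks or an rng
    are supplied); ``mode='infer'`` uses the stored running statistics
    and no dropout.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    single = X.shape[0] == 1
    if X.shape[1] != model.topology.n_inputs:
        raise ShapeError(f"expected {model.topology.n_inputs} features, "
                         f"got {X.shape[1]}")
    if mode not in ("train", "infer"):
        raise InvalidSpecError("mode must be 'train' or 'infer'")

    if mode == "train":
        mean, var = X.mean(axis=0), X.var(axis=0)
    else:
        mean, var = model.bn.mean, model.bn.var
    z, _ = _bn_apply(model.bn, X, mean, var)

    a = z
    hidden, masks = [], []
    n_hidden = model.topology.depth - 1
    for l in range(n_hidden):
        s = a @ model.dense.W[l] + model.dense.b[l]
        masks.append(s > 0)
        h = np.where(s > 0, s, 0.0)
        if mode == "train" and dropout_rate > 0:
            if dropout_masks is not None:
                dm = dropout_masks[l]
            elif rng is not None:
                dm = rng.random(h.shape) >= dropout_rate
            else:
                dm = np.ones_like(h, dtype=bool)
            h = h * dm / (1.0 - dropout_rate)
        hidden.append(h)
        a = h
    logits = a @ model.dense.W[-1] + model.dense.b[-1]
    probs = _softmax(logits)

    if single:
        return ForwardResult(z[0], [h[0] for h in hidden], logits[0], probs[0],
                             [m[0] for m in masks])
    return ForwardResult(z, hidden, logits, probs, masks)


def _label_indices(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "iu":
        return labels.astype(int)
    lut = {c: i for i, c in enumerate(CLASSES)}
    try:
        return np.array([lut[str(x)] for x in labels])
    except KeyError as exc:
        raise InvalidSpecError(f"unknown class label {exc.args[0]!r}") from exc


def loss(probs, labels, class_weights) -> float:
    """Weighted categorical cross-entropy of a batch of probabilities."""
    cw = np.asarray(class_weights, dtype=float)
    if np.any(cw < 0) or abs(cw.sum() - 1.0) > 1e-8:
        raise InvalidSpecError("class weights must be >= 0 and sum to 1")
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    y = _label_indices(labels)
    p_true = probs[np.arange(len(y)), y]
    if np.any(p_true < PROB_FLOOR):
        warnings.warn("true-class probability clipped at 1e-12 in loss",
                      RuntimeWarning, stacklevel=2)
        p_true = np.clip(p_true, PROB_FLOOR, None)
    return float(-(cw[y] * np.log(p_true)).mean())


def loss_and_gradients(model: TrainedModel, X, labels, class_weights,
                       bn_mode: str = "batch", dropout_masks=None,
                       dropout_rate: float = 0.0):
    """Analytic loss and gradients w.r.t. every trainable parameter.

    ``bn_mode='batch'`` uses the batch statistics of ``X`` (training
    behaviour); ``'running'`` uses the stored statistics.  Gradients are
    returned as a dict with keys ``gamma``, ``beta``, ``W`` (list) and
    ``b`` (list).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = _label_indices(labels)
    cw = np.asarray(class_weights, dtype=float)
    n = X.shape[0]
    n_hidden = model.topology.depth - 1

    if bn_mode == "batch":
        mean, var = X.mean(axis=0), X.var(axis=0)
    else:
        mean, var = model.bn.mean, model.bn.var
    z, xhat = _bn_apply(model.bn, X, mean, var)

    a = z
    acts = [z]        # inputs to each dense layer
    pre = []          # pre-activations of hidden layers
    scales = []       # dropout scale masks applied to each hidden output
    for l in range(n_hidden):
        s = a @ model.dense.W[l] + model.dense.b[l]
        pre.append(s)
        h = np.where(s > 0, s, 0.0)
        if dropout_rate > 0 and dropout_masks is not None:
            sc = dropout_masks[l] / (1.0 - dropout_rate)
        else:
            sc = np.ones_like(h)
        scales.append(sc)
        h = h * sc
        acts.append(h)
        a = h
    logits = a @ model.dense.W[-1] + model.dense.b[-1]
    probs = _softmax(logits)

    p_true = np.clip(probs[np.arange(n), y], PROB_FLOOR, None)
    L = float(-(cw[y] * np.log(p_true)).mean())

    G = probs.copy()
    G[np.arange(n), y] -= 1.0
    G *= cw[y][:, None] / n

    gW = [None] * (n_hidden + 1)
    gb = [None] * (n_hidden + 1)
    for l in range(n_hidden, -1, -1):
        gW[l] = acts[l].T @ G
        gb[l] = G.sum(axis=0)
        if l > 0:
            G = (G @ model.dense.W[l].T) * scales[l - 1] * (pre[l - 1] > 0)
    dz = G @ model.dense.W[0].T  # back through the first dense layer to z
    grads = {
        "gamma": (dz * xhat).sum(axis=0),
        "beta": dz.sum(axis=0),
        "W": gW,
        "b": gb,
    }
    return L, grads, probs


def _init_model(topology: Topology, config: TrainingConfig,
                rng: np.random.Generator) -> TrainedModel:
    w = topology.widths
    W = [rng.uniform(-config.init_bound, config.init_bound, size=(w[i], w[i + 1]))
         for i in range(topology.depth)]
    b = [np.zeros(w[i + 1]) for i in range(topology.depth)]
    bn = BNParams(gamma=np.ones(w[0]), beta=np.zeros(w[0]),
                  mean=np.zeros(w[0]), var=np.ones(w[0]))
    return TrainedModel(topology, bn, DenseParams(W, b),
                        meta={"seed": config.seed})


def train(X, labels, topology: Topology, config: TrainingConfig,
          X_val=None, labels_val=None):
    """Fit the classifier with mini-batch Adam and early stopping.

    The monitored loss is the validation loss when a validation set is
    supplied, else the (inference-mode) training loss.  The parameter
    snapshot with minimal monitored loss over all epochs is returned,
    together with the per-epoch loss history.
    """
    X = np.asarray(X, dtype=float)
    y = _label_indices(labels)
    if len(np.unique(y)) < 2:
        raise InvalidSpecError("training labels must contain >= 2 classes")
    if X_val is not None:
        X_val = np.asarray(X_val, dtype=float)
        y_val = _label_indices(labels_val)

    rng = np.random.default_rng(config.seed)
    model = _init_model(topology, config, rng)
    cw = np.asarray(config.class_weights, dtype=float)
    n = X.shape[0]
    bs = min(config.batch_size, n)

    # Adam state, one slot per parameter array
    def zeros_like_params():
        return {
            "gamma": np.zeros_like(model.bn.gamma),
            "beta": np.zeros_like(model.bn.beta),
            "W": [np.zeros_like(w) for w in model.dense.W],
            "b": [np.zeros_like(b) for b in model.dense.b],
        }

    m_t, v_t = zeros_like_params(), zeros_like_params()
    step = 0

    def adam_update(param, grad, m, v):
        nonlocal step
        m *= config.beta1
        m += (1 - config.beta1) * grad
        v *= config.beta2
        v += (1 - config.beta2) * grad ** 2
        mhat = m / (1 - config.beta1 ** step)
        vhat = v / (1 - config.beta2 ** step)
        param -= config.learning_rate * mhat / (np.sqrt(vhat) + 1e-8)

    best_loss = np.inf
    best_state = None
    best_epoch = -1
    history = []
    mom = BN_MOMENTUM

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            Xb, yb = X[idx], y[idx]
            if len(idx) < 2:
                continue  # batch statistics undefined for a single sample
            mu, var = Xb.mean(axis=0), Xb.var(axis=0)
            model.bn.mean = mom * model.bn.mean + (1 - mom) * mu
            model.bn.var = mom * model.bn.var + (1 - mom) * var
            dm = None
            if config.dropout_rate > 0:
                dm = [rng.random((len(idx), w)) >= config.dropout_rate
                      for w in topology.hidden_widths]
            L, grads, _ = loss_and_gradients(
                model, Xb, yb, cw, bn_mode="batch",
                dropout_masks=dm, dropout_rate=config.dropout_rate)
            if not np.isfinite(L):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: lr or data degenerate")
            step += 1
            adam_update(model.bn.gamma, grads["gamma"], m_t["gamma"], v_t["gamma"])
            adam_update(model.bn.beta, grads["beta"], m_t["beta"], v_t["beta"])
            for l in range(topology.depth):
                adam_update(model.dense.W[l], grads["W"][l], m_t["W"][l], v_t["W"][l])
                adam_update(model.dense.b[l], grads["b"][l], m_t["b"][l], v_t["b"][l])

        if X_val is not None:
            res = forward(model, X_val, mode="infer")
            monitored = loss(res.probs, y_val, cw)
        else:
            res = forward(model, X, mode="infer")
            monitored = loss(res.probs, y, cw)
        history.append(monitored)
        if monitored < best_loss - 1e-12:
            best_loss = monitored
            best_epoch = epoch
            best_state = (copy.deepcopy(model.bn), copy.deepcopy(model.dense))
        if epoch - best_epoch > config.patience:
            break

    bn, dense = best_state
    out = TrainedModel(topology, bn, dense, meta={
        "epochs_run": len(history),
        "best_epoch": int(best_epoch),
        "best_loss": float(best_loss),
        "seed": int(config.seed),
    })
    return out, history


def predict(model: TrainedModel, X):
    """Class labels (argmax probability; ties -> lowest class index) and probs."""
    res = forward(model, np.atleast_2d(np.asarray(X, dtype=float)), mode="infer")
    probs = np.atleast_2d(res.probs)
    idx = probs.argmax(axis=1)  # argmax returns the first maximum on ties
    labels = np.array([CLASSES[i] for i in idx], dtype=object)
    return labels, probs


def save_model(model: TrainedModel, path) -> None:
    """Persist all parameters, topology and meta to an HDF5 container."""
    with h5py.File(path, "w") as f:
        g = f.create_group("bn")
        g.create_dataset("gamma", data=model.bn.gamma)
        g.create_dataset("beta", data=model.bn.beta)
        g.create_dataset("mean", data=model.bn.mean)
        g.create_dataset("var", data=model.bn.var)
        for i, (W, b) in enumerate(zip(model.dense.W, model.dense.b), start=1):
            g = f.create_group(f"dense{i}")
            g.create_dataset("W", data=W)
            g.create_dataset("b", data=b)
        f.attrs["topology"] = json.dumps({
            "n_inputs": model.topology.n_inputs,
            "hidden_widths": list(model.topology.hidden_widths),
            "n_classes": model.topology.n_classes,
        })
        f.attrs["meta"] = json.dumps(model.meta)


def load_model(path) -> TrainedModel:
    """Load a model saved by :func:`save_model`; validates the shape chain."""
    try:
        with h5py.File(path, "r") as f:
            topo_d = json.loads(f.attrs["topology"])
            meta = json.loads(f.attrs["meta"])
            topo = Topology(topo_d["n_inputs"], tuple(topo_d["hidden_widths"]),
                            topo_d["n_classes"])
            bn = BNParams(f["bn/gamma"][()], f["bn/beta"][()],
                          f["bn/mean"][()], f["bn/var"][()])
            W, b = [], []
            for i in range(1, topo.depth + 1):
                W.append(f[f"dense{i}/W"][()])
                b.append(f[f"dense{i}/b"][()])
    except (OSError, KeyError) as exc:
        raise FormatError(f"cannot read model container {path}: {exc}") from exc
    try:
        return TrainedModel(topo, bn, DenseParams(W, b), meta=meta)
    except ShapeError as exc:
        raise FormatError(f"model container {path} is inconsistent: {exc}") from exc
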