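"""Connection-weights feature importance for the dense classifier.

The importance of input feature ``F_i`` for output class ``C_j`` is the
sum over every input-to-output path of the product of the weights along
that path — a chained matrix product ``W1 @ W2 @ ... @ WD``.  Because the
hidden neurons are ReLU units, a path only transmits when its neurons are
active, so the case-level variant masks each hidden factor with the
Boolean activation state of the input at hand,

    W1 @ diag(a1) @ W2 @ diag(a2) @ ... @ WD,

which is exactly the local linearization (Jacobian of the logits with
respect to the batch-normalized inputs) of the ReLU network.  The global
variant replaces the Boolean masks by their per-neuron medians over a
dataset (values 0, 0.5 or 1).  Signs are preserved and nothing is
rescaled; the relative variant normalizes each class column so the
strongest feature scores +-1.

Rankings aggregate the mean absolute global importance over any number
of trained models (e.g. all folds of repeated cross-validation), summed
over classes (a cumulative global-weights importance, ``cumGWI``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from densecg.errors import InvalidSpecError, ShapeError
from densecg.net import TrainedModel, forward

__all__ = [
    "ImportanceMatrix", "FeatureRanking",
    "connection_weights", "activation_state", "case_weights_importance",
    "median_activation", "global_weights_importance",
    "relative_feature_importance", "case_feature_importance",
    "rank_by_cum_gwi", "reduce_feature_set",
]


@dataclass
class ImportanceMatrix:
    """Signed (n_features x n_classes) importance scores."""

    values: np.ndarray
    kind: str  # connection | case_weights | global_weights | relative | case_feature
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError("importance values must be 2-D")


@dataclass
class FeatureRanking:
    """Feature indices (0-based) ordered by descending score."""

    indices: np.ndarray
    scores: np.ndarray
    score_kind: str = "cumGWI"

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)


def _masked_product(model: TrainedModel, masks=None) -> np.ndarray:
    """W1 @ diag(m1) @ W2 @ ... @ WD with optional per-hidden-layer factors."""
    W = model.dense.W
    out = W[0]
    for l in range(1, len(W)):
        if masks is not None:
            out = out * np.asarray(masks[l - 1], dtype=float)
        out = out @ W[l]
    return out


def connection_weights(model: TrainedModel) -> ImportanceMatrix:
    """Path-sum importance ignoring activations (all paths transmit)."""
    return ImportanceMatrix(_masked_product(model), "connection",
                            {"model": model.meta.get("seed")})


def activation_state(model: TrainedModel, x) -> list:
    """Boolean ReLU masks per hidden layer for one input (inference mode)."""
    return forward(model, x, mode="infer").activations


def case_weights_importance(model: TrainedModel, x) -> ImportanceMatrix:
    """Activation-masked path sum for one input.

    Equals the Jacobian d(logit_j)/d(z_i) of the ReLU network at ``x``
    whenever no pre-activation sits exactly at zero.
    """
    masks = activation_state(model, x)
    return ImportanceMatrix(_masked_product(model, masks), "case_weights",
                            {"model": model.meta.get("seed")})


def median_activation(model: TrainedModel, X) -> list:
    """Per-neuron median of the Boolean activation masks over a dataset."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise InvalidSpecError("median_activation requires a non-empty dataset")
    res = forward(model, X, mode="infer")
    return [np.median(m.astype(float), axis=0) for m in res.activations]


def global_weights_importance(model: TrainedModel, X) -> ImportanceMatrix:
    """Path sum with each hidden factor weighted by its median activation."""
    med = median_activation(model, X)
    return ImportanceMatrix(_masked_product(model, med), "global_weights",
                            {"model": model.meta.get("seed"), "n": int(np.atleast_2d(X).shape[0])})


def relative_feature_importance(gwi: ImportanceMatrix) -> ImportanceMatrix:
    """Normalize each class column so its strongest feature scores +-1."""
    if gwi.kind != "global_weights":
        raise InvalidSpecError("relative importance is defined on global weights")
    vals = gwi.values.copy()
    for j in range(vals.shape[1]):
        m = np.max(np.abs(vals[:, j]))
        if m == 0:
            warnings.warn(f"class column {j} is identically zero",
                          RuntimeWarning, stacklevel=2)
        else:
            vals[:, j] /= m
    return ImportanceMatrix(vals, "relative", dict(gwi.provenance))


def case_feature_importance(model: TrainedModel, x) -> ImportanceMatrix:
    """Receptive-field-scaled case importance for one input.

    The batch-normalized input value plays the role of the local
    receptive field: importance(F_i, C_j) = z_i * case_weights(F_i, C_j).
    A positive score marks a feature pushing the sample toward the class,
    a negative score one pushing it away.
    """
    z = forward(model, x, mode="infer").z
    cwi = case_weights_importance(model, x)
    return ImportanceMatrix(np.asarray(z)[:, None] * cwi.values, "case_feature",
                            dict(cwi.provenance))


def rank_by_cum_gwi(gwi_list) -> FeatureRanking:
    """Rank features by class-cumulative mean absolute importance.

    ``score(F_i) = sum_j mean_over_runs |GWI(F_i, C_j)|`` with runs being
    however many importance matrices are supplied (e.g. one per trained
    cross-validation model).  Ties break toward the lower feature index.
    """
    if len(gwi_list) == 0:
        raise InvalidSpecError("need at least one importance matrix")
    mats = [np.abs(np.asarray(g.values if isinstance(g, ImportanceMatrix) else g,
                              dtype=float)) for g in gwi_list]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ShapeError("importance matrices differ in shape")
    mean_abs = np.mean(mats, axis=0)          # features x classes
    scores = mean_abs.sum(axis=1)             # cumulative over classes
    order = np.lexsort((np.arange(len(scores)), -scores))
    return FeatureRanking(order, scores[order], "cumGWI")


def reduce_feature_set(ranking: FeatureRanking, k: int) -> np.ndarray:
    """The top-k ranked feature indices (0-based), rank order preserved."""
    if k < 1:
        raise InvalidSpecError("k must be >= 1")
    if k > len(ranking.indices):
        raise InvalidSpecError("k exceeds the number of ranked features")
    return ranking.indices[:k].copy()
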