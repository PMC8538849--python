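"""Performance metrics, stratified cross-validation and grid searches.

The headline score is the Challenge-style total F1: the unweighted mean
of the per-class F1 over the three rhythm classes N, AF and O.  The
Noise class (X) is excluded from the average because of its small
prevalence, but all four classes keep full per-class precision, recall
and accuracy reports.

Cross-validation splits are stratified: within each class the records
are shuffled by seed and dealt round-robin over the k folds, so
per-class fold sizes differ by at most one record with the larger folds
first — a deterministic remainder pattern that makes fold contents
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np

from densecg.errors import InvalidSpecError
from densecg.net import (CLASSES, Topology, TrainingConfig, predict, train)

__all__ = [
    "ConfusionMatrix4", "MetricsReport", "CVSplit", "CVResult",
    "GridSearchResult", "confusion_matrix", "per_class_metrics",
    "challenge_f1", "stratified_kfold", "run_cv",
    "enumerate_architectures", "class_weight_grid", "grid_search",
]


@dataclass
class ConfusionMatrix4:
    """4x4 tally; rows = true class, columns = predicted, order N/AF/O/X."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (4, 4) or np.any(self.counts < 0):
            raise InvalidSpecError("confusion matrix must be 4x4 non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other):
        return ConfusionMatrix4(self.counts + other.counts)


@dataclass
class MetricsReport:
    """Per-class and total classification metrics.

    Per-class F1 is unitless in [0, 1]; precision/recall/accuracy are
    percentages.  ``f1_total`` is the Challenge mean over N, AF, O.
    Because no single convention pins down a "total" precision/recall,
    three labeled aggregates are reported (macro over 4 classes, macro
    over the 3 rhythm classes, support-weighted).
    """

    f1: dict
    precision_pct: dict
    recall_pct: dict
    accuracy_pct: dict
    f1_total: float
    acc_total_pct: float
    aggregates: dict = field(default_factory=dict)


def confusion_matrix(y_true, y_pred) -> ConfusionMatrix4:
    """Tally counts[t][p] = #(true == t and predicted == p)."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise InvalidSpecError("label arrays must have equal length")
    lut = {c: i for i, c in enumerate(CLASSES)}
    cm = np.zeros((4, 4), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in lut or p not in lut:
            raise InvalidSpecError(f"unknown label {t!r}/{p!r}")
        cm[lut[t], lut[p]] += 1
    return ConfusionMatrix4(cm)


def _tp_fn_fp_tn(cm: np.ndarray, i: int):
    tp = cm[i, i]
    fn = cm[i].sum() - tp
    fp = cm[:, i].sum() - tp
    tn = cm.sum() - tp - fn - fp
    return tp, fn, fp, tn


def per_class_metrics(cm: ConfusionMatrix4) -> MetricsReport:
    """F1, precision, recall, accuracy per class and total aggregates."""
    if cm.total == 0:
        raise InvalidSpecError("empty confusion matrix")
    c = cm.counts
    f1, prec, rec, acc = {}, {}, {}, {}
    for i, name in enumerate(CLASSES):
        tp, fn, fp, tn = _tp_fn_fp_tn(c, i)
        denom = 2 * tp + fn + fp
        f1[name] = 2 * tp / denom if denom else np.nan
        prec[name] = 100.0 * tp / (tp + fp) if (tp + fp) else np.nan
        rec[name] = 100.0 * tp / (tp + fn) if (tp + fn) else np.nan
        acc[name] = 100.0 * (tp + tn) / cm.total
    support = c.sum(axis=1)
    with np.errstate(invalid="ignore"):
        aggregates = {
            "prec_macro4": float(np.nanmean([prec[k] for k in CLASSES])),
            "prec_macro3": float(np.nanmean([prec[k] for k in ("N", "AF", "O")])),
            "prec_weighted": float(np.nansum(
                [prec[k] * support[i] for i, k in enumerate(CLASSES)]) / support.sum()),
            "recall_macro4": float(np.nanmean([rec[k] for k in CLASSES])),
            "recall_macro3": float(np.nanmean([rec[k] for k in ("N", "AF", "O")])),
            "recall_weighted": float(np.nansum(
                [rec[k] * support[i] for i, k in enumerate(CLASSES)]) / support.sum()),
        }
    return MetricsReport(
        f1=f1, precision_pct=prec, recall_pct=rec, accuracy_pct=acc,
        f1_total=challenge_f1(cm),
        acc_total_pct=100.0 * np.trace(c) / cm.total,
        aggregates=aggregates,
    )


def challenge_f1(cm: ConfusionMatrix4) -> float:
    """Mean per-class F1 over N, AF and O (Noise excluded), unrounded."""
    if cm.total == 0:
        raise InvalidSpecError("empty confusion matrix")
    vals = []
    for i in (0, 1, 2):
        tp, fn, fp, _ = _tp_fn_fp_tn(cm.counts, i)
        denom = 2 * tp + fn + fp
        vals.append(2 * tp / denom if denom else np.nan)
    return float(np.mean(vals))


@dataclass
class CVSplit:
    """Fold assignment (0..k-1) per record."""

    fold: np.ndarray
    k: int
    seed: int

    def train_val(self, f: int):
        val = np.where(self.fold == f)[0]
        trn = np.where(self.fold != f)[0]
        return trn, val


def stratified_kfold(labels, k: int, seed: int = 0) -> CVSplit:
    """Deal each class round-robin over k folds after a seeded shuffle.

    Fold sizes within a class differ by at most one, with the larger
    folds first (fold 0 gets the first remainder record, and so on).
    """
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    if k < 2:
        raise InvalidSpecError("k must be >= 2")
    if k > n:
        raise InvalidSpecError("k exceeds the number of records")
    rng = np.random.default_rng(seed)
    fold = np.full(n, -1, dtype=int)
    for c in dict.fromkeys(labels):  # preserves first-appearance order
        idx = np.where(labels == c)[0]
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % k
    return CVSplit(fold, k, seed)


@dataclass
class CVResult:
    pooled_cm: ConfusionMatrix4
    mean_report: MetricsReport
    fold_f1: list          # per (run, fold) Challenge F1
    models: list           # every trained model, for importance aggregation
    per_run_f1: list       # pooled Challenge F1 per run


def run_cv(X, labels, topology: Topology, config: TrainingConfig,
           k: int = 5, n_runs: int = 1) -> CVResult:
    """Repeated stratified k-fold cross-validation.

    Each run re-splits with a run-specific seed, trains on k-1 folds with
    the held-out fold as validation (also used for early stopping), and
    pools the held-out predictions.  All trained models are retained so
    importance statistics can aggregate over runs x folds.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object)
    pooled = ConfusionMatrix4(np.zeros((4, 4), dtype=int))
    fold_f1, models, per_run = [], [], []
    for r in range(n_runs):
        run_seed = config.seed + 1000 * r
        split = stratified_kfold(labels, k, seed=run_seed)
        run_cm = ConfusionMatrix4(np.zeros((4, 4), dtype=int))
        for f in range(k):
            trn, val = split.train_val(f)
            cfg = TrainingConfig(**{**config.__dict__,
                                    "seed": run_seed + f})
            model, _ = train(X[trn], labels[trn], topology, cfg,
                             X_val=X[val], labels_val=labels[val])
            pred, _ = predict(model, X[val])
            cm = confusion_matrix(labels[val], pred)
            run_cm = run_cm + cm
            pooled = pooled + cm
            fold_f1.append(challenge_f1(cm))
            models.append(model)
        per_run.append(challenge_f1(run_cm))
    return CVResult(pooled, per_class_metrics(pooled), fold_f1, models, per_run)


def enumerate_architectures(width_choices, max_depth: int = 4,
                            n_inputs: int = 137, n_classes: int = 4):
    """All topologies with 1..max_depth dense layers and non-increasing
    hidden widths drawn from ``width_choices``."""
    if len(width_choices) == 0:
        raise InvalidSpecError("width_choices must be non-empty")
    widths = sorted(set(int(w) for w in width_choices), reverse=True)
    topologies = []
    for h in range(0, max_depth):  # number of hidden layers
        for combo in combinations_with_replacement(widths, h):
            topologies.append(Topology(n_inputs, tuple(combo), n_classes))
    return topologies


def class_weight_grid(step: float = 0.05, w_max: float = 0.5):
    """All (W_N, W_AF, W_O, W_X) with the first three on the grid
    {0, step, ..., w_max}, summing with W_X to 1, and W_X in [0, w_max]."""
    n_steps = int(round(w_max / step))
    grid = [round(i * step, 10) for i in range(n_steps + 1)]
    out = []
    for wn in grid:
        for wa in grid:
            for wo in grid:
                wx = 1.0 - wn - wa - wo
                if -1e-9 <= wx <= w_max + 1e-9:
                    out.append((wn, wa, wo, max(wx, 0.0)))
    return out


@dataclass
class GridSearchResult:
    axis: str
    entries: list       # dicts: setting, mean_f1, fold_f1 or error
    best: dict


def grid_search(X, labels, axis: str, values, topology: Topology,
                config: TrainingConfig, k: int = 5, n_runs: int = 1) -> GridSearchResult:
    """Sweep one hyperparameter axis with cross-validated Challenge F1.

    ``axis`` is one of architecture, class_weights, batch_size,
    learning_rate; ``values`` the settings to try.  Training failures are
    recorded per setting without aborting the sweep.
    """
    if axis not in ("architecture", "class_weights", "batch_size", "learning_rate"):
        raise InvalidSpecError(f"unknown grid axis {axis!r}")
    entries = []
    for v in values:
        topo = topology
        cfg_kwargs = dict(config.__dict__)
        if axis == "architecture":
            topo = v if isinstance(v, Topology) else Topology(
                topology.n_inputs, tuple(v), topology.n_classes)
        elif axis == "class_weights":
            cfg_kwargs["class_weights"] = tuple(v)
        elif axis == "batch_size":
            cfg_kwargs["batch_size"] = int(v)
        else:
            cfg_kwargs["learning_rate"] = float(v)
        cfg = TrainingConfig(**cfg_kwargs)
        try:
            res = run_cv(X, labels, topo, cfg, k=k, n_runs=n_runs)
            entries.append({"setting": v, "mean_f1": float(np.mean(res.per_run_f1)),
                            "fold_f1": list(res.fold_f1)})
        except (FloatingPointError, InvalidSpecError) as exc:
            entries.append({"setting": v, "mean_f1": np.nan, "error": str(exc)})
    ok = [e for e in entries if np.isfinite(e.get("mean_f1", np.nan))]
    if not ok:
        raise InvalidSpecError("every grid setting failed")
    best = max(ok, key=lambda e: e["mean_f1"])
    return GridSearchResult(axis, entries, best)
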