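"""Repeated stratified-split training and evaluation protocol.

Datasets are partitioned 7:2:1 (train:validation:test) by stratified
sampling; each of the 10 repeats uses a fresh seed controlling the
split, parameter initialization, batch shuffling, and dropout. Models
are optimized with Adam on categorical cross-entropy, early-stopped on
validation loss (patience 20, strict improvement), restored to the best
checkpoint, and scored by per-class precision / recall / F1 plus
accuracy on all three subsets. Repeats aggregate as mean +/- sample SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import GraspClassifier, NetworkConfig, build_model
from .preprocess import ModelInput
from .simulate import FROST, NORMAL
from . import nn

__all__ = [
    "SplitPlan",
    "TrainingConfig",
    "RunResult",
    "AggregateReport",
    "stratified_split",
    "train_run",
    "compute_metrics",
    "repeat_protocol",
    "aggregate_results",
    "stack_inputs",
]

CLASS_NAMES = (NORMAL, FROST)
SUBSETS = ("train", "val", "test")
METRIC_NAMES = ("precision", "recall", "f1")


@dataclass
class SplitPlan:
    seed: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)

    def subsets(self):
        return {"train": self.train_idx, "val": self.val_idx,
                "test": self.test_idx}


@dataclass
class TrainingConfig:
    learning_rate: float = 0.001
    batch_size: int = 16
    max_epochs: int = 300
    patience: int = 20
    restore_best: bool = True
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.max_epochs,
               self.patience) <= 0:
            raise ValueError("training settings must be positive")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass
class RunResult:
    seed: int
    kind: str
    train_loss_history: list[float]
    val_loss_history: list[float]
    best_epoch: int
    best_val_loss: float
    confusions: dict          # subset -> 2x2 nested list, rows = true class
    metrics: dict             # subset -> {accuracy, per_class: {...}}
    n_params: int
    stopped_epoch: int

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "kind": self.kind,
            "train_loss_history": self.train_loss_history,
            "val_loss_history": self.val_loss_history,
            "best_epoch": self.best_epoch,
            "best_val_loss": self.best_val_loss,
            "confusions": self.confusions, "metrics": self.metrics,
            "n_params": self.n_params, "stopped_epoch": self.stopped_epoch,
        }

    @staticmethod
    def from_dict(d: dict) -> "RunResult":
        return RunResult(**d)


@dataclass
class AggregateReport:
    """kind -> subset -> {accuracy: {mean, sd}, per_class: {...}}."""

    n_repeats: int
    seeds: list[int]
    table: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"n_repeats": self.n_repeats, "seeds": self.seeds,
                "table": self.table}


def stratified_split(labels, ratios=(0.7, 0.2, 0.1), seed: int = 0) -> SplitPlan:
    """Per-class shuffled 7:2:1 assignment, floor allocation with
    largest-remainder top-up; deterministic per seed."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    parts: dict[str, list[int]] = {"train": [], "val": [], "test": []}
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        if len(idx) < 10:
            raise ValueError("need at least 10 samples per class")
        idx = rng.permutation(idx)
        exact = np.array(ratios) * len(idx)
        counts = np.floor(exact).astype(int)
        rem = len(idx) - counts.sum()
        order = np.argsort(-(exact - counts), kind="stable")
        for j in order[:rem]:
            counts[j] += 1
        a, b = counts[0], counts[0] + counts[1]
        parts["train"].extend(idx[:a])
        parts["val"].extend(idx[a:b])
        parts["test"].extend(idx[b:])
    return SplitPlan(seed=seed,
                     train_idx=np.sort(np.array(parts["train"])),
                     val_idx=np.sort(np.array(parts["val"])),
                     test_idx=np.sort(np.array(parts["test"])),
                     ratios=tuple(ratios))


def stack_inputs(inputs: list[ModelInput]):
    """Assemble (P, V, Y) arrays from a list of model inputs."""
    P = np.stack([m.pressure_seq for m in inputs])
    V = np.stack([m.vibration_seq for m in inputs])
    Y = np.stack([m.label_onehot for m in inputs])
    return P, V, Y


def compute_metrics(confusion) -> dict:
    """Per-class one-vs-rest precision / recall / F1 plus accuracy.

    ``confusion`` is a 2x2 count matrix, rows = true class, columns =
    predicted class, class order (normal, frost_damaged). Zero
    denominators yield 0 and set the ``degenerate`` flag.
    """
    cm = np.asarray(confusion, dtype=float)
    if cm.shape != (2, 2) or (cm < 0).any():
        raise ValueError("confusion must be a non-negative 2x2 matrix")
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zero")
    out = {"accuracy": float(np.trace(cm) / total), "per_class": {},
           "degenerate": False}
    for c, name in enumerate(CLASS_NAMES):
        tp = cm[c, c]
        fp = cm[1 - c, c]
        fn = cm[c, 1 - c]
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = (2 * prec * rec / (prec + rec)) if prec + rec > 0 else 0.0
        if tp + fp == 0 or tp + fn == 0 or prec + rec == 0:
            out["degenerate"] = True
        out["per_class"][name] = {"precision": float(prec),
                                  "recall": float(rec), "f1": float(f1)}
    return out


def _confusion(model: GraspClassifier, P, V, Y, idx) -> np.ndarray:
    args = {"P": P[idx] if "P" in model.required else None,
            "V": V[idx] if "V" in model.required else None}
    proba = model.predict_proba(**args)
    pred = proba.argmax(axis=1)
    true = Y[idx].argmax(axis=1)
    cm = np.zeros((2, 2), dtype=int)
    for t, p in zip(true, pred):
        cm[t, p] += 1
    return cm


def _mean_loss(model: GraspClassifier, P, V, Y, idx) -> float:
    args = {"P": P[idx] if "P" in model.required else None,
            "V": V[idx] if "V" in model.required else None}
    return float(model.loss(Y[idx], train=False, **args).data)


def train_run(kind: str, inputs: list[ModelInput], plan: SplitPlan,
              tcfg: TrainingConfig, ncfg: NetworkConfig | None = None,
              return_model: bool = False):
    """Train one model on one split and score it on all three subsets."""
    for name, idx in plan.subsets().items():
        if len(idx) == 0:
            raise ValueError(f"empty {name} subset")
    P, V, Y = stack_inputs(inputs)
    model = build_model(kind, ncfg, seed=tcfg.seed)
    opt = nn.Adam(model.params(), lr=tcfg.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([tcfg.seed, 1]))

    train_idx = plan.train_idx
    train_hist, val_hist = [], []
    best_val = np.inf
    best_epoch = -1
    best_state = model.get_state()
    waited = 0
    for epoch in range(tcfg.max_epochs):
        order = rng.permutation(train_idx)
        for s in range(0, len(order), tcfg.batch_size):
            batch = order[s:s + tcfg.batch_size]
            args = {"P": P[batch] if "P" in model.required else None,
                    "V": V[batch] if "V" in model.required else None}
            loss = model.loss(Y[batch], train=True, rng=rng, **args)
            opt.zero_grad()
            loss.backward()
            opt.step()
        train_hist.append(_mean_loss(model, P, V, Y, train_idx))
        val_loss = _mean_loss(model, P, V, Y, plan.val_idx)
        val_hist.append(val_loss)
        if val_loss < best_val:   # strict improvement resets patience
            best_val = val_loss
            best_epoch = epoch
            best_state = model.get_state()
            waited = 0
        else:
            waited += 1
            if waited >= tcfg.patience:
                break
    if tcfg.restore_best:
        model.set_state(best_state)

    confusions, metrics = {}, {}
    for name, idx in plan.subsets().items():
        cm = _confusion(model, P, V, Y, idx)
        confusions[name] = cm.tolist()
        metrics[name] = compute_metrics(cm)
    result = RunResult(
        seed=tcfg.seed, kind=kind,
        train_loss_history=train_hist, val_loss_history=val_hist,
        best_epoch=best_epoch, best_val_loss=float(best_val),
        confusions=confusions, metrics=metrics,
        n_params=model.n_params, stopped_epoch=len(val_hist) - 1,
    )
    return (result, model) if return_model else result


def aggregate_results(results: dict[str, list[RunResult]]) -> AggregateReport:
    """Mean and sample SD of every metric over the repeats, per kind,
    subset, and class. Recomputable exactly from the stored RunResults."""
    any_runs = next(iter(results.values()))
    if len(any_runs) < 2:
        raise ValueError("need at least 2 repeats for a sample SD")
    table: dict = {}
    for kind, runs in results.items():
        table[kind] = {}
        for subset in SUBSETS:
            acc = np.array([r.metrics[subset]["accuracy"] for r in runs])
            entry = {"accuracy": {"mean": float(acc.mean()),
                                  "sd": float(acc.std(ddof=1))}}
            for cls in CLASS_NAMES:
                entry[cls] = {}
                for m in METRIC_NAMES:
                    vals = np.array(
                        [r.metrics[subset]["per_class"][cls][m] for r in runs])
                    entry[cls][m] = {"mean": float(vals.mean()),
                                     "sd": float(vals.std(ddof=1))}
            table[kind][subset] = entry
    return AggregateReport(n_repeats=len(any_runs),
                           seeds=[r.seed for r in any_runs], table=table)


def repeat_protocol(kinds, inputs: list[ModelInput], n_repeats: int = 10,
                    base_seed: int = 0,
                    tcfg: TrainingConfig | None = None,
                    ncfg: NetworkConfig | None = None,
                    keep_models: bool = False):
    """Run the full repeated-split protocol for several model kinds.

    For each repeat, a fresh stratified split and fresh initialization
    are drawn from ``base_seed + repeat``; all kinds share the identical
    split and preprocessing per repeat. Returns ``(results, report)``
    where results maps kind -> list of RunResult (and, if requested,
    ``models`` maps kind -> list of trained models).
    """
    if n_repeats < 2:
        raise ValueError("need at least 2 repeats for a sample SD")
    tcfg = tcfg or TrainingConfig()
    labels = [m.label for m in inputs]
    results: dict[str, list[RunResult]] = {k: [] for k in kinds}
    models: dict[str, list] = {k: [] for k in kinds}
    for r in range(n_repeats):
        seed = base_seed + r
        plan = stratified_split(labels, seed=seed)
        run_tcfg = TrainingConfig(
            learning_rate=tcfg.learning_rate, batch_size=tcfg.batch_size,
            max_epochs=tcfg.max_epochs, patience=tcfg.patience,
            restore_best=tcfg.restore_best, seed=seed)
        for kind in kinds:
            res, model = train_run(kind, inputs, plan, run_tcfg, ncfg,
                                   return_model=True)
            results[kind].append(res)
            if keep_models:
                models[kind].append(model)
    report = aggregate_results(results)
    if keep_models:
        return results, report, models
    return results, report
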