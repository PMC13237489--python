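"""Cross-validated training, evaluation metrics, and hyperparameter search.

Training follows the recipe used for every architecture variant: focal loss
with per-fold inverse-frequency class weights, Adam/AdamW, a 5-step linear
learning-rate warm-up followed by 0.95 exponential decay per optimizer
step, early stopping on validation Macro-F1 with patience 5, stratified
5-fold cross-validation, and mean-per-fold metric reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn import metrics as skm
from sklearn.model_selection import StratifiedKFold

from .embeddings import ResidueEmbedding, pad_batch
from .model import (ActivityClassifier, ActivityLabel, Ensemble, ModelConfig,
                    TrainingCriterion, softmax_focal_loss)
from .nn import Adam, lr_at_step

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "MetricReport",
    "HyperparameterSpace",
    "stratified_kfold",
    "inverse_frequency_weights",
    "train_fold",
    "cross_validate",
    "compute_metrics",
    "search_hyperparameters",
    "rank_correlations",
]


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 2e-4
    weight_decay: float = 2e-5
    optimizer_kind: str = "adam"      # {"adam", "adamw"}
    batch_size: int = 16
    max_epochs: int = 50
    patience: int = 5
    min_epochs: int = 1
    n_restarts: int = 1
    restart_threshold: float = 0.0
    warmup_steps: int = 5
    decay_per_step: float = 0.95
    schedule_unit: str = "epoch"      # {"step", "epoch"}; see methods note
    seed: int = 0

    def __post_init__(self):
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.optimizer_kind not in ("adam", "adamw"):
            raise ValueError(f"unknown optimizer {self.optimizer_kind!r}")
        if self.schedule_unit not in ("step", "epoch"):
            raise ValueError(f"unknown schedule_unit {self.schedule_unit!r}")


@dataclass
class MetricReport:
    accuracy: float
    balanced_accuracy: float
    macro_f1: float
    mcc: float
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)
    n_rejected: int = 0


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> np.ndarray:
    """Per-record fold ids (0..k-1); per-class counts differ by <= 1."""
    y = np.asarray([int(v) for v in labels])
    classes, counts = np.unique(y, return_counts=True)
    for c, n in zip(classes, counts):
        if n < k:
            raise ValueError(
                f"class {ActivityLabel(c).name} has only {n} members, "
                f"fewer than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    for i, (_, val_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        folds[val_idx] = i
    return folds


def inverse_frequency_weights(labels, n_classes: int = 3) -> np.ndarray:
    """Per-fold group weights: inverse class frequency, normalized to mean 1."""
    y = np.asarray([int(v) for v in labels])
    counts = np.bincount(y, minlength=n_classes).astype(float)
    counts[counts == 0] = np.inf  # absent classes get zero weight
    w = 1.0 / counts
    return w / w[np.isfinite(w)].mean() if np.isfinite(w).any() else w


@dataclass
class TrainResult:
    model: ActivityClassifier
    best_val_macro_f1: float
    best_epoch: int
    history: list[dict]


def _macro_f1_argmax(model: ActivityClassifier, x, mask, y) -> float:
    pred = np.argmax(model.predict_proba(x, mask), axis=-1)
    return float(skm.f1_score(y, pred, average="macro", zero_division=0.0))


def train_fold(train_embeddings: list[ResidueEmbedding], train_labels,
               val_embeddings: list[ResidueEmbedding], val_labels,
               model_config: ModelConfig, training_config: TrainingConfig,
               criterion: TrainingCriterion = TrainingCriterion()) -> TrainResult:
    """Train one fold with early stopping on validation Macro-F1.

    Returns the checkpoint of the best validation epoch; training halts when
    the validation Macro-F1 has not improved for ``patience`` epochs.

    Multi-start: when ``n_restarts`` > 1 the fold is retrained from fresh
    seeds while the best validation Macro-F1 stays below
    ``restart_threshold`` (validation-based acceptance, the same pattern as
    multi-start clustering or curve fitting), and the best run is returned.
    """
    tc = training_config
    best: TrainResult | None = None
    for restart in range(max(1, tc.n_restarts)):
        run_tc = replace(tc, n_restarts=1, seed=tc.seed + 1000 * restart)
        result = _train_fold_once(train_embeddings, train_labels,
                                  val_embeddings, val_labels,
                                  model_config, run_tc, criterion)
        if best is None or result.best_val_macro_f1 > best.best_val_macro_f1:
            best = result
        if best.best_val_macro_f1 >= tc.restart_threshold:
            break
        if restart + 1 < max(1, tc.n_restarts):
            logger.info("restarting fold training (val Macro-F1 %.3f below "
                        "threshold %.2f)", best.best_val_macro_f1,
                        tc.restart_threshold)
    return best


def _train_fold_once(train_embeddings, train_labels, val_embeddings,
                     val_labels, model_config, training_config,
                     criterion) -> TrainResult:
    if len(train_embeddings) == 0:
        raise ValueError("empty training split")
    tc = training_config
    ytr = np.asarray([int(v) for v in train_labels])
    yval = np.asarray([int(v) for v in val_labels])
    weights = (np.asarray(criterion.class_weights)
               if criterion.class_weights is not None
               else inverse_frequency_weights(ytr))

    model = ActivityClassifier(model_config, seed=tc.seed)
    opt = Adam(model.parameters(), lr=tc.learning_rate,
               weight_decay=tc.weight_decay,
               decoupled=(tc.optimizer_kind == "adamw"))
    rng = np.random.default_rng(tc.seed)
    xval, mval = pad_batch(val_embeddings)

    best_f1, best_epoch, best_weights = -np.inf, -1, model.get_weights()
    history: list[dict] = []
    step = 0
    for epoch in range(tc.max_epochs):
        order = rng.permutation(len(train_embeddings))
        losses = []
        for start in range(0, len(order), tc.batch_size):
            idx = order[start:start + tc.batch_size]
            x, mask = pad_batch([train_embeddings[i] for i in idx])
            step += 1
            if tc.schedule_unit == "step":
                lr = lr_at_step(step, tc.learning_rate,
                                tc.warmup_steps, tc.decay_per_step)
            else:
                # warm up over the first optimizer steps, decay per epoch
                ramp = min(1.0, step / tc.warmup_steps)
                lr = tc.learning_rate * ramp * tc.decay_per_step ** epoch
            logits = model.forward(x, mask, train=True)
            loss, dlogits = softmax_focal_loss(
                logits, ytr[idx], gamma=criterion.gamma, class_weights=weights)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step(lr=lr)
            losses.append(loss)
        val_f1 = _macro_f1_argmax(model, xval, mval, yval)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_macro_f1": val_f1, "lr": lr})
        if val_f1 > best_f1:
            best_f1, best_epoch = val_f1, epoch
            best_weights = model.get_weights()
        elif epoch - best_epoch >= tc.patience and epoch + 1 >= tc.min_epochs:
            break
    model.set_weights(best_weights)
    return TrainResult(model=model, best_val_macro_f1=best_f1,
                       best_epoch=best_epoch, history=history)


@dataclass
class CVResult:
    fold_reports: list[MetricReport]
    fold_models: list[ActivityClassifier]
    folds: np.ndarray

    @property
    def mean_macro_f1(self) -> float:
        return float(np.mean([r.macro_f1 for r in self.fold_reports]))

    @property
    def mean_mcc(self) -> float:
        return float(np.mean([r.mcc for r in self.fold_reports]))

    @property
    def ensemble(self) -> Ensemble:
        return Ensemble(self.fold_models)


def cross_validate(embeddings: list[ResidueEmbedding], labels,
                   model_config: ModelConfig, training_config: TrainingConfig,
                   k: int = 5,
                   criterion: TrainingCriterion = TrainingCriterion()) -> CVResult:
    """Stratified k-fold cross-validation; returns per-fold reports + models."""
    y = np.asarray([int(v) for v in labels])
    folds = stratified_kfold(y, k=k, seed=training_config.seed)
    reports, models = [], []
    for f in range(k):
        tr = np.flatnonzero(folds != f)
        va = np.flatnonzero(folds == f)
        res = train_fold([embeddings[i] for i in tr], y[tr],
                         [embeddings[i] for i in va], y[va],
                         model_config, training_config, criterion)
        xva, mva = pad_batch([embeddings[i] for i in va])
        pred = np.argmax(res.model.predict_proba(xva, mva), axis=-1)
        reports.append(compute_metrics(pred, y[va]))
        models.append(res.model)
        logger.info("fold %d: macro-F1 %.4f (best epoch %d)",
                    f, reports[-1].macro_f1, res.best_epoch)
    return CVResult(fold_reports=reports, fold_models=models, folds=folds)


def compute_metrics(predictions, truth) -> MetricReport:
    """Standard classification metrics; rejected predictions are excluded."""
    pred = np.asarray([int(v) for v in predictions])
    y = np.asarray([int(v) for v in truth])
    if len(pred) != len(y):
        raise ValueError("predictions and truth differ in length")
    if np.any(y == ActivityLabel.REJECTED):
        raise ValueError("ground truth may not contain the REJECTED label")
    keep = pred != ActivityLabel.REJECTED
    n_rejected = int((~keep).sum())
    if n_rejected:
        logger.info("excluding %d rejected predictions from metrics", n_rejected)
    pred, y = pred[keep], y[keep]
    classes = sorted(set(y) | set(pred))
    prec, rec, f1, _ = skm.precision_recall_fscore_support(
        y, pred, labels=classes, zero_division=0.0)
    per_class = {
        ActivityLabel(c).name: {"precision": float(p), "recall": float(r),
                                "f1": float(f)}
        for c, p, r, f in zip(classes, prec, rec, f1)
    }
    return MetricReport(
        accuracy=float(skm.accuracy_score(y, pred)),
        balanced_accuracy=float(skm.balanced_accuracy_score(y, pred)),
        macro_f1=float(skm.f1_score(y, pred, average="macro", zero_division=0.0)),
        mcc=float(skm.matthews_corrcoef(y, pred)),
        per_class=per_class,
        n_rejected=n_rejected,
    )


@dataclass(frozen=True)
class HyperparameterSpace:
    """The search space: block depth, LR, dropout, weight decay, heads,
    optimizer, and the high-activity decision threshold."""

    num_blocks: tuple[int, int] = (4, 10)
    learning_rate: tuple[float, float] = (1e-5, 5e-3)
    dropout: tuple[float, float] = (0.1, 0.7)
    weight_decay: tuple[float, float] = (1e-6, 1e-2)
    n_heads: tuple[int, ...] = (4, 8, 16)
    optimizer: tuple[str, ...] = ("adam", "adamw")
    tau_high: tuple[float, float] = (0.3, 0.9)

    def sample(self, rng: np.random.Generator) -> dict:
        log_u = lambda lo, hi: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        return {
            "num_blocks": int(rng.integers(self.num_blocks[0],
                                           self.num_blocks[1] + 1)),
            "learning_rate": log_u(*self.learning_rate),
            "dropout": float(rng.uniform(*self.dropout)),
            "weight_decay": log_u(*self.weight_decay),
            "n_heads": int(rng.choice(self.n_heads)),
            "optimizer": str(rng.choice(self.optimizer)),
            "tau_high": float(rng.uniform(*self.tau_high)),
        }


def search_hyperparameters(space: HyperparameterSpace, budget: int, objective,
                           seed: int = 0) -> tuple[dict, list[dict]]:
    """Seeded random search maximizing the objective (mean CV Macro-F1).

    Returns ``(best_config, trial_log)``; a trial whose objective raises is
    marked failed and the search continues.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    log: list[dict] = []
    best_cfg, best_score = None, -np.inf
    for trial in range(budget):
        cfg = space.sample(rng)
        entry = {"trial": trial, **cfg}
        try:
            score = float(objective(cfg))
            entry["score"] = score
            entry["status"] = "ok"
            if score > best_score:
                best_cfg, best_score = cfg, score
        except Exception as exc:  # noqa: BLE001 - any trial failure is logged
            entry["score"] = float("nan")
            entry["status"] = f"failed: {exc}"
            logger.warning("trial %d failed: %s", trial, exc)
        log.append(entry)
    if best_cfg is None:
        raise RuntimeError("every trial failed")
    return best_cfg, log


def rank_correlations(scores, gold) -> tuple[float, float]:
    """Spearman's rho and Kendall's tau with midrank ties.

    Constant inputs have no defined rank correlation and return NaN.
    """
    s = np.asarray(scores, dtype=float)
    g = np.asarray(gold, dtype=float)
    if len(s) != len(g) or len(s) < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.ptp(s) == 0 or np.ptp(g) == 0:
        return float("nan"), float("nan")
    rho = stats.spearmanr(s, g).statistic
    tau = stats.kendalltau(s, g).statistic
    return float(rho), float(tau)
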