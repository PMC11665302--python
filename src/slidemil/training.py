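"""Training and evaluation protocol for the MIL models.

The protocol: split slides 80/20 into train/test (label-stratified), run
5-fold cross-validation on the training set, keep the model from the
best-validation fold, and score it on the held-out test set; repeat over
several split seeds and report mean +/- std of the test AUCs.

Models are trained with binary cross-entropy on the positive-class
probability of the two-class softmax head, one bag per optimization step
(bags have variable instance counts), using Adam. Gradients of the small
attention scorer and affine head are computed in closed form, so training is
exact and bit-reproducible for a given seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .bags import Bag
from .models import (
    MILModel,
    activation_grad,
    attention_normalize,
    build_model,
    forward,
    softmax,
)

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Protocol and optimizer settings.

    ``split_seed`` seeds the train/test split of the first replicate;
    replicate ``r`` uses ``split_seed + r`` so replicate seeds are distinct.
    """

    variant: str = "amil"
    split_seed: int = 0
    train_fraction: float = 0.8
    n_folds: int = 5
    n_replicates: int = 5
    D: int = 128
    C: int = 2
    learning_rate: float = 1e-4
    weight_decay: float = 0.0
    epochs: int = 30
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    fold_selection: str = "auc"  # or "loss"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.fold_selection not in ("auc", "loss"):
            raise ValueError("fold_selection must be 'auc' or 'loss'")


@dataclass
class FoldResult:
    model: MILModel
    loss_trace: list[float]
    val_auc: float | None
    val_loss: float | None
    n_train: int = 0
    n_val: int = 0


@dataclass
class CVResult:
    fold_results: list[FoldResult]
    best_fold_index: int

    @property
    def best_model(self) -> MILModel:
        return self.fold_results[self.best_fold_index].model


@dataclass
class ReplicateResult:
    """Per-replicate test AUCs of the best-fold models, with summary stats."""

    aucs: list[float]
    seeds: list[int]
    best_fold_indices: list[int]
    models: list[MILModel] | None = None
    test_sets: list[list[Bag]] | None = None

    @property
    def mean(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def std(self) -> float:
        return float(np.std(self.aucs))


def split_dataset(bags: list[Bag], seed: int) -> tuple[list[Bag], list[Bag]]:
    """Label-stratified 80/20 partition with |train| = round(0.8 N) exactly.

    Per-class train counts are allocated by largest remainder so the global
    count matches the rounded target while keeping class balance.
    """
    return _split_dataset(bags, seed, 0.8)


def _split_dataset(
    bags: list[Bag], seed: int, train_fraction: float
) -> tuple[list[Bag], list[Bag]]:
    if len(bags) < 5:
        raise ValueError(f"need at least 5 bags to split, got {len(bags)}")
    labels = np.array([b.label for b in bags])
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("cannot stratify: only one class present")
    n_train = int(round(train_fraction * len(bags)))
    rng = np.random.default_rng(seed)

    per_class_idx = {c: np.flatnonzero(labels == c) for c in classes}
    if any(len(ix) < 2 for ix in per_class_idx.values()):
        raise ValueError("too few bags of one class to stratify the split")
    # largest-remainder apportionment of the train quota across classes
    quotas = {c: train_fraction * len(ix) for c, ix in per_class_idx.items()}
    take = {c: int(np.floor(q)) for c, q in quotas.items()}
    remainder_order = sorted(
        classes, key=lambda c: (-(quotas[c] - take[c]), c)
    )
    i = 0
    while sum(take.values()) < n_train:
        take[remainder_order[i % len(classes)]] += 1
        i += 1
    while sum(take.values()) > n_train:
        take[remainder_order[-(1 + i % len(classes))]] -= 1
        i += 1

    train_idx: list[int] = []
    for c in classes:
        perm = rng.permutation(per_class_idx[c])
        train_idx.extend(perm[: take[c]].tolist())
    train_set = set(train_idx)
    train = [bags[i] for i in sorted(train_set)]
    test = [bags[i] for i in range(len(bags)) if i not in train_set]
    return train, test


def bag_loss(model: MILModel, bag: Bag) -> float:
    """Binary cross-entropy of the bag's positive-class probability."""
    pred = forward(bag, model)
    p = float(pred.class_probabilities[bag.label])
    return -float(np.log(max(p, 1e-12)))


def _backward(model: MILModel, bag: Bag) -> tuple[float, dict[str, np.ndarray]]:
    """One-bag loss and exact gradients for all four parameter arrays.

    Closed-form backprop through head, instance softmax and the two-layer
    attention scorer. For additive variants the bag logits are
    ``W z + n b`` with ``z = sum_i a_i h_i``, so the only difference from
    attention pooling is the bias gradient scaled by ``n``.
    """
    H = bag.instances  # (n, d)
    n = H.shape[0]
    A = model.attention
    t = H @ A.V.T  # (n, D) pre-activation
    if A.activation == "tanh":
        u = np.tanh(t)
    else:
        u = np.where(t > 0, t, np.float32(0.01) * t)
    s = u @ A.w  # (n,) attention logits
    a = attention_normalize(s)  # (n,)
    z = a @ H  # (d,)
    if model.is_additive:
        logits = model.W @ z + n * model.b
    else:
        logits = model.W @ z + model.b
    p = softmax(logits)
    loss = -float(np.log(max(float(p[bag.label]), 1e-12)))

    dlogits = p.astype(np.float64)
    dlogits[bag.label] -= 1.0
    dlogits = dlogits.astype(np.float32)
    dW = np.outer(dlogits, z)
    db = (n * dlogits) if model.is_additive else dlogits
    dz = model.W.T @ dlogits  # (d,)
    da = H @ dz  # (n,)
    ds = a * (da - float(a @ da))  # softmax Jacobian product
    dw = u.T @ ds  # (D,)
    du = np.outer(ds, A.w)  # (n, D)
    dt = du * activation_grad(t, A.activation)
    dV = dt.T @ H  # (D, d)
    return loss, {"V": dV, "w": dw, "W": dW, "b": db}


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], cfg: ExperimentConfig):
        self.cfg = cfg
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        c = self.cfg
        self.t += 1
        b1t = 1.0 - c.adam_beta1**self.t
        b2t = 1.0 - c.adam_beta2**self.t
        for k, p in params.items():
            g = grads[k]
            if c.weight_decay:
                g = g + c.weight_decay * p
            self.m[k] = c.adam_beta1 * self.m[k] + (1 - c.adam_beta1) * g
            self.v[k] = c.adam_beta2 * self.v[k] + (1 - c.adam_beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p -= (c.learning_rate * mhat / (np.sqrt(vhat) + c.adam_eps)).astype(
                p.dtype
            )


def train_fold(
    train_bags: list[Bag],
    val_bags: list[Bag],
    config: ExperimentConfig,
    seed: int = 0,
) -> FoldResult:
    """Fit one model on ``train_bags``; validate on ``val_bags`` if non-empty.

    ``seed`` controls both weight initialization and the per-epoch shuffling
    of bag order; two calls with identical inputs produce bit-identical loss
    traces and parameters.
    """
    if not train_bags:
        raise ValueError("empty training set")
    labels = {b.label for b in train_bags}
    if labels != {0, 1}:
        raise ValueError("training set must contain both classes")
    d = train_bags[0].d
    model = build_model(config.variant, d=d, seed=seed, D=config.D, C=config.C)
    params = model.parameters()
    opt = _Adam(params, config)
    rng = np.random.default_rng(seed + 1)
    trace: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(len(train_bags))
        epoch_loss = 0.0
        for i in order:
            loss, grads = _backward(model, train_bags[i])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss during training (variant={config.variant}, "
                    f"epoch {len(trace)}, bag index {i})"
                )
            opt.step(params, grads)
            epoch_loss += loss
        trace.append(epoch_loss / len(train_bags))
    val_auc = None
    val_loss = None
    if val_bags:
        val_loss = float(np.mean([bag_loss(model, b) for b in val_bags]))
        if len({b.label for b in val_bags}) == 2:
            val_auc = evaluate_auc(model, val_bags)
        else:
            warnings.warn(
                "validation fold contains a single class; AUC undefined",
                stacklevel=2,
            )
    return FoldResult(
        model=model, loss_trace=trace, val_auc=val_auc, val_loss=val_loss,
        n_train=len(train_bags), n_val=len(val_bags),
    )


def predict_scores(model: MILModel, bags: list[Bag]) -> np.ndarray:
    """Positive-class probability for each bag."""
    return np.array(
        [float(forward(b, model).class_probabilities[1]) for b in bags]
    )


def evaluate_auc(model_or_scores, bags: list[Bag]) -> float:
    """Test-set AUROC of the positive-class probabilities.

    Tie-aware rank-based AUC (trapezoidal ROC integration), i.e. the
    Mann-Whitney U statistic normalized by n_pos * n_neg with ties at half
    credit.
    """
    labels = np.array([b.label for b in bags])
    if np.unique(labels).size < 2:
        raise ValueError("AUC undefined: bags contain a single class")
    if isinstance(model_or_scores, MILModel):
        scores = predict_scores(model_or_scores, bags)
    else:
        scores = np.asarray(model_or_scores, dtype=float)
    return float(roc_auc_score(labels, scores))


def cross_validate(
    train: list[Bag], config: ExperimentConfig, seed: int = 0
) -> CVResult:
    """Stratified k-fold CV; the best fold is the argmax of validation AUC.

    Ties break toward the lowest fold index. Folds whose validation split
    contains one class have no AUC and are excluded from the argmax (with a
    warning); ``fold_selection='loss'`` uses minimum validation loss instead.
    """
    if len(train) < config.n_folds:
        raise ValueError(
            f"{len(train)} training bags cannot form {config.n_folds} folds"
        )
    labels = np.array([b.label for b in train])
    counts = np.bincount(labels, minlength=2)
    if counts.min() >= config.n_folds:
        skf = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=seed
        )
    else:
        warnings.warn(
            "too few bags per class to stratify folds; using plain k-fold"
        )
        skf = KFold(n_splits=config.n_folds, shuffle=True, random_state=seed)
    fold_results: list[FoldResult] = []
    for fold, (tr_idx, va_idx) in enumerate(skf.split(np.zeros(len(train)), labels)):
        res = train_fold(
            [train[i] for i in tr_idx],
            [train[i] for i in va_idx],
            config,
            seed=seed * 1000 + fold,
        )
        fold_results.append(res)
    if config.fold_selection == "auc":
        crit = [
            (-np.inf if r.val_auc is None else r.val_auc) for r in fold_results
        ]
        if all(c == -np.inf for c in crit):
            warnings.warn("no fold had a defined validation AUC; using fold 0")
            best = 0
        else:
            best = int(np.argmax(crit))
    else:
        crit = [np.inf if r.val_loss is None else r.val_loss for r in fold_results]
        best = int(np.argmin(crit))
    return CVResult(fold_results=fold_results, best_fold_index=best)


def run_replicates(
    bags: list[Bag],
    config: ExperimentConfig,
    keep_models: bool = False,
) -> ReplicateResult:
    """Full protocol: replicated split -> CV -> best-fold test evaluation."""
    aucs: list[float] = []
    seeds: list[int] = []
    best_folds: list[int] = []
    models: list[MILModel] = []
    test_sets: list[list[Bag]] = []
    for r in range(config.n_replicates):
        seed_r = config.split_seed + r
        train, test = _split_dataset(bags, seed_r, config.train_fraction)
        cv = cross_validate(train, config, seed=seed_r)
        auc = evaluate_auc(cv.best_model, test)
        aucs.append(auc)
        seeds.append(seed_r)
        best_folds.append(cv.best_fold_index)
        if keep_models:
            models.append(cv.best_model)
            test_sets.append(test)
        logger.info(
            "replicate %d (seed %d): best fold %d, test AUC %.4f",
            r, seed_r, cv.best_fold_index, auc,
        )
    return ReplicateResult(
        aucs=aucs,
        seeds=seeds,
        best_fold_indices=best_folds,
        models=models if keep_models else None,
        test_sets=test_sets if keep_models else None,
    )


def attention_entropy(attention: np.ndarray, normalized: bool = True) -> float:
    """Shannon entropy of an attention distribution (nats).

    With ``normalized=True`` the entropy is divided by ``ln n`` so bags of
    different sizes are comparable; a uniform distribution scores 1.
    """
    a = np.asarray(attention, dtype=float)
    a = a[a > 0]
    h = float(-(a * np.log(a)).sum())
    if normalized and a.size > 1:
        h /= np.log(len(attention))
    return h
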