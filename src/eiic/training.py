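"""Two-phase optimization: contrastive prior learning, then transfer.

Phase 1 (prior learning) draws mini-batches of *subject pairs* from the pool
of all unordered pairs of the training set, reshuffled every epoch.  Pairs
with the same diagnosis label contribute the IIC loss at the two-class head
and at the overclustering head; pairs with different labels contribute the
IIC loss at the two-class head against the complemented second output.  The
epoch ends when a full mini-batch can no longer be extracted (the partial
remainder is discarded), and one weight update per mini-batch is one
iteration.

Phase 2 (transfer learning) freezes the trunk and fits only the classifier
head's linear map with cross-entropy over subject mini-batches.

Both phases early-stop on a validation loss — the summed pair loss over a
fixed, seeded validation pair set in phase 1, mean cross-entropy in phase 2 —
and return the parameters of the best validation epoch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import FeatureVector, stack_features
from .losses import _iic_pair_loss_grads, cross_entropy
from .network import Adam, EiicModel, softmax_backward

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "PairedBatch",
    "PairPool",
    "make_pair_pool",
    "next_minibatch",
    "train_prior",
    "train_transfer",
    "train_supervised",
]


@dataclass
class TrainConfig:
    batch_size: int = 500
    learning_rate: float = 1e-4
    patience: int = 10
    max_epochs: int = 200
    lambda_weight: float = 5.0
    seed: int = 0
    #: validation pairs are subsampled to at most this many (fixed per fold)
    val_pair_cap: int = 2000
    #: subject mini-batch size in the transfer phase; None -> min(batch_size, n)
    transfer_batch_size: int | None = None

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.patience < 1 or self.max_epochs < 1:
            raise ValueError("batch_size, patience and max_epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.lambda_weight < 1:
            raise ValueError("lambda_weight must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_early: bool = False


@dataclass
class PairedBatch:
    """A mini-batch of subject pairs with their same-label flags."""

    x1: np.ndarray
    x2: np.ndarray
    same: np.ndarray

    @property
    def n(self) -> int:
        return self.x1.shape[0]


class PairPool:
    """A seeded shuffle of all unordered index pairs {i < j}, drawn in order."""

    def __init__(self, pairs: np.ndarray):
        self.pairs = pairs
        self.cursor = 0

    def __len__(self) -> int:
        return self.pairs.shape[0]

    @property
    def remaining(self) -> int:
        return len(self) - self.cursor


def make_pair_pool(records, rng: np.random.Generator) -> PairPool:
    """All m(m-1)/2 unordered pairs of ``records`` in seeded random order."""
    m = records if isinstance(records, (int, np.integer)) else len(records)
    if m < 2:
        raise ValueError("need at least 2 records to form pairs")
    i, j = np.triu_indices(m, k=1)
    pairs = np.column_stack([i, j])
    return PairPool(pairs[rng.permutation(pairs.shape[0])])


def next_minibatch(pool: PairPool, batch_size: int) -> np.ndarray | None:
    """Next ``batch_size`` index pairs, or None at epoch end.

    A partial remainder is discarded — the epoch terminates on the failure to
    extract a full mini-batch.  A batch size exceeding the whole pool yields
    zero iterations per epoch and raises a configuration warning.
    """
    if batch_size > len(pool) and pool.cursor == 0:
        warnings.warn(
            f"batch_size {batch_size} exceeds the pair pool size {len(pool)}; "
            "every epoch will perform zero iterations",
            stacklevel=2,
        )
        pool.cursor = len(pool)
        return None
    if pool.remaining < batch_size:
        pool.cursor = len(pool)
        return None
    batch = pool.pairs[pool.cursor : pool.cursor + batch_size]
    pool.cursor += batch_size
    return batch


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")


def _pair_loss_and_step(model, adam, x, y, idx, lam):
    """One prior-phase iteration: forward both pair members, backprop, Adam."""
    b = idx.shape[0]
    xa = np.vstack([x[idx[:, 0]], x[idx[:, 1]]])
    probs, cache = model.forward_all(xa, training=True, heads=("iic", "iic_oc"))
    pm, poc = probs["iic"], probs["iic_oc"]
    same = y[idx[:, 0]] == y[idx[:, 1]]
    diff = ~same
    d_pm = np.zeros_like(pm)
    d_poc = np.zeros_like(poc)
    loss = 0.0
    if same.any():
        l_m, d1, d2 = _iic_pair_loss_grads(pm[:b][same], pm[b:][same], lam)
        loss += l_m
        d_pm[:b][same] += d1
        d_pm[b:][same] += d2
        l_oc, d1, d2 = _iic_pair_loss_grads(poc[:b][same], poc[b:][same], lam)
        loss += l_oc
        d_poc[:b][same] += d1
        d_poc[b:][same] += d2
    if diff.any():
        phi2c = 1.0 - pm[b:][diff]
        l_d, d1, d2c = _iic_pair_loss_grads(pm[:b][diff], phi2c, lam)
        loss += l_d
        d_pm[:b][diff] += d1
        d_pm[b:][diff] += -d2c
    grads = model.backward(
        cache,
        {
            "iic": softmax_backward(pm, d_pm),
            "iic_oc": softmax_backward(poc, d_poc),
        },
    )
    adam.step(grads)
    return loss


def _prior_loss_eval(model, x, y, idx, lam) -> float:
    """Pair loss on a fixed pair set in evaluation mode (no updates)."""
    phi_m = model.forward(x, "iic", training=False)
    phi_oc = model.forward(x, "iic_oc", training=False)
    same = y[idx[:, 0]] == y[idx[:, 1]]
    loss = 0.0
    if same.any():
        i, j = idx[same, 0], idx[same, 1]
        loss += _iic_pair_loss_grads(phi_m[i], phi_m[j], lam)[0]
        loss += _iic_pair_loss_grads(phi_oc[i], phi_oc[j], lam)[0]
    if (~same).any():
        i, j = idx[~same, 0], idx[~same, 1]
        loss += _iic_pair_loss_grads(phi_m[i], 1.0 - phi_m[j], lam)[0]
    return loss


def _early_stopping_loop(run_epoch, eval_val, model, config) -> TrainHistory:
    """Shared epoch loop: strict-improvement early stopping, best snapshot."""
    history = TrainHistory()
    best_val = np.inf
    best_snap = model.snapshot()
    bad = 0
    for epoch in range(config.max_epochs):
        history.train_loss.append(run_epoch(epoch))
        val = eval_val()
        history.val_loss.append(val)
        if val < best_val:
            best_val = val
            history.best_epoch = epoch
            best_snap = model.snapshot()
            bad = 0
        else:
            bad += 1
            if bad >= config.patience:
                history.stopped_early = True
                break
    model.load_snapshot(best_snap)
    return history


def train_prior(
    model: EiicModel,
    train: Sequence[FeatureVector],
    val: Sequence[FeatureVector],
    config: TrainConfig,
) -> tuple[EiicModel, TrainHistory]:
    """Contrastive prior learning on labeled pairs with early stopping."""
    if not train or not val:
        raise ValueError("train and validation sets must be non-empty")
    x_tr, y_tr, _, _ = stack_features(train)
    x_va, y_va, _, _ = stack_features(val)
    _check_two_classes(y_tr)
    lam = config.lambda_weight
    rng = np.random.default_rng(config.seed)
    # fixed seeded validation pair set, comparable across epochs
    val_pool = make_pair_pool(len(val), rng)
    val_idx = val_pool.pairs[: config.val_pair_cap]
    adam = Adam(model, lr=config.learning_rate)

    def run_epoch(_epoch: int) -> float:
        pool = make_pair_pool(len(train), rng)
        losses = []
        with warnings.catch_warnings():
            warnings.simplefilter("once")
            while (idx := next_minibatch(pool, config.batch_size)) is not None:
                losses.append(_pair_loss_and_step(model, adam, x_tr, y_tr, idx, lam))
        return float(np.mean(losses)) if losses else float("nan")

    history = _early_stopping_loop(
        run_epoch, lambda: _prior_loss_eval(model, x_va, y_va, val_idx, lam), model, config
    )
    return model, history


def _mean_ce(probs: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean([cross_entropy(p, int(t)) for p, t in zip(probs, y)]))


def _ce_phase(model, train, val, config, training_mode: bool):
    x_tr, y_tr, _, _ = stack_features(train)
    x_va, y_va, _, _ = stack_features(val)
    _check_two_classes(y_tr)
    n = x_tr.shape[0]
    bs = config.transfer_batch_size or min(config.batch_size, n)
    bs = min(bs, n)
    rng = np.random.default_rng(config.seed)
    adam = Adam(model, lr=config.learning_rate)
    onehot = np.eye(2)[y_tr]

    def run_epoch(_epoch: int) -> float:
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n - bs + 1, bs):
            sel = perm[start : start + bs]
            probs, cache = model.forward_all(
                x_tr[sel], training=training_mode, heads=("classifier",)
            )
            p = probs["classifier"]
            losses.append(_mean_ce(p, y_tr[sel]))
            d_logits = (p - onehot[sel]) / sel.shape[0]
            adam.step(model.backward(cache, {"classifier": d_logits}))
        return float(np.mean(losses))

    def eval_val() -> float:
        return _mean_ce(model.forward(x_va, "classifier", training=False), y_va)

    history = _early_stopping_loop(run_epoch, eval_val, model, config)
    return model, history


def train_transfer(
    model: EiicModel,
    train: Sequence[FeatureVector],
    val: Sequence[FeatureVector],
    config: TrainConfig,
) -> tuple[EiicModel, TrainHistory]:
    """Cross-entropy fit of the classifier head on a frozen trunk."""
    if not model.frozen:
        raise ValueError("train_transfer requires a frozen model (call freeze_trunk first)")
    return _ce_phase(model, train, val, config, training_mode=False)


def train_supervised(
    model: EiicModel,
    train: Sequence[FeatureVector],
    val: Sequence[FeatureVector],
    config: TrainConfig,
) -> tuple[EiicModel, TrainHistory]:
    """Supervised baseline: train ALL parameters with cross-entropy only.

    This is the no-prior ablation — the same architecture without the
    contrastive phase or the freeze.
    """
    if model.frozen:
        raise ValueError("train_supervised expects an unfrozen model")
    return _ce_phase(model, train, val, config, training_mode=True)
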