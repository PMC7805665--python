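"""Optimization loop: He initialization, Adam with l2 weight decay,
EMA-plateau learning-rate schedule, stopping rule, and k-fold
cross-validation splits.

The schedule tracks an exponential moving average (EMA, coefficient
0.9) of the per-epoch training loss.  Whenever the best EMA has not
improved (by at least 1e-5) for 30 consecutive epochs, the learning
rate is multiplied by 0.2 and the patience counter resets.  Training
stops when the learning rate falls below 1e-6 or after 1000 epochs.
An epoch is one iteration over all training cases (case count divided
by batch size, rounded up).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .losses import one_hot, total_loss
from .network import NetworkSpec, SegmentationNetwork, build_network
from .nn import Adam
from .nn import functional as F
from .sampling import AugmentConfig, TrainingCase, augment, sample_batch

__all__ = ["TrainState", "FoldSplit", "TrainConfig", "he_init",
           "schedule_step", "should_stop", "make_folds", "train",
           "TrainResult", "save_checkpoint", "load_checkpoint"]


# ---------------------------------------------------------------------------
# learning-rate schedule state machine
# ---------------------------------------------------------------------------

EMA_BETA = 0.9
PATIENCE_EPOCHS = 30
LR_FACTOR = 0.2
LR_FLOOR = 1e-6
MAX_EPOCHS = 1000
IMPROVE_EPS = 1e-5


@dataclass
class TrainState:
    epoch: int = 0
    lr: float = 3e-5
    loss_ema: float | None = None
    best_ema: float = math.inf
    epochs_since_improvement: int = 0


def schedule_step(state: TrainState, epoch_loss: float,
                  beta: float = EMA_BETA,
                  patience: int = PATIENCE_EPOCHS,
                  factor: float = LR_FACTOR) -> TrainState:
    """Advance the schedule by one epoch; returns a new state."""
    ema = epoch_loss if state.loss_ema is None \
        else beta * state.loss_ema + (1.0 - beta) * epoch_loss
    if ema < state.best_ema - IMPROVE_EPS:
        best, since = ema, 0
    else:
        best, since = state.best_ema, state.epochs_since_improvement + 1
    lr = state.lr
    if since >= patience:
        lr *= factor
        since = 0
    return TrainState(epoch=state.epoch + 1, lr=lr, loss_ema=ema,
                      best_ema=best, epochs_since_improvement=since)


def should_stop(state: TrainState, lr_floor: float = LR_FLOOR,
                max_epochs: int = MAX_EPOCHS) -> bool:
    return state.lr < lr_floor or state.epoch >= max_epochs


# ---------------------------------------------------------------------------
# cross-validation folds
# ---------------------------------------------------------------------------

@dataclass
class FoldSplit:
    fold_id: int
    train_ids: list[str]
    val_ids: list[str]


def make_folds(case_ids, k: int = 5, seed: int = 0) -> list[FoldSplit]:
    """Deterministic shuffled split into k near-equal validation folds."""
    ids = list(case_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(ids) < k:
        raise ValueError(f"cannot split {len(ids)} cases into {k} folds")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    chunks = np.array_split(np.arange(len(order)), k)
    folds = []
    for f, chunk in enumerate(chunks):
        val = [order[i] for i in chunk]
        tr = [cid for cid in order if cid not in set(val)]
        folds.append(FoldSplit(f, tr, val))
    return folds


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def he_init(network: SegmentationNetwork, seed: int = 0) -> SegmentationNetwork:
    """He-normal conv weights, zero biases, pass-through attention gates."""
    return network.initialize(seed)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    lr: float = 3e-5
    weight_decay: float = 3e-5
    batch_size: int = 2
    max_epochs: int = MAX_EPOCHS
    max_iterations: int | None = None   # cap for scaled-down experiments
    augment: AugmentConfig | None = field(default_factory=AugmentConfig)
    include_background_dice: bool = True
    ce_reduction: str = "mean"


@dataclass
class TrainResult:
    network: SegmentationNetwork
    state: TrainState
    history: list[dict]
    best_params: dict


def train(cases: list[TrainingCase], patch_size, spec: NetworkSpec,
          config: TrainConfig, seed: int = 0) -> TrainResult:
    """Train a network on preprocessed cases.

    Deterministic given the seed (up to floating-point reduction
    order).  The returned ``best_params`` snapshot corresponds to the
    lowest training-loss EMA.
    """
    if not cases:
        raise ValueError("no training cases")
    ss = np.random.SeedSequence(seed)
    net_seed, sample_seed, aug_seed = [int(s.generate_state(1)[0]) % (2**31)
                                       for s in ss.spawn(3)]
    net = build_network(spec, seed=net_seed)
    net.initialize(net_seed)
    opt = Adam(net.parameters(), lr=config.lr, betas=(0.9, 0.999),
               weight_decay=config.weight_decay)
    s_rng = np.random.default_rng(sample_seed)
    a_rng = np.random.default_rng(aug_seed)

    iters_per_epoch = math.ceil(len(cases) / config.batch_size)
    state = TrainState(lr=config.lr)
    history: list[dict] = []
    best_params = net.state_dict()
    total_iters = 0

    while not should_stop(state, max_epochs=config.max_epochs):
        epoch_losses, epoch_dice, epoch_ce = [], [], []
        for _ in range(iters_per_epoch):
            batch = sample_batch(cases, config.batch_size, patch_size, s_rng)
            if config.augment is not None:
                batch = [augment(p, config.augment, a_rng) for p in batch]
            x = np.stack([p.image for p in batch])[:, None]
            lab = np.stack([p.labels for p in batch])
            v = one_hot(lab, spec.num_classes)
            logits = net.forward(x, mode="train")
            u = F.softmax_channels(logits)
            loss, l_dice, l_ce = total_loss(
                u, v, include_background=config.include_background_dice,
                ce_reduction=config.ce_reduction)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite loss at epoch {state.epoch}: "
                    f"dice={l_dice}, ce={l_ce}")
            net.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
            epoch_dice.append(l_dice)
            epoch_ce.append(l_ce)
            total_iters += 1
            if config.max_iterations and total_iters >= config.max_iterations:
                break

        prev_best = state.best_ema
        state = schedule_step(state, float(np.mean(epoch_losses)))
        opt.lr = state.lr
        if state.best_ema < prev_best - IMPROVE_EPS or not history:
            best_params = net.state_dict()
        history.append({
            "epoch": state.epoch, "loss": float(np.mean(epoch_losses)),
            "dice_loss": float(np.mean(epoch_dice)),
            "ce_loss": float(np.mean(epoch_ce)),
            "loss_ema": state.loss_ema, "lr": state.lr,
        })
        if config.max_iterations and total_iters >= config.max_iterations:
            break

    return TrainResult(network=net, state=state, history=history,
                       best_params=best_params)


# ---------------------------------------------------------------------------
# checkpoints: parameters + topology spec (+ optional plan) in one file
# ---------------------------------------------------------------------------

def save_checkpoint(path, network: SegmentationNetwork,
                    params: dict | None = None, plan=None) -> None:
    import json

    meta = {"spec": network.spec.to_dict()}
    if plan is not None:
        meta["plan"] = {
            "task_name": plan.task_name, "resolution": plan.resolution,
            "patch_size": list(plan.patch_size),
            "levels_per_axis": list(plan.levels_per_axis),
            "batch_size": plan.batch_size,
            "target_spacing": (list(plan.target_spacing)
                               if plan.target_spacing else None),
            "median_shape": (list(plan.median_shape)
                             if plan.median_shape else None),
        }
    state = params if params is not None else network.state_dict()
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8),
        **{f"param/{k}": v for k, v in state.items()})


def load_checkpoint(path):
    """Returns (network, plan_dict_or_None) rebuilt from a checkpoint."""
    import json

    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {k[len("param/"):]: archive[k] for k in archive.files
                 if k.startswith("param/")}
    spec = NetworkSpec.from_dict(meta["spec"])
    net = build_network(spec, seed=0)
    net.load_state_dict(state)
    return net, meta.get("plan")
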