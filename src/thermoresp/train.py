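"""Training loop, subject-grouped cross-validation and grid search.

Training uses a two-phase learning-rate schedule: a constant warmup rate
for the first ``warmup_epochs`` epochs, then a (10x higher by default)
post-warmup rate with cosine decay to zero over the remaining epochs.
Evaluation is always subject-grouped: recordings of one volunteer never
appear on both sides of a train/validation split, and `kfold_split`
enforces that every subject's recordings share a fold.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from ._tensor import Tensor
from .losses import LossSpec, loss_tensor, rmse_metric
from .net import NetConfig, TwoPathwayRegressor, build_model, predict_rr, _stack_clips
from .simulate import ThermalSequence
from .windows import ClipPair, WindowSpec, sequence_to_clips

__all__ = [
    "TrainConfig",
    "FoldPlan",
    "EvalReport",
    "kfold_split",
    "train",
    "evaluate",
    "cross_validate",
    "grid_search",
    "derive_seeds",
]


@dataclass(frozen=True)
class TrainConfig:
    """Everything the training loop needs besides the data.

    Defaults follow the best swept configuration where one is known
    (warmup 64 epochs at learning rate 5e-5, dropout 0.2 via `NetConfig`);
    epoch count, batch size, post-warmup rate and optimiser are this
    package's own defaults and are all config-exposed.
    """

    loss: LossSpec = field(default_factory=LossSpec)
    warmup_epochs: int = 64
    warmup_lr: float = 5e-5
    post_warmup_lr: float = 5e-4
    epochs: int = 100
    batch_size: int = 8
    optimizer: str = "sgd"
    momentum: float = 0.9
    weight_decay: float = 0.0
    seed: int = 0
    net: NetConfig = field(default_factory=NetConfig)
    window: WindowSpec = field(default_factory=WindowSpec)

    def __post_init__(self) -> None:
        if self.warmup_epochs > self.epochs:
            raise ValueError(
                f"warmup_epochs ({self.warmup_epochs}) must be <= epochs ({self.epochs})"
            )
        if self.warmup_lr <= 0 or self.post_warmup_lr <= 0:
            raise ValueError("learning rates must be > 0")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"optimizer must be 'sgd' or 'adam', got {self.optimizer!r}")

    def lr_at(self, epoch: int) -> float:
        """Learning rate for a given epoch under the warmup + cosine schedule."""
        if epoch < self.warmup_epochs:
            return self.warmup_lr
        span = max(1, self.epochs - self.warmup_epochs)
        progress = (epoch - self.warmup_epochs) / span
        return self.post_warmup_lr * 0.5 * (1.0 + np.cos(np.pi * progress))


def derive_seeds(master_seed: int) -> dict[str, int]:
    """Fan a master seed out to the independently replayable stages."""
    ss = np.random.SeedSequence(master_seed)
    names = ("simulator", "folds", "weights", "shuffle")
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(names, children)
    }


@dataclass
class FoldPlan:
    """Mapping subject_id -> fold index; all recordings of a subject share a fold."""

    assignment: dict[str, int]
    k: int

    def fold_of(self, subject_id: str) -> int:
        return self.assignment[subject_id]

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.k
        for f in self.assignment.values():
            sizes[f] += 1
        return sizes


@dataclass
class EvalReport:
    """Per-fold and aggregate RMSE; the aggregate is the mean across folds."""

    per_fold_rmse: list[tuple[float, float]]
    aggregate_rmse: float
    aggregate_spread: float
    config_fingerprint: str

    @classmethod
    def from_folds(cls, per_fold: list[tuple[float, float]], fingerprint: str) -> "EvalReport":
        rmses = [r for r, _ in per_fold]
        spreads = [s for _, s in per_fold]
        return cls(
            per_fold_rmse=per_fold,
            aggregate_rmse=float(np.mean(rmses)),
            aggregate_spread=float(np.mean(spreads)),
            config_fingerprint=fingerprint,
        )


def _fingerprint(config: TrainConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def kfold_split(subject_ids: list[str], k: int, seed: int = 0) -> FoldPlan:
    """Shuffle distinct subjects under ``seed`` and deal them round-robin
    into ``k`` folds (sizes differ by at most one subject)."""
    subjects = sorted(set(subject_ids))
    if len(subjects) < k:
        raise ValueError(f"need at least k={k} distinct subjects, got {len(subjects)}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    return FoldPlan(assignment={s: i % k for i, s in enumerate(order)}, k=k)


def _check_no_leakage(train_clips: list[ClipPair], val_clips: list[ClipPair]) -> None:
    train_subjects = {c.subject_id for c in train_clips}
    val_subjects = {c.subject_id for c in val_clips}
    common = train_subjects & val_subjects
    if common:
        raise ValueError(f"subject leakage between train and validation: {sorted(common)}")


def train(
    model: TwoPathwayRegressor,
    clips: list[ClipPair],
    config: TrainConfig,
    val_clips: list[ClipPair] | None = None,
) -> tuple[TwoPathwayRegressor, dict]:
    """Train in place; returns the model and a per-epoch trace.

    The trace records the training loss and the learning rate of every
    epoch (and validation RMSE when ``val_clips`` is given).  Deterministic
    under ``config.seed`` on a single device.
    """
    if not clips:
        raise ValueError("empty training set")
    if val_clips:
        _check_no_leakage(clips, val_clips)

    from . import nn

    if config.epochs == 0:
        return model, {"epoch_loss": [], "lr": [], "val_rmse": []}

    labels = np.array([c.label_rr for c in clips], dtype=np.float32)
    model.init_head_bias(float(labels.mean()))
    params = model.parameters()
    if config.optimizer == "adam":
        opt = nn.Adam(params, lr=config.warmup_lr, weight_decay=config.weight_decay)
    else:
        opt = nn.SGD(params, lr=config.warmup_lr, momentum=config.momentum,
                     weight_decay=config.weight_decay)

    seeds = derive_seeds(config.seed)
    rng = np.random.default_rng(seeds["shuffle"])
    trace: dict = {"epoch_loss": [], "lr": [], "val_rmse": []}
    n = len(clips)

    for epoch in range(config.epochs):
        lr = config.lr_at(epoch)
        opt.lr = lr
        model.train()
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            batch = [clips[i] for i in order[start : start + config.batch_size]]
            dense, sparse = _stack_clips(batch)
            targets = np.array([c.label_rr for c in batch], dtype=np.float32)
            preds = model(Tensor(dense, requires_grad=False), Tensor(sparse))
            batch_loss = loss_tensor(config.loss, preds, targets)
            opt.zero_grad()
            batch_loss.backward()
            opt.step()
            epoch_losses.append(float(batch_loss.data))
        trace["epoch_loss"].append(float(np.mean(epoch_losses)))
        trace["lr"].append(lr)
        if val_clips:
            rmse, _ = rmse_metric(
                predict_rr(model, val_clips), [c.label_rr for c in val_clips]
            )
            trace["val_rmse"].append(rmse)
    return model, trace


def evaluate(model: TwoPathwayRegressor, clips: list[ClipPair]) -> tuple[float, float]:
    """Predict every clip and score with `rmse_metric` -> (rmse, spread)."""
    if not clips:
        raise ValueError("evaluate: empty clip set")
    preds = predict_rr(model, clips)
    return rmse_metric(preds, [c.label_rr for c in clips])


def cohort_to_clips(
    cohort: list[ThermalSequence], spec: WindowSpec, alpha: int, beta: int
) -> list[ClipPair]:
    clips: list[ClipPair] = []
    for seq in cohort:
        clips.extend(sequence_to_clips(seq, spec, alpha, beta))
    return clips


def cross_validate(
    cohort: list[ThermalSequence], k: int, config: TrainConfig
) -> EvalReport:
    """Subject-grouped k-fold cross-validation of the full train/eval cycle.

    Every recording is validated exactly once; the aggregate RMSE is the
    mean of the per-fold RMSEs.  Deterministic under ``config.seed``.
    """
    seeds = derive_seeds(config.seed)
    plan = kfold_split([s.subject_id for s in cohort], k, seed=seeds["folds"])
    clips = cohort_to_clips(cohort, config.window, config.net.alpha, config.net.beta)
    per_fold: list[tuple[float, float]] = []
    for fold in range(k):
        train_clips = [c for c in clips if plan.fold_of(c.subject_id) != fold]
        val_clips = [c for c in clips if plan.fold_of(c.subject_id) == fold]
        model = build_model(config.net, seed=seeds["weights"] + fold)
        model, _ = train(model, train_clips, config, val_clips=None)
        per_fold.append(evaluate(model, val_clips))
    return EvalReport.from_folds(per_fold, _fingerprint(config))


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

#: Sweepable keys (the sweep vocabulary) -> how they map onto the configs.
GRID_KEYS = (
    "lossfunc", "reduction", "samplingrate", "input_window_length", "alpha",
    "beta", "fusionkernels", "warmupepoch", "warmuplr", "dropout",
    "target_fps", "backbone", "receptive_field", "width_multiplier",
)

#: receptive-field vocabulary: residual spatial kernel -> (stem, residual).
_RF_PAIRS = {3: (5, 3), 5: (7, 5), 7: (9, 7), 9: (11, 9)}


def _apply_cell(base: TrainConfig, cell: dict) -> TrainConfig:
    net = base.net
    window = base.window
    lspec = base.loss
    updates: dict = {}
    for key, value in cell.items():
        if key == "lossfunc":
            lspec = replace(lspec, name=str(value).lower())
        elif key == "reduction":
            lspec = replace(lspec, reduction=str(value).lower())
        elif key == "samplingrate":
            window = replace(window, stride_frames=int(value))
        elif key == "input_window_length":
            window = replace(window, window_len_frames=int(value))
            net = replace(net, window_len=int(value))
        elif key == "alpha":
            net = replace(net, alpha=int(value))
        elif key == "beta":
            net = replace(net, beta=int(value))
        elif key == "fusionkernels":
            net = replace(net, fusion_kernel_t=int(value))
        elif key == "warmupepoch":
            updates["warmup_epochs"] = int(value)
        elif key == "warmuplr":
            updates["warmup_lr"] = float(value)
        elif key == "dropout":
            net = replace(net, dropout=float(value))
        elif key == "target_fps":
            window = replace(window, target_fps=float(value))
        elif key == "backbone":
            net = replace(net, backbone=str(value).lower())
        elif key == "receptive_field":
            stem, resid = _RF_PAIRS[int(value)]
            net = replace(net, stem_spatial_k=stem, residual_spatial_k=resid)
        elif key == "width_multiplier":
            net = replace(net, width_multiplier=float(value))
        else:  # pragma: no cover - guarded by grid_search
            raise ValueError(f"unknown grid key {key!r}")
    warmup = updates.get("warmup_epochs", base.warmup_epochs)
    if warmup > base.epochs:  # keep the schedule invariant satisfiable
        updates["epochs"] = max(base.epochs, warmup)
    return replace(base, loss=lspec, net=net, window=window, **updates)


def grid_search(
    space: dict[str, list],
    base_config: TrainConfig,
    cohort: list[ThermalSequence],
    k: int = 2,
    budget: int | None = None,
    seed: int = 0,
    evaluator=None,
) -> list[dict]:
    """Cartesian hyperparameter sweep ranked by aggregate RMSE.

    ``space`` maps sweep keys (see ``GRID_KEYS``) to candidate values; the
    product is enumerated (capped at ``budget`` cells, chosen uniformly
    without replacement under ``seed``), each cell evaluated by
    subject-grouped ``k``-fold cross-validation (or a custom ``evaluator``
    taking ``(config, cohort, k)`` and returning ``(rmse, n_params)``).
    Ties in RMSE are broken by smaller parameter count.
    """
    unknown = set(space) - set(GRID_KEYS)
    if unknown:
        raise ValueError(
            f"unknown grid key(s) {sorted(unknown)}; valid keys: {sorted(GRID_KEYS)}"
        )
    keys = list(space)
    cells = [dict(zip(keys, combo)) for combo in itertools.product(*space.values())]
    if budget is not None and budget < len(cells):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(cells), size=budget, replace=False)
        cells = [cells[i] for i in sorted(idx)]

    if evaluator is None:
        def evaluator(config: TrainConfig, cohort, k):
            report = cross_validate(cohort, k, config)
            return report.aggregate_rmse, build_model(config.net).n_parameters()

    results = []
    for cell in cells:
        config = _apply_cell(base_config, cell)
        rmse, n_params = evaluator(config, cohort, k)
        results.append({"cell": cell, "rmse": float(rmse), "n_params": int(n_params)})
    results.sort(key=lambda r: (r["rmse"], r["n_params"]))
    return results
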