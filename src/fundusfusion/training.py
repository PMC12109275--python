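"""Block/epoch/batch training schedule and evaluation.

Training is organized as ``l`` blocks (default 5).  Each block trains a
freshly initialized network for up to ``h`` epochs (default 200) of
``b`` batches (default 100) with batch size ``m`` (default 40), batches
drawn at random from the training set.  Every ``checkpoint_every``
batches (default 40) the current weights are scored on the validation
set; the best-scoring candidate becomes that block's *block-model*.  A
block stops early when validation loss has not improved for
``patience`` consecutive epochs.  Each completed block-model is applied
to the held-out test set, and performance is reported per block plus as
mean (standard error) over blocks.

The train/validation/test split is stratified by class with
largest-remainder rounding, applied before image augmentation so both
augmented copies of a subject stay in one set (no leakage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import metrics as _metrics
from .lossfn import LossParams, concat_loss, concat_loss_grad, predict_label
from .nn import Adam, FusionNetwork
from .phantom import PhantomSpec, SubjectRecord, render_fundus_phantom, text_band
from .preprocess import PreprocessConfig, default_config_for, preprocess_pipeline
from .features import wa_mt, wa_rnfl


class TrainingDiverged(RuntimeError):
    """The batch loss became non-finite."""


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/validation/test fractions."""

    fractions: tuple[float, float, float] = (0.5, 0.2, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fractions):
            raise ValueError(f"all fractions must be positive, got {self.fractions}")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {self.fractions}")


@dataclass(frozen=True)
class Schedule:
    """Block/epoch/batch training schedule."""

    l_blocks: int = 5
    h_max_epochs: int = 200
    b_batches: int = 100
    m_batch_size: int = 40
    patience: int = 10
    checkpoint_every: int = 40
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("l_blocks", "h_max_epochs", "b_batches", "m_batch_size",
                     "patience", "checkpoint_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")


@dataclass
class BlockModel:
    """One block's checkpoint and its validation/test scores."""

    block_index: int
    state: list = field(repr=False)
    validation_loss: float = np.inf
    epochs_run: int = 0
    batches_run: int = 0
    epoch_val_losses: list = field(default_factory=list, repr=False)
    validation_metrics: _metrics.MetricReport | None = None


@dataclass
class TrainingData:
    """Arrays for one split: NCHW images and/or 2-column features."""

    images: np.ndarray | None
    feats: np.ndarray | None
    y: np.ndarray

    @property
    def n(self) -> int:
        return len(self.y)

    def take(self, idx: np.ndarray) -> "TrainingData":
        return TrainingData(
            images=None if self.images is None else self.images[idx],
            feats=None if self.feats is None else self.feats[idx],
            y=self.y[idx],
        )


def stratified_split(
    labels, spec: SplitSpec = SplitSpec()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified three-way split with largest-remainder rounding.

    Within every class, member indices are shuffled (seeded) and
    partitioned so per-class counts match the fractions to within one
    sample; the three index sets are disjoint and exhaustive.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    out: list[list[int]] = [[], [], []]
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        if len(members) < 3:
            raise ValueError(f"class {cls!r} has only {len(members)} members; need >= 3")
        members = rng.permutation(members)
        quotas = np.array(spec.fractions) * len(members)
        counts = np.floor(quotas).astype(int)
        remainder = quotas - counts
        # distribute leftover samples to the largest fractional remainders
        for j in np.argsort(-remainder)[: len(members) - counts.sum()]:
            counts[j] += 1
        start = 0
        for j in range(3):
            out[j].extend(members[start : start + counts[j]])
            start += counts[j]
    return tuple(np.array(sorted(s), dtype=int) for s in out)


def run_batch(
    network: FusionNetwork,
    batch: TrainingData,
    loss_params: LossParams,
    optimizer: Adam,
) -> float:
    """One gradient step on the mean modulated cross-entropy loss."""
    p = network.forward(batch.images, batch.feats, train=True)
    loss = concat_loss(batch.y, p, loss_params)
    if not np.isfinite(loss):
        raise TrainingDiverged(
            f"non-finite batch loss {loss} (p_hat range "
            f"[{np.min(p):.3g}, {np.max(p):.3g}])"
        )
    grad = concat_loss_grad(batch.y, p, loss_params) / batch.n
    network.backward(grad)
    optimizer.step()
    return float(loss)


def predict_proba(network: FusionNetwork, data: TrainingData, chunk: int = 64) -> np.ndarray:
    """Evaluation-mode p_hat for a whole split, chunked for memory."""
    parts = []
    for start in range(0, data.n, chunk):
        sl = slice(start, start + chunk)
        parts.append(
            network.forward(
                None if data.images is None else data.images[sl],
                None if data.feats is None else data.feats[sl],
                train=False,
            )
        )
    return np.concatenate(parts) if parts else np.empty(0)


def _validation_loss(network, val: TrainingData, loss_params) -> float:
    return concat_loss(val.y, predict_proba(network, val), loss_params)


def run_block(
    network: FusionNetwork,
    train: TrainingData,
    val: TrainingData,
    schedule: Schedule,
    loss_params: LossParams,
    rng: np.random.Generator,
    block_index: int = 1,
) -> BlockModel:
    """Train one block and return its best validation checkpoint.

    Candidate checkpoints are scored on the validation set every
    ``checkpoint_every`` batches and at each epoch end; the best becomes
    the block-model.  Early stopping triggers when the per-epoch
    validation loss fails to improve for ``patience`` epochs.
    """
    optimizer = Adam(network, lr=schedule.learning_rate)
    best_loss = np.inf
    best_state = network.get_state()
    epoch_losses: list[float] = []
    best_epoch_loss = np.inf
    stale_epochs = 0
    batches = 0
    epochs = 0
    for _ in range(schedule.h_max_epochs):
        epochs += 1
        for _ in range(schedule.b_batches):
            replace = train.n < schedule.m_batch_size
            idx = rng.choice(train.n, size=schedule.m_batch_size, replace=replace)
            run_batch(network, train.take(idx), loss_params, optimizer)
            batches += 1
            if batches % schedule.checkpoint_every == 0:
                vl = _validation_loss(network, val, loss_params)
                if vl < best_loss:
                    best_loss = vl
                    best_state = network.get_state()
        epoch_loss = _validation_loss(network, val, loss_params)
        epoch_losses.append(epoch_loss)
        if epoch_loss < best_loss:
            best_loss = epoch_loss
            best_state = network.get_state()
        if epoch_loss < best_epoch_loss - 1e-12:
            best_epoch_loss = epoch_loss
            stale_epochs = 0
        else:
            stale_epochs += 1
            if stale_epochs >= schedule.patience:
                break
    network.set_state(best_state)
    p_val = predict_proba(network, val)
    report = _metrics.evaluate(val.y, predict_label(p_val)) if val.n else None
    return BlockModel(
        block_index=block_index,
        state=best_state,
        validation_loss=best_loss,
        epochs_run=epochs,
        batches_run=batches,
        epoch_val_losses=epoch_losses,
        validation_metrics=report,
    )


def train_and_evaluate(
    model_factory,
    train: TrainingData,
    val: TrainingData,
    test: TrainingData,
    schedule: Schedule = Schedule(),
    loss_params: LossParams = LossParams(),
    seed: int = 0,
) -> dict:
    """Run the full block schedule and score each block-model on test.

    Each block restarts from a fresh initialization (``model_factory``
    is called with a block-specific seed) with a re-seeded batch
    sampler but the same split, so the spread over blocks reflects
    training variability against a fixed test set.

    Returns a dict with ``block_models``, ``test_reports`` (one
    MetricReport per block) and ``summary`` (mean/sd/se per metric).
    """
    block_models: list[BlockModel] = []
    reports: list[_metrics.MetricReport] = []
    for i in range(1, schedule.l_blocks + 1):
        network = model_factory(seed + 7919 * i)
        rng = np.random.default_rng(seed + 104729 * i)
        bm = run_block(network, train, val, schedule, loss_params, rng, block_index=i)
        network.set_state(bm.state)
        p_test = predict_proba(network, test)
        reports.append(_metrics.evaluate(test.y, predict_label(p_test)))
        block_models.append(bm)
    return {
        "block_models": block_models,
        "test_reports": reports,
        "summary": _metrics.aggregate_reports(reports),
    }


def prepare_cohort_arrays(
    records: list[SubjectRecord],
    phantom_spec: PhantomSpec,
    split_spec: SplitSpec = SplitSpec(),
    preprocess_config: PreprocessConfig | None = None,
    seed: int = 0,
    binary: bool = True,
) -> dict:
    """Render, preprocess and split a phantom cohort into model arrays.

    The split is made on subjects before augmentation; training keeps
    both augmented views of each subject, validation and test use the
    unrotated view only (one decision per eye).  Thickness features are
    z-scored with training-set statistics.  Images are scaled to [0, 1]
    NCHW float32.

    Returns a dict with ``train``/``val``/``test`` TrainingData, the
    split indices, and the feature scaler (mean, scale).
    """
    if preprocess_config is None:
        preprocess_config = default_config_for(
            phantom_spec.image_rows, phantom_spec.image_cols, band=text_band(phantom_spec)
        )
    labels = [r.label for r in records]
    idx_train, idx_val, idx_test = stratified_split(labels, split_spec)

    rng = np.random.default_rng(seed)
    feats = np.array(
        [[wa_mt(r.thickness.macular), wa_rnfl(r.thickness.rnfl)] for r in records], dtype=float
    )
    y_all = np.array([r.y for r in records], dtype=int) if binary else np.asarray(labels)

    processed: list[list[np.ndarray]] = []
    for rec in records:
        raw = render_fundus_phantom(rec, phantom_spec)
        pair = preprocess_pipeline(raw, preprocess_config, rng, source_id=rec.subject_id)
        processed.append(
            [
                np.clip(p.pixels.transpose(2, 0, 1), 0.0, 255.0).astype(np.float32) / 255.0
                for p in pair
            ]
        )

    mean = feats[idx_train].mean(axis=0)
    scale = feats[idx_train].std(axis=0)
    scale[scale == 0] = 1.0
    z = (feats - mean) / scale

    def _pack(idx: np.ndarray, augmented: bool) -> TrainingData:
        imgs, fs, ys = [], [], []
        for i in idx:
            views = processed[i] if augmented else processed[i][:1]
            for v in views:
                imgs.append(v)
                fs.append(z[i])
                ys.append(y_all[i])
        return TrainingData(
            images=np.stack(imgs) if imgs else None,
            feats=np.array(fs) if fs else None,
            y=np.array(ys),
        )

    return {
        "train": _pack(idx_train, augmented=True),
        "val": _pack(idx_val, augmented=False),
        "test": _pack(idx_test, augmented=False),
        "indices": (idx_train, idx_val, idx_test),
        "feature_mean": mean,
        "feature_scale": scale,
    }
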