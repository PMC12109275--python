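"""Scikit-learn-style estimators wrapping the three classifiers.

* :class:`AnnBranchClassifier` — thickness-only model on the two
  structural features (WA_MT, WA_RNFL); X is (n_samples, 2).
* :class:`CnnBranchClassifier` — image-only model; X is
  (n_samples, 78, 116, 3) RGB, (n_samples, 3, 78, 116) NCHW, or the
  flattened equivalent.
* :class:`ConcatenatedClassifier` — the fused model; X is a dict (or
  2-tuple) with ``"image"`` and ``"features"`` arrays.

All three implement fit / predict / predict_proba with
``get_params``/``set_params`` and trailing-underscore fitted
attributes, so they compose with sklearn model selection.  ``fit``
carves a stratified validation split off the supplied data, runs the
block/epoch/batch schedule (each block an independent restart), and
keeps the block-model with the best validation loss for prediction.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .lossfn import LossParams, predict_label
from .models import AnnSpec, CnnSpec, ConcatSpec, build_concat_model
from .nn import FusionNetwork
from .training import Schedule, TrainingData, predict_proba, run_block


class _FusionClassifierBase(BaseEstimator, ClassifierMixin):
    """Shared schedule/loss plumbing; subclasses parse X per modality."""

    _mode: str = "concat"  # "cnn", "ann", or "concat"

    def __init__(
        self,
        ann_layers=4,
        ann_nodes=16,
        head_layers=2,
        head_nodes=16,
        n_kernels=32,
        alpha=1.0,
        beta=1.5,
        n_blocks=1,
        max_epochs=10,
        batches_per_epoch=10,
        batch_size=8,
        learning_rate=1e-3,
        patience=10,
        checkpoint_every=40,
        validation_fraction=0.2,
        random_state=None,
    ):
        self.ann_layers = ann_layers
        self.ann_nodes = ann_nodes
        self.head_layers = head_layers
        self.head_nodes = head_nodes
        self.n_kernels = n_kernels
        self.alpha = alpha
        self.beta = beta
        self.n_blocks = n_blocks
        self.max_epochs = max_epochs
        self.batches_per_epoch = batches_per_epoch
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.patience = patience
        self.checkpoint_every = checkpoint_every
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- modality plumbing -------------------------------------------------
    def _parse_X(self, X) -> tuple[np.ndarray | None, np.ndarray | None]:
        raise NotImplementedError

    def _specs(self):
        cnn = (
            CnnSpec(n_kernels=self.n_kernels)
            if self._mode in ("cnn", "concat")
            else None
        )
        ann = (
            AnnSpec(n_layers=self.ann_layers, n_nodes=self.ann_nodes)
            if self._mode in ("ann", "concat")
            else None
        )
        head = ConcatSpec(n_layers=self.head_layers, n_nodes=self.head_nodes)
        return cnn, ann, head

    def _build(self, seed: int) -> FusionNetwork:
        cnn, ann, head = self._specs()
        return build_concat_model(cnn, ann, head, rng=seed)

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y):
        images, feats = self._parse_X(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"expected exactly 2 classes, got {self.classes_}")
        y01 = (y == self.classes_[1]).astype(int)

        n = len(y01)
        idx_train, idx_val = train_test_split(
            np.arange(n),
            test_size=self.validation_fraction,
            stratify=y01,
            random_state=self.random_state,
        )
        full = TrainingData(images=images, feats=feats, y=y01)
        train, val = full.take(idx_train), full.take(idx_val)

        schedule = Schedule(
            l_blocks=self.n_blocks,
            h_max_epochs=self.max_epochs,
            b_batches=self.batches_per_epoch,
            m_batch_size=self.batch_size,
            patience=self.patience,
            checkpoint_every=self.checkpoint_every,
            learning_rate=self.learning_rate,
        )
        loss_params = LossParams(alpha=self.alpha, beta=self.beta)
        base = 0 if self.random_state is None else int(self.random_state)

        self.block_models_ = []
        best = None
        for i in range(1, schedule.l_blocks + 1):
            network = self._build(base + 7919 * i)
            rng = np.random.default_rng(base + 104729 * i)
            bm = run_block(network, train, val, schedule, loss_params, rng, block_index=i)
            self.block_models_.append(bm)
            if best is None or bm.validation_loss < best.validation_loss:
                best = bm
                self.model_ = network
        self.model_.set_state(best.state)
        self.best_block_ = best.block_index
        self.loss_params_ = loss_params
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        images, feats = self._parse_X(X)
        p1 = predict_proba(self.model_, TrainingData(images=images, feats=feats,
                                                     y=np.zeros(self._n_of(images, feats))))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return self.classes_[predict_label(p)]

    @staticmethod
    def _n_of(images, feats) -> int:
        return len(images) if images is not None else len(feats)


class AnnBranchClassifier(_FusionClassifierBase):
    """Thickness-feature ANN classifier (Model 2).

    X is (n_samples, 2): WA_MT and WA_RNFL.  With ``standardize=True``
    (default) features are z-scored using statistics of the fitted
    data, stored as ``feature_mean_`` / ``feature_scale_``.
    """

    _mode = "ann"

    def __init__(
        self,
        standardize=True,
        ann_layers=4,
        ann_nodes=16,
        head_layers=2,
        head_nodes=16,
        n_kernels=32,
        alpha=1.0,
        beta=1.5,
        n_blocks=1,
        max_epochs=10,
        batches_per_epoch=10,
        batch_size=8,
        learning_rate=1e-3,
        patience=10,
        checkpoint_every=40,
        validation_fraction=0.2,
        random_state=None,
    ):
        super().__init__(
            ann_layers=ann_layers,
            ann_nodes=ann_nodes,
            head_layers=head_layers,
            head_nodes=head_nodes,
            n_kernels=n_kernels,
            alpha=alpha,
            beta=beta,
            n_blocks=n_blocks,
            max_epochs=max_epochs,
            batches_per_epoch=batches_per_epoch,
            batch_size=batch_size,
            learning_rate=learning_rate,
            patience=patience,
            checkpoint_every=checkpoint_every,
            validation_fraction=validation_fraction,
            random_state=random_state,
        )
        self.standardize = standardize

    def _parse_X(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError(f"expected (n_samples, 2) features, got {X.shape}")
        if self.standardize:
            if not hasattr(self, "feature_mean_"):
                self.feature_mean_ = X.mean(axis=0)
                scale = X.std(axis=0)
                scale[scale == 0] = 1.0
                self.feature_scale_ = scale
            X = (X - self.feature_mean_) / self.feature_scale_
        return None, X

    def fit(self, X, y):
        # reset the scaler so refitting re-estimates it
        for attr in ("feature_mean_", "feature_scale_"):
            if hasattr(self, attr):
                delattr(self, attr)
        return super().fit(X, y)


class CnnBranchClassifier(_FusionClassifierBase):
    """Fundus-image CNN classifier (Model 1).

    Accepts preprocessed 78x116 RGB tensors in HWC, CHW or flattened
    layout; pixel values are used as given (scale to [0, 1] upstream).
    """

    _mode = "cnn"

    def _parse_X(self, X):
        X = np.asarray(X, dtype=np.float32)
        rows, cols = CnnSpec().input_shape[:2]
        if X.ndim == 2 and X.shape[1] == rows * cols * 3:
            X = X.reshape(-1, 3, rows, cols)
        elif X.ndim == 4 and X.shape[1:] == (rows, cols, 3):
            X = X.transpose(0, 3, 1, 2)
        elif X.ndim == 4 and X.shape[1:] == (3, rows, cols):
            pass
        else:
            raise ValueError(
                f"expected images of shape (n,{rows},{cols},3), (n,3,{rows},{cols}) "
                f"or flattened, got {X.shape}"
            )
        return np.ascontiguousarray(X), None


class ConcatenatedClassifier(_FusionClassifierBase):
    """The fused CNN+ANN classifier (Model 3).

    X is a mapping (or 2-tuple) with ``"image"`` — (n, 78, 116, 3) or
    NCHW — and ``"features"`` — (n, 2).
    """

    _mode = "concat"

    def _parse_X(self, X):
        if isinstance(X, (tuple, list)) and len(X) == 2:
            image, feats = X
        elif hasattr(X, "keys"):
            image, feats = X["image"], X["features"]
        else:
            raise ValueError(
                "ConcatenatedClassifier expects {'image': ..., 'features': ...} "
                "or a (images, features) pair"
            )
        images, _ = CnnBranchClassifier._parse_X(self, image)
        feats = np.asarray(feats, dtype=float)
        if feats.ndim != 2 or feats.shape[1] != 2:
            raise ValueError(f"expected (n_samples, 2) features, got {feats.shape}")
        if len(images) != len(feats):
            raise ValueError("image and feature sample counts differ")
        return images, feats
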