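"""Scikit-learn style classifiers over the numpy 3D CNN backend.

:class:`CNNClassifier` trains a single volumetric network (the subject-level
baseline, or one patch-level subnetwork) with Adam, balanced class weights,
and early stopping on a validation metric, restoring the best-validation
checkpoint. :class:`CascadeClassifier` implements the two-stage cascade:
one patch-level subnetwork is pretrained per patch position, then every
convolutional layer is frozen and a subject-level fusion head is trained on
the concatenated deep (Conv4) features.

Both follow the estimator protocol (``fit``/``predict``/``predict_proba``,
``get_params``/``set_params``, trailing-underscore fitted attributes) so
they compose with sklearn model selection; ``fit`` additionally accepts an
explicit validation set, as the experiment protocol trains against a held
out validation split.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .architecture import ArchitectureSpec, patch_subnet_spec, fusion_spec
from .nn import AdamOptimizer, Network, build_model
from .patches import PatchSpec

__all__ = ["EarlyStopper", "CNNClassifier", "CascadeClassifier"]


class EarlyStopper:
    """Stop when the monitored value fails to improve for ``patience`` epochs.

    Improvement means a strict decrease of the monitored loss (or increase,
    for ``mode='max'``). The best value's weights are the caller's to
    snapshot; :meth:`update` returns True when training should stop.
    """

    def __init__(self, patience: int, mode: str = "min"):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.sign = 1.0 if mode == "min" else -1.0
        self.best = np.inf
        self.best_epoch = -1
        self.stale = 0
        self.improved = False

    def update(self, value: float, epoch: int) -> bool:
        if self.sign * value < self.best:
            self.best = self.sign * value
            self.best_epoch = epoch
            self.stale = 0
            self.improved = True
            return False
        self.stale += 1
        self.improved = False
        return self.stale >= self.patience


def _as_batch(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 4:  # (N, D, H, W) -> single channel
        X = X[:, None]
    if X.ndim != 5 and X.ndim != 2:
        raise ValueError(f"X must be (N,D,H,W), (N,1,D,H,W) or flat (N,F); got {X.shape}")
    return X


def _encode(y, classes: np.ndarray) -> np.ndarray:
    lut = {c: i for i, c in enumerate(classes)}
    try:
        return np.asarray([lut[v] for v in y], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"unknown label {exc.args[0]!r}; expected one of {list(classes)}")


def _balanced_sample_weights(y_idx: np.ndarray, n_classes: int) -> np.ndarray:
    """Per-sample weights inversely proportional to class frequency (mean 1)."""
    n = len(y_idx)
    w = np.empty(n, dtype=np.float64)
    for c in range(n_classes):
        mask = y_idx == c
        n_c = int(mask.sum())
        if n_c == 0:
            raise ValueError("every class must appear in the training labels")
        w[mask] = n / (n_classes * n_c)
    return w


def _train_network(
    net: Network,
    X: np.ndarray,
    y_idx: np.ndarray,
    X_val: np.ndarray,
    yv_idx: np.ndarray,
    *,
    learning_rate: float,
    batch_size: int,
    max_epochs: int,
    patience: int,
    monitor: str,
    seed: int,
) -> dict:
    """Adam training loop with balanced class weights and early stopping."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x7EA1)))
    n_classes = int(max(y_idx.max(), yv_idx.max())) + 1
    w_train = _balanced_sample_weights(y_idx, n_classes)
    wv = np.ones(len(yv_idx), dtype=np.float64)
    opt = AdamOptimizer(net.params, lr=learning_rate)
    stopper = EarlyStopper(patience=patience, mode="min")
    best_weights = net.get_weights()
    history = {"train_loss": [], "val_loss": [], "val_acc": []}
    n = X.shape[0]
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            loss = net.loss_and_grad(X[idx], y_idx[idx], w_train[idx], rng)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(model {net.spec.name})"
                )
            opt.step()
            epoch_loss += loss * len(idx)
        val_loss = net.eval_loss(X_val, yv_idx, wv)
        val_pred = net.predict_proba(X_val).argmax(axis=1)
        val_acc = float((val_pred == yv_idx).mean())
        history["train_loss"].append(epoch_loss / n)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        monitored = val_loss if monitor == "val_loss" else -val_acc
        stop = stopper.update(monitored, epoch)
        if stopper.improved:
            best_weights = net.get_weights()
        if stop:
            break
    net.set_weights(best_weights)
    history["best_epoch"] = stopper.best_epoch
    return history


class CNNClassifier(ClassifierMixin, BaseEstimator):
    """A single volumetric CNN classifier (baseline or patch-level subnetwork).

    Parameters
    ----------
    spec
        An :class:`ArchitectureSpec`. Required; build it with
        :func:`~patchcascade.architecture.baseline_spec` or
        :func:`~patchcascade.architecture.patch_subnet_spec`.
    learning_rate, batch_size, max_epochs, patience
        Adam step size (default 1e-4), minibatch size (default 24), epoch
        cap, and early-stopping patience in epochs (default 20).
    dropout
        Overrides the spec's dropout rates when not None (a grid-search
        hyperparameter).
    l2
        L2 weight-decay coefficient on conv/dense kernels (default 1e-4).
    monitor
        ``'val_loss'`` (default) or ``'val_acc'``.
    validation_fraction
        Used to carve a stratified validation set out of ``fit``'s training
        data when no explicit validation set is passed.
    random_state
        Seed for initialization, batching and dropout; fits are
        reproducible given it.
    """

    def __init__(
        self,
        spec: ArchitectureSpec | None = None,
        learning_rate: float = 1e-4,
        batch_size: int = 24,
        max_epochs: int = 300,
        patience: int = 20,
        dropout: float | None = None,
        l2: float = 1e-4,
        monitor: str = "val_loss",
        validation_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.spec = spec
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.dropout = dropout
        self.l2 = l2
        self.monitor = monitor
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _validate(self):
        if self.spec is None:
            raise ValueError("spec is required")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.max_epochs < self.patience:
            raise ValueError("max_epochs must be >= patience")

    def fit(self, X, y, X_val=None, y_val=None):
        self._validate()
        X = _as_batch(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training data must contain both classes")
        y_idx = _encode(y, self.classes_)
        if X_val is None:
            X, X_val, y_idx, yv_idx = train_test_split(
                X,
                y_idx,
                test_size=self.validation_fraction,
                stratify=y_idx,
                random_state=self.random_state % (2**32),
            )
        else:
            X_val = _as_batch(X_val)
            yv_idx = _encode(np.asarray(y_val), self.classes_)
        self.network_ = build_model(
            self.spec, l2=self.l2, seed=self.random_state, dropout_override=self.dropout
        )
        self.history_ = _train_network(
            self.network_,
            X,
            y_idx,
            X_val,
            yv_idx,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            monitor=self.monitor,
            seed=self.random_state,
        )
        self.n_epochs_ = len(self.history_["train_loss"])
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "network_")
        return self.network_.predict_proba(_as_batch(X))

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def score_positive(self, X, positive_label="AD"):
        """Probability of the positive class for each sample."""
        col = int(np.nonzero(self.classes_ == positive_label)[0][0])
        return self.predict_proba(X)[:, col]


class CascadeClassifier(ClassifierMixin, BaseEstimator):
    """Two-stage cascade: pretrained patch-level subnetworks + fusion head.

    One subnetwork is trained per patch position (random init, its own FC
    head, early stopping). The subnetworks' convolutional layers are then
    frozen — fusion training never touches them — and a dense fusion head
    is trained on the concatenation of every subnetwork's flattened deep
    feature map.

    Parameters mirror :class:`CNNClassifier` plus the patch layout
    (``patch_specs``) and the desk-scalable width settings
    (``channels``, ``subnet_fc_units``, ``fusion_fc_units``). Subnet epochs
    default lower than the baseline's because patch-level networks converge
    faster.
    """

    def __init__(
        self,
        patch_specs: tuple[PatchSpec, ...] = (),
        channels: tuple[int, int, int, int] = (8, 16, 32, 64),
        subnet_fc_units: tuple[int, int] = (1024, 128),
        fusion_fc_units: tuple[int, int] = (2048, 512),
        learning_rate: float = 1e-4,
        batch_size: int = 24,
        subnet_max_epochs: int = 200,
        fusion_max_epochs: int = 300,
        patience: int = 20,
        dropout: float | None = None,
        l2: float = 1e-4,
        monitor: str = "val_loss",
        validation_fraction: float = 0.1,
        random_state: int = 0,
    ):
        self.patch_specs = patch_specs
        self.channels = channels
        self.subnet_fc_units = subnet_fc_units
        self.fusion_fc_units = fusion_fc_units
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.subnet_max_epochs = subnet_max_epochs
        self.fusion_max_epochs = fusion_max_epochs
        self.patience = patience
        self.dropout = dropout
        self.l2 = l2
        self.monitor = monitor
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _extract(self, X: np.ndarray, spec: PatchSpec) -> np.ndarray:
        sl = (slice(None), slice(None)) + spec.slices()
        return X[sl]

    def _conv_features(self, net: Network, X: np.ndarray) -> np.ndarray:
        """Forward through the frozen conv/pool stack up to the flatten."""
        out = X
        for layer in net.layers:
            out = layer.forward(out, train=False, rng=None)
            if type(layer).__name__ == "Flatten":
                return out
        raise RuntimeError("subnetwork has no flatten layer")  # pragma: no cover

    def fit(self, X, y, X_val=None, y_val=None):
        if not self.patch_specs:
            raise ValueError("patch_specs must list at least one patch")
        X = _as_batch(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training data must contain both classes")
        y_idx = _encode(y, self.classes_)
        if X_val is None:
            X, X_val, y_idx, yv_idx = train_test_split(
                X,
                y_idx,
                test_size=self.validation_fraction,
                stratify=y_idx,
                random_state=self.random_state % (2**32),
            )
        else:
            X_val = _as_batch(X_val)
            yv_idx = _encode(np.asarray(y_val), self.classes_)

        seed_seq = np.random.SeedSequence(self.random_state)
        subnet_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(len(self.patch_specs) + 1)]
        self.subnetworks_ = []
        self.subnet_histories_ = []
        arch_specs = []
        for p_idx, pspec in enumerate(self.patch_specs):
            arch = patch_subnet_spec(
                pspec.shape, channels=self.channels, fc_units=self.subnet_fc_units
            )
            arch_specs.append(arch)
            net = build_model(
                arch, l2=self.l2, seed=subnet_seeds[p_idx], dropout_override=self.dropout
            )
            try:
                hist = _train_network(
                    net,
                    self._extract(X, pspec),
                    y_idx,
                    self._extract(X_val, pspec),
                    yv_idx,
                    learning_rate=self.learning_rate,
                    batch_size=self.batch_size,
                    max_epochs=self.subnet_max_epochs,
                    patience=self.patience,
                    monitor=self.monitor,
                    seed=subnet_seeds[p_idx],
                )
            except RuntimeError as exc:
                raise RuntimeError(f"patch {p_idx}: {exc}") from exc
            self.subnetworks_.append(net)
            self.subnet_histories_.append(hist)

        # conv layers frozen: fusion consumes precomputed deep features
        feats = np.concatenate(
            [
                self._conv_features(net, self._extract(X, ps))
                for net, ps in zip(self.subnetworks_, self.patch_specs)
            ],
            axis=1,
        )
        feats_val = np.concatenate(
            [
                self._conv_features(net, self._extract(X_val, ps))
                for net, ps in zip(self.subnetworks_, self.patch_specs)
            ],
            axis=1,
        )
        self.fusion_spec_ = fusion_spec(arch_specs, fc_units=self.fusion_fc_units)
        self.fusion_network_ = build_model(
            self.fusion_spec_, l2=self.l2, seed=subnet_seeds[-1],
            dropout_override=self.dropout,
        )
        self.fusion_history_ = _train_network(
            self.fusion_network_,
            feats,
            y_idx,
            feats_val,
            yv_idx,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.fusion_max_epochs,
            patience=self.patience,
            monitor=self.monitor,
            seed=subnet_seeds[-1],
        )
        return self

    def conv_weight_hashes(self) -> list[str]:
        """Per-subnetwork hash over conv-layer weights (freezing audit)."""
        check_is_fitted(self, "subnetworks_")
        import hashlib

        hashes = []
        for net in self.subnetworks_:
            h = hashlib.sha256()
            for layer in net.layers:
                if type(layer).__name__ == "Conv3D":
                    for p in layer.params:
                        h.update(np.ascontiguousarray(p.value).tobytes())
            hashes.append(h.hexdigest())
        return hashes

    def predict_proba(self, X):
        check_is_fitted(self, "fusion_network_")
        X = _as_batch(X)
        feats = np.concatenate(
            [
                self._conv_features(net, self._extract(X, ps))
                for net, ps in zip(self.subnetworks_, self.patch_specs)
            ],
            axis=1,
        )
        return self.fusion_network_.predict_proba(feats)

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def score_positive(self, X, positive_label="AD"):
        col = int(np.nonzero(self.classes_ == positive_label)[0][0])
        return self.predict_proba(X)[:, col]
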