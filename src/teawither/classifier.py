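"""Scikit-learn estimators wrapping the withering network.

``LeafImageClassifier`` is a classifier over image stacks: fit takes
(n, H, W, 3) uint8 arrays and integer class labels, predict_proba returns
softmax confidence vectors. ``ConfidenceMoistureRegressor`` composes a
classifier with a moisture label table to produce continuous wet-basis
moisture and withering-degree verdicts. Both follow sklearn conventions
(get_params/set_params, clone-compatible constructors, fitted attributes
with trailing underscores).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, clone
from sklearn.utils.validation import check_is_fitted

from . import nn
from .autodiff import Tensor
from .moisture import (
    MoistureLabelTable,
    WitheringAssessment,
    predict_batch,
)

__all__ = ["LeafImageClassifier", "ConfidenceMoistureRegressor"]


def _as_image_stack(X) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim != 4 or X.shape[-1] != 3:
        raise ValueError("X must be an (n, H, W, 3) image stack")
    return X


def _to_input(X: np.ndarray) -> Tensor:
    # NHWC uint8 -> NCHW float32 in [0, 1]
    return Tensor(X.astype(np.float32).transpose(0, 3, 1, 2) / 255.0)


class LeafImageClassifier(ClassifierMixin, BaseEstimator):
    """Withering time-point classifier (RFAConv + C2f_CA backbone).

    Parameters
    ----------
    profile : {"mini", "full"} or ArchitecturePlan
        "mini" is the CPU profile (1/16 channel width, 64x64 inputs);
        "full" the full-width plan (224x224-scale inputs).
    epochs, learning_rate, batch_size, momentum, weight_decay
        Training hyperparameters; momentum is Adam's beta1.
    random_state : int
        Seeds initialization and batch shuffling.
    """

    def __init__(self, profile="mini", epochs=30, learning_rate=0.01,
                 batch_size=16, momentum=0.937, weight_decay=5e-4,
                 random_state=0, verbose=0):
        self.profile = profile
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.random_state = random_state
        self.verbose = verbose

    # -- plan -----------------------------------------------------------
    def _make_plan(self, n_classes: int) -> nn.ArchitecturePlan:
        if isinstance(self.profile, nn.ArchitecturePlan):
            plan = self.profile
            if plan.n_classes != n_classes:
                plan = nn.ArchitecturePlan(
                    stages=plan.stages,
                    n_classes=n_classes,
                    width_multiplier=plan.width_multiplier,
                    head_channels=plan.head_channels,
                    ca_reduction=plan.ca_reduction,
                )
            return plan
        if self.profile == "mini":
            return nn.mini_plan(n_classes)
        if self.profile == "full":
            return nn.default_plan(n_classes)
        raise ValueError(f"unknown profile {self.profile!r}")

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y):
        X = _as_image_stack(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        y_idx = np.searchsorted(self.classes_, y)
        plan = self._make_plan(len(self.classes_))
        rng = np.random.default_rng(self.random_state)
        self.model_ = nn.WitherNet(plan, rng=rng)
        params = self.model_.parameters()
        opt = nn.Adam(
            params,
            lr=self.learning_rate,
            betas=(self.momentum, 0.999),
            weight_decay=self.weight_decay,
        )
        n = len(X)
        self.loss_curve_ = []
        self.model_.train()
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                if len(idx) < 2:
                    continue  # batch norm needs more than one sample
                logits = self.model_(_to_input(X[idx]))
                loss = nn.cross_entropy(logits, y_idx[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            self.loss_curve_.append(float(np.mean(losses)))
            if self.verbose:
                print(f"epoch {epoch + 1}/{self.epochs} loss {self.loss_curve_[-1]:.4f}")
        self.model_.eval()
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = _as_image_stack(X)
        self.model_.eval()
        out = []
        for start in range(0, len(X), 64):
            out.append(self.model_.predict_proba(_to_input(X[start : start + 64])))
        return np.concatenate(out, axis=0)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]  # ties -> lowest index

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        check_is_fitted(self, "model_")
        nn.save_checkpoint(path, self.model_, extra={"__classes__": self.classes_})

    @classmethod
    def load(cls, path) -> "LeafImageClassifier":
        est = cls()
        est.model_, extra = nn.load_checkpoint(path)
        est.classes_ = np.asarray(
            extra.get("__classes__", np.arange(est.model_.plan.n_classes))
        )
        est.loss_curve_ = []
        return est


class ConfidenceMoistureRegressor(RegressorMixin, BaseEstimator):
    """Continuous moisture from classification confidence.

    Wraps a ``LeafImageClassifier`` (or any predict_proba estimator over the
    same classes) and a moisture label table; predict returns the
    confidence-weighted moisture fraction per image, and ``assess`` adds the
    withering-degree verdict against the moderate band.

    ``fit`` expects integer class labels; the label table supplies each
    class's moisture.
    """

    def __init__(self, classifier=None, label_table=None, decimals=None):
        self.classifier = classifier
        self.label_table = label_table
        self.decimals = decimals

    def _table(self) -> MoistureLabelTable:
        table = self.label_table
        if table is None:
            return MoistureLabelTable.reference()
        if isinstance(table, MoistureLabelTable):
            return table
        return MoistureLabelTable(tuple(table))

    def fit(self, X, y):
        table = self._table()
        y = np.asarray(y)
        if np.any((y < 0) | (y >= len(table))):
            raise ValueError("class labels outside the moisture table range")
        base = self.classifier if self.classifier is not None else LeafImageClassifier()
        self.classifier_ = clone(base)
        self.classifier_.fit(X, y)
        self.label_table_ = table
        return self

    def _check(self):
        check_is_fitted(self, "classifier_")
        n_model = len(self.classifier_.classes_)
        if n_model != len(self.label_table_):
            raise ValueError(
                f"classifier has {n_model} classes but table has {len(self.label_table_)}"
            )

    def predict(self, X) -> np.ndarray:
        self._check()
        return np.array(
            [a.predicted_moisture for a in self.assess(X)], dtype=np.float64
        )

    def assess(self, X) -> list[WitheringAssessment]:
        self._check()
        X = _as_image_stack(X)
        return predict_batch(X, self.classifier_, self.label_table_, self.decimals)
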