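"""Max-margin classification on latent codes.

Joint training needs a differentiable classification loss, so the default
head is a linear hinge objective (an SVM primal) on the latent code z,
optimized together with the autoencoder.  A post-hoc linear SVM fitted on
frozen latents is available as an alternative decision rule over the same
representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import LinearSVC

from .aae import TrainedModel
from .autodiff import Tensor, as_tensor

__all__ = ["ClassifierConfig", "classification_loss", "predict", "fit_frozen_svm"]


@dataclass(frozen=True)
class ClassifierConfig:
    mode: str = "joint_hinge"      # or "frozen_svm"
    margin: float = 1.0
    c_reg: float = 1e-3
    threshold: float = 0.0

    def __post_init__(self):
        if self.margin <= 0 or self.c_reg < 0:
            raise ValueError("margin > 0 and c_reg >= 0 required")
        if self.mode not in ("joint_hinge", "frozen_svm"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _to_pm1(y) -> np.ndarray:
    """Map labels to {-1, +1}: accepts one-hot rows or {0,1} vectors."""
    y = np.asarray(y, dtype=float)
    if y.ndim == 2:
        if not np.allclose(y.sum(axis=1), 1.0):
            raise ValueError("one-hot rows must sum to 1")
        y = y[:, 1]
    return y * 2.0 - 1.0


def classification_loss(scores, y, cfg: ClassifierConfig = ClassifierConfig(),
                        weights=None):
    """Mean hinge loss max(0, margin - s*y) plus c_reg * ||w||^2.

    ``scores`` may be a numpy vector or an autodiff tensor (joint mode);
    ``weights`` is the linear head's weight vector for the penalty term.
    """
    s = as_tensor(scores)
    y_pm = _to_pm1(y)
    if s.value.shape[0] != y_pm.shape[0]:
        raise ValueError("score / label length mismatch")
    loss = (cfg.margin - s * y_pm).relu().mean()
    if weights is not None and cfg.c_reg > 0:
        w = as_tensor(weights)
        loss = loss + cfg.c_reg * (w * w).sum()
    if isinstance(scores, Tensor) or isinstance(weights, Tensor):
        return loss
    return float(loss.value)


def fit_frozen_svm(model: TrainedModel, X: np.ndarray, y: np.ndarray,
                   c_reg: float = 1e-3) -> LinearSVC:
    """Fit a linear SVM on the frozen latent codes of training windows."""
    svm = LinearSVC(C=1.0 / max(c_reg, 1e-12), random_state=0)
    svm.fit(model.encode(X), np.asarray(y, dtype=int))
    return svm


def predict(model: TrainedModel, X: np.ndarray,
            cfg: ClassifierConfig = ClassifierConfig(),
            svm: LinearSVC | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-window scores and binary labels (1 = preictal alarm).

    ``joint_hinge`` uses the jointly trained head; ``frozen_svm`` requires a
    fitted SVM from :func:`fit_frozen_svm` and scores with its decision
    function.  A window is positive iff score > threshold.
    """
    if cfg.mode == "frozen_svm":
        if svm is None:
            raise ValueError("frozen_svm mode needs a fitted SVM")
        scores = svm.decision_function(model.encode(X))
    else:
        scores = model.classifier_scores(X)
    labels = (scores > cfg.threshold).astype(int)
    return scores, labels
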