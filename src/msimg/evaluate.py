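"""Lightweight linear-classifier check of class separability of the images.

This is a sanity probe, not the downstream model: images are flattened and
fed to an L2 logistic regression under stratified k-fold cross-validation.
If even a linear model separates the classes from the multi-channel
representation, the representation carries class signal; a null corpus must
score at chance.

Features are deliberately NOT standardized: all pixels already share the
[0, 1] intensity scale, and per-feature standardization would blow sparse
near-constant background pixels up to huge z-scores that swamp the signal
under L2 regularization.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_validate

from .patches import MultiChannelImage

__all__ = ["evaluate_separability"]


def evaluate_separability(
    images: Sequence[MultiChannelImage | np.ndarray],
    labels: Sequence[str] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> dict[str, float]:
    """Stratified k-fold accuracy / macro-F1 of a linear probe on flattened images.

    ``labels`` may be omitted when the images carry their own ``label``
    attribute.  Returns mean and standard deviation across folds; a fixed
    seed fixes the folds and hence the numbers.
    """
    arrs = [im.tensor if isinstance(im, MultiChannelImage) else np.asarray(im) for im in images]
    if labels is None:
        labels = [im.label for im in images]  # type: ignore[union-attr]
        if any(lab is None for lab in labels):
            raise ValueError("labels missing: pass them explicitly or use labeled images")
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes to evaluate separability")
    X = np.stack(arrs).reshape(len(arrs), -1)
    clf = LogisticRegression(max_iter=5000, C=1.0)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = cross_validate(clf, X, y, cv=cv, scoring=("accuracy", "f1_macro"))
    return {
        "accuracy_mean": float(np.mean(scores["test_accuracy"])),
        "accuracy_sd": float(np.std(scores["test_accuracy"])),
        "f1_mean": float(np.mean(scores["test_f1_macro"])),
        "f1_sd": float(np.std(scores["test_f1_macro"])),
        "folds": float(folds),
    }
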