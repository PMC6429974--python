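"""Soft-margin linear SVM staging of beats into ordinal classes 0-3.

Multiclass staging uses the one-vs-one construction: one binary soft-margin
separator per unordered class pair, each minimizing the standard primal
objective ``1/2 ||w||^2 + C sum(xi)`` on that pair's beats, followed by
majority voting. The regularization coefficient C trades training error
against margin width; the study grid spans 0.001 to 100 in decades. Voting
ties are broken toward the LOWER class index — the less severe stage — which
is deterministic and conservative on alarm rate.

The pairwise quadratic programs are solved by libsvm (via scikit-learn); the
voting layer, tie rule and model container live here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .features import FeatureMatrix

__all__ = ["C_GRID", "StagingModel", "train_svm", "predict_classes"]

#: Regularization grid explored by the evaluation protocol.
C_GRID = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class StagingModel:
    """Linear one-vs-one multiclass SVM.

    ``weights[p]``/``biases[p]`` parametrize the separator of ``pairs[p] =
    (ci, cj)`` with ``ci < cj``; decision value ``w.x + b > 0`` votes for the
    lower class ``ci``, ``< 0`` for ``cj``, and exactly 0 votes ``ci`` (the
    tie rule).
    """

    C: float
    k: int
    classes_present: np.ndarray        # sorted class labels seen in training
    pairs: list[tuple[int, int]]
    weights: np.ndarray                # (n_pairs, k)
    biases: np.ndarray                 # (n_pairs,)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """Pairwise decision values, shape (n, n_pairs); antisymmetric in the
        pair's label order by construction."""
        return X @ self.weights.T + self.biases


def train_svm(features: FeatureMatrix, C: float, tol: float = 1e-6) -> StagingModel:
    """Train the one-vs-one linear soft-margin SVM at regularization ``C``.

    Deterministic for a fixed input order and solver tolerance. Requires at
    least two classes and finite features.
    """
    if not C > 0:
        raise ValueError("C must be positive")
    X = np.asarray(features.scores, dtype=float)
    y = np.asarray(features.labels, dtype=int)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data contains a single class")
    svc = SVC(kernel="linear", C=C, tol=tol, decision_function_shape="ovo")
    svc.fit(X, y)
    # libsvm's ovo coef_/intercept_ rows follow pair order (0,1),(0,2),...
    # with positive decision favouring the pair's first (lower) class —
    # except in the 2-class case, where sklearn flips the sign so that
    # positive favours classes_[1]; normalize to "positive -> lower class"
    pairs = [
        (int(classes[i]), int(classes[j]))
        for i in range(classes.size)
        for j in range(i + 1, classes.size)
    ]
    sign = -1.0 if classes.size == 2 else 1.0
    return StagingModel(
        C=float(C),
        k=X.shape[1],
        classes_present=classes,
        pairs=pairs,
        weights=sign * np.asarray(svc.coef_, dtype=float),
        biases=sign * np.asarray(svc.intercept_, dtype=float),
    )


def predict_classes(model: StagingModel, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Stage beats by one-vs-one majority vote with lower-class tie-break."""
    X = features.scores if isinstance(features, FeatureMatrix) else np.asarray(features)
    if X.ndim != 2 or X.shape[1] != model.k:
        raise ValueError(f"expected (n, {model.k}) features, got {X.shape}")
    dec = model.decision_values(X)
    n = X.shape[0]
    all_classes = model.classes_present
    votes = np.zeros((n, all_classes.size), dtype=int)
    idx = {int(c): i for i, c in enumerate(all_classes)}
    for p, (ci, cj) in enumerate(model.pairs):
        lo = dec[:, p] >= 0.0        # zero decision votes the lower class
        votes[lo, idx[ci]] += 1
        votes[~lo, idx[cj]] += 1
    # argmax returns the first maximum; classes are sorted ascending, so vote
    # ties resolve to the lower (less severe) class automatically
    return all_classes[np.argmax(votes, axis=1)]
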