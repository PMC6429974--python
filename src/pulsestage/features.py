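"""PCA parametrization of the 33-sample beat matrix.

Each normalized beat is expressed as scores on orthonormal waveform shape
modes obtained from the covariance PCA of the (unstandardized, mmHg-valued)
beat matrix; the leading few modes capture pulse-pressure, upstroke and
dicrotic-notch variation and serve as the classifier's features. To make the
basis reproducible across runs and solvers, every component is sign-fixed so
that its largest-magnitude loading is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .beats import BeatMatrix

__all__ = ["PCABasis", "FeatureMatrix", "fit_pca", "project"]


@dataclass
class PCABasis:
    """Mean waveform plus orthonormal shape modes, variance-ordered."""

    mean_vector: np.ndarray        # (33,)
    components: np.ndarray         # (33, m), columns orthonormal
    explained_variance: np.ndarray # (m,) nonincreasing
    fitted_on: str = ""

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


@dataclass
class FeatureMatrix:
    """Per-beat scores on the first k shape modes, bookkeeping carried."""

    scores: np.ndarray             # (n_beats, k)
    labels: np.ndarray
    subject_ids: np.ndarray
    onsets_s: np.ndarray
    fitted_on: str = ""

    def __len__(self) -> int:
        return self.scores.shape[0]


def fit_pca(matrix: BeatMatrix, fitted_on: str = "") -> PCABasis:
    """Fit the covariance PCA of a beat matrix.

    Components are the right-singular vectors of the centered matrix, ordered
    by decreasing explained variance, each sign-fixed so its largest-|loading|
    entry is positive.

    Raises
    ------
    ValueError
        If fewer than 2 beats are given or all beats are identical (zero
        variance: nothing to parametrize).
    """
    X = np.asarray(matrix.values, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 beats")
    if np.ptp(X, axis=0).max() == 0.0:
        raise ValueError("all beats identical: zero variance in every direction")
    pca = PCA(svd_solver="full")
    pca.fit(X)
    comps = pca.components_.T.copy()          # (33, m)
    flip = np.sign(comps[np.abs(comps).argmax(axis=0), np.arange(comps.shape[1])])
    flip[flip == 0] = 1.0
    comps *= flip
    return PCABasis(
        mean_vector=pca.mean_.copy(),
        components=comps,
        explained_variance=pca.explained_variance_.copy(),
        fitted_on=fitted_on,
    )


def project(
    basis: PCABasis, matrix: BeatMatrix, k: int, expect_fitted_on: str | None = None
) -> FeatureMatrix:
    """Score beats on the first ``k`` shape modes of ``basis``.

    ``expect_fitted_on`` is a leakage guard: when given, it must match the
    basis' ``fitted_on`` tag, so held-out data can only ever be scored with a
    basis fitted on the corresponding training fold.
    """
    if not 1 <= k <= basis.n_components:
        raise ValueError(f"k={k} out of range 1..{basis.n_components}")
    if expect_fitted_on is not None and basis.fitted_on != expect_fitted_on:
        raise AssertionError(
            f"PCA basis fitted on {basis.fitted_on!r}, expected "
            f"{expect_fitted_on!r}: possible train/test leakage"
        )
    scores = (matrix.values - basis.mean_vector) @ basis.components[:, :k]
    return FeatureMatrix(
        scores=scores,
        labels=matrix.labels.copy(),
        subject_ids=matrix.subject_ids.copy(),
        onsets_s=matrix.onsets_s.copy(),
        fitted_on=basis.fitted_on,
    )
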