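"""Rotation-forest classifier built from scratch on decision-tree learners.

Each of the L base trees is trained on a rotated copy of the data.  The
rotation is assembled per tree as follows:

1. The m feature indices are permuted and split into K disjoint subsets of
   near-equal size.
2. For each subset, a bootstrap sample (75% of the rows by default, drawn
   with replacement) restricted to that subset's columns is mean-centred and
   decomposed by PCA; all loadings are kept, so each block contributes a
   square coefficient matrix.
3. The block loadings are placed into an m x m matrix at the rows/columns of
   their original feature indices, producing a sparse rotation matrix whose
   entries linking features of different subsets are zero.
4. An unpruned CART tree is fit on the full (centred, rotated) training set.

Prediction averages the per-tree class-probability vectors (mean
combination) and assigns the argmax class; ties break toward the class
earlier in the stored class order.

The bootstrap exists only to diversify the PCA loadings; a fraction of
exactly 1.0 means the full data is used unresampled, so the configuration
K=1, L=1, fraction=1.0 degenerates to a single tree on the classical PCA
rotation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import joblib
import numpy as np
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class RotationForestConfig:
    """Hyperparameters of the rotation forest.

    n_subsets
        K, the number of disjoint feature subsets per tree.  Default 28.
    n_trees
        L, the ensemble size.  Default 26.
    bootstrap_fraction
        Fraction of rows resampled (with replacement) to fit each block's
        PCA; exactly 1.0 uses all rows unresampled.  Default 0.75.
    seed
        Seed controlling partitions, bootstraps and tree randomness.
    tree_params
        Extra keyword arguments passed through to the CART base learner.
    """

    n_subsets: int = 28
    n_trees: int = 26
    bootstrap_fraction: float = 0.75
    seed: int = 0
    tree_params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0 < self.bootstrap_fraction <= 1:
            raise ValueError("bootstrap_fraction must be in (0, 1]")


def partition_features(
    m: int, K: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Randomly split feature indices 0..m-1 into K disjoint subsets.

    A random permutation is chunked into K parts whose sizes differ by at
    most one (the first ``m % K`` subsets get the extra feature).  Indices
    within each subset are returned sorted, so the subset is a set — the
    block rotation does not depend on the draw order inside it.
    """
    if not 1 <= K <= m:
        raise ValueError(f"need 1 <= K <= m, got K={K}, m={m}")
    return [np.sort(s) for s in np.array_split(rng.permutation(m), K)]


def _block_loadings(Xb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centred PCA loadings of one bootstrap block.

    Returns ``(mean, W)`` where W is C x C with principal-axis columns.
    Rank-deficient blocks are padded with zero loadings; a block with no
    variance at all falls back to identity loadings.  Both cases are logged.
    """
    C = Xb.shape[1]
    mean = Xb.mean(axis=0)
    Xc = Xb - mean
    if not np.any(Xc):
        warnings.warn(
            "feature block has zero variance in every column; "
            "using identity loadings",
            RuntimeWarning,
            stacklevel=3,
        )
        return mean, np.eye(C)
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(Xc.shape) * np.finfo(float).eps))
    W = np.zeros((C, C))
    W[:, :rank] = Vt[:rank].T
    if rank < C:
        # routine for sparse/binary blocks under bootstrap duplication
        logger.debug(
            "PCA block rank %d < %d features; padding with zero loadings",
            rank, C,
        )
    return mean, W


@dataclass
class _TreeRotation:
    """One ensemble member: its rotation, centring vector and fitted tree."""

    partition: list[np.ndarray]
    rotation: np.ndarray  # m x m, block-sparse under the partition
    center: np.ndarray    # length-m translation applied before rotating
    tree: DecisionTreeClassifier


class RotationForestClassifier:
    """Rotation-forest ensemble with scikit-learn-style fit/predict API."""

    def __init__(self, config: RotationForestConfig | None = None, **kwargs):
        if config is None:
            config = RotationForestConfig(**kwargs)
        elif kwargs:
            raise TypeError("pass either a config or keyword overrides")
        self.config = config
        self.classes_: np.ndarray | None = None
        self.n_features_: int | None = None
        self.trees_: list[_TreeRotation] = []

    # -- training ---------------------------------------------------------

    def fit(self, X: np.ndarray, y: Sequence) -> "RotationForestClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, m = X.shape
        if n < 2:
            raise ValueError("need at least 2 training samples")
        if np.isnan(X).any():
            raise ValueError("X contains NaN")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes")
        if self.config.n_subsets > m:
            raise ValueError(
                f"n_subsets={self.config.n_subsets} exceeds "
                f"feature count m={m}"
            )
        self.n_features_ = m

        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        n_boot = int(round(cfg.bootstrap_fraction * n))
        self.trees_ = []
        for _ in range(cfg.n_trees):
            partition = partition_features(m, cfg.n_subsets, rng)
            R = np.zeros((m, m))
            center = np.zeros(m)
            for subset in partition:
                if cfg.bootstrap_fraction == 1.0:
                    rows = np.arange(n)
                else:
                    rows = rng.integers(0, n, size=n_boot)
                mean, W = _block_loadings(X[np.ix_(rows, subset)])
                R[np.ix_(subset, subset)] = W
                center[subset] = mean
            tree_seed = int(rng.integers(_MAX_SEED))
            params = dict(cfg.tree_params)
            params.setdefault("random_state", tree_seed)
            tree = DecisionTreeClassifier(**params)
            tree.fit((X - center) @ R, y)
            self.trees_.append(
                _TreeRotation(partition=partition, rotation=R,
                              center=center, tree=tree)
            )
        return self

    # -- prediction -------------------------------------------------------

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        if not self.trees_:
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_:
            raise ValueError(
                f"X must have {self.n_features_} columns, "
                f"got shape {X.shape}"
            )
        return X

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Mean of the per-tree class-probability vectors; rows sum to 1."""
        X = self._check_X(X)
        proba = np.zeros((X.shape[0], self.classes_.size))
        for tr in self.trees_:
            proba += tr.tree.predict_proba((X - tr.center) @ tr.rotation)
        return proba / len(self.trees_)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Argmax class of the mean probabilities (first class wins ties)."""
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialise the fitted model (config, classes, rotations, trees)."""
        joblib.dump(self, Path(path))

    @staticmethod
    def load(path: str | Path) -> "RotationForestClassifier":
        model = joblib.load(Path(path))
        if not isinstance(model, RotationForestClassifier):
            raise TypeError(f"{path} does not contain a rotation forest")
        return model


def fit(
    X: np.ndarray, y: Sequence, config: RotationForestConfig | None = None
) -> RotationForestClassifier:
    """Functional entry point: fit a rotation forest and return the model."""
    return RotationForestClassifier(config).fit(X, y)
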