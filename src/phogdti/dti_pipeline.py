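"""Drug-target pair assembly, negative downsampling, metrics and 5-fold CV.

A drug-target interaction (DTI) benchmark is a bipartite graph: drugs on one
side, target proteins on the other, with verified interactions as edges.
Every (drug, protein) pair is a candidate; the verified pairs are positives
and an equal-size random draw from the remaining pairs serves as the
negative class (downsampling).  Each pair is described by concatenating the
drug's 881-bit substructure fingerprint with the protein's 680-dimensional
PHOG descriptor (1561 features at defaults, fingerprint block first), and a
rotation forest is evaluated under stratified 5-fold cross-validation with
accuracy, precision, sensitivity, specificity, the Matthews correlation
coefficient and ROC AUC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .fingerprints import Fingerprint
from .rotation_forest import RotationForestClassifier, RotationForestConfig

_MAX_SEED = 2**31 - 1


# ---------------------------------------------------------------------------
# interaction sets and candidate pairs
# ---------------------------------------------------------------------------

@dataclass
class InteractionSet:
    """A bipartite DTI network: entity lists plus the verified positive pairs."""

    drugs: list[str]
    proteins: list[str]
    positives: set[tuple[str, str]]

    def __post_init__(self) -> None:
        drugs, proteins = set(self.drugs), set(self.proteins)
        if len(drugs) != len(self.drugs) or len(proteins) != len(self.proteins):
            raise ValueError("duplicate drug or protein ids")
        for d, p in self.positives:
            if d not in drugs:
                raise ValueError(f"positive pair references unknown drug {d!r}")
            if p not in proteins:
                raise ValueError(
                    f"positive pair references unknown protein {p!r}"
                )

    @property
    def n_candidates(self) -> int:
        return len(self.drugs) * len(self.proteins)


def enumerate_candidates(
    iset: InteractionSet,
) -> list[tuple[str, str, int]]:
    """All |drugs| x |proteins| pairs, labelled 1 iff verified interacting."""
    if not iset.drugs or not iset.proteins:
        raise ValueError("drug and protein lists must be nonempty")
    return [
        (d, p, int((d, p) in iset.positives))
        for d in iset.drugs
        for p in iset.proteins
    ]


def sample_negatives(
    iset: InteractionSet, n: int | None = None, seed: int = 0
) -> list[tuple[str, str]]:
    """Downsample the non-interacting pairs to serve as the negative class.

    Draws ``n`` distinct non-positive pairs uniformly without replacement
    (default ``n = |positives|``, giving a balanced data set).  Deterministic
    per seed.
    """
    if n is None:
        n = len(iset.positives)
    pool = [
        (d, p)
        for d in iset.drugs
        for p in iset.proteins
        if (d, p) not in iset.positives
    ]
    if n > len(pool):
        raise ValueError(
            f"requested {n} negatives but only {len(pool)} "
            f"non-interacting pairs are available"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# pair feature vectors
# ---------------------------------------------------------------------------

@dataclass
class PairSample:
    """One labelled drug-target pair with its concatenated feature vector."""

    drug_id: str
    protein_id: str
    label: int
    features: np.ndarray


def build_pair_features(
    pairs: Sequence[tuple[str, str, int]],
    phog_table: Mapping[str, np.ndarray],
    fp_table: Mapping[str, Fingerprint],
) -> list[PairSample]:
    """Describe each (drug, protein, label) pair by fingerprint + PHOG.

    The feature vector is the drug's fingerprint bits (as reals) followed by
    the protein's PHOG descriptor: 881 + 680 = 1561 entries at defaults.
    Missing ids raise a KeyError naming the id.
    """
    samples = []
    for drug_id, protein_id, label in pairs:
        if drug_id not in fp_table:
            raise KeyError(f"drug {drug_id!r} missing from fingerprint table")
        if protein_id not in phog_table:
            raise KeyError(f"protein {protein_id!r} missing from PHOG table")
        features = np.concatenate([
            fp_table[drug_id].bits.astype(float),
            np.asarray(phog_table[protein_id], dtype=float),
        ])
        samples.append(PairSample(drug_id, protein_id, int(label), features))
    return samples


def stack_samples(
    samples: Sequence[PairSample],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack PairSamples into an (X, y) pair for the classifier."""
    X = np.vstack([s.features for s in samples])
    y = np.array([s.label for s in samples])
    return X, y


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN counts of a binary prediction (positive class = 1)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(
    y_true: np.ndarray, y_pred: np.ndarray
) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


@dataclass(frozen=True)
class Metrics:
    """Acc/Pre/Sen/Spec/MCC (+AUC when scores are available), as fractions."""

    acc: float
    pre: float
    sen: float
    spec: float
    mcc: float
    auc: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "acc": self.acc, "pre": self.pre, "sen": self.sen,
            "spec": self.spec, "mcc": self.mcc, "auc": self.auc,
        }


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve by trapezoidal integration over thresholds."""
    fpr, tpr, _ = roc_curve(y_true, scores)
    return float(np.trapezoid(tpr, fpr))


def compute_metrics(
    c: ConfusionCounts,
    scores: np.ndarray | None = None,
    y_true: np.ndarray | None = None,
) -> Metrics:
    """Standard confusion-matrix metrics, plus AUC when scores are given.

    Acc = (TP+TN)/total, Sen = TP/(TP+FN), Pre = TP/(TP+FP),
    Spec = TN/(TN+FP), MCC = (TN*TP - FN*FP) / sqrt((TN+FN)(TP+FP)(TN+FP)(TP+FN)).

    A metric whose denominator is zero is NaN with a warning (an all-one-class
    truth makes the rate metrics undefined, not silently 0); a zero MCC
    denominator yields MCC = 0 with a warning, the conventional limit.
    """
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn

    def _rate(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(
                f"{name} is undefined (zero denominator)", RuntimeWarning,
                stacklevel=3,
            )
            return float("nan")
        return num / den

    acc = _rate(tp + tn, c.total, "accuracy")
    sen = _rate(tp, tp + fn, "sensitivity")
    pre = _rate(tp, tp + fp, "precision")
    spec = _rate(tn, tn + fp, "specificity")
    mcc_den = (tn + fn) * (tp + fp) * (tn + fp) * (tp + fn)
    if mcc_den == 0:
        warnings.warn(
            "MCC denominator is zero; defining MCC = 0", RuntimeWarning,
            stacklevel=2,
        )
        mcc = 0.0
    else:
        mcc = (tn * tp - fn * fp) / np.sqrt(mcc_den)
    auc = None
    if scores is not None:
        if y_true is None:
            raise ValueError("y_true is required to compute AUC from scores")
        auc = roc_auc(y_true, scores)
    return Metrics(acc=acc, pre=pre, sen=sen, spec=spec, mcc=float(mcc),
                   auc=auc)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvReport:
    """Per-fold metrics with their mean and sample standard deviation."""

    folds: list[Metrics]
    roc_points: list[tuple[np.ndarray, np.ndarray]] = field(
        default_factory=list
    )

    def _values(self, name: str) -> np.ndarray:
        return np.array([getattr(m, name) for m in self.folds], dtype=float)

    def mean(self, name: str) -> float:
        return float(np.nanmean(self._values(name)))

    def std(self, name: str) -> float:
        vals = self._values(name)
        return float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0

    def summary(self) -> dict[str, tuple[float, float]]:
        return {
            name: (self.mean(name), self.std(name))
            for name in ("acc", "pre", "sen", "spec", "mcc", "auc")
        }

    def to_dict(self) -> dict:
        return {
            "folds": [m.as_dict() for m in self.folds],
            "mean": {k: v[0] for k, v in self.summary().items()},
            "std": {k: v[1] for k, v in self.summary().items()},
        }

    def to_json(self, path: str | Path | None = None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            Path(path).write_text(text)
        return text


def cross_validate(
    samples: Sequence[PairSample] | tuple[np.ndarray, np.ndarray],
    config: RotationForestConfig | None = None,
    folds: int = 5,
    seed: int = 0,
    stratified: bool = True,
) -> CvReport:
    """K-fold cross-validation of the rotation forest on labelled pairs.

    Folds are stratified by default (per-class sizes differ by at most one);
    each fold is held out once.  The ROC score of a pair is the mean
    ensemble confidence for the interacting class.  Per-fold model seeds are
    derived from ``seed``.
    """
    if isinstance(samples, tuple):
        X, y = samples
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
    else:
        X, y = stack_samples(samples)
    if config is None:
        config = RotationForestConfig()
    classes, counts = np.unique(y, return_counts=True)
    if stratified and counts.min() < folds:
        raise ValueError(
            f"need at least {folds} samples of each class for "
            f"stratified {folds}-fold CV"
        )
    splitter_cls = StratifiedKFold if stratified else KFold
    splitter = splitter_cls(n_splits=folds, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(0, _MAX_SEED, size=folds)

    report = CvReport(folds=[])
    for k, (train, test) in enumerate(splitter.split(X, y)):
        fold_cfg = RotationForestConfig(
            n_subsets=config.n_subsets,
            n_trees=config.n_trees,
            bootstrap_fraction=config.bootstrap_fraction,
            seed=int(fold_seeds[k]),
            tree_params=config.tree_params,
        )
        model = RotationForestClassifier(fold_cfg).fit(X[train], y[train])
        proba = model.predict_proba(X[test])
        pos_col = int(np.argmax(model.classes_ == 1))
        scores = proba[:, pos_col]
        y_pred = model.predict(X[test])
        c = confusion_counts(y[test], y_pred)
        report.folds.append(compute_metrics(c, scores=scores, y_true=y[test]))
        fpr, tpr, _ = roc_curve(y[test], scores)
        report.roc_points.append((fpr, tpr))
    return report


# ---------------------------------------------------------------------------
# grid search over (K, L)
# ---------------------------------------------------------------------------

@dataclass
class GridSearchResult:
    """Mean CV accuracy surface over the (K, L) grid, with the best cell."""

    K_grid: list[int]
    L_grid: list[int]
    surface: np.ndarray  # |K_grid| x |L_grid| mean accuracies
    best: tuple[int, int]  # (K, L) of the highest accuracy


def grid_search(
    samples: Sequence[PairSample] | tuple[np.ndarray, np.ndarray],
    K_grid: Sequence[int],
    L_grid: Sequence[int],
    folds: int = 5,
    seed: int = 0,
    bootstrap_fraction: float = 0.75,
) -> GridSearchResult:
    """Sweep the subset count K and ensemble size L, scoring by mean CV accuracy.

    K values exceeding the feature count are skipped (NaN in the surface)
    with a warning.  Ties break toward smaller (K, L) in grid order.
    """
    if not K_grid or not L_grid:
        raise ValueError("K_grid and L_grid must be nonempty")
    if isinstance(samples, tuple):
        X, y = samples
    else:
        X, y = stack_samples(samples)
    m = np.asarray(X).shape[1]
    surface = np.full((len(K_grid), len(L_grid)), np.nan)
    best: tuple[int, int] | None = None
    best_acc = -np.inf
    for i, K in enumerate(K_grid):
        if K > m:
            warnings.warn(
                f"K={K} exceeds feature count {m}; skipped", RuntimeWarning,
                stacklevel=2,
            )
            continue
        for j, L in enumerate(L_grid):
            cfg = RotationForestConfig(
                n_subsets=K, n_trees=L,
                bootstrap_fraction=bootstrap_fraction, seed=seed,
            )
            report = cross_validate((X, y), cfg, folds=folds, seed=seed)
            acc = report.mean("acc")
            surface[i, j] = acc
            if acc > best_acc:
                best_acc = acc
                best = (K, L)
    if best is None:
        raise ValueError("every K in the grid exceeded the feature count")
    return GridSearchResult(
        K_grid=list(K_grid), L_grid=list(L_grid), surface=surface, best=best
    )


# ---------------------------------------------------------------------------
# on-disk formats and plotting
# ---------------------------------------------------------------------------

def read_interactions(path: str | Path) -> list[tuple[str, str]]:
    """Read positive (drug_id, protein_id) pairs from a two-column TSV."""
    pairs = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(
                f"{path}:{lineno}: expected 'drug_id<TAB>protein_id'"
            )
        pairs.append((parts[0], parts[1]))
    return pairs


def write_interactions(
    pairs: Sequence[tuple[str, str]], path: str | Path
) -> None:
    Path(path).write_text(
        "".join(f"{d}\t{p}\n" for d, p in pairs)
    )


def plot_roc(report: CvReport, path: str | Path) -> None:
    """Save per-fold ROC curves (with AUCs) of a CV report to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for k, (fpr, tpr) in enumerate(report.roc_points):
        auc = report.folds[k].auc
        label = f"fold {k + 1}" + (f" (AUC={auc:.4f})" if auc is not None else "")
        ax.plot(fpr, tpr, label=label)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"mean AUC = {report.mean('auc'):.4f}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
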