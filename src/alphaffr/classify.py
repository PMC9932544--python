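"""Permutation-validated SVM decoding of perceptual performance from FFR spectra.

Poor vs. good performers (clear-condition target detection, 30th/70th
percentile split) are classified from the 226-point amplitude spectra of
their low- or high-alpha FFR averages.  Each iteration re-randomizes a
stratified four-fold split, oversamples the minority class inside the
training folds only, fits an RBF-kernel SVM (C = 1,000, gamma = scale) on
raw amplitudes, and averages the fold accuracies.  Significance comes from
a feature-shuffle null (each participant's 226 features permuted
independently, per iteration) and the empirical p-value
``p = (a + 1)/(n + 1)`` where ``a`` counts null accuracies strictly
exceeding the median of the actual accuracy distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

N_FEATURES = 226
N_FOLDS = 4
SVM_C = 1000.0
DEFAULT_ITERATIONS = 5000


@dataclass
class FeatureMatrix:
    """Participants x 226 spectral amplitudes with binary performance labels."""

    X: np.ndarray
    y: np.ndarray  # 0 = poor, 1 = good
    participants: tuple[str, ...]
    provenance: dict

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[1] != N_FEATURES:
            raise ValueError(
                f"feature matrix must have exactly {N_FEATURES} columns, "
                f"got {self.X.shape}"
            )
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values")
        if set(np.unique(self.y)) - {0, 1}:
            raise ValueError("labels must be binary (0 = poor, 1 = good)")
        if len(set(self.participants)) != len(self.participants):
            raise ValueError("duplicate participant ids")
        if len(self.participants) != self.X.shape[0]:
            raise ValueError("participants must align with rows")


def build_features(
    spectra: dict,
    labels: dict,
    alpha_state: str,
    condition: str,
) -> FeatureMatrix:
    """Assemble the classifier input from per-participant spectra.

    ``spectra`` maps participant id -> 226-point amplitude array for the
    chosen alpha state and condition; ``labels`` maps id -> 'poor'/'good'.
    Only poor/good participants enter (average-level listeners are
    excluded upstream).
    """
    ids = sorted(pid for pid, lab in labels.items() if lab in ("poor", "good"))
    if not ids:
        raise ValueError("no poor/good participants to classify")
    X = np.vstack([np.asarray(spectra[pid], dtype=float) for pid in ids])
    y = np.array([1 if labels[pid] == "good" else 0 for pid in ids])
    return FeatureMatrix(
        X=X,
        y=y,
        participants=tuple(ids),
        provenance={"alpha_state": alpha_state, "condition": condition},
    )


def _oversample(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Random minority oversampling (with replacement) to class balance."""
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("a class is absent from the training fold")
    n_max = counts.max()
    idx = []
    for cls, cnt in zip(classes, counts):
        members = np.flatnonzero(y == cls)
        idx.append(members)
        if cnt < n_max:
            idx.append(rng.choice(members, size=n_max - cnt, replace=True))
    idx = np.concatenate(idx)
    return X[idx], y[idx]


def crossval_accuracy(features: FeatureMatrix, seed) -> float:
    """Mean accuracy of one stratified four-fold CV iteration.

    Oversampling happens strictly inside the training folds; held-out
    folds are never resampled.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    y = features.y
    if min(np.bincount(y)) < N_FOLDS:
        raise ValueError(f"need >= {N_FOLDS} participants per class")
    skf = StratifiedKFold(
        n_splits=N_FOLDS, shuffle=True, random_state=int(rng.integers(2**31))
    )
    accs = []
    for train, test in skf.split(features.X, y):
        Xt, yt = _oversample(features.X[train], y[train], rng)
        clf = SVC(kernel="rbf", C=SVM_C, gamma="scale")
        clf.fit(Xt, yt)
        accs.append(float(np.mean(clf.predict(features.X[test]) == y[test])))
    return float(np.mean(accs))


def run_iterations(
    features: FeatureMatrix, n_iterations: int = DEFAULT_ITERATIONS, seed=0
) -> np.ndarray:
    """Accuracy distribution over independent fold/oversampling re-randomizations."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return np.array([crossval_accuracy(features, rng) for _ in range(n_iterations)])


def null_distribution(
    features: FeatureMatrix, n_iterations: int = DEFAULT_ITERATIONS, seed=0
) -> np.ndarray:
    """Feature-shuffle null: permute each participant's 226 features, re-run.

    The shuffle is redrawn every iteration (each row permuted
    independently), then the identical train/test procedure runs on the
    shuffled matrix.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = np.empty(n_iterations)
    for i in range(n_iterations):
        Xs = features.X.copy()
        for row in Xs:
            rng.shuffle(row)
        fm = FeatureMatrix(
            X=Xs,
            y=features.y,
            participants=features.participants,
            provenance={**features.provenance, "null": True},
        )
        out[i] = crossval_accuracy(fm, rng)
    return out


@dataclass
class ClassifierSignificance:
    """Empirical significance of the actual accuracy distribution vs. the null."""

    actual_median: float
    null_median: float
    a: int  # null accuracies strictly exceeding the actual median
    n: int
    p: float

    def __post_init__(self) -> None:
        assert self.p == (self.a + 1) / (self.n + 1)


def empirical_p(actual: np.ndarray, null: np.ndarray) -> ClassifierSignificance:
    """p = (a + 1)/(n + 1), a = #{null > median(actual)} (strict)."""
    actual = np.asarray(actual, dtype=float)
    null = np.asarray(null, dtype=float)
    if actual.size == 0 or null.size == 0:
        raise ValueError("empty accuracy distribution")
    med = float(np.median(actual))
    a = int(np.sum(null > med))
    n = int(null.size)
    return ClassifierSignificance(
        actual_median=med,
        null_median=float(np.median(null)),
        a=a,
        n=n,
        p=(a + 1) / (n + 1),
    )


def classify_performance(
    features: FeatureMatrix, n_iterations: int = DEFAULT_ITERATIONS, seed=0
) -> dict:
    """Full procedure: actual distribution, null distribution, empirical p."""
    rng = np.random.default_rng(seed)
    actual = run_iterations(features, n_iterations, rng)
    null = null_distribution(features, n_iterations, rng)
    sig = empirical_p(actual, null)
    return {"actual": actual, "null": null, "significance": sig}
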