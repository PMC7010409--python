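"""Iterated random-forest classification protocol.

The protocol trains a random forest ``iterations`` times (default 50) on
group-balanced training draws and evaluates each model on the held-out
samples. With N samples in G groups and a smallest group of size n, the
per-group training count is P = floor(N / G); when that would exhaust the
smallest group (P >= n) it falls back to P = floor(0.75 n), reconciling the
balanced-draw construction with a 75% training fraction. Accuracy is
averaged over iterations; per-group sensitivity and specificity come from
the per-iteration confusion matrices, and each sample accumulates a
prediction rate: the fraction of the iterations that held it out in which it
was classified correctly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import ProtocolError, ValidationError

MIN_COHORT = 20


@dataclass(frozen=True)
class ClassifierSpec:
    """Configuration of one classification run."""

    group_variable: str
    features: tuple[str, ...]
    iterations: int = 50
    train_fraction: float = 0.75
    seed: int = 0
    n_trees: int = 500
    max_features: str | float = "sqrt"

    def __post_init__(self):
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if not self.features:
            raise ValidationError("at least one feature is required")


@dataclass(eq=False)
class ClassifierReport:
    per_iteration_accuracy: np.ndarray
    global_accuracy: float
    per_group_sensitivity: pd.Series
    per_group_specificity: pd.Series
    per_sample_prediction_rate: pd.Series
    confusion: pd.DataFrame          # aggregate, rows = true, cols = predicted
    training_count: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "global_accuracy": self.global_accuracy,
            "training_count": self.training_count,
            "per_iteration_accuracy": self.per_iteration_accuracy.tolist(),
            "per_group_sensitivity": self.per_group_sensitivity.to_dict(),
            "per_group_specificity": self.per_group_specificity.to_dict(),
            "confusion": {
                str(t): {str(p): int(v) for p, v in row.items()}
                for t, row in self.confusion.iterrows()
            },
        }


def training_count(N: int, G: int, n: int) -> int:
    """Per-group training draw P.

    P = floor(N/G); when drawing P from the smallest group (size n) would
    leave it without held-out members (P >= n), P falls back to
    floor(0.75 n). The cohort must have at least 20 samples and the final P
    must exceed 1.
    """
    if N < MIN_COHORT:
        raise ProtocolError(f"cohort too small: N={N} < {MIN_COHORT}")
    if G < 2:
        raise ProtocolError("need at least two groups")
    P = N // G
    if P >= n:
        P = int(0.75 * n)
    if P <= 1:
        raise ProtocolError(f"training draw P={P} is too small")
    return P


def validate_features(features: pd.DataFrame, G: int) -> pd.DataFrame:
    """Drop categorical features with as many or more levels than groups.

    Numeric features are always accepted; rejected columns warn, and an empty
    result is an error.
    """
    keep = []
    for col in features.columns:
        series = features[col]
        if pd.api.types.is_numeric_dtype(series):
            keep.append(col)
            continue
        z = series.nunique(dropna=True)
        if z >= G:
            warnings.warn(
                f"categorical feature {col!r} has {z} levels >= {G} groups; "
                "rejected")
        else:
            keep.append(col)
    if not keep:
        raise ProtocolError("no usable features remain after validation")
    return features[keep]


def _encode(features: pd.DataFrame) -> pd.DataFrame:
    cat = [c for c in features.columns
           if not pd.api.types.is_numeric_dtype(features[c])]
    if cat:
        return pd.get_dummies(features, columns=cat, dtype=float)
    return features.astype(float)


def run_protocol(features: pd.DataFrame, labels: pd.Series,
                 spec: ClassifierSpec) -> ClassifierReport:
    """Run the iterated balanced-training random-forest protocol.

    ``features`` and ``labels`` share an index of sample ids. Draws are
    without replacement within each iteration; iterations use independent
    sub-seeds spawned from ``spec.seed`` so the whole report is reproducible.
    """
    df = features.reindex(labels.index)
    if df.isna().any().any():
        raise ValidationError("features contain missing values")
    groups = sorted(labels.unique(), key=str)
    sizes = labels.value_counts()
    N, G, n = len(labels), len(groups), int(sizes.min())
    P = training_count(N, G, n)
    if P >= n:
        raise ProtocolError(
            f"group {sizes.idxmin()!r} (size {n}) would be exhausted by P={P}")
    checked = validate_features(df, G)
    X = _encode(checked)

    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.iterations)
    accs = np.empty(spec.iterations)
    sens = np.zeros((spec.iterations, G))
    specif = np.zeros((spec.iterations, G))
    held = pd.Series(0, index=labels.index, dtype=int)
    correct = pd.Series(0, index=labels.index, dtype=int)
    confusion = pd.DataFrame(0, index=groups, columns=groups, dtype=int)

    for it in range(spec.iterations):
        rng = np.random.default_rng(children[it])
        train_idx = []
        for g in groups:
            members = labels.index[labels == g].to_numpy()
            train_idx.extend(rng.choice(members, size=P, replace=False))
        train_mask = labels.index.isin(train_idx)
        rf = RandomForestClassifier(
            n_estimators=spec.n_trees, max_features=spec.max_features,
            random_state=int(rng.integers(2 ** 31)), n_jobs=1,
        )
        rf.fit(X.loc[train_mask], labels[train_mask])
        test_index = labels.index[~train_mask]
        pred = pd.Series(rf.predict(X.loc[test_index]), index=test_index)
        truth = labels[test_index]
        accs[it] = float((pred == truth).mean())
        held[test_index] += 1
        correct[test_index[pred == truth]] += 1
        cm = pd.crosstab(truth, pred).reindex(
            index=groups, columns=groups, fill_value=0)
        confusion += cm
        cm_v = cm.to_numpy(float)
        tp = np.diag(cm_v)
        row = cm_v.sum(axis=1)
        col = cm_v.sum(axis=0)
        tot = cm_v.sum()
        with np.errstate(invalid="ignore"):
            sens[it] = np.where(row > 0, tp / row, np.nan)
            tn = tot - row - col + tp
            specif[it] = np.where((tot - row) > 0, tn / (tot - row), np.nan)

    rate = (correct / held.replace(0, np.nan)).rename("prediction_rate")
    return ClassifierReport(
        per_iteration_accuracy=accs,
        global_accuracy=float(accs.mean()),
        per_group_sensitivity=pd.Series(np.nanmean(sens, axis=0), index=groups),
        per_group_specificity=pd.Series(np.nanmean(specif, axis=0), index=groups),
        per_sample_prediction_rate=rate,
        confusion=confusion,
        training_count=P,
    )
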