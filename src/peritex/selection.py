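"""Feature reduction: Fisher coefficient ranking and greedy POE+ACC.

Two classic MaZda-style reduction methods shortlist a small number of texture
features (ten each by default) before univariate testing:

* The **Fisher coefficient** of a feature is the ratio of between-class to
  within-class variance, ``F = sum_k P_k (mu_k - mu)^2 / sum_k P_k s_k^2``
  with class proportions ``P_k`` and population within-class variances.
* **POE + ACC** greedily picks features minimizing the probability of
  classification error of a single-threshold rule (POE) plus the average
  absolute Pearson correlation with already-selected features (ACC), with
  equal weights.  POE here is the minimal empirical misclassification
  fraction over all thresholds and both polarities — a reconstruction of the
  MaZda criterion, which is not published in closed form.

Ties are broken by feature name so runs are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "SelectionResult",
    "fisher_coefficient",
    "select_fisher",
    "poe",
    "select_poe_acc",
    "merge_selections",
]


@dataclass
class FeatureMatrix:
    """Subjects x features value grid with a two-class label vector.

    ``labels`` is boolean per subject, True for the positive class (the
    high-grade-glioma-like class in the packaged study).
    """

    subjects: list[str]
    features: list[str]
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        n, p = self.values.shape
        if len(self.subjects) != n or len(self.features) != p or len(self.labels) != n:
            raise ValueError("inconsistent FeatureMatrix dimensions")
        if self.labels.sum() < 2 or (~self.labels).sum() < 2:
            raise ValueError("each class needs at least 2 subjects")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "label",
                       positive: str | int | bool = 1) -> "FeatureMatrix":
        features = [c for c in df.columns if c != label_col]
        return cls(
            subjects=[str(i) for i in df.index],
            features=features,
            values=df[features].to_numpy(float),
            labels=(df[label_col] == positive).to_numpy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.subjects, columns=self.features)
        df["label"] = self.labels.astype(int)
        return df

    def column(self, feature: str) -> np.ndarray:
        return self.values[:, self.features.index(feature)]

    def drop_unusable(self) -> "FeatureMatrix":
        """Drop features that are constant or contain missing values."""
        ok = []
        for j, name in enumerate(self.features):
            col = self.values[:, j]
            if not np.all(np.isfinite(col)):
                warnings.warn(f"dropping feature {name!r}: missing values")
            elif np.ptp(col) == 0:
                warnings.warn(f"dropping feature {name!r}: constant across subjects")
            else:
                ok.append(j)
        return FeatureMatrix(
            subjects=self.subjects,
            features=[self.features[j] for j in ok],
            values=self.values[:, ok],
            labels=self.labels,
        )


@dataclass(frozen=True)
class SelectionResult:
    method: Literal["fisher", "poe_acc"]
    ranked: tuple[tuple[str, float], ...]
    k: int = 10

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.ranked]


def fisher_coefficient(x: Sequence[float], labels: Sequence[bool]) -> float:
    """Between-class over within-class variance of one feature."""
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be non-empty")
    mu = x.mean()
    between = within = 0.0
    for cls in (True, False):
        xv = x[labels == cls]
        pk = xv.size / x.size
        between += pk * (xv.mean() - mu) ** 2
        within += pk * xv.var()  # population variance
    if within == 0:
        return float("inf") if between > 0 else 0.0
    return between / within


def select_fisher(M: FeatureMatrix, k: int = 10) -> SelectionResult:
    M = M.drop_unusable()
    scores = [(name, fisher_coefficient(M.column(name), M.labels)) for name in M.features]
    # descending score, ascending name on ties
    scores.sort(key=lambda t: (-t[1], t[0]))
    return SelectionResult(method="fisher", ranked=tuple(scores[:k]), k=k)


def poe(x: np.ndarray, labels: np.ndarray) -> float:
    """Minimal misclassification fraction of a single-threshold rule.

    Both polarities (positive above or below the threshold) are searched.
    """
    order = np.argsort(x, kind="stable")
    pos = labels[order].astype(int)
    n = x.size
    n_pos = pos.sum()
    # after sorting, rule "positive if rank > c": errors = pos among first c
    # + neg among the rest; evaluate every cut (only cuts between distinct
    # values are realizable, but extra cuts never improve the true minimum)
    cum_pos = np.concatenate([[0], np.cumsum(pos)])
    cuts = np.arange(n + 1)
    err_gt = cum_pos + ((n - cuts) - (n_pos - cum_pos))
    realizable = np.ones(n + 1, dtype=bool)
    xs = x[order]
    realizable[1:-1] = xs[1:] != xs[:-1]
    err = np.minimum(err_gt, n - err_gt)[realizable]
    return float(err.min()) / n


def select_poe_acc(M: FeatureMatrix, k: int = 10) -> SelectionResult:
    """Greedy forward selection by POE + average absolute correlation."""
    M = M.drop_unusable()
    if len(M.features) < k:
        warnings.warn(f"only {len(M.features)} eligible features; returning all")
        k = len(M.features)
    Z = (M.values - M.values.mean(axis=0)) / M.values.std(axis=0)
    poes = np.array([poe(Z[:, j], M.labels) for j in range(Z.shape[1])])
    corr = np.abs(np.corrcoef(Z, rowvar=False))
    order = sorted(range(len(M.features)), key=lambda j: (poes[j], M.features[j]))
    selected = [order[0]]
    scores = [poes[order[0]]]
    while len(selected) < k:

        def criterion(j: int) -> tuple[float, str]:
            return poes[j] + float(np.mean(corr[j, selected])), M.features[j]

        best = min(
            (j for j in range(len(M.features)) if j not in selected), key=criterion
        )
        selected.append(best)
        scores.append(criterion(best)[0])
    ranked = tuple((M.features[j], s) for j, s in zip(selected, scores))
    return SelectionResult(method="poe_acc", ranked=ranked, k=k)


def merge_selections(a: SelectionResult, b: SelectionResult) -> tuple[list[str], list[str]]:
    """Union of the two shortlists (first-seen order) and their overlap."""
    union = list(dict.fromkeys(a.names + b.names))
    overlap = [name for name in a.names if name in b.names]
    return union, overlap
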