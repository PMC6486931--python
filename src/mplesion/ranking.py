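"""Feature-contribution ranking: Gini importance and mRMR.

Gini importance (GI) is the mean impurity decrease a feature earns across
the splits of a random forest; redundant-but-informative features all rank
highly.  Minimum-redundancy-maximum-relevance (mRMR) greedily selects the
feature maximising mutual information with the label minus its mean mutual
information with already-selected features (the MID difference form), so
duplicated information is demoted.  Continuous features are discretised by
equal-frequency binning (3 bins) before mutual-information estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import mutual_info_score

__all__ = ["RankingResult", "roc_auc", "gini_ranking", "mrmr_ranking", "discretise"]


@dataclass
class RankingResult:
    """Ordered feature names with per-feature scores.

    For GI the order is descending in score; for mRMR the order is the
    greedy selection order and the score is the criterion value at the
    step the feature was picked.
    """

    names: list[str]
    scores: np.ndarray
    method: str

    def top(self, k: int) -> list[str]:
        return self.names[:k]


def roc_auc(scores, labels) -> float:
    """Rank-based ROC AUC with midrank tie handling (Mann-Whitney U / (n1*n0))."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    r = rankdata(s)
    u = r[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def gini_ranking(features: np.ndarray, labels, names: list[str],
                 n_trees: int = 100, seed: int = 0) -> RankingResult:
    """Features ordered by random-forest mean impurity decrease (sums to 1)."""
    x = np.asarray(features, dtype=float)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    forest.fit(x, np.asarray(labels))
    imp = forest.feature_importances_
    order = np.argsort(-imp, kind="stable")
    return RankingResult(names=[names[i] for i in order], scores=imp[order], method="GI")


def discretise(column: np.ndarray, bins: int = 3) -> np.ndarray:
    """Equal-frequency discretisation; constant columns map to one bin."""
    col = np.asarray(column, dtype=float)
    if np.unique(col).size <= bins:
        _, inv = np.unique(col, return_inverse=True)
        return inv
    edges = np.quantile(col, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(edges, col, side="right")


def mrmr_ranking(features: np.ndarray, labels, names: list[str],
                 k: int | None = None, bins: int = 3,
                 variant: str = "MID") -> RankingResult:
    """Greedy mRMR selection order over discretised features.

    Step 1 picks argmax I(f; y); each later step maximises
    I(f; y) - mean I(f; selected) (MID) or the ratio I(f; y) / mean I(f;
    selected) (MIQ).  Deterministic given the discretisation.
    """
    if variant not in ("MID", "MIQ"):
        raise ValueError("variant must be 'MID' or 'MIQ'")
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n_features = x.shape[1]
    if k is None:
        k = n_features
    if k > n_features:
        raise ValueError(f"k={k} exceeds feature count {n_features}")
    disc = np.stack([discretise(x[:, j], bins) for j in range(n_features)], axis=1)

    relevance = np.array([mutual_info_score(disc[:, j], y) for j in range(n_features)])
    selected: list[int] = []
    scores: list[float] = []
    redundancy = np.zeros(n_features)
    remaining = set(range(n_features))
    for step in range(k):
        if step == 0:
            crit = relevance.copy()
        else:
            mean_red = redundancy / step
            if variant == "MID":
                crit = relevance - mean_red
            else:
                crit = relevance / np.maximum(mean_red, 1e-12)
        crit_masked = np.full(n_features, -np.inf)
        idx = sorted(remaining)
        crit_masked[idx] = crit[idx]
        pick = int(np.argmax(crit_masked))
        selected.append(pick)
        scores.append(float(crit_masked[pick]))
        remaining.discard(pick)
        if remaining:
            for j in remaining:
                redundancy[j] += mutual_info_score(disc[:, j], disc[:, pick])
    return RankingResult(names=[names[i] for i in selected],
                         scores=np.asarray(scores), method=f"mRMR-{variant}")
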