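"""Exact FDR, posterior-based FDR/q-value estimation, ROC and hop curves.

The identification task returns one hit per query, ordered by a score. The
*exact* FDR of a reported prefix is the fraction of incorrect hits in it —
computable only on reference data where correctness labels are known. In
application, labels are unknown; treating each hit's posterior error
probability p_j = 1 - confidence as a (not necessarily independent)
Bernoulli error probability, the estimated FDR of the top k hits is the
running mean (1/k) * sum_{j<=k} p_j, which is monotone when hits are
ordered by confidence and therefore also the q-value estimate.

Hop curves complement ROC curves for identification tasks: both correct
and incorrect hit counts are normalized by the *total* number of queries N,
plotting TP/N against FP/N over all thresholds. The curve starts at the
origin and ends at a point (x, y) with x + y = 1, where y is the overall
correct-annotation rate — information a ROC curve discards.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "RankedHitList",
    "exact_fdr",
    "estimate_fdr_q",
    "roc_curve",
    "hop_curve",
    "fdr_threshold_report",
    "qq_estimated_vs_exact",
]


@dataclass
class RankedHitList:
    """Hits ordered by descending score/confidence.

    ``labels`` (1 = correct) enable exact-FDR evaluation; ``posterior_error``
    (p_j in [0, 1], non-decreasing along the list) enables FDR estimation.
    Either may be omitted.
    """

    scores: np.ndarray
    labels: np.ndarray | None = None
    posterior_error: np.ndarray | None = None
    ids: List[str] | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        order = np.argsort(-self.scores, kind="stable")
        self.scores = self.scores[order]
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)[order]
            if set(np.unique(self.labels)) - {0, 1}:
                raise ValueError("labels must be binary 0/1")
        if self.posterior_error is not None:
            self.posterior_error = np.asarray(self.posterior_error, dtype=float)[order]
            if np.any(self.posterior_error < 0) or np.any(self.posterior_error > 1):
                raise ValueError("posterior error probabilities must lie in [0, 1]")
        if self.ids is not None:
            self.ids = [self.ids[i] for i in order]

    def __len__(self) -> int:
        return len(self.scores)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        score_col: str = "confidence",
        label_col: str | None = "correct",
        posterior_col: str | None = "posterior_error",
        id_col: str | None = None,
    ) -> "RankedHitList":
        return cls(
            scores=df[score_col].to_numpy(),
            labels=df[label_col].to_numpy() if label_col and label_col in df else None,
            posterior_error=(
                df[posterior_col].to_numpy()
                if posterior_col and posterior_col in df
                else None
            ),
            ids=df[id_col].astype(str).tolist() if id_col and id_col in df else None,
        )


def _require_labels(hits: RankedHitList) -> np.ndarray:
    if hits.labels is None:
        raise ValueError("correctness labels are required for this computation")
    return hits.labels


def exact_fdr(hits: RankedHitList, k: int | None = None) -> float:
    """Exact FDR (percent) of the top-k prefix: 100 * incorrect / k.

    ``k`` defaults to the whole list. Requires labels; k = 0 is an error.
    An empty list reports 0 (flagged convention for empty reports).
    """
    labels = _require_labels(hits)
    if len(hits) == 0:
        return 0.0
    if k is None:
        k = len(hits)
    if not (1 <= k <= len(hits)):
        raise ValueError(f"prefix length k={k} outside [1, {len(hits)}]")
    fp = int(np.sum(labels[:k] == 0))
    return 100.0 * fp / k


def estimate_fdr_q(hits: RankedHitList) -> pd.DataFrame:
    """Estimated FDR and q values from posterior error probabilities.

    FDR-hat_k is the running mean of p_1..p_k; because hits are ordered by
    confidence (p non-decreasing), the estimate is monotone and equals the
    q-value estimate. Returns a DataFrame with columns rank, fdr_estimate,
    q_estimate.
    """
    if hits.posterior_error is None:
        raise ValueError("posterior error probabilities are required")
    p = hits.posterior_error
    k = np.arange(1, len(p) + 1)
    fdr_hat = np.cumsum(p) / k
    # monotone by construction when p is sorted; enforce against float noise
    q_hat = np.maximum.accumulate(fdr_hat)
    return pd.DataFrame({"rank": k, "fdr_estimate": fdr_hat, "q_estimate": q_hat})


def roc_curve(hits: RankedHitList) -> Tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (FPR, TPR over all thresholds) and trapezoidal AUC.

    Requires both classes; a hit score ranked randomly has expected AUC 0.5.
    Unlike generic binary classification, the score direction is fixed by
    the identification task, so an AUC below 0.5 is reported as-is.
    """
    labels = _require_labels(hits)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC/AUC undefined: only one class present")
    fpr, tpr, _ = _sk_roc_curve(labels, hits.scores)
    return fpr, tpr, float(_auc(fpr, tpr))


def hop_curve(hits: RankedHitList) -> Tuple[np.ndarray, np.ndarray]:
    """Hop curve: TP/N vs FP/N over all score thresholds.

    N counts all queries. The curve starts at (0, 0); its endpoint (x, y)
    satisfies x + y = 1 with y the overall correct-hit ratio. Ties share a
    threshold, so tied hits enter the curve together.
    """
    labels = _require_labels(hits)
    n = len(hits)
    if n == 0:
        raise ValueError("hop curve undefined for an empty hit list")
    tp = np.concatenate([[0], np.cumsum(labels == 1)])
    fp = np.concatenate([[0], np.cumsum(labels == 0)])
    # collapse tied scores: keep the last cumulative point of each tie block
    boundary = np.concatenate([[True], hits.scores[1:] != hits.scores[:-1], [True]])
    keep = np.nonzero(boundary)[0]
    return fp[keep] / n, tp[keep] / n


def fdr_threshold_report(
    hits: RankedHitList, fdr_levels: Sequence[float]
) -> pd.DataFrame:
    """Correct-hit yield and score cutoff at each exact-FDR level (percent).

    For each level, finds the largest prefix whose exact FDR is <= level,
    reporting its size, number of correct hits and the score of its last
    hit. Prefixes are extended over tied scores as a block. Levels with no
    qualifying prefix yield a row of zeros and a NaN threshold.
    """
    labels = _require_labels(hits)
    n = len(hits)
    rows = []
    fp = np.cumsum(labels == 0) if n else np.array([])
    k_arr = np.arange(1, n + 1)
    fdr_pct = 100.0 * fp / k_arr if n else np.array([])
    for level in fdr_levels:
        valid = np.nonzero(fdr_pct <= level)[0]
        if valid.size == 0:
            rows.append(
                {"fdr_level": level, "n_hits": 0, "n_correct": 0, "threshold": np.nan}
            )
            continue
        k = int(valid[-1]) + 1
        # include whole tie block at the cutoff score
        while k < n and hits.scores[k] == hits.scores[k - 1]:
            k += 1
        if fdr_pct[k - 1] > level:  # tie extension may break the level
            k = int(valid[-1]) + 1
        rows.append(
            {
                "fdr_level": level,
                "n_hits": k,
                "n_correct": int(np.sum(labels[:k])),
                "threshold": float(hits.scores[k - 1]),
            }
        )
    return pd.DataFrame(rows)


def qq_estimated_vs_exact(hits: RankedHitList) -> pd.DataFrame:
    """Per-rank pairs of estimated vs exact q values, for Q-Q calibration plots.

    Requires both labels and posterior errors. The exact q value at rank k
    is the smallest exact FDR over all prefixes extending k. Also reports
    the fraction of ranks at which the estimate is conservative
    (q_estimate >= q_exact).
    """
    labels = _require_labels(hits)
    if hits.posterior_error is None:
        raise ValueError("posterior error probabilities are required")
    n = len(hits)
    k = np.arange(1, n + 1)
    fdr_exact = np.cumsum(labels == 0) / k
    q_exact = np.minimum.accumulate(fdr_exact[::-1])[::-1]
    q_est = estimate_fdr_q(hits)["q_estimate"].to_numpy()
    out = pd.DataFrame({"rank": k, "q_estimate": q_est, "q_exact": q_exact})
    out.attrs["conservative_fraction"] = float(np.mean(q_est >= q_exact))
    return out
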