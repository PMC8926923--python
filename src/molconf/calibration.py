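"""Kernel-density calibration of hit scores into P values and E values.

No reasonable decoy structures exist for small molecules, so the score
distribution of candidates from a very large structure database serves as
a proxy for the distribution of incorrect-hit scores. Scores are
log-transformed and the log-score distribution is modelled by a Gaussian
kernel density estimate with Silverman's rule-of-thumb bandwidth

    h = 1.059223841 * sigma_hat * n**(-1/5).

The E value of a hit with log-score y against proxy-decoy log-scores
y_1..y_n (the hit itself excluded) in a target database of m candidates is
the expected number of random candidates scoring at least as high:

    E = (m/n) * sum_i [ 1/2 - 1/2 * erf((y - y_i) / (sqrt(2) h)) ]

i.e. m times the upper tail probability of the KDE. The P value is E/m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "ScoreSample",
    "Bandwidth",
    "SILVERMAN_CONSTANT",
    "silverman_bandwidth",
    "e_value",
    "p_value",
    "calibrated_feature",
    "log_transform_scores",
]

SILVERMAN_CONSTANT = 1.059223841


def log_transform_scores(
    scores: Sequence[float], shift: float | None = None
) -> tuple[np.ndarray, float]:
    """Monotone pre-transform making scores positive, then natural log.

    Scorers may emit non-positive scores; the default shift is
    ``1 - min(scores)`` so the smallest transformed score is ln(1) = 0.
    Returns (log-scores, shift); the shift must be recorded alongside any
    calibration so it can be reapplied to new hits.
    """
    arr = np.asarray(scores, dtype=float)
    if shift is None:
        shift = max(0.0, 1.0 - float(arr.min())) if arr.size else 0.0
    shifted = arr + shift
    if np.any(shifted <= 0):
        raise ValueError(
            "scores must be positive after shifting for the log transform"
        )
    return np.log(shifted), shift


@dataclass(frozen=True)
class ScoreSample:
    """One query's hit log-score, proxy-decoy log-scores, and database size.

    ``decoy_log_scores`` must exclude the hit itself; ``m`` is the number
    of candidates in the target search database.
    """

    hit_log_score: float
    decoy_log_scores: np.ndarray
    m: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "decoy_log_scores", np.asarray(self.decoy_log_scores, dtype=float)
        )
        if self.m < 1:
            raise ValueError("target database candidate count m must be >= 1")
        if not np.all(np.isfinite(self.decoy_log_scores)) or not np.isfinite(
            self.hit_log_score
        ):
            raise ValueError("all log-scores must be finite")

    @property
    def n(self) -> int:
        return int(self.decoy_log_scores.size)


@dataclass(frozen=True)
class Bandwidth:
    h: float
    sigma_hat: float

    def __post_init__(self) -> None:
        if not (self.h > 0):
            raise ValueError("bandwidth must be positive")


def silverman_bandwidth(
    ys: Sequence[float], fallback: float = 1e-6
) -> Bandwidth:
    """Rule-of-thumb KDE bandwidth on the log-score scale.

    Uses the n-1 sample standard deviation. A degenerate sample
    (sigma_hat = 0) falls back to a small fixed bandwidth with a warning;
    fewer than two samples is an error.
    """
    ys = np.asarray(ys, dtype=float)
    n = ys.size
    if n < 2:
        raise ValueError("need at least two scores to estimate a bandwidth")
    sigma_hat = float(np.std(ys, ddof=1))
    if sigma_hat == 0.0:
        warnings.warn(
            "degenerate score sample (zero variance); using fallback bandwidth",
            RuntimeWarning,
            stacklevel=2,
        )
        return Bandwidth(h=fallback, sigma_hat=0.0)
    return Bandwidth(h=SILVERMAN_CONSTANT * sigma_hat * n ** (-1 / 5), sigma_hat=sigma_hat)


def e_value(sample: ScoreSample, bandwidth: Bandwidth | None = None) -> float:
    """Expected number of random candidates scoring at least the hit score.

    Closed-form upper tail of the Gaussian-mixture KDE over the proxy-decoy
    log-scores, scaled by the target-database size m. Lies in [0, m] and is
    strictly decreasing in the hit log-score.
    """
    bw = bandwidth or silverman_bandwidth(sample.decoy_log_scores)
    y = sample.hit_log_score
    yi = sample.decoy_log_scores
    tail = 0.5 - 0.5 * erf((y - yi) / (np.sqrt(2.0) * bw.h))
    return float(sample.m / sample.n * np.sum(tail))


def p_value(sample: ScoreSample, bandwidth: Bandwidth | None = None) -> float:
    """Probability of a random candidate scoring at least the hit score (E/m)."""
    return e_value(sample, bandwidth) / sample.m


def calibrated_feature(
    sample_or_e: ScoreSample | float, eps: float = 1e-300
) -> float:
    """Confidence-feature transform of the E value: -log10(E + eps).

    Monotone decreasing in E, so better (more significant) hits receive
    larger feature values.
    """
    if isinstance(sample_or_e, ScoreSample):
        e = e_value(sample_or_e)
    else:
        e = float(sample_or_e)
    if e < 0:
        raise ValueError("E value must be non-negative")
    return float(-np.log10(e + eps))


def kde_tail_numeric(
    sample: ScoreSample, bandwidth: Bandwidth | None = None
) -> Callable[[float], float]:
    """Return a quadrature-based evaluator of m * P(Y >= y) under the KDE.

    Intended as an independent numerical check of :func:`e_value`; it
    integrates the explicit normal-mixture density instead of using the
    closed-form erf sum.
    """
    from scipy.integrate import quad

    bw = bandwidth or silverman_bandwidth(sample.decoy_log_scores)
    yi = sample.decoy_log_scores
    n = sample.n
    h = bw.h

    def density(t: float) -> float:
        return float(
            np.mean(np.exp(-0.5 * ((t - yi) / h) ** 2)) / (h * np.sqrt(2 * np.pi))
        )

    def tail(y: float) -> float:
        upper = float(yi.max() + 12 * h)
        if y >= upper:
            return 0.0
        pts = [p for p in np.sort(yi) if y < p < upper][:50]
        total, _ = quad(density, y, upper, limit=400, points=pts or None)
        return sample.m * total

    return tail
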