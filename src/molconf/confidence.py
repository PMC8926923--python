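"""Confidence scoring of structure annotations.

The confidence score of a hit (the top-ranked structure candidate for one
query spectrum) is the Platt-scaled decision value of a linear SVM over a
small set of hit features — the raw scorer output, the KDE-calibrated
E value, the score gap to the runner-up candidate, the number of
candidates, how much of the spectrum the fragmentation model explains, and
fingerprint descriptors. It is a ranking score, not a calibrated
probability of correctness.

Two modelling devices guard against overfitting:

* **Enforced directionality.** For most features the sign of a sensible
  weight is known a priori (a higher raw hit score must never lower the
  confidence). Rather than constraining the optimiser, one synthetic
  positive training sample per constrained feature is added, with that
  feature at +/- beta (beta = 1e7 by default, in standardized units) and
  all others zero. With a large beta an optimal squared-hinge solution
  must use the feature in the declared direction, while any standard
  linear-SVM solver remains applicable. The exact beta is immaterial:
  1e8 or 1e9 produce essentially the same model.
* **Feature capping.** The training minimum and maximum of every feature
  are stored in the model; at application time feature values are clipped
  to that range before standardization, preventing exaggerated decision
  values from out-of-range inputs.

Separate models are trained per collision energy (10, 20, 40 eV, merged)
and per candidate-count regime: queries whose filtered candidate list has
a single structure lack candidate-comparison features and are scored by a
dedicated single-candidate model. At application time the model with the
nearest collision energy and the matching regime is selected.

The module follows the Model/Results convention: :class:`ConfidenceSVM`
holds the training data and configuration, ``fit()`` returns a
:class:`ConfidenceResults` carrying weights, caps, standardization stats
and Platt parameters, with ``summary()``, scoring and JSON persistence.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

__all__ = [
    "Feature",
    "FeatureSchema",
    "DEFAULT_SCHEMA",
    "HitFeatures",
    "extract_features",
    "ConfidenceSVM",
    "ConfidenceResults",
    "platt_fit",
    "platt_probability",
    "ModelRegistry",
    "select_model",
    "DEFAULT_C_GRID",
    "DEFAULT_BETA",
]

DEFAULT_BETA = 1e7
DEFAULT_C_GRID: Tuple[float, ...] = tuple(10.0 ** k for k in range(-5, 6))

MULTI_CANDIDATE = "multi-candidate"
SINGLE_CANDIDATE = "single-candidate"


@dataclass(frozen=True)
class Feature:
    """One feature of the confidence model.

    ``direction`` is +1 if a larger value must only increase confidence,
    -1 if it must only decrease it, 0 for an unconstrained weight.
    """

    name: str
    direction: int = 0
    requires_multiple_candidates: bool = False
    db_specific: bool = False

    def __post_init__(self) -> None:
        if self.direction not in (-1, 0, 1):
            raise ValueError("feature direction must be -1, 0 or +1")


class FeatureSchema:
    """Ordered, uniquely named collection of :class:`Feature` definitions."""

    def __init__(self, features: Iterable[Feature]):
        self.features: List[Feature] = list(features)
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        self._by_name = {f.name: f for f in self.features}

    @property
    def names(self) -> List[str]:
        return [f.name for f in self.features]

    @property
    def directions(self) -> np.ndarray:
        return np.array([f.direction for f in self.features], dtype=float)

    def __getitem__(self, name: str) -> Feature:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown feature: {name!r}") from None

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def for_regime(self, regime: str) -> "FeatureSchema":
        """Schema restricted to the candidate-count regime."""
        if regime == MULTI_CANDIDATE:
            return self
        return FeatureSchema(
            f for f in self.features if not f.requires_multiple_candidates
        )

    def with_features(self, extra: Iterable[Feature]) -> "FeatureSchema":
        return FeatureSchema([*self.features, *extra])

    def to_dict(self) -> List[dict]:
        return [vars(f).copy() for f in self.features]

    @classmethod
    def from_dict(cls, data: Sequence[Mapping]) -> "FeatureSchema":
        return cls(Feature(**dict(d)) for d in data)


#: Built-in schema: the features named in the model description, with the
#: a-priori weight directions. Users may register additional features.
DEFAULT_SCHEMA = FeatureSchema(
    [
        Feature("hit_score", +1),
        Feature("calibrated_score", +1, requires_multiple_candidates=True),
        Feature("score_gap_runner_up", +1, requires_multiple_candidates=True),
        Feature("log_num_candidates", -1, requires_multiple_candidates=True),
        Feature("explained_intensity_fraction", +1),
        Feature("fingerprint_cardinality_hit", +1),
        Feature("tree_score", +1),
        Feature("fingerprint_quality", +1),
    ]
)


@dataclass
class HitFeatures:
    """Feature values for one annotated query.

    ``n_candidates`` counts candidates sharing the hit's molecular formula;
    features requiring several candidates are absent from ``values`` when
    ``n_candidates == 1``.
    """

    query_id: str
    hit_id: str
    values: Dict[str, float]
    n_candidates: int
    collision_energy: float | str | None = None

    @property
    def regime(self) -> str:
        return MULTI_CANDIDATE if self.n_candidates > 1 else SINGLE_CANDIDATE


def extract_features(
    candidates: pd.DataFrame,
    query_id: str = "",
    metadata: Mapping[str, float] | None = None,
    collision_energy: float | str | None = None,
    select: str = "top",
    rng: np.random.Generator | int | None = None,
) -> HitFeatures:
    """Build the hit feature vector from one query's scored candidate list.

    ``candidates`` needs columns ``candidate_id`` and ``score``; an
    optional ``formula`` column restricts the list to candidates sharing
    the molecular formula of the highest-scoring candidate before the gap
    and count features are computed. The hit is the top-scoring candidate
    (ties broken lexicographically by candidate id); ``select="random"``
    instead picks the hit uniformly (used when re-purposing multi-candidate
    queries as single-candidate training rows). Extra per-hit features
    (explained intensity, tree score, fingerprint descriptors, calibrated
    score) are passed through ``metadata``.
    """
    if candidates.empty:
        raise ValueError(f"query {query_id!r} has an empty candidate list")
    if select not in ("top", "random"):
        raise ValueError("select must be 'top' or 'random'")
    df = candidates.sort_values(
        ["score", "candidate_id"], ascending=[False, True]
    ).reset_index(drop=True)
    top = df.iloc[0]
    if "formula" in df.columns:
        df = df[df["formula"] == top["formula"]].reset_index(drop=True)
    if select == "random":
        hit = df.iloc[int(np.random.default_rng(rng).integers(0, len(df)))]
        n_candidates = 1  # the row is used as a single-candidate instance
    else:
        hit = df.iloc[0]
        n_candidates = len(df)
    values: Dict[str, float] = {"hit_score": float(hit["score"])}
    if n_candidates > 1:
        values["score_gap_runner_up"] = float(hit["score"] - df.iloc[1]["score"])
        values["log_num_candidates"] = float(np.log(n_candidates))
    for key, val in (metadata or {}).items():
        values[key] = float(val)
    return HitFeatures(
        query_id=query_id,
        hit_id=str(hit["candidate_id"]),
        values=values,
        n_candidates=n_candidates,
        collision_energy=collision_energy,
    )


# ---------------------------------------------------------------------------
# Platt scaling


def platt_probability(f: np.ndarray | float, A: float, B: float) -> np.ndarray | float:
    """Sigmoid posterior P(correct | f) = 1 / (1 + exp(A f + B)).

    Note the sign convention: a well-separated model has A < 0 so larger
    decision values map to larger posteriors.
    """
    z = A * np.asarray(f, dtype=float) + B
    out = np.where(z >= 0, np.exp(-z) / (1.0 + np.exp(-z)), 1.0 / (1.0 + np.exp(z)))
    return float(out) if np.isscalar(f) else out


def platt_fit(
    decision_values: Sequence[float],
    labels: Sequence[int],
    max_iter: int = 200,
    min_step: float = 1e-10,
    sigma: float = 1e-12,
) -> Tuple[float, float]:
    """Maximum-likelihood fit of the Platt sigmoid parameters (A, B).

    Newton iteration with backtracking line search on the regularised
    cross-entropy, using prior-corrected targets t+ = (N+ + 1)/(N+ + 2)
    and t- = 1/(N- + 2) to avoid overfitting the sigmoid to the training
    labels. Degenerate inputs (all decision values equal) fall back to a
    B-only fit with a warning.
    """
    f = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("Platt fit requires both classes")
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    if np.ptp(f) == 0.0:
        warnings.warn(
            "all decision values identical; fitting intercept-only sigmoid",
            RuntimeWarning,
            stacklevel=2,
        )
        p = t.mean()
        return 0.0, float(np.log((1.0 - p) / p))

    def objective(A: float, B: float) -> float:
        z = A * f + B
        # stable -[t log p + (1-t) log(1-p)] with p = 1/(1+exp(z))
        return float(np.sum(np.where(z >= 0, t * z + np.log1p(np.exp(-z)),
                                     (t - 1) * z + np.log1p(np.exp(z)))))

    A, B = 0.0, float(np.log((n_neg + 1.0) / (n_pos + 1.0)))
    fval = objective(A, B)
    for _ in range(max_iter):
        z = A * f + B
        p = np.where(z >= 0, np.exp(-z) / (1 + np.exp(-z)), 1 / (1 + np.exp(z)))
        d1 = t - p  # dF/dz per sample, with p = P(y=1) = sigmoid(-z)
        w = p * (1 - p)
        g1 = float(np.dot(f, d1))
        g2 = float(np.sum(d1))
        if abs(g1) < 1e-5 and abs(g2) < 1e-5:
            break
        h11 = float(np.dot(f * f, w)) + sigma
        h22 = float(np.sum(w)) + sigma
        h12 = float(np.dot(f, w))
        det = h11 * h22 - h12 * h12
        dA = -(h22 * g1 - h12 * g2) / det
        dB = -(-h12 * g1 + h11 * g2) / det
        gd = g1 * dA + g2 * dB
        step = 1.0
        while step >= min_step:
            newA, newB = A + step * dA, B + step * dB
            newf = objective(newA, newB)
            if newf < fval + 1e-4 * step * gd:
                A, B, fval = newA, newB, newf
                break
            step /= 2.0
        else:
            warnings.warn("Platt line search failed", RuntimeWarning, stacklevel=2)
            break
    return float(A), float(B)


# ---------------------------------------------------------------------------
# Model / Results


class ConfidenceSVM:
    """Sign-constrained linear SVM confidence model (unfitted).

    Parameters
    ----------
    X : DataFrame of feature columns (one row per training hit)
    y : binary labels, 1 = correct annotation
    schema : FeatureSchema declaring weight directions; only schema
        features present in ``X`` are used, restricted to ``regime``.
    collision_energy : tag of the training spectra (10, 20, 40 or "merged")
    regime : "multi-candidate" or "single-candidate"
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y: Sequence[int],
        schema: FeatureSchema = DEFAULT_SCHEMA,
        collision_energy: float | str | None = "merged",
        regime: str = MULTI_CANDIDATE,
    ):
        if regime not in (MULTI_CANDIDATE, SINGLE_CANDIDATE):
            raise ValueError(f"unknown regime {regime!r}")
        schema = schema.for_regime(regime)
        cols = [n for n in schema.names if n in X.columns]
        if not cols:
            raise ValueError("no schema features present in the training table")
        self.schema = FeatureSchema(schema[n] for n in cols)
        self.X = X[cols].astype(float).reset_index(drop=True)
        if self.X.isna().any().any():
            raise ValueError("training features contain missing values")
        self.y = np.asarray(y, dtype=int)
        if len(self.y) != len(self.X):
            raise ValueError("X and y length mismatch")
        if len(np.unique(self.y)) < 2:
            raise ValueError("training data must contain both classes")
        self.collision_energy = collision_energy
        self.regime = regime

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        label_col: str = "correct",
        schema: FeatureSchema = DEFAULT_SCHEMA,
        **kwargs,
    ) -> "ConfidenceSVM":
        y = data[label_col].astype(int).to_numpy()
        X = data.drop(columns=[label_col])
        return cls(X, y, schema=schema, **kwargs)

    # -- fitting helpers ---------------------------------------------------

    def _standardize(self, X: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
        return (X - mean) / std

    def _augmented(self, Z: np.ndarray, y: np.ndarray, beta: float):
        """Append one synthetic positive row per direction-constrained feature."""
        dirs = self.schema.directions
        rows = []
        for j, d in enumerate(dirs):
            if d != 0:
                row = np.zeros(Z.shape[1])
                row[j] = d * beta
                rows.append(row)
        if not rows:
            return Z, y
        return np.vstack([Z, rows]), np.concatenate([y, np.ones(len(rows), dtype=int)])

    def _svc(self, C: float, max_iter: int) -> LinearSVC:
        # Dual coordinate descent: the only liblinear mode that stays
        # numerically exact with the +/-beta augmentation rows (their dual
        # variables take O(1/beta^2) steps; primal trust-region stalls on
        # the beta^2 Hessian entries).
        return LinearSVC(
            C=C,
            loss="squared_hinge",
            penalty="l2",
            dual=True,
            fit_intercept=True,
            intercept_scaling=100.0,
            tol=1e-5,
            max_iter=max_iter,
            random_state=0,
        )

    # Weakly regularized grid points (large C) converge slowly in the dual;
    # model selection only compares held-out AUCs, so the grid search runs
    # on a capped iteration budget while the final refit (and the
    # out-of-fold decision values feeding Platt scaling) get a large one.
    CV_MAX_ITER = 20_000
    FINAL_MAX_ITER = 500_000

    def _fit_svc(
        self, C: float, Z: np.ndarray, y: np.ndarray, max_iter: int
    ) -> LinearSVC:
        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            return self._svc(C, max_iter).fit(Z, y)

    def fit(
        self,
        C: float | None = None,
        C_grid: Sequence[float] = DEFAULT_C_GRID,
        beta: float = DEFAULT_BETA,
        cv_folds: int = 5,
        seed: int = 0,
    ) -> "ConfidenceResults":
        """Fit the directional SVM and the Platt sigmoid.

        The regularization constant is selected from ``C_grid`` by
        stratified cross-validation (ranking AUC on held-out folds) unless
        ``C`` is given. Augmented direction rows are injected into every
        training fold, in standardized feature space. Platt parameters are
        fitted on out-of-fold decision values so the sigmoid is not biased
        by training-set separation.
        """
        X = self.X.to_numpy()
        y = self.y
        cap_min, cap_max = X.min(axis=0), X.max(axis=0)
        Xc = np.clip(X, cap_min, cap_max)
        mean = Xc.mean(axis=0)
        std = Xc.std(axis=0, ddof=0)
        std = np.where(std == 0, 1.0, std)
        Z = self._standardize(Xc, mean, std)

        folds = min(cv_folds, int(np.bincount(y).min()))
        skf = StratifiedKFold(n_splits=max(2, folds), shuffle=True, random_state=seed)
        if C is None:
            scores = []
            for c in C_grid:
                aucs = []
                for tr, va in skf.split(Z, y):
                    Zt, yt = self._augmented(Z[tr], y[tr], beta)
                    clf = self._fit_svc(c, Zt, yt, self.CV_MAX_ITER)
                    dv = clf.decision_function(Z[va])
                    if len(np.unique(y[va])) == 2:
                        aucs.append(roc_auc_score(y[va], dv))
                scores.append(np.mean(aucs) if aucs else 0.0)
            C = float(C_grid[int(np.argmax(scores))])

        Za, ya = self._augmented(Z, y, beta)
        clf = self._fit_svc(C, Za, ya, self.FINAL_MAX_ITER)
        w = clf.coef_.ravel().copy()
        b = float(clf.intercept_[0])
        w = self._enforce_signs(w, beta)

        # out-of-fold decision values for Platt fitting
        dv_oof = np.empty(len(y))
        for tr, va in skf.split(Z, y):
            Zt, yt = self._augmented(Z[tr], y[tr], beta)
            fold_clf = self._fit_svc(C, Zt, yt, self.FINAL_MAX_ITER)
            fw = self._enforce_signs(fold_clf.coef_.ravel().copy(), beta)
            dv_oof[va] = Z[va] @ fw + float(fold_clf.intercept_[0])
        A, B = platt_fit(dv_oof, y)

        return ConfidenceResults(
            schema=self.schema,
            weights=pd.Series(w, index=self.schema.names),
            bias=b,
            mean=pd.Series(mean, index=self.schema.names),
            std=pd.Series(std, index=self.schema.names),
            cap_min=pd.Series(cap_min, index=self.schema.names),
            cap_max=pd.Series(cap_max, index=self.schema.names),
            platt_a=A,
            platt_b=B,
            C=float(C),
            beta=float(beta),
            collision_energy=self.collision_energy,
            regime=self.regime,
            model=self,
        )

    def _enforce_signs(self, w: np.ndarray, beta: float) -> np.ndarray:
        """Snap solver-tolerance sign violations to zero; real ones raise.

        At the optimum a constrained weight is either used in its declared
        direction or pinned to ~(1 - b)/beta ~ 0 by the augmentation row;
        the dual solver leaves boundary weights within its convergence
        tolerance of zero (standardized features keep weights O(1), so an
        absolute cutoff separates noise from a genuine violation).
        """
        dirs = self.schema.directions
        viol = (w * dirs) < 0
        small = np.abs(w) < max(10.0 / beta, 1e-3)
        if np.any(viol & ~small):
            raise RuntimeError(
                "direction constraint violated beyond numerical tolerance; "
                "increase beta or check the training data"
            )
        w[viol & small] = 0.0
        return w


@dataclass
class ConfidenceResults:
    """Fitted confidence model: weights, caps, standardization, Platt sigmoid."""

    schema: FeatureSchema
    weights: pd.Series
    bias: float
    mean: pd.Series
    std: pd.Series
    cap_min: pd.Series
    cap_max: pd.Series
    platt_a: float
    platt_b: float
    C: float
    beta: float
    collision_energy: float | str | None
    regime: str
    model: ConfidenceSVM | None = field(default=None, repr=False)

    SCHEMA_VERSION = 1

    # -- application -------------------------------------------------------

    def _as_matrix(self, features) -> np.ndarray:
        names = self.schema.names
        if isinstance(features, HitFeatures):
            if self.regime == MULTI_CANDIDATE and features.regime == SINGLE_CANDIDATE:
                raise ValueError(
                    "single-candidate features cannot be scored by a "
                    "multi-candidate model; select the single-candidate model"
                )
            missing = [n for n in names if n not in features.values]
            if missing:
                raise KeyError(f"features missing for this model: {missing}")
            return np.array([[features.values[n] for n in names]], dtype=float)
        if isinstance(features, pd.DataFrame):
            missing = [n for n in names if n not in features.columns]
            if missing:
                raise KeyError(f"feature columns missing: {missing}")
            return features[names].to_numpy(dtype=float)
        arr = np.atleast_2d(np.asarray(features, dtype=float))
        if arr.shape[1] != len(names):
            raise ValueError(f"expected {len(names)} feature columns")
        return arr

    def standardize_and_cap(self, features) -> np.ndarray:
        """Clip to the training range, then z-score with the training stats."""
        X = self._as_matrix(features)
        Xc = np.clip(X, self.cap_min.to_numpy(), self.cap_max.to_numpy())
        return (Xc - self.mean.to_numpy()) / self.std.to_numpy()

    def decision_values(self, features) -> np.ndarray:
        return self.standardize_and_cap(features) @ self.weights.to_numpy() + self.bias

    def confidence_score(self, features) -> np.ndarray | float:
        """Platt-scaled decision value in (0, 1). A ranking score: it must
        not be read as the probability that the annotation is correct."""
        f = self.decision_values(features)
        p = platt_probability(f, self.platt_a, self.platt_b)
        return float(p[0]) if isinstance(features, HitFeatures) else p

    def posterior_error(self, features) -> np.ndarray | float:
        """1 - confidence: the posterior error probability used for FDR estimates."""
        return 1.0 - self.confidence_score(features)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Confidence model (sign-constrained linear SVM + Platt scaling)",
            "=" * 66,
            f"collision energy: {self.collision_energy}    regime: {self.regime}",
            f"C: {self.C:g}    beta: {self.beta:g}    "
            f"Platt A: {self.platt_a:.6g}  B: {self.platt_b:.6g}",
            f"bias: {self.bias:.6g}",
            "-" * 66,
            f"{'feature':<30}{'dir':>4}{'weight':>12}{'cap_min':>10}{'cap_max':>10}",
        ]
        for name in self.schema.names:
            d = self.schema[name].direction
            lines.append(
                f"{name:<30}{d:>+4d}{self.weights[name]:>12.5f}"
                f"{self.cap_min[name]:>10.3g}{self.cap_max[name]:>10.3g}"
            )
        lines.append("=" * 66)
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": self.SCHEMA_VERSION,
            "schema": self.schema.to_dict(),
            "weights": self.weights.to_dict(),
            "bias": self.bias,
            "mean": self.mean.to_dict(),
            "std": self.std.to_dict(),
            "cap_min": self.cap_min.to_dict(),
            "cap_max": self.cap_max.to_dict(),
            "platt_a": self.platt_a,
            "platt_b": self.platt_b,
            "C": self.C,
            "beta": self.beta,
            "collision_energy": self.collision_energy,
            "regime": self.regime,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: Mapping) -> "ConfidenceResults":
        schema = FeatureSchema.from_dict(d["schema"])
        names = schema.names
        as_series = lambda key: pd.Series({n: d[key][n] for n in names})
        return cls(
            schema=schema,
            weights=as_series("weights"),
            bias=float(d["bias"]),
            mean=as_series("mean"),
            std=as_series("std"),
            cap_min=as_series("cap_min"),
            cap_max=as_series("cap_max"),
            platt_a=float(d["platt_a"]),
            platt_b=float(d["platt_b"]),
            C=float(d["C"]),
            beta=float(d["beta"]),
            collision_energy=d.get("collision_energy"),
            regime=d["regime"],
        )

    @classmethod
    def load(cls, path: str | Path) -> "ConfidenceResults":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Model registry / selection


class ModelRegistry:
    """Trained models keyed by (collision energy, candidate-count regime)."""

    def __init__(self, models: Iterable[ConfidenceResults] = ()):
        self._models: Dict[Tuple, ConfidenceResults] = {}
        for m in models:
            self.add(m)

    def add(self, results: ConfidenceResults) -> None:
        self._models[(results.collision_energy, results.regime)] = results

    def __len__(self) -> int:
        return len(self._models)

    def items(self):
        return self._models.items()

    @classmethod
    def from_dir(cls, directory: str | Path) -> "ModelRegistry":
        reg = cls()
        for path in sorted(Path(directory).glob("*.json")):
            reg.add(ConfidenceResults.load(path))
        return reg

    def select(
        self, collision_energy: float | str | None, n_candidates: int
    ) -> ConfidenceResults:
        return select_model(self, collision_energy, n_candidates)


def select_model(
    registry: ModelRegistry,
    collision_energy: float | str | None,
    n_candidates: int,
) -> ConfidenceResults:
    """Pick the trained model for a query.

    Single-candidate queries take the single-candidate regime model.
    Merged-spectrum queries take the "merged" model; numeric collision
    energies take the model with the smallest energy difference (e.g. the
    40-eV model for a 35-eV query), ties resolved toward the lower energy.
    """
    if len(registry) == 0:
        raise ValueError("model registry is empty")
    regime = MULTI_CANDIDATE if n_candidates > 1 else SINGLE_CANDIDATE
    pool = {e: m for (e, r), m in registry.items() if r == regime}
    if not pool:
        raise LookupError(
            f"no model for regime {regime!r}; train one or add it to the registry"
        )
    if collision_energy == "merged" or collision_energy is None:
        if "merged" in pool:
            return pool["merged"]
        if collision_energy == "merged":
            raise LookupError("no merged-spectra model in the registry")
        collision_energy = 0.0
    numeric = {e: m for e, m in pool.items() if not isinstance(e, str)}
    if not numeric:
        if "merged" in pool:
            return pool["merged"]
        raise LookupError("no model with a numeric collision energy available")
    energy = float(collision_energy)
    best = min(numeric, key=lambda e: (abs(e - energy), e))
    return numeric[best]
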