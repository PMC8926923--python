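"""Synthetic-data generators: score mixtures, hit datasets, toy spectra.

Everything downstream (calibration, confidence training, FDR evaluation,
noisification) is testable without external data:

* candidate score lists are drawn from mixtures of log-normal components —
  empirically, per-query candidate score distributions are roughly
  log-normal, sometimes multimodal;
* labeled hit/feature datasets plant configurable effect sizes along each
  feature's declared direction, stand-ins for real spectral-library
  training data;
* toy fragmentation spectra place peaks at masses of random subformulas of
  a precursor formula (guaranteed decomposable), optionally planting
  non-decomposable peaks for the noise-peak pool machinery.

All generators take explicit seeds; no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .confidence import DEFAULT_SCHEMA, FeatureSchema
from .formula import PROTON_MASS, formula_mass, iter_subformulas, subformula_decomposable
from .spectra import Spectrum

__all__ = [
    "ScoreMixtureSpec",
    "HitDatasetSpec",
    "gen_scores",
    "gen_hit_dataset",
    "gen_spectrum",
]


@dataclass(frozen=True)
class ScoreMixtureSpec:
    """Mixture of log-normal score components.

    ``components`` is a sequence of (weight, log_mean, log_std) triples;
    weights must sum to 1 and log_std must be positive.
    """

    components: Tuple[Tuple[float, float, float], ...]
    n_samples: int = 100
    n_queries: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("at least one mixture component is required")
        weights = np.array([c[0] for c in self.components], dtype=float)
        if not np.isclose(weights.sum(), 1.0):
            raise ValueError(f"component weights must sum to 1, got {weights.sum()}")
        if any(c[2] <= 0 for c in self.components):
            raise ValueError("log-std of every component must be positive")


def gen_scores(spec: ScoreMixtureSpec) -> List[np.ndarray]:
    """Draw per-query candidate score arrays from the log-normal mixture."""
    rng = np.random.default_rng(spec.seed)
    weights = np.array([c[0] for c in spec.components])
    out = []
    for _ in range(spec.n_queries):
        comp = rng.choice(len(spec.components), size=spec.n_samples, p=weights)
        mu = np.array([spec.components[c][1] for c in comp])
        sd = np.array([spec.components[c][2] for c in comp])
        out.append(np.exp(rng.normal(mu, sd)))
    return out


@dataclass(frozen=True)
class HitDatasetSpec:
    """Labeled hit/feature dataset with planted effect sizes.

    ``effect_sizes`` maps feature name to the class separation (in feature
    standard deviations) between correct and incorrect hits, applied along
    the feature's declared direction — correct hits shift up for +1
    features and down for -1 features. ``candidate_counts`` gives the
    support and probabilities of the per-query candidate-count
    distribution (single-candidate queries arise when a count of 1 is
    drawn).
    """

    n_queries: int = 1000
    fraction_correct: float = 0.5
    effect_sizes: Dict[str, float] = field(
        default_factory=lambda: {
            "hit_score": 1.5,
            "calibrated_score": 1.5,
            "score_gap_runner_up": 1.0,
            "log_num_candidates": 0.5,
            "explained_intensity_fraction": 1.0,
            "fingerprint_cardinality_hit": 0.3,
            "tree_score": 0.8,
            "fingerprint_quality": 0.8,
        }
    )
    candidate_counts: Tuple[Tuple[int, float], ...] = (
        (1, 0.15),
        (5, 0.35),
        (20, 0.35),
        (100, 0.15),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fraction_correct < 1):
            raise ValueError("fraction_correct must lie strictly in (0, 1)")
        if self.n_queries < 10:
            raise ValueError("n_queries must be at least 10")
        probs = np.array([p for _, p in self.candidate_counts], dtype=float)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("candidate-count probabilities must sum to 1")


def gen_hit_dataset(
    spec: HitDatasetSpec, schema: FeatureSchema = DEFAULT_SCHEMA
) -> pd.DataFrame:
    """Generate a labeled feature table (one row per query hit).

    Incorrect-hit features are standard normal; correct hits are shifted
    by direction * effect size. Features requiring several candidates are
    NaN for single-candidate queries. Columns: query_id, n_candidates,
    correct, plus one column per schema feature.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_queries
    correct = (rng.random(n) < spec.fraction_correct).astype(int)
    counts = np.array([c for c, _ in spec.candidate_counts])
    probs = np.array([p for _, p in spec.candidate_counts])
    n_cand = rng.choice(counts, size=n, p=probs)
    data: Dict[str, np.ndarray] = {
        "query_id": np.array([f"q{i:05d}" for i in range(n)]),
        "n_candidates": n_cand,
        "correct": correct,
    }
    for feat in schema:
        shift = spec.effect_sizes.get(feat.name, 0.0) * (feat.direction or 1)
        col = rng.normal(0.0, 1.0, size=n) + shift * correct
        if feat.requires_multiple_candidates:
            col = np.where(n_cand > 1, col, np.nan)
        data[feat.name] = col
    return pd.DataFrame(data)


def gen_spectrum(
    precursor_formula: str,
    n_peaks: int,
    seed: int = 0,
    n_nondecomposable: int = 0,
    adduct_mass: float = PROTON_MASS,
    tol_ppm: float = 10.0,
    spectrum_id: str | None = None,
) -> Spectrum:
    """Toy fragmentation spectrum with decomposable peaks by construction.

    Peaks sit at monoisotopic masses of ``n_peaks`` distinct random
    nonempty subformulas of the precursor (plus the adduct mass), with
    exponential random intensities. ``n_nondecomposable`` extra peaks are
    planted at masses verified to have no subformula decomposition.
    Raises if the formula has fewer than ``n_peaks`` distinct subformula
    masses.
    """
    if n_peaks < 2:
        raise ValueError("a spectrum needs at least two peaks")
    rng = np.random.default_rng(seed)
    masses = sorted(
        {
            round(sum(formula_mass(sub) for sub in [f]), 9)
            for f in iter_subformulas(precursor_formula)
            if any(f.values())
        }
    )
    if len(masses) < n_peaks:
        raise ValueError(
            f"formula {precursor_formula} has only {len(masses)} distinct "
            f"subformula masses, fewer than n_peaks={n_peaks}"
        )
    chosen = rng.choice(len(masses), size=n_peaks, replace=False)
    mzs = [masses[i] + adduct_mass for i in sorted(chosen)]
    planted: List[float] = []
    lo, hi = mzs[0], masses[-1] + adduct_mass
    attempts = 0
    while len(planted) < n_nondecomposable:
        cand = float(rng.uniform(max(5.0, lo * 0.5), hi))
        attempts += 1
        if attempts > 10000:
            raise RuntimeError("could not place non-decomposable peaks")
        if not subformula_decomposable(
            cand, precursor_formula, tol_ppm=2 * tol_ppm, adduct_mass=adduct_mass
        ):
            planted.append(cand)
    all_mz = np.array(mzs + planted)
    intensities = rng.exponential(1.0, size=all_mz.size) + 0.01
    precursor_mz = formula_mass(precursor_formula) + adduct_mass
    return Spectrum.from_arrays(
        all_mz,
        intensities,
        id=spectrum_id or f"synthetic_{precursor_formula}_{seed}",
        precursor_mz=precursor_mz,
        collision_energy=20.0,
    )
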