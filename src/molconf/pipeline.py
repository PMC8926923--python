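"""End-to-end scoring workflow: select model, score, rank, estimate q values.

One row per query hit goes in (feature columns plus identifiers and the
collision energy); one confidence-ranked annotation table comes out, with
estimated q values from the running mean of posterior error probabilities.
Annotations can then be de-duplicated per 2D structure, keeping the
highest-confidence hit as representative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .confidence import HitFeatures, ModelRegistry
from .fdr import RankedHitList, estimate_fdr_q

__all__ = ["RunConfig", "run_score_pipeline", "dedupe_by_structure"]

logger = logging.getLogger("molconf")

#: Default report cutoff on the confidence score, roughly FDR 10%
#: for the reference calibration.
DEFAULT_CONFIDENCE_THRESHOLD = 0.64

ID_COLUMNS = ("query_id", "hit_id", "structure_key", "collision_energy", "n_candidates")


@dataclass
class RunConfig:
    """Paths and knobs of one scoring run."""

    queries: Path
    model_dir: Path
    output: Path
    threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.queries = Path(self.queries)
        self.model_dir = Path(self.model_dir)
        self.output = Path(self.output)
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("confidence threshold must lie in [0, 1]")
        for p in (self.queries, self.model_dir):
            if not p.exists():
                raise FileNotFoundError(p)


def run_score_pipeline(
    queries: pd.DataFrame,
    registry: ModelRegistry,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Score every query hit and return the confidence-ranked annotation table.

    ``queries`` needs columns query_id, hit_id, n_candidates, optionally
    structure_key and collision_energy, plus the feature columns of the
    registered models. Rows are scored with the nearest-energy model of
    the matching candidate-count regime, sorted by confidence descending
    (ties broken by query_id for determinism), and annotated with the
    estimated q value. If ``threshold`` is given, a boolean ``reported``
    column marks hits at or above it.
    """
    columns = ["query_id", "hit_id", "structure_key", "confidence", "q_estimate"]
    if queries.empty:
        return pd.DataFrame(columns=columns)
    records = []
    for _, row in queries.iterrows():
        n_cand = int(row.get("n_candidates", 2))
        energy = row.get("collision_energy", "merged")
        model = registry.select(energy, n_cand)
        values = {
            name: float(row[name])
            for name in model.schema.names
            if name in row and pd.notna(row[name])
        }
        feats = HitFeatures(
            query_id=str(row["query_id"]),
            hit_id=str(row.get("hit_id", "")),
            values=values,
            n_candidates=n_cand,
            collision_energy=energy,
        )
        conf = model.confidence_score(feats)
        records.append(
            {
                "query_id": feats.query_id,
                "hit_id": feats.hit_id,
                "structure_key": str(row.get("structure_key", feats.hit_id)),
                "confidence": conf,
            }
        )
        logger.debug("scored %s with %s/%s model", feats.query_id,
                     model.collision_energy, model.regime)
    out = pd.DataFrame.from_records(records)
    out = out.sort_values(
        ["confidence", "query_id"], ascending=[False, True]
    ).reset_index(drop=True)
    ranked = RankedHitList(
        scores=out["confidence"].to_numpy(),
        posterior_error=np.clip(1.0 - out["confidence"].to_numpy(), 0.0, 1.0),
    )
    out["q_estimate"] = estimate_fdr_q(ranked)["q_estimate"].to_numpy()
    if threshold is not None:
        out["reported"] = out["confidence"] >= threshold
    return out


def dedupe_by_structure(
    annotations: pd.DataFrame, key: str = "structure_key"
) -> pd.DataFrame:
    """One row per distinct 2D structure, keeping the highest-confidence hit.

    Ties on confidence are broken stably by query_id then hit_id.
    """
    if annotations.empty or key not in annotations.columns:
        return annotations.copy()
    sort_cols = ["confidence"] + [
        c for c in ("query_id", "hit_id") if c in annotations.columns
    ]
    ordered = annotations.sort_values(
        sort_cols, ascending=[False] + [True] * (len(sort_cols) - 1), kind="stable"
    )
    return ordered.drop_duplicates(subset=[key], keep="first").reset_index(drop=True)
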