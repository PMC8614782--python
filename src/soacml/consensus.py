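"""Rank-based consensus feature importance.

Single-model importances (impurity gains, LASSO coefficients) are not
comparable across algorithms on a common numeric scale, so the consensus
works on ranks: for each eligible model — test R² >= 0, importance-capable
algorithm — the ten highest-importance features receive scores
10, 9, ..., 1 by rank (zero-importance features are never scored), and
scores are summed feature-wise across models.  A feature that many
accurate models rank highly accumulates a large total, bounded by
``10 x number of eligible models``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .suite import IMPORTANCE_CAPABLE, ModelRun

TOP_N_SCORED = 10  # ranks 1..10 map to scores 10..1


@dataclass(frozen=True)
class ImportanceVector:
    """One model's nonnegative importance per feature."""

    model_id: tuple[str, str, int]   # (algorithm, feature_set, random_state)
    values: pd.Series

    def __post_init__(self):
        if (self.values.to_numpy() < 0).any():
            raise ValueError("importance values must be nonnegative")


@dataclass
class ConsensusRanking:
    """Summed rank scores with per-feature contributor provenance."""

    scores: dict[str, int] = field(default_factory=dict)
    # feature -> [(model_id, rank, score), ...]
    contributors: dict[str, list[tuple[tuple[str, str, int], int, int]]] = \
        field(default_factory=dict)
    eligible_models: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def max_possible_score(self) -> int:
        return TOP_N_SCORED * len(self.eligible_models)

    def sorted_features(self) -> list[tuple[str, int]]:
        """Features by total score descending, ties by name order."""
        return sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for feature, score in self.sorted_features():
            contrib = "; ".join(
                f"{alg}/{fset}/rs{rs}:rank{rank}={sc}"
                for (alg, fset, rs), rank, sc in self.contributors.get(feature, []))
            rows.append({"feature": feature, "score": score, "contributors": contrib})
        return pd.DataFrame(rows, columns=["feature", "score", "contributors"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def extract_importance(run: ModelRun) -> ImportanceVector:
    """The importance vector of one run; the MLP is unsupported."""
    if run.algorithm == "dnn":
        raise ValueError("the dnn exposes no importance vector")
    if run.algorithm not in IMPORTANCE_CAPABLE:
        raise ValueError(f"unsupported algorithm {run.algorithm!r}")
    if run.importance is None:
        raise ValueError(f"run {run.model_id} carries no importance vector")
    return ImportanceVector(model_id=run.model_id, values=run.importance)


def score_ranking(v: ImportanceVector) -> dict[str, int]:
    """Map the top-10 positive-importance features to scores 10..1.

    Features are sorted by importance descending with ties broken stably
    by name; rank k (1-based) receives score 11 - k.  Zero-importance
    features and ranks beyond 10 score 0 and are omitted.
    """
    ordered = sorted(v.values.items(), key=lambda kv: (-kv[1], kv[0]))
    scores: dict[str, int] = {}
    for rank, (feature, importance) in enumerate(ordered[:TOP_N_SCORED], start=1):
        if importance <= 0:
            break
        scores[feature] = TOP_N_SCORED + 1 - rank
    return scores


def is_eligible(run: ModelRun) -> bool:
    """Eligibility filter: importance-capable algorithm with test R² >= 0."""
    return (run.algorithm in IMPORTANCE_CAPABLE
            and run.algorithm != "dnn"
            and run.importance is not None
            and not math.isnan(run.r2)
            and run.r2 >= 0)


def build_consensus(runs: Sequence[ModelRun]) -> ConsensusRanking:
    """Sum rank scores over all eligible runs.

    An empty eligible set yields an (explicitly warned) empty consensus,
    not an exception.
    """
    if len(runs) == 0:
        raise ValueError("need at least one run")
    ranking = ConsensusRanking()
    for run in runs:
        if not is_eligible(run):
            continue
        ranking.eligible_models.append(run.model_id)
        per_model = score_ranking(extract_importance(run))
        rank_of = {f: TOP_N_SCORED + 1 - s for f, s in per_model.items()}
        for feature, score in per_model.items():
            ranking.scores[feature] = ranking.scores.get(feature, 0) + score
            ranking.contributors.setdefault(feature, []).append(
                (run.model_id, rank_of[feature], score))
    if not ranking.eligible_models:
        warnings.warn("no eligible models (all R² < 0 or importance-free); "
                      "consensus is empty", stacklevel=2)
    return ranking


def top_k(ranking: ConsensusRanking, k: int = 7) -> list[tuple[str, int]]:
    """First ``k`` features of the consensus (fewer if fewer are scored)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return ranking.sorted_features()[:k]
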