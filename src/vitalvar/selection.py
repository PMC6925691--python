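"""Two-phase importance-based feature selection.

Phase one trains each of the five classifier families on the full
20-feature training table and scores every feature by permutation
importance: the drop in AUC when that feature's column is shuffled, averaged
over repeats, rescaled so the best feature of each model scores 100.  Phase
two keeps the top two features per model and merges the per-model picks into
one deduplicated set (first-appearance order), which is the final compact
model input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.inspection import permutation_importance

from .models import FAMILIES, fit

DEFAULT_N_REPEATS = 20


@dataclass
class ImportanceTable:
    model_name: str
    scores: pd.Series  # normalised to [0, 100]; the top feature scores 100
    raw_drops: pd.Series  # mean AUC drop per permuted feature


@dataclass
class SelectedFeatureSet:
    features: list[str]
    provenance: dict[str, list[str]] = field(default_factory=dict)  # model -> its top-k


def importance(
    model_family: str,
    train: pd.DataFrame,
    n_repeats: int = DEFAULT_N_REPEATS,
    seed: int = 0,
    *,
    hyper: dict | None = None,
) -> ImportanceTable:
    """Permutation importance (AUC scoring) of every feature for one family.

    The model is trained on ``train`` (a feature table with a ``label``
    column), then each feature column is permuted ``n_repeats`` times and the
    mean AUC drop recorded.  Negative mean drops are floored at zero before
    rescaling the maximum to 100.
    """
    y = train["label"].to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("importance needs both classes in the training data")
    names = [c for c in train.columns if c != "label"]
    fitted = fit(model_family, train, y, hyper, seed=seed)
    result = permutation_importance(
        fitted.estimator,
        train[names],
        y,
        scoring="roc_auc",
        n_repeats=n_repeats,
        random_state=seed,
    )
    raw = pd.Series(result.importances_mean, index=names)
    clipped = raw.clip(lower=0.0)
    top = clipped.max()
    scores = clipped * (100.0 / top) if top > 0 else clipped * 0.0
    return ImportanceTable(model_name=model_family, scores=scores, raw_drops=raw)


def top_k(table: ImportanceTable, k: int) -> list[str]:
    """The k highest-scoring features; ties broken by feature name."""
    if k > len(table.scores):
        raise ValueError(f"k={k} exceeds the {len(table.scores)} available features")
    ordered = sorted(table.scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [name for name, _ in ordered[:k]]


def merge_selections(per_model: Sequence[Iterable[str]]) -> SelectedFeatureSet:
    """Deduplicated union of per-model picks, in first-appearance order."""
    if not per_model:
        raise ValueError("need at least one model's selection")
    merged: list[str] = []
    provenance: dict[str, list[str]] = {}
    for i, picks in enumerate(per_model):
        picks = list(picks)
        provenance[f"model_{i}"] = picks
        for name in picks:
            if name not in merged:
                merged.append(name)
    return SelectedFeatureSet(features=merged, provenance=provenance)


def select_features(
    train: pd.DataFrame,
    families: Sequence[str] = FAMILIES,
    k: int = 2,
    *,
    n_repeats: int = DEFAULT_N_REPEATS,
    seed: int = 0,
) -> SelectedFeatureSet:
    """Run the full two-phase selection over the given model families."""
    per_model: list[list[str]] = []
    provenance: dict[str, list[str]] = {}
    for family in families:
        picks = top_k(importance(family, train, n_repeats=n_repeats, seed=seed), k)
        per_model.append(picks)
        provenance[family] = picks
    merged = merge_selections(per_model)
    merged.provenance = provenance
    return merged
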