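"""Pairwise combination vectors, growth impact scores and the DGIS ranking.

A two-drug OMU vector takes, per OMU, the larger of the two single-drug
activities (each drug is assumed to act on an OMU independently and the
stronger effect dominates) and is renormalized to proportions.  Its ILR at
the fitted balance point, pushed through the linear model, is the pair's
growth impact score (GIS) -- a prediction on the GRmax scale but, being a
model extrapolation, not confined to [-1, 1].  The differential growth
impact score (DGIS) compares the pair against its two self-pairs:

* GIS below both self-pair scores  -> DGIS = GIS - min(self scores)  (< 0,
  predicted super-additive growth inhibition),
* GIS between the self-pair scores -> DGIS = 0 (independent action),
* GIS above both                   -> DGIS = GIS - max(self scores)  (> 0).

Candidates are ranked ascending by DGIS: the most negative scores are the
strongest synergy candidates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .balance import BalanceNode, LinearModel, ilr_balance
from .omu import OMUVector

logger = logging.getLogger("omu_synergy")


@dataclass
class CombinedVector:
    """Unordered drug pair with its combined, proportion-normalized vector."""

    pair: tuple[str, str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.pair = tuple(sorted(self.pair))
        total = self.values.sum()
        if not np.isclose(total, 1.0, atol=1e-12):
            raise ValueError("combined vector must sum to 1")


def normalize(values: np.ndarray) -> np.ndarray:
    total = values.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero vector")
    return values / total


def combine_omu_vectors(
    v1: OMUVector, v2: OMUVector, rule: str = "max"
) -> CombinedVector:
    """Element-wise combination of two single-drug vectors, then proportions.

    ``rule='max'`` is the operative definition (larger single-drug activity
    wins per OMU); ``rule='sum'`` adds activities instead and is provided for
    sensitivity analysis.
    """
    if v1.values.shape != v2.values.shape:
        raise ValueError("vectors come from different OMU systems")
    if rule == "max":
        combined = np.maximum(v1.values, v2.values)
    elif rule == "sum":
        combined = v1.values + v2.values
    else:
        raise ValueError(f"unknown combine rule {rule!r}")
    return CombinedVector(
        pair=(v1.sample_id, v2.sample_id), values=normalize(combined)
    )


def growth_impact_score(
    cv: CombinedVector,
    model: LinearModel,
    node: BalanceNode,
    pseudocount: float = 0.0,
) -> float | None:
    """Model prediction for a combined vector; None when unscorable.

    A pair whose combined vector has no positive component on one side of the
    fitted balance point cannot be placed on the regression line; such pairs
    are flagged unscorable and excluded from the ranking.
    """
    b = ilr_balance(cv.values, node, pseudocount=pseudocount)
    if b is None:
        return None
    return model.predict(b)


def dgis(gis12: float, gis11: float, gis22: float) -> float:
    """Three-case differential growth impact score (boundaries map to 0)."""
    for v in (gis12, gis11, gis22):
        if not np.isfinite(v):
            raise ValueError("GIS values must be finite")
    lo, hi = min(gis11, gis22), max(gis11, gis22)
    if gis12 < lo:
        return gis12 - lo
    if gis12 > hi:
        return gis12 - hi
    return 0.0


def score_all_pairs(
    vectors: dict[str, OMUVector],
    model: LinearModel,
    node: BalanceNode,
    rule: str = "max",
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """GIS and DGIS for every unordered two-drug pair.

    Returns a table with one row per pair (columns drug_1, drug_2, gis, dgis)
    plus the per-drug self-pair predictions in attrs['self_gis'].  Unscorable
    pairs are dropped with a log entry.
    """
    drugs = sorted(vectors)
    self_gis: dict[str, float] = {}
    for d in drugs:
        g = growth_impact_score(
            combine_omu_vectors(vectors[d], vectors[d], rule=rule),
            model, node, pseudocount=pseudocount,
        )
        if g is None:
            logger.warning("drug %s is unscorable at the fitted balance point", d)
        else:
            self_gis[d] = g
    rows = []
    skipped = 0
    for d1, d2 in itertools.combinations(drugs, 2):
        if d1 not in self_gis or d2 not in self_gis:
            skipped += 1
            continue
        cv = combine_omu_vectors(vectors[d1], vectors[d2], rule=rule)
        g12 = growth_impact_score(cv, model, node, pseudocount=pseudocount)
        if g12 is None:
            skipped += 1
            continue
        rows.append(
            {
                "drug_1": d1,
                "drug_2": d2,
                "gis": g12,
                "dgis": dgis(g12, self_gis[d1], self_gis[d2]),
            }
        )
    if skipped:
        logger.info("score_all_pairs: %d unscorable pair(s) excluded", skipped)
    df = pd.DataFrame(rows, columns=["drug_1", "drug_2", "gis", "dgis"])
    df.attrs["self_gis"] = self_gis
    return df


def rank_pairs(scores: pd.DataFrame, top_k: int = 30) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ascending DGIS ranking (ties: GIS ascending, then pair lexicographic).

    Returns (top_k table, full ranked table), both with a 1-based 'rank'
    column.  Asking for more rows than exist returns everything with a
    warning.
    """
    if scores.empty:
        raise ValueError("no scorable pairs to rank")
    ranked = scores.sort_values(
        ["dgis", "gis", "drug_1", "drug_2"], kind="mergesort"
    ).reset_index(drop=True)
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    if top_k > len(ranked):
        logger.warning("rank_pairs: top_k=%d exceeds %d pairs; returning all",
                       top_k, len(ranked))
        top_k = len(ranked)
    return ranked.head(top_k).copy(), ranked
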