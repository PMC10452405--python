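"""Quantile-rank iCMS2/iCMS3 scoring.

Single-sample subtyping of CRC expression profiles into the two intrinsic
epithelial tumor-cell states. Per sample, every gene's expression is
replaced by its quantile rank (average-tie rank / n, range (0, 1]); the
ranks are summarized over the four marker classes as means (Mq2U, Mq2D,
Mq3U, Mq3D) and sums (Sq2U, Sq2D, Sq3U, Sq3D) and combined into two scores:

    A = (Mq2U / Mq2D) - (Mq3U / Mq3D)
    B = (Sq2U - Sq2D) - (Sq3U - Sq3D)

Positive values point to iCMS2, negative to iCMS3. A sample is given a
consensus call only when the two scores agree in sign; disagreement (or a
score of exactly zero, which supports neither class) is reported as
discordant. Because only within-sample ranks enter, the scores are
invariant under any strictly increasing per-sample transform of the
expression values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix, FeatureLevel, ICMSGeneSets

logger = logging.getLogger("crcsubtype")

CLASS_KEYS = ("2U", "2D", "3U", "3D")

SCORE_COLUMNS = [
    "Mq2U", "Mq2D", "Mq3U", "Mq3D",
    "Sq2U", "Sq2D", "Sq3U", "Sq3D",
    "score_A", "score_B", "call_A", "call_B", "consensus",
]


@dataclass
class QuantileRankMatrix:
    """Per-sample quantile ranks; same shape and ids as the source matrix."""

    data: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


def quantile_ranks(m: ExpressionMatrix, restrict_to: set[str] | None = None) -> QuantileRankMatrix:
    """Rank each sample's genes ascending and scale to (0, 1].

    Ties get the average rank; ranks are divided by the number of genes, so
    the top gene maps to 1.0 and no value is 0. ``restrict_to`` optionally
    limits ranking to a gene subset (default: all measured genes).
    """
    data = m.data
    if restrict_to is not None:
        keep = [g for g in data.index if g in restrict_to]
        data = data.loc[keep]
    if data.shape[0] < 2:
        raise ValueError("quantile ranks need at least 2 genes (ranks degenerate)")
    ranks = data.rank(axis=0, method="average") / data.shape[0]
    return QuantileRankMatrix(ranks)


def _intersect_classes(
    genes: pd.Index, sets: ICMSGeneSets
) -> dict[str, list[str]]:
    """Per class, the marker genes present in the matrix (coverage logged)."""
    present = {}
    for key, gene_set in zip(CLASS_KEYS, sets.as_tuple()):
        hit = [g for g in genes if g in gene_set]
        if not hit:
            raise ValueError(f"gene class {key} has no genes in the matrix")
        coverage = len(hit) / len(gene_set)
        logger.info("iCMS class %s: %d/%d genes in matrix (%.0f%%)",
                    key, len(hit), len(gene_set), 100 * coverage)
        present[key] = hit
    return present


def icms_scores(
    q: QuantileRankMatrix, sets: ICMSGeneSets
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute Mq/Sq summaries and scores A/B with per-sample calls.

    Returns ``(summaries, results)``: summaries has the eight Mq/Sq columns
    plus the per-class gene counts used; results has score_A, score_B,
    call_A, call_B, consensus and a zero_score flag. A call is iCMS2 iff
    the score is strictly positive; a score of exactly 0 yields a
    discordant consensus flagged ``zero_score``.
    """
    present = _intersect_classes(q.data.index, sets)
    mq = {k: q.data.loc[present[k]].mean(axis=0) for k in CLASS_KEYS}
    sq = {k: q.data.loc[present[k]].sum(axis=0) for k in CLASS_KEYS}

    score_a = mq["2U"] / mq["2D"] - mq["3U"] / mq["3D"]
    score_b = (sq["2U"] - sq["2D"]) - (sq["3U"] - sq["3D"])

    summaries = pd.DataFrame({
        "Mq2U": mq["2U"], "Mq2D": mq["2D"], "Mq3U": mq["3U"], "Mq3D": mq["3D"],
        "Sq2U": sq["2U"], "Sq2D": sq["2D"], "Sq3U": sq["3U"], "Sq3D": sq["3D"],
        "n2U": len(present["2U"]), "n2D": len(present["2D"]),
        "n3U": len(present["3U"]), "n3D": len(present["3D"]),
    })
    summaries.index.name = "sample_id"

    call_a = np.where(score_a > 0, "iCMS2", "iCMS3")
    call_b = np.where(score_b > 0, "iCMS2", "iCMS3")
    zero = (score_a == 0) | (score_b == 0)
    consensus = np.where((call_a == call_b) & ~zero, call_a, "discordant")
    results = pd.DataFrame({
        "score_A": score_a,
        "score_B": score_b,
        "call_A": call_a,
        "call_B": call_b,
        "consensus": consensus,
        "zero_score": zero,
    })
    results.index.name = "sample_id"
    return summaries, results


def score_cohort(
    m: ExpressionMatrix,
    sets: ICMSGeneSets,
    restrict_to_set_genes: bool = False,
) -> pd.DataFrame:
    """Quantile-rank a gene-level cohort and score every sample.

    One row per sample with Mq/Sq summaries, scores A and B, per-score
    calls and the consensus. ``restrict_to_set_genes`` ranks over only the
    marker-class union instead of all measured genes.
    """
    if m.feature_level is not FeatureLevel.gene:
        raise ValueError("score_cohort expects a gene-level matrix (collapse probes first)")
    restrict = set(sets.union) if restrict_to_set_genes else None
    q = quantile_ranks(m, restrict_to=restrict)
    summaries, results = icms_scores(q, sets)
    return summaries.join(results)
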