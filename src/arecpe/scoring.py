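"""ARE:CPE dominance scoring.

The ARE:CPE score of a gene is ``log2(n_are / n_cpe)`` computed on its
longest 3'-UTR.  Genes with more AREs than CPEs (score > 0) are
ARE-dominant and tend to be destabilised late in the LPS response; genes
with more CPEs (score < 0) are CPE-dominant and tend to be sustained.
Genes lacking either element class are excluded before scoring, so the
score is never evaluated at zero counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

from .seqmotif import MotifCounts

logger = logging.getLogger(__name__)

#: Strictly more than this many AREs puts a gene in the ARE-high class.
ARE_HIGH_THRESHOLD = 4


class ExcludedGeneError(ValueError):
    """Score requested for a gene with zero AREs or zero CPEs."""


class Dominance(str, Enum):
    ARE_DOMINANT = "ARE_DOMINANT"
    CPE_DOMINANT = "CPE_DOMINANT"
    BALANCED = "BALANCED"


class AreLevel(str, Enum):
    ARE_HIGH = "ARE_HIGH"
    ARE_LOW = "ARE_LOW"


@dataclass
class ScoreRecord:
    gene_id: str
    n_are: int
    n_cpe: int
    score: float
    dominance: Dominance
    are_level: AreLevel


def are_cpe_score(n_are: int, n_cpe: int) -> float:
    """log2 ratio of ARE to CPE counts; both counts must be >= 1."""
    if n_are < 1 or n_cpe < 1:
        raise ExcludedGeneError(
            f"score undefined for counts ({n_are}, {n_cpe}); genes lacking "
            "either element must be excluded upstream"
        )
    return math.log2(n_are / n_cpe)


def classify_dominance(score: float) -> Dominance:
    """score > 0 -> ARE-dominant; score < 0 -> CPE-dominant; 0 -> balanced."""
    if not math.isfinite(score):
        raise ValueError("score must be finite")
    if score > 0:
        return Dominance.ARE_DOMINANT
    if score < 0:
        return Dominance.CPE_DOMINANT
    return Dominance.BALANCED


def classify_are_level(n_are: int) -> AreLevel:
    """More than 4 AREs -> ARE-high, otherwise ARE-low."""
    if n_are < 0:
        raise ValueError("n_are must be non-negative")
    return AreLevel.ARE_HIGH if n_are > ARE_HIGH_THRESHOLD else AreLevel.ARE_LOW


def score_gene(gene_id: str, n_are: int, n_cpe: int) -> ScoreRecord:
    score = are_cpe_score(n_are, n_cpe)
    return ScoreRecord(
        gene_id=gene_id,
        n_are=n_are,
        n_cpe=n_cpe,
        score=score,
        dominance=classify_dominance(score),
        are_level=classify_are_level(n_are),
    )


def build_score_table(counts: Iterable[MotifCounts]) -> list[ScoreRecord]:
    """Score every gene carrying at least one ARE and one CPE.

    Genes with only AREs, only CPEs, or neither are dropped (and summarised
    in the module log); duplicated gene ids are an error.
    """
    seen: set[str] = set()
    records: list[ScoreRecord] = []
    dropped = {"no_are": 0, "no_cpe": 0, "neither": 0}
    for row in counts:
        if row.gene_id in seen:
            raise ValueError(f"duplicate gene_id {row.gene_id!r}")
        seen.add(row.gene_id)
        if row.n_are >= 1 and row.n_cpe >= 1:
            records.append(score_gene(row.gene_id, row.n_are, row.n_cpe))
        elif row.n_are < 1 and row.n_cpe < 1:
            dropped["neither"] += 1
        elif row.n_are < 1:
            dropped["no_are"] += 1
        else:
            dropped["no_cpe"] += 1
    n_dropped = sum(dropped.values())
    if n_dropped:
        logger.info(
            "build_score_table: dropped %d/%d genes (no ARE: %d, no CPE: %d, "
            "neither: %d)",
            n_dropped,
            n_dropped + len(records),
            dropped["no_are"],
            dropped["no_cpe"],
            dropped["neither"],
        )
    return records
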