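"""RIP-seq-style target calling, set overlap, and motif-class enrichment.

A transcript is called a binding-protein target when its 3'-UTR
enrichment statistics satisfy any of three criteria (strict
inequalities):

1. Benjamini-Yekutieli adjusted p (pvBY) < 0.02 and log2 RPKM fold
   change (IP vs input) > 0.5;
2. raw enrichment p < 0.02 and fold change > 1.2;
3. maximal overlapping peak score (MaxScore) > 500 and fold change > 0.5.

UTR regions with no overlapping peak carry MaxScore 0.  The expressed
transcriptome is defined as transcripts with more than 10 input reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cmle_odds_ratio

DEFAULT_MIN_INPUT_READS = 10


@dataclass
class EnrichmentRow:
    """Per-UTR RIP enrichment statistics feeding the target call."""

    gene_id: str
    input_reads: int
    log2_rpkm_fc: float
    pv: float
    pv_by: float
    max_score: float = 0.0
    region_id: str | None = None


@dataclass(frozen=True)
class TargetCallThresholds:
    """The three-clause target-calling rule; all comparisons are strict."""

    by_p: float = 0.02
    by_fc: float = 0.5
    raw_p: float = 0.02
    raw_fc: float = 1.2
    peak_score: float = 500.0
    peak_fc: float = 0.5


@dataclass(frozen=True)
class TargetSet:
    name: str
    members: frozenset[str]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members <= self.universe:
            raise ValueError("members must be a subset of the universe")


@dataclass
class ClassEnrichment:
    """2x2 contingency of target status vs a boolean gene class."""

    table: np.ndarray
    odds_ratio: float
    p: float


def _check_pvalue(name: str, value: float, gene_id: str) -> None:
    if not 0.0 < value <= 1.0:
        raise ValueError(
            f"{name}={value} for {gene_id} outside (0, 1]"
        )


def define_transcriptome(
    rows: Iterable[EnrichmentRow], min_reads: int = DEFAULT_MIN_INPUT_READS
) -> frozenset[str]:
    """Expressed genes: strictly more than ``min_reads`` input reads."""
    return frozenset(r.gene_id for r in rows if r.input_reads > min_reads)


def is_target(
    row: EnrichmentRow, thresholds: TargetCallThresholds = TargetCallThresholds()
) -> bool:
    _check_pvalue("pv", row.pv, row.gene_id)
    _check_pvalue("pv_by", row.pv_by, row.gene_id)
    if row.max_score < 0:
        raise ValueError(f"max_score must be non-negative for {row.gene_id}")
    t = thresholds
    fc = row.log2_rpkm_fc
    return (
        (row.pv_by < t.by_p and fc > t.by_fc)
        or (row.pv < t.raw_p and fc > t.raw_fc)
        or (row.max_score > t.peak_score and fc > t.peak_fc)
    )


def call_targets(
    rows: Iterable[EnrichmentRow],
    thresholds: TargetCallThresholds = TargetCallThresholds(),
    name: str = "targets",
) -> TargetSet:
    """Union of the three enrichment criteria over all rows.

    Multiple regions per gene are collapsed to the gene level: a gene is a
    target if any of its regions qualifies (per-gene maximum behaviour).
    """
    rows = list(rows)
    universe = frozenset(r.gene_id for r in rows)
    members = frozenset(r.gene_id for r in rows if is_target(r, thresholds))
    return TargetSet(name=name, members=members, universe=universe)


def overlap_stats(a: TargetSet, b: TargetSet) -> dict[str, float]:
    """Intersection size and the percentage of ``b`` members also in ``a``."""
    if not b.members:
        raise ValueError("set b is empty; percent of b undefined")
    n_int = len(a.members & b.members)
    n_b = len(b.members)
    return {
        "n_intersection": n_int,
        "n_b": n_b,
        "percent_of_b": 100.0 * n_int / n_b,
    }


def class_enrichment(
    targets: TargetSet, labels: Mapping[str, bool]
) -> ClassEnrichment:
    """Fisher's exact test of target status against a boolean gene class.

    Rows of the 2x2 table are target / non-target over the target set's
    universe; columns are in-class / out-of-class.  The p-value is
    two-sided; the odds ratio is the conditional maximum-likelihood
    estimate.
    """
    missing = [g for g in targets.universe if g not in labels]
    if missing:
        raise ValueError(
            f"{len(missing)} universe genes lack a class label "
            f"(e.g. {sorted(missing)[:3]})"
        )
    in_class = {g for g in targets.universe if labels[g]}
    if not in_class:
        raise ValueError("class is empty over the universe")
    tgt = targets.members
    non = targets.universe - tgt
    table = np.array(
        [
            [len(tgt & in_class), len(tgt - in_class)],
            [len(non & in_class), len(non - in_class)],
        ],
        dtype=int,
    )
    _, p = stats.fisher_exact(table, alternative="two-sided")
    or_est = float(_cmle_odds_ratio(table).statistic)
    return ClassEnrichment(table=table, odds_ratio=or_est, p=float(p))
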