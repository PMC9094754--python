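"""LPS time-course kinetics: normalisation, persistence classes, signatures.

Expression time courses (default sampling 0, 1, 3, 6, 9 h post-LPS) are
peak-normalised per gene, and a transcript is called *sustained* when its
peak-normalised abundance at 9 h exceeds 0.5, *downregulated* when it
falls below.  Replicates are averaged per timepoint before any kinetic
operation.  Group comparisons use the two-sided Mann-Whitney test with an
exact small-sample path; per-sample gene-set activity is summarised as a
globally centred z-score signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_TIMEPOINTS: tuple[float, ...] = (0.0, 1.0, 3.0, 6.0, 9.0)

#: Peak-normalised 9 h value at or above which a transcript is "sustained".
SUSTAINED_THRESHOLD = 0.5

#: Largest per-group size for which the Mann-Whitney p is computed exactly.
EXACT_MW_MAX_N = 8


class Persistence(str, Enum):
    SUSTAINED = "SUSTAINED"
    DOWNREGULATED = "DOWNREGULATED"


@dataclass(frozen=True)
class TimeCourse:
    """Per-gene abundances over ordered timepoints (hours)."""

    gene_id: str
    timepoints: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.timepoints) != len(self.values):
            raise ValueError("timepoints and values must have equal length")
        tp = np.asarray(self.timepoints, dtype=float)
        if len(tp) and np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if any(v < 0 for v in self.values):
            raise ValueError("abundances must be non-negative")

    def value_at(self, t: float) -> float:
        for tp, v in zip(self.timepoints, self.values):
            if tp == t:
                return v
        raise KeyError(f"timepoint {t} not present in {self.gene_id}")


class MannWhitneyResult(NamedTuple):
    statistic: float
    pvalue: float


def peak_normalize(tc: TimeCourse) -> TimeCourse:
    """Scale a course by its maximum so the peak equals 1."""
    peak = max(tc.values)
    if peak <= 0:
        raise ValueError(f"all-zero time course for {tc.gene_id}")
    return replace(tc, values=tuple(v / peak for v in tc.values))


def late_ratio(tc: TimeCourse, t_num: float = 9.0, t_den: float = 6.0) -> float:
    """Abundance at ``t_num`` divided by abundance at ``t_den`` (default 9h/6h)."""
    num = tc.value_at(t_num)
    den = tc.value_at(t_den)
    if den <= 0:
        raise ValueError(
            f"zero denominator at t={t_den} for {tc.gene_id}"
        )
    return num / den


def classify_persistence(peak_norm_value_at_9h: float) -> Persistence:
    """Sustained vs downregulated call from the peak-normalised 9 h value.

    The boundary value 0.5 is assigned to SUSTAINED.
    """
    x = peak_norm_value_at_9h
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"peak-normalised value {x} outside [0, 1]")
    return (
        Persistence.SUSTAINED
        if x >= SUSTAINED_THRESHOLD
        else Persistence.DOWNREGULATED
    )


def percent_remaining(series: TimeCourse, reference: TimeCourse) -> TimeCourse:
    """Transcription-shutoff decay series as percent of the t0 level.

    Each value is normalised to the matching reference (housekeeping)
    value, then rescaled so the first timepoint reads 100 (percent).
    """
    if series.timepoints != reference.timepoints:
        raise ValueError("series and reference timepoints differ")
    ref = np.asarray(reference.values, dtype=float)
    if np.any(ref <= 0):
        raise ValueError("reference values must be positive")
    vals = np.asarray(series.values, dtype=float) / ref
    if vals[0] <= 0:
        raise ValueError("series value at t0 must be positive")
    return replace(series, values=tuple(100.0 * vals / vals[0]))


def average_replicates(
    expr: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Average replicate columns per timepoint.

    ``expr`` is genes x samples; ``samples`` maps sample id (index) to a
    numeric ``timepoint`` column.  Returns genes x timepoints (ascending).
    """
    missing = [c for c in expr.columns if c not in samples.index]
    if missing:
        raise ValueError(f"samples table lacks annotation for {missing}")
    groups = samples.loc[list(expr.columns), "timepoint"].astype(float)
    out = expr.T.groupby(groups.values).mean().T
    return out.reindex(sorted(out.columns), axis=1)


def matrix_to_timecourses(mean_expr: pd.DataFrame) -> list[TimeCourse]:
    """Rows of a genes x timepoints table as TimeCourse objects."""
    tps = tuple(float(t) for t in mean_expr.columns)
    return [
        TimeCourse(gene_id=str(g), timepoints=tps, values=tuple(row))
        for g, row in mean_expr.iterrows()
    ]


def zscore_signature(
    matrix: pd.DataFrame, gene_set: Iterable[str], ddof: int = 1
) -> pd.Series:
    """Globally centred z-score signature of a gene set, per sample.

    Genes are z-scored across samples; the signature is the mean z-score
    over the set minus the mean z-score over *all* genes (a priori global
    centring, which removes gene-correlation bias).  Zero-variance genes
    are dropped with a warning.
    """
    genes = [g for g in dict.fromkeys(gene_set) if g in matrix.index]
    if not genes:
        raise ValueError("gene_set has empty intersection with the matrix")
    sd = matrix.std(axis=1, ddof=ddof)
    keep = sd > 0
    if not keep.all():
        logger.warning(
            "zscore_signature: dropping %d zero-variance genes", (~keep).sum()
        )
    z = matrix.loc[keep].sub(matrix.loc[keep].mean(axis=1), axis=0)
    z = z.div(sd[keep], axis=0)
    genes = [g for g in genes if keep.get(g, False)]
    if not genes:
        raise ValueError("all gene_set members have zero variance")
    sig = z.loc[genes].mean(axis=0) - z.mean(axis=0)
    sig.name = "signature"
    return sig


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float]
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact permutation distribution when both groups have at most
    8 observations (full enumeration of group relabellings, valid with
    ties), and the normal approximation with tie correction otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size <= EXACT_MW_MAX_N and b.size <= EXACT_MW_MAX_N:
        if min(a.size, b.size) < 2:
            return _exact_mannwhitney_singleton(a, b)
        # n_resamples exceeds C(16, 8), forcing exhaustive enumeration
        method = stats.PermutationMethod(n_resamples=20_000)
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return MannWhitneyResult(float(res.statistic), float(res.pvalue))


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def _exact_mannwhitney_singleton(a: np.ndarray, b: np.ndarray) -> MannWhitneyResult:
    """Exact two-sided permutation p when one group has a single value.

    scipy's permutation machinery requires two observations per group, so
    this degenerate case enumerates the group relabellings directly
    (doubled smaller tail, capped at 1 — the same convention scipy uses).
    """
    from itertools import combinations

    pooled = np.concatenate([a, b])
    n = a.size
    obs = _u_statistic(a, b)
    us = np.array(
        [
            _u_statistic(pooled[list(idx)], np.delete(pooled, list(idx)))
            for idx in combinations(range(pooled.size), n)
        ]
    )
    eps = 1e-12
    p_ge = float((us >= obs - eps).mean())
    p_le = float((us <= obs + eps).mean())
    return MannWhitneyResult(obs, min(1.0, 2.0 * min(p_ge, p_le)))
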