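"""Synthetic study generator with known ground truth.

Emulates the three data layers the analysis consumes, with exact planted
truth so every stage is testable without any download:

* 3'-UTR sequences with exactly the requested number of ARE and CPE
  motifs (verified by re-scanning) and an optional PAS hexamer near the
  3' end;
* LPS-response time courses whose post-peak decay rate is a linear
  function of the planted motif counts, ``k = max(0, k0 + alpha_are*nA -
  alpha_cpe*nC)`` — AREs accelerate late decay, CPEs oppose it;
* per-UTR RIP enrichment tables with a known target truth set, on which
  the three-clause target-calling rule can be benchmarked.

The decay-vs-motif-count law is a generator assumption chosen to make
parameter-recovery tests meaningful, not an empirical claim; it is fully
parameterised.  A single seed drives everything through an explicit
splitting scheme (numpy ``SeedSequence.spawn``), so every sub-generator
is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .kinetics import DEFAULT_TIMEPOINTS, TimeCourse
from .seqmotif import (
    ARE_MOTIF,
    CPE_MOTIFS,
    DEFAULT_PAS_MOTIFS,
    MotifDesignError,
    UTRRecord,
    count_are,
    count_cpe,
    find_overlapping,
)
from .targets import EnrichmentRow

_BASES = np.array(list("ACGT"))

#: Guard inserted on both sides of every planted motif.  No ARE, CPE or
#: PAS literal contains "CC" or starts/ends with "C", so no motif can span
#: a guard boundary.
_GUARD = "CC"

_SCRUB_MOTIFS = (ARE_MOTIF,) + CPE_MOTIFS + DEFAULT_PAS_MOTIFS


@dataclass
class KineticParams:
    """Time-course model parameters (rates per hour)."""

    k0: float = 0.05
    alpha_are: float = 0.04
    alpha_cpe: float = 0.05
    noise_sigma: float = 0.1
    peak_times: tuple[float, ...] = (1.0, 3.0, 6.0)
    baseline_log_mean: float = 0.0
    baseline_log_sigma: float = 0.5
    induction_log_mean: float = math.log(10.0)
    induction_log_sigma: float = 0.5

    def decay_rate(self, n_are: int, n_cpe: int) -> float:
        return max(0.0, self.k0 + self.alpha_are * n_are - self.alpha_cpe * n_cpe)


@dataclass
class EnrichmentParams:
    """RIP enrichment table parameters.

    True targets draw strongly enriched fold changes and very small raw
    p-values (uniform below ``true_p_max``), as produced by count-based
    enrichment tests on genuinely bound regions; non-targets draw null
    fold changes and uniform p-values.  Adjusted p-values are computed by
    Benjamini-Yekutieli over the whole table.
    """

    frac_targets: float = 0.1
    fc_mean: float = 1.5
    fc_sd: float = 0.4
    null_fc_sd: float = 0.3
    true_p_max: float = 5e-6
    input_mean: float = 200.0
    input_dispersion: float = 0.5
    frac_peak_flagged: float = 0.0
    peak_score_range: tuple[float, float] = (600.0, 1500.0)


@dataclass
class SyntheticSpec:
    """Study-level configuration: count laws, kinetics, enrichment, seed."""

    n_genes: int = 200
    are_count_mean: float = 3.0
    are_count_max: int = 12
    cpe_count_mean: float = 2.0
    cpe_count_max: int = 8
    utr_length_range: tuple[int, int] = (200, 2000)
    with_pas: bool = True
    n_replicates: int = 4
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    kinetics: KineticParams = field(default_factory=KineticParams)
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    seed: int = 0


@dataclass
class StudyBundle:
    """In-memory fixture bundle cross-referenced by gene_id."""

    utrs: list[UTRRecord]
    expression: pd.DataFrame  # genes x samples
    samples: pd.DataFrame  # sample annotations (timepoint, replicate)
    enrichment: list[EnrichmentRow]
    truth: pd.DataFrame  # per-gene planted n_are, n_cpe, decay rate, target flag
    manifest: dict


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _clean_background(rng: np.random.Generator, length: int, max_iter: int = 500) -> str:
    """Uniform A/C/G/T background with accidental motifs scrubbed out."""
    if length <= 0:
        return ""
    chars = rng.choice(_BASES, size=length)
    seq = "".join(chars)
    for _ in range(max_iter):
        hit = None
        for motif in _SCRUB_MOTIFS:
            pos = seq.find(motif)
            if pos != -1:
                hit = (pos, len(motif))
                break
        if hit is None:
            return seq
        pos, mlen = hit
        chars[pos:pos + mlen] = rng.choice(_BASES, size=mlen)
        seq = "".join(chars)
    raise MotifDesignError("background scrub did not converge")


def generate_utr(
    n_are: int,
    n_cpe: int,
    length: int,
    seed: int | np.random.Generator,
    with_pas: bool = False,
    gene_id: str = "synthetic",
    transcript_id: str | None = None,
) -> UTRRecord:
    """A UTR of ``length`` nt with exactly the planted motif counts.

    Motifs are placed in random order with CC guards, separated by
    motif-free background; the result is verified by re-scanning.  The
    PAS, when requested, sits near the 3' end.  Deterministic given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_are < 0 or n_cpe < 0 or length <= 0:
        raise ValueError("counts must be non-negative and length positive")

    motifs = [ARE_MOTIF] * n_are + [
        str(m) for m in rng.choice(np.array(CPE_MOTIFS, dtype=object), size=n_cpe)
    ]
    order = rng.permutation(len(motifs))
    blocks = [_GUARD + motifs[i] + _GUARD for i in order]
    pas_block = _GUARD + DEFAULT_PAS_MOTIFS[0] + _GUARD if with_pas else ""
    need = sum(len(b) for b in blocks) + len(pas_block)
    if need > length:
        raise MotifDesignError(
            f"cannot fit {n_are} AREs + {n_cpe} CPEs"
            f"{' + PAS' if with_pas else ''} in {length} nt (need {need})"
        )

    spare = length - need
    # PAS near the 3' end: keep the final background gap short
    n_gaps = len(blocks) + 1
    if with_pas:
        tail = int(min(spare, rng.integers(5, 26)))
        spare -= tail
    gap_lens = rng.multinomial(spare, np.ones(n_gaps) / n_gaps)

    parts: list[str] = []
    for gap, block in zip(gap_lens, blocks + [""]):
        parts.append(_clean_background(rng, int(gap)))
        parts.append(block)
    if with_pas:
        parts.append(pas_block)
        parts.append(_clean_background(rng, tail))
    seq = "".join(parts)
    assert len(seq) == length

    if count_are(seq) != n_are or count_cpe(seq) != n_cpe:
        raise MotifDesignError(
            f"planted counts not reproduced on re-scan for {gene_id}"
        )
    if with_pas and not find_overlapping(seq, DEFAULT_PAS_MOTIFS[0]):
        raise MotifDesignError(f"planted PAS missing for {gene_id}")
    return UTRRecord(gene_id=gene_id, sequence=seq, transcript_id=transcript_id)


def generate_timecourse(
    n_are: int,
    n_cpe: int,
    params: KineticParams | None = None,
    seed: int | np.random.Generator = 0,
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS,
    gene_id: str = "synthetic",
) -> TimeCourse:
    """An LPS-induced pulse whose post-peak decay reflects motif counts.

    The course rises linearly from a lognormal baseline to a lognormal
    peak at a drawn peak time, then decays as ``exp(-k * dt)`` with
    ``k = max(0, k0 + alpha_are*nA - alpha_cpe*nC)``; every value is then
    multiplied by lognormal noise.  Deterministic given seed.
    """
    params = params or KineticParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    baseline = math.exp(rng.normal(params.baseline_log_mean, params.baseline_log_sigma))
    amplitude = math.exp(rng.normal(params.induction_log_mean, params.induction_log_sigma))
    peak_value = baseline * (1.0 + amplitude)
    t_peak = float(rng.choice(np.asarray(params.peak_times)))
    k = params.decay_rate(n_are, n_cpe)

    t = np.asarray(timepoints, dtype=float)
    values = np.where(
        t <= t_peak,
        baseline + (peak_value - baseline) * (t / t_peak),
        peak_value * np.exp(-k * (t - t_peak)),
    )
    if params.noise_sigma > 0:
        values = values * np.exp(rng.normal(0.0, params.noise_sigma, size=t.size))
    return TimeCourse(gene_id=gene_id, timepoints=tuple(t), values=tuple(values))


def sample_counts(
    rng: np.random.Generator, spec: SyntheticSpec
) -> tuple[int, int]:
    """Draw one (n_are, n_cpe) pair from the study's count laws."""
    n_are = int(min(rng.poisson(spec.are_count_mean), spec.are_count_max))
    n_cpe = int(min(rng.poisson(spec.cpe_count_mean), spec.cpe_count_max))
    return n_are, n_cpe


def generate_enrichment_table(
    n_genes: int,
    params: EnrichmentParams | None = None,
    seed: int | np.random.Generator = 0,
    gene_ids: Sequence[str] | None = None,
) -> tuple[list[EnrichmentRow], pd.DataFrame]:
    """Enrichment rows plus the per-gene target truth table."""
    params = params or EnrichmentParams()
    if not 0.0 <= params.frac_targets <= 1.0:
        raise ValueError("frac_targets must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if gene_ids is None:
        width = len(str(max(n_genes, 1)))
        gene_ids = [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]
    if len(gene_ids) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")

    is_target = rng.random(n_genes) < params.frac_targets
    fc = np.where(
        is_target,
        rng.normal(params.fc_mean, params.fc_sd, n_genes),
        rng.normal(0.0, params.null_fc_sd, n_genes),
    )
    pv = np.where(
        is_target,
        rng.uniform(0.0, params.true_p_max, n_genes),
        rng.uniform(0.0, 1.0, n_genes),
    )
    pv = np.clip(pv, 1e-300, 1.0)
    pv_by = multipletests(pv, method="fdr_by")[1]
    pv_by = np.clip(pv_by, pv, 1.0)

    # negative binomial with variance m + d*m^2  =>  size r = 1/d
    r = 1.0 / params.input_dispersion
    p = r / (r + params.input_mean)
    input_reads = rng.negative_binomial(r, p, n_genes)

    max_score = np.zeros(n_genes)
    if params.frac_peak_flagged > 0:
        flagged = is_target & (rng.random(n_genes) < params.frac_peak_flagged)
        lo, hi = params.peak_score_range
        max_score[flagged] = rng.uniform(lo, hi, int(flagged.sum()))

    rows = [
        EnrichmentRow(
            gene_id=g,
            input_reads=int(input_reads[i]),
            log2_rpkm_fc=float(fc[i]),
            pv=float(pv[i]),
            pv_by=float(pv_by[i]),
            max_score=float(max_score[i]),
            region_id=f"{g}_utr3",
        )
        for i, g in enumerate(gene_ids)
    ]
    truth = pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "is_target": is_target,
            "log2_rpkm_fc": fc,
            "pv": pv,
        }
    )
    return rows, truth


def generate_study(spec: SyntheticSpec, outdir: str | Path | None = None) -> StudyBundle:
    """Full cross-referenced fixture bundle (FASTA + expression + enrichment).

    Each gene's time course is driven by its own planted motif counts, so
    dominance classes derived from the sequences predict late-phase
    persistence exactly as the kinetic model dictates.
    """
    rng_counts, rng_seq, rng_kin, rng_enr = _spawn_rngs(spec.seed, 4)
    lo, hi = spec.utr_length_range

    width = len(str(max(spec.n_genes, 1)))
    gene_ids = [f"g{i:0{width}d}" for i in range(1, spec.n_genes + 1)]

    utrs: list[UTRRecord] = []
    truth_rows = []
    for g in gene_ids:
        n_are, n_cpe = sample_counts(rng_counts, spec)
        length = int(rng_counts.integers(lo, hi + 1))
        utrs.append(
            generate_utr(
                n_are,
                n_cpe,
                length,
                rng_seq,
                with_pas=spec.with_pas,
                gene_id=g,
                transcript_id=f"{g}.t1",
            )
        )
        truth_rows.append(
            {
                "gene_id": g,
                "n_are": n_are,
                "n_cpe": n_cpe,
                "utr_length": length,
                "decay_rate": spec.kinetics.decay_rate(n_are, n_cpe),
            }
        )
    truth = pd.DataFrame(truth_rows)

    sample_ids = [
        f"LPS{tp:g}h_r{rep}"
        for tp in spec.timepoints
        for rep in range(1, spec.n_replicates + 1)
    ]
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "timepoint": [
                tp for tp in spec.timepoints for _ in range(spec.n_replicates)
            ],
            "replicate": [
                rep
                for _ in spec.timepoints
                for rep in range(1, spec.n_replicates + 1)
            ],
            "genotype": "WT",
        }
    ).set_index("sample_id")

    expr = np.empty((spec.n_genes, len(sample_ids)))
    for i, row in truth.iterrows():
        for rep in range(spec.n_replicates):
            tc = generate_timecourse(
                int(row.n_are),
                int(row.n_cpe),
                spec.kinetics,
                rng_kin,
                timepoints=spec.timepoints,
                gene_id=row.gene_id,
            )
            expr[i, rep::spec.n_replicates] = tc.values
    expression = pd.DataFrame(expr, index=gene_ids, columns=sample_ids)
    expression.index.name = "gene_id"

    enrichment, enr_truth = generate_enrichment_table(
        spec.n_genes, spec.enrichment, rng_enr, gene_ids=gene_ids
    )
    truth = truth.merge(enr_truth[["gene_id", "is_target"]], on="gene_id")

    manifest = {
        "seed": spec.seed,
        "n_genes": spec.n_genes,
        "timepoints": list(spec.timepoints),
        "n_replicates": spec.n_replicates,
        "kinetics": asdict(spec.kinetics),
        "enrichment": asdict(spec.enrichment),
        "are_count_mean": spec.are_count_mean,
        "cpe_count_mean": spec.cpe_count_mean,
        "utr_length_range": list(spec.utr_length_range),
        "with_pas": spec.with_pas,
    }
    bundle = StudyBundle(
        utrs=utrs,
        expression=expression,
        samples=samples,
        enrichment=enrichment,
        truth=truth,
        manifest=manifest,
    )
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def write_bundle(bundle: StudyBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as FASTA + TSV files plus a plain-text manifest."""
    from . import io as _io  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "utrs.fa",
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "enrichment": outdir / "enrichment.tsv",
        "truth": outdir / "truth.tsv",
        "manifest": outdir / "manifest.txt",
    }
    _io.write_fasta(bundle.utrs, paths["fasta"])
    bundle.expression.to_csv(paths["expression"], sep="\t")
    bundle.samples.to_csv(paths["samples"], sep="\t")
    _io.write_enrichment_table(bundle.enrichment, paths["enrichment"])
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["manifest"], "w") as fh:
        for key, value in bundle.manifest.items():
            fh.write(f"{key}: {value}\n")
    return paths
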