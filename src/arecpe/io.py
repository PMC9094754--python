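"""File formats, run configuration, and the pipeline driver.

Tabular I/O uses a single dialect: tab-separated, header row, ``.`` for
missing optional values.  All output tables are sorted by gene_id so
reruns are diff-stable.
"""

from __future__ import annotations

import dataclasses
import logging
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .kinetics import (
    average_replicates,
    classify_persistence,
    compare_groups,
    matrix_to_timecourses,
    peak_normalize,
)
from .scoring import Dominance, ScoreRecord, build_score_table
from .seqmotif import (
    InvalidAlphabetError,
    MotifCounts,
    PositionalConfig,
    UTRRecord,
    normalize_sequence,
    scan_records,
)
from .targets import EnrichmentRow

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A table is missing required columns or a field fails coercion."""


#: required column -> dtype for each tabular schema
SCHEMAS: dict[str, dict[str, type]] = {
    "counts": {
        "gene_id": str,
        "transcript_id": str,
        "utr_length": int,
        "n_are": int,
        "n_cpe": int,
        "cpe_positional": bool,
    },
    "scores": {
        "gene_id": str,
        "n_are": int,
        "n_cpe": int,
        "score": float,
        "dominance": str,
        "are_level": str,
    },
    "enrichment": {
        "region_id": str,
        "gene_id": str,
        "input_reads": int,
        "log2_rpkm_fc": float,
        "pv": float,
        "pv_by": float,
        "max_score": float,
    },
    "classes": {
        "gene_id": str,
        "peak_norm_9h": float,
        "persistence": str,
    },
}


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[UTRRecord]:
    """Read UTR records; the header token is the transcript id and an
    optional ``gene=`` tag gives the gene id (defaults to transcript id).

    Sequences are canonicalised (uppercase DNA); duplicate transcript ids
    and invalid characters raise with the offending record named.
    """
    records: list[UTRRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if rec.id in seen:
            raise ValueError(f"duplicate transcript id {rec.id!r} in {path}")
        seen.add(rec.id)
        gene_id = rec.id
        for token in rec.description.split()[1:]:
            if token.startswith("gene="):
                gene_id = token[len("gene="):]
        try:
            seq = normalize_sequence(str(rec.seq))
        except InvalidAlphabetError as exc:
            raise InvalidAlphabetError(
                f"record {rec.id!r} (#{i + 1}) in {path}: {exc}"
            ) from exc
        records.append(
            UTRRecord(gene_id=gene_id, sequence=seq, transcript_id=rec.id)
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[UTRRecord], path: str | Path) -> None:
    seqrecords = [
        SeqRecord(
            Seq(r.sequence),
            id=r.transcript_id or r.gene_id,
            description=f"gene={r.gene_id}",
        )
        for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


# ---------------------------------------------------------------------------
# Tables

def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a TSV and validate/coerce it against a named schema.

    Extra columns are preserved; missing required columns raise
    :class:`SchemaError`, as does any value that fails coercion (named by
    row and column).  ``.`` is the missing-value marker.
    """
    spec = SCHEMAS[schema]
    df = pd.read_csv(path, sep="\t", na_values=["."], dtype=str)
    missing = [c for c in spec if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col, typ in spec.items():
        if typ is str:
            continue
        for idx, raw in df[col].items():
            if pd.isna(raw):
                continue
            try:
                if typ is bool:
                    if str(raw) not in {"True", "False", "0", "1"}:
                        raise ValueError(raw)
                else:
                    typ(raw)
            except (TypeError, ValueError):
                raise SchemaError(
                    f"{path}: cannot coerce {raw!r} to {typ.__name__} "
                    f"at row {idx}, column {col!r}"
                ) from None
        if typ is bool:
            df[col] = df[col].map({"True": True, "1": True, "False": False, "0": False})
        else:
            df[col] = df[col].astype(typ)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def counts_to_frame(counts: Sequence[MotifCounts]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in counts],
            "transcript_id": [c.transcript_id or c.gene_id for c in counts],
            "utr_length": [c.utr_length for c in counts],
            "n_are": [c.n_are for c in counts],
            "n_cpe": [c.n_cpe for c in counts],
            "cpe_positional": [c.cpe_positional for c in counts],
        }
    )
    return df.sort_values("gene_id", ignore_index=True)


def frame_to_counts(df: pd.DataFrame) -> list[MotifCounts]:
    return [
        MotifCounts(
            gene_id=row.gene_id,
            transcript_id=row.transcript_id,
            utr_length=int(row.utr_length),
            n_are=int(row.n_are),
            n_cpe=int(row.n_cpe),
            cpe_positional=bool(row.cpe_positional),
        )
        for row in df.itertuples(index=False)
    ]


def scores_to_frame(scores: Sequence[ScoreRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in scores],
            "n_are": [s.n_are for s in scores],
            "n_cpe": [s.n_cpe for s in scores],
            "score": [s.score for s in scores],
            "dominance": [s.dominance.value for s in scores],
            "are_level": [s.are_level.value for s in scores],
        }
    )
    return df.sort_values("gene_id", ignore_index=True)


def read_enrichment_table(path: str | Path) -> list[EnrichmentRow]:
    df = read_table(path, "enrichment")
    return [
        EnrichmentRow(
            gene_id=row.gene_id,
            region_id=row.region_id,
            input_reads=int(row.input_reads),
            log2_rpkm_fc=float(row.log2_rpkm_fc),
            pv=float(row.pv),
            pv_by=float(row.pv_by),
            max_score=float(row.max_score),
        )
        for row in df.itertuples(index=False)
    ]


def write_enrichment_table(rows: Sequence[EnrichmentRow], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "region_id": [r.region_id or f"{r.gene_id}_utr3" for r in rows],
            "gene_id": [r.gene_id for r in rows],
            "input_reads": [r.input_reads for r in rows],
            "log2_rpkm_fc": [r.log2_rpkm_fc for r in rows],
            "pv": [r.pv for r in rows],
            "pv_by": [r.pv_by for r in rows],
            "max_score": [r.max_score for r in rows],
        }
    ).sort_values("gene_id", ignore_index=True)
    write_table(df, path)


def read_gene_set(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and ``#`` comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_set(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


# ---------------------------------------------------------------------------
# Run configuration and pipeline

@dataclass
class RunConfig:
    """Paths, thresholds and the seed for a full pipeline run.

    Threshold defaults echo the owning modules' defaults.
    """

    fasta: str = "utrs.fa"
    expression: str = "expression.tsv"
    samples: str = "samples.tsv"
    outdir: str = "arecpe_out"
    seed: int = 0
    pas_window: int = 100
    require_pas: bool = True
    positional: bool = False
    sustained_threshold: float = 0.5
    late_t_num: float = 9.0
    late_t_den: float = 6.0
    verbosity: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """scan -> score -> kinetics-classify -> group comparison.

    Writes per-stage TSVs plus a run log (versions, seed, thresholds) into
    ``config.outdir`` and returns the artifact paths.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pos_cfg = PositionalConfig(
        max_distance_nt=config.pas_window, require_pas=config.require_pas
    )

    records = read_fasta(config.fasta)
    counts = scan_records(records, pos_cfg)
    counts_df = counts_to_frame(counts)
    counts_path = outdir / "counts.tsv"
    write_table(counts_df, counts_path)

    scores = build_score_table(counts)
    scores_df = scores_to_frame(scores)
    scores_path = outdir / "scores.tsv"
    write_table(scores_df, scores_path)

    expr = pd.read_csv(config.expression, sep="\t", index_col=0)
    samples = pd.read_csv(config.samples, sep="\t", index_col=0)
    mean_expr = average_replicates(expr, samples)
    scored_ids = set(scores_df.gene_id)
    mean_expr = mean_expr.loc[[g for g in mean_expr.index if g in scored_ids]]
    class_rows = []
    for tc in matrix_to_timecourses(mean_expr):
        norm = peak_normalize(tc)
        v9 = norm.value_at(config.late_t_num)
        class_rows.append(
            {
                "gene_id": tc.gene_id,
                "peak_norm_9h": v9,
                "persistence": classify_persistence(v9).value,
            }
        )
    classes_df = pd.DataFrame(class_rows).sort_values("gene_id", ignore_index=True)
    classes_path = outdir / "classes.tsv"
    write_table(classes_df, classes_path)

    merged = scores_df.merge(classes_df, on="gene_id")
    groups = {
        dom.value: merged.loc[merged.dominance == dom.value, "peak_norm_9h"]
        for dom in (Dominance.ARE_DOMINANT, Dominance.CPE_DOMINANT)
    }
    stats_lines = [
        f"n_scored\t{len(scores_df)}",
        f"n_sustained\t{(classes_df.persistence == 'SUSTAINED').sum()}",
        f"n_downregulated\t{(classes_df.persistence == 'DOWNREGULATED').sum()}",
    ]
    a, b = groups["ARE_DOMINANT"], groups["CPE_DOMINANT"]
    if len(a) and len(b):
        res = compare_groups(a, b)
        stats_lines += [
            f"median_9h_are_dominant\t{a.median():.6g}",
            f"median_9h_cpe_dominant\t{b.median():.6g}",
            f"mannwhitney_U\t{res.statistic:.6g}",
            f"mannwhitney_p\t{res.pvalue:.6g}",
        ]
    stats_path = outdir / "comparison.tsv"
    stats_path.write_text("".join(line + "\n" for line in stats_lines))

    log_path = outdir / "run_log.txt"
    log_path.write_text(
        "arecpe run log\n"
        f"version: {__version__}\n"
        f"python: {platform.python_version()}\n"
        + "".join(
            f"{f.name}: {getattr(config, f.name)}\n"
            for f in dataclasses.fields(config)
        )
    )
    return {
        "counts": counts_path,
        "scores": scores_path,
        "classes": classes_path,
        "comparison": stats_path,
        "log": log_path,
    }
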