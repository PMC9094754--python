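#!/usr/bin/env python
"""Classify LPS time courses and compare persistence across dominance classes.

Averages replicates per timepoint, peak-normalises each gene, calls
sustained (peak-normalised 9 h value >= 0.5) versus downregulated, and
tests whether CPE-dominant genes persist longer than ARE-dominant genes
(two-sided Mann-Whitney). Writes classes.tsv under results/.
"""

from pathlib import Path

import pandas as pd

from arecpe import io as aio
from arecpe.kinetics import (
    average_replicates,
    classify_persistence,
    compare_groups,
    matrix_to_timecourses,
    peak_normalize,
)

ROOT = Path(__file__).resolve().parents[1]
FIXTURES = ROOT / "results" / "fixtures"
RESULTS = ROOT / "results"


def main() -> None:
    expr = pd.read_csv(FIXTURES / "expression.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(FIXTURES / "samples.tsv", sep="\t", index_col=0)
    scores = pd.read_csv(RESULTS / "scores.tsv", sep="\t")

    mean_expr = average_replicates(expr, samples).loc[scores.gene_id]
    rows = []
    for tc in matrix_to_timecourses(mean_expr):
        v9 = peak_normalize(tc).value_at(9.0)
        rows.append(
            {
                "gene_id": tc.gene_id,
                "peak_norm_9h": v9,
                "persistence": classify_persistence(v9).value,
            }
        )
    classes = pd.DataFrame(rows).sort_values("gene_id", ignore_index=True)
    aio.write_table(classes, RESULTS / "classes.tsv")

    n_sus = (classes.persistence == "SUSTAINED").sum()
    print(
        f"{len(classes)} genes with both elements: {n_sus} sustained, "
        f"{len(classes) - n_sus} downregulated at the 0.5 threshold"
    )

    merged = scores.merge(classes, on="gene_id")
    v_are = merged.loc[merged.dominance == "ARE_DOMINANT", "peak_norm_9h"]
    v_cpe = merged.loc[merged.dominance == "CPE_DOMINANT", "peak_norm_9h"]
    res = compare_groups(v_are, v_cpe)
    print(
        f"median peak-normalised 9 h value: ARE-dominant {v_are.median():.3f} "
        f"(n={len(v_are)}) vs CPE-dominant {v_cpe.median():.3f} (n={len(v_cpe)})"
    )
    print(f"Mann-Whitney two-sided p = {res.pvalue:.3g}")


if __name__ == "__main__":
    main()
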