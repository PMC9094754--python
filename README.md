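# arecpe

Post-transcriptional control of inflammation depends on *cis*-elements in
mRNA 3′-UTRs: AU-rich elements (AREs, the AUUUA pentamer bound by TTP and
HuR) destabilise transcripts late in the LPS response, while cytoplasmic
polyadenylation elements (CPEs, bound by CPEB proteins) oppose that decay
and sustain expression. `arecpe` implements the sequence analysis that
quantifies this balance for macrophage biologists and RNA regulation
researchers:

- **Motif scanning** — overlapping AUUUA counting (a run `A(UUUA)^k`
  counts `k`), the seven-motif CPE literal set (`UUUUAU`, `UUUUAAU`,
  `UUUUAAAU`, `UUUUACU`, `UUUUCAU`, `UUUUAAGU`, `UUUUGU`), PAS hexamers,
  and a configurable PAS-distance-aware CPE call. mRNAs with ≥ 2 AUUUA
  motifs are "ARE-containing".
- **ARE:CPE score** — for each gene's longest 3′-UTR,
  `score = log2(n_ARE / n_CPE)`; score > 0 is ARE-dominant, score < 0
  CPE-dominant. Genes with > 4 AREs are ARE-high, otherwise ARE-low.
- **Kinetics** — LPS time courses (0/1/3/6/9 h) are replicate-averaged and
  peak-normalised; a transcript is *sustained* if its peak-normalised 9 h
  value is ≥ 0.5, *downregulated* otherwise. Group comparisons use the
  two-sided Mann–Whitney test (exact for small groups); decay assays are
  expressed as percent mRNA remaining; gene sets are summarised as
  globally centred z-score signatures.
- **RIP target calling** — a transcript is a binding-protein target if
  (1) pvBY < 0.02 and log2 fold change > 0.5, (2) raw p < 0.02 and fold
  change > 1.2, or (3) MaxScore > 500 and fold change > 0.5; the expressed
  transcriptome is everything with > 10 input reads. Set overlaps and
  Fisher's exact motif-class enrichment are included.
- **Synthetic studies** — a generator plants exact ARE/CPE counts in
  random UTRs, drives each gene's late decay from its own motif counts,
  and emits enrichment tables with a known target truth set, so the whole
  pipeline is verifiable end to end with no external data.

## Worked example

The numbered drivers under `analysis/` run the complete study on a
300-gene synthetic bundle (seed 42):

```bash
python analysis/01_simulate.py
python analysis/02_scan_and_score.py
python analysis/03_kinetics.py
python analysis/04_call_targets.py
```

which prints:

```
scanned 300 UTRs; planted-count mismatches: 0
scored 247 genes with both elements: 120 ARE-dominant, 66 CPE-dominant, 61 balanced
ARE-level split: 41 ARE-high (>4 AREs), 206 ARE-low
247 genes with both elements: 218 sustained, 29 downregulated at the 0.5 threshold
median peak-normalised 9 h value: ARE-dominant 0.643 (n=120) vs CPE-dominant 1.000 (n=66)
Mann-Whitney two-sided p = 7.49e-29
called 17/300 genes; sensitivity 0.944, false-positive rate 0.0000
17/18 planted targets recovered (94.4%)
```

Read top to bottom: the scanner reproduces every planted motif count; of
the 300 genes, 247 carry at least one ARE *and* one CPE and receive an
ARE:CPE score; CPE-dominant genes persist at 9 h (median peak-normalised
value 1.000) while ARE-dominant genes have decayed (0.643), a difference
the Mann–Whitney test finds overwhelming — the kinetic signature the
score is designed to capture. The three-clause caller recovers 17 of the
18 planted RIP targets with no false positives.

The same steps are available as a CLI for real data
(`arecpe scan | score | kinetics | call-targets | overlap | enrich |
simulate | run`), e.g.:

```bash
arecpe scan --fasta utrs.fa --out counts.tsv
arecpe score --counts counts.tsv --out scores.tsv
```

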