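# Methods

## Motif model

All scanning operates on the sense strand of canonical DNA-alphabet
3′-UTR sequences (input may be RNA or lowercase; `normalize_sequence`
maps U→T and uppercases, rejecting anything outside {A,C,G,T,N}).
Coordinates are 0-based, half-open. `N` never participates in a match —
a conservative choice for masked references.

**ARE.** The ARE is the literal pentamer `ATTTA`. Occurrences are counted
at every start offset, so overlapping copies each count: a maximal run
`A(TTTA)^k` yields exactly `k`. Runs are not capped at any length — the
overlapping-start rule generalises uniformly, and the counter is proven
equal to an all-offsets brute-force oracle in the test suite. A UTR is
"ARE-containing" at ≥ 2 motifs.

**CPE.** The CPE is represented by seven literals — `TTTTAT`, `TTTTAAT`,
`TTTTAAAT`, `TTTTACT`, `TTTTCAT`, `TTTTAAGT`, `TTTTGT` — scanned the same
way and summed. No two of these can match at the same offset (each pair
differs within the length of the shorter), so the sum never
double-counts; this pairwise start-exclusivity is asserted as a property
test. The plain occurrence count deliberately ignores PAS distance.

**Positional CPE call.** A separate, configurable predicate implements a
distance-aware call: a UTR is positionally CPE-containing when some CPE
start lies within `max_distance_nt` (default 100 nt) upstream of a PAS
hexamer start (`AATAAA`/`ATTAAA`). The optimal distance windows in the
CPE-prediction literature are not hard-coded here; 100 nt is a documented
default and every piece (PAS set, window, whether a PAS is required) is a
parameter. When no PAS is required and none is present, any CPE
suffices.

**Longest-UTR rule.** Multi-isoform genes are reduced to the longest
3′-UTR before counting; ties break on the lexicographically smallest
transcript id for determinism.

**Motif inactivation.** `inactivate_motifs` emulates reporter
mutagenesis (e.g. `TTTTAAT → TTgggAT`): 2–3 positions inside each
targeted match are resampled until the target no longer matches and no
new ARE/CPE match exists anywhere in the sequence (verified by
re-scanning); the edit is deterministic given a seed, and a bounded retry
budget turns an infeasible design into an explicit error.

## ARE:CPE score

`score = log2(n_ARE / n_CPE)` with both counts ≥ 1; genes carrying only
one element class are excluded rather than smoothed with pseudocounts,
because the downstream dominance interpretation is a ratio of observed
elements, not an estimate. Score > 0 ⇒ ARE-dominant, < 0 ⇒ CPE-dominant;
exactly 0 is labelled `BALANCED` and belongs to neither dominance group
(the published groups are defined by strict inequalities). The ARE-level
classification is independent of CPEs: > 4 AREs ⇒ ARE-high, ≤ 4 ⇒
ARE-low.

## Kinetics

Time courses are sampled at 0, 1, 3, 6 and 9 h post-LPS by default.
Replicates are averaged per timepoint first; each gene is then scaled by
its maximum over the course (peak normalisation), which makes the 9 h
value directly interpretable as "fraction of peak expression retained".
The sustained/downregulated boundary is 0.5 on that value; the boundary
itself is assigned to SUSTAINED (the published strict inequalities leave
0.5 unassigned; it must belong to one class for the split to be a
partition, and the larger class was chosen). The late ratio (9 h / 6 h)
is provided for the complementary analysis on raw averaged values.
Transcription-shutoff decay series are normalised to a housekeeping
reference per timepoint and rescaled so t₀ = 100 %.

**Group comparison.** `compare_groups` is a two-sided Mann–Whitney U
test. With ≤ 8 observations per group the p-value comes from the exact
permutation distribution (exhaustive enumeration of group relabellings,
valid under ties; doubled smaller tail capped at 1); larger groups use
the normal approximation with tie correction. The exact path is proven
equal to an independent brute-force enumeration oracle for all group
sizes ≤ 7 in the test suite.

**Z-score signatures.** Genes are centred and scaled across samples
(sample standard deviation, ddof = 1); the signature of a set is the mean
z-score over the set per sample, minus the mean z-score over *all* genes
(a priori global centring), which removes the association expected for a
randomly chosen signature. Zero-variance genes are dropped with a logged
warning rather than propagating undefined values; the all-genes signature
is identically zero by construction.

## Target calling

A gene is called a target when any of three clauses holds, all strict:
pvBY < 0.02 ∧ log2FC > 0.5; pv < 0.02 ∧ log2FC > 1.2; MaxScore > 500 ∧
log2FC > 0.5. Regions with no overlapping peak carry MaxScore 0, and
multiple regions per gene are collapsed so a gene qualifies if any region
does (per-gene maximum). P-values outside (0, 1] are rejected. The
expressed transcriptome is defined by input reads strictly greater
than 10. The call is monotone in every threshold (relaxing a cutoff can
only add targets), which the suite checks on randomised tables.
Class-enrichment contingency tests use Fisher's exact two-sided p with
the conditional maximum-likelihood odds ratio.

## Synthetic studies

The generator produces the three data layers with exact ground truth.

**Sequences.** Planted motifs (AREs, CPEs drawn uniformly from the seven
literals, optionally one `AATAAA` near the 3′ end) are placed in random
order, each flanked by a `CC` guard; because no ARE/CPE/PAS literal
contains `CC`, starts with `C`, or ends with `C`, no motif can span a
guard boundary. Background gaps are uniform A/C/G/T with any accidental
ARE/CPE/PAS occurrence resampled away. Every generated UTR is re-scanned
and must reproduce its planted counts exactly; packing that cannot fit is
an explicit error.

**Time courses.** Each gene rises linearly from a lognormal baseline
(log-sd 0.5) to a lognormal-amplitude peak (median 10-fold, log-sd 0.5)
at a peak time drawn from {1, 3, 6} h, then decays as `exp(−k·Δt)` with

    k = max(0, k0 + α_ARE·n_ARE − α_CPE·n_CPE),

defaults k0 = 0.05 /h, α_ARE = 0.04, α_CPE = 0.05, with multiplicative
lognormal noise (σ = 0.1) on every observation. The linear-in-counts,
clipped-at-zero decay law is a generator assumption that encodes the
direction of the biology (AREs accelerate late decay, CPEs oppose it) so
that parameter-recovery and null-calibration tests are meaningful; it is
not an empirical claim, and every constant is a parameter.

**Enrichment tables.** A Bernoulli fraction (default 0.1) of genes are
true targets. True targets draw log2FC ~ N(1.5, 0.4) and raw
p ~ U(0, 5×10⁻⁶) — the near-zero enrichment p-values that count-based
tests assign to genuinely bound regions, and small enough that the
Benjamini–Yekutieli adjustment over the whole table (computed with
statsmodels) keeps them below the 0.02 clause; appreciably larger raw
p-values (e.g. on the order of 10⁻³) would be pushed above that cutoff by
the BY penalty `m·c(m)/rank` and the adjusted-p clause would never fire.
Non-targets draw log2FC ~ N(0, 0.3) and p ~ U(0, 1). Input reads are
negative binomial (mean 200, dispersion 0.5); MaxScore is 0 unless a
peak-flag fraction is set. Under these defaults the three-clause caller
achieves sensitivity ≥ 0.9 with a false-positive rate ≤ 0.05, which the
acceptance suite verifies over 20 seeds.

**Seeding.** One study seed drives everything through numpy
`SeedSequence.spawn`, with separate streams for count draws, sequences,
kinetics and enrichment, so each sub-generator is independently
reproducible and bundles are byte-identical across reruns.

## What the synthetic benchmark does and does not show

Passing tests demonstrate that the implementation is internally coherent:
counters are exact, classifications follow their definitions, the exact
tests match enumeration, and the pipeline recovers structure it planted
itself under the generator's assumptions (independent genes, literal
motifs in uniform background, a monotone decay law, lognormal noise).
Real 3′-UTRs have correlated composition, motif context effects,
secondary structure, and isoform ambiguity that the generator does not
emulate, and real RIP-seq enrichment statistics are not independent
across genes; results on synthetic data therefore validate the software,
not the biology.

## Problem sizes and numerical choices

The analysis drivers and the acceptance script use a 300-gene study with
4 replicates, and 10 × 1000-gene enrichment tables; the statistical
acceptance tests use 100 replicates of 200 genes per dominance class for
directional recovery and 1000 null replicates of 50 + 50 for calibration
— sizes at which the binomial uncertainty of the checked rates is well
inside the asserted bands. Floating-point score identities are asserted
to 1e-12; the sustained threshold, the dominance boundary at 0 and the
ARE-high boundary at 4 are exact comparisons on exact inputs. Degenerate
inputs (empty sequences, all-zero courses, zero denominators, empty
groups, invalid p-values) raise typed errors rather than propagating
NaNs.
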