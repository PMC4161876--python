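# Methods

This note records the models, conventions and numerical choices behind
`ectocage`, what the synthetic-data generator does and does not emulate,
and the limitations a user should keep in mind.

## Coordinates and formats

All intervals are 0-based half-open internally; conversions happen only at
I/O boundaries.  CTSS tables are four tab-separated columns (chrom,
0-based 5′-end position, strand, count ≥ 1).  BED6 loci take their
annotated TSS as `start` on `+` and `end − 1` on `−`; an optional seventh
column carries the biotype (gene/pseudogene).  UCSC chain files are parsed
with block arithmetic verified against the declared spans, and
minus-strand target coordinates are converted to plus-strand half-open
intervals at parse time, so a single convention holds everywhere
downstream.  Readers fail loudly with the offending line or chain id;
nothing is silently skipped.

## Lift-over

`lift_interval` uses the single highest-scoring chain overlapping the
query (ties broken by chain id); there is no multi-chain stitching, which
keeps "one putative promoter per receptor" well defined.  The target
interval is the hull of mapped bases.  Three failure statuses instead of
exceptions:

* `unmapped` — no base maps (no overlapping chain, or the query sits in a
  source gap);
* `split` — the internal unmapped gap inside the target hull exceeds the
  window's unmapped allowance, (1 − `min_match`) × window length;
* `low_coverage` — mapped fraction below `min_match`.

`min_match` defaults to 0.95, the conventional lift-over remap threshold.
Raising it never changes a mapped target interval, only flips statuses.
Collision deduplication requires exact (chrom, start, end, strand)
equality of lifted coordinates and keeps the first window in input order;
with *k* windows colliding, *k* − 1 are discarded.  A `keep_split` flag
lets split mappings through for permissive screens.

The lift is verified in tests against a per-base brute-force mapper that
pushes every base independently through the raw chain blocks — an
intentionally separate code path from the block-interval arithmetic of the
implementation.

## Quantification and promoter shape

Window counts are strand-blind (a lifted promoter window has no reliable
strand of its own); locus counts (`sum5end`) are strand-matched.  TPM uses
the library's total tag count as denominator, so TPMs over all positions
of a library sum to exactly 10⁶.

Shape thresholds: `sharp_width` = 4 bp on the 10–90% positional spread
(linear-interpolation percentiles of the tag-position distribution),
`sharp_dominance` = 0.5, `min_tags_for_shape` = 20.  The sharp/broad
dichotomy is qualitative in the CAGE literature; these cutoffs follow the
common interquantile-width convention and are exposed as parameters.  The
dominant position is the argmax with smallest-coordinate tie-break; no
peak decomposition across libraries is attempted.

## The screening cascade

Q3 is the 75th percentile (linear interpolation between order statistics;
nearest-rank available as a config switch) of pooled counts over **all**
windows in the screen, and both filters are strict inequalities ("more
tags than").  The library subset to pool over is a required explicit
parameter — pooling everything versus pooling a tissue subset changes Q3,
and the choice is echoed into the run metadata.  Both flags are always
reported; the verdict `candidate` requires passing the absolute cutoff
(default 100 tags).

Artifact flagging mechanises what is, in practice, a manual inspection
step: a window is an artifact when it overlaps no receptor gene locus, or
only pseudogene loci when `pseudogene_is_artifact` is set.  The output
metadata records this rule explicitly, because it is a stand-in for human
judgement, not a model of it.

TSS-position classes are assigned from the signed distance
d = (annotated start − dominant TSS) in transcription orientation,
checked in order: |d| ≤ 50 bp → at the annotated start; 500 ≤ d ≤ 2000 →
upstream proximal; d > 5000 → far-upstream discard; inside the gene body →
intragenic; within 500 bp of the 3′ end → 3′-end; else unclassified.  The
gap d ∈ (50, 500) deliberately falls to `unclassified` rather than
guessing an unstated binning.  Verdict precedence is fixed:
far-upstream discard, then artifact, then filtered, then candidate.

## Parsimony

Complete deletion removes every column containing `-`, `?` or `X`
(case-blind) in any row.  Fitch scoring uses bitmask state sets vectorised
over columns; the score is invariant to the rooting edge.  Starting trees
come from seeded stepwise random addition: taxa in a seeded random order,
each attached at the Fitch-minimising edge, first minimum in a seeded edge
enumeration order — randomising the enumeration order (rather than a fixed
sorted order) makes replicates break score ties differently, which is what
gives the 10 replicates genuinely diverse starting topologies.

The local search is close-neighbour-interchange at level 0: accept the
first strictly improving nearest-neighbour interchange; when no single
interchange improves, scan compositions of two interchanges before
declaring a local optimum.  The two-swap extension reflects CNI's "close
neighbourhood" (a pure one-swap hill climb strands ~1% of random
6–7-taxon instances in local optima that the two-swap neighbourhood
escapes).  `exhaustive_search` enumerates all (2n − 5)!! topologies for
small n and is the oracle the heuristic is measured against — 105
topologies at 6 taxa, 945 at 7.

Percent identity: Biopython's global aligner with match +1, mismatch 0,
linear gap −1; identity = matching columns / aligned columns, excluding
terminal-gap overhangs from the denominator.  All three scores and the
denominator convention are parameters, since published identity figures
rarely state their alignment scheme.

## ΔΔCt and reporter assays

Technical replicates collapse by mean Ct before any differencing.
Normalisation uses the arithmetic mean Ct of the reference genes
(equivalent to a geometric mean on the expression scale); calibration
subtracts the mean ΔCt of the calibrator samples per gene; fold change is
2^(−ΔΔCt), exactly 1 at ΔΔCt = 0.  Heat-map rescaling divides by the
maximum |ΔΔCt| and is idempotent.  Amplification efficiency is assumed to
be exactly 2 per cycle; no efficiency correction is applied.  Group
statistics (t-tests, ANOVA) are left to standard routines and are not
re-derived here.

## Calcium traces

R(t) = F340/F380; the baseline R₀ is the mean ratio over all pre-stimulus
samples (robust to sampling noise), with an `r0_at_t0` flag restoring the
literal single-sample definition R₀ = R(0).  The response is the peak
(R − R₀)/R₀ × 100 at or after stimulus onset.  Responder criterion: peak
≥ 20% with threshold crossing within 30 s of onset — a declared
convention, exposed as parameters and echoed into output metadata, not an
inference of any published rule.  Duration is measured between the first
and last sample above half the peak.

## The synthetic-data generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.  Per dataset: 20 receptors and 5 pseudogene decoys on a
source chromosome, each with its own three-block chain (small indel gaps
placed downstream of the TSS window, every third chain on the minus
strand) into a disjoint target region; 2 receptors are unmappable and 3
pairs of windows lift to identical target coordinates (the second member
of each pair is the planted discard).  Expression: 60% of plain mapped
receptors are expressed at 400 TPM in each of 3 libraries of 10⁶ tags;
half sharp (95% of tags at the TSS, a minor 10 bp downstream shoulder),
half broad (uniform over 100 bp downstream of the TSS — downstream so the
whole initiation region stays inside the annotated locus).  Decoys get a
30 bp spurious pile-up at 400 TPM.  Background is Poisson at 0.005
tags/bp/library over annotated space only, and a distant bulk block
absorbs the remaining library mass so each library's depth is exact by a
single multinomial draw.

Ct tables plant fold changes {4, 1, 0.25} against three reference genes
(Ct ≈ 20, baseline ΔCt 5) over 3 calibrator and 3 test samples, 3
replicates, 0.2-cycle Gaussian noise.  Calcium traces sample every 3 s
for 300 s with a 60–90 s stimulus; responder amplitudes are
Normal(80.5, 26)% floored at 30% so planted responders stay separable
from channel noise, onsets fall within 9 s of stimulus onset, durations
are 60–120 s, and Gaussian noise is applied per channel *before*
ratioing so ratio artifacts arise the way they do in real recordings.
With 37 traces and a responder fraction of 11/37, exactly 11 responders
are planted.

What the generator does **not** emulate: read-level sequence content and
mapping ambiguity, PCR duplicates, nested chain inversions, realistic
CAGE background structure near pseudogenes (the decoy pile-up is a simple
stand-in), amplification-efficiency drift in qPCR, and photobleaching or
motion in imaging.  Passing the recovery tests therefore shows the
*arithmetic* of the screen is right under its stated assumptions — it
does not validate performance on real atlas data, where depth, background
and annotation error are all harsher.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
libraries of 10⁶ tags, 25 loci per dataset, 20 seeded screen replicates,
200 loci for shape recovery, 100 enumerable parsimony instances (6–7
taxa, 30 columns), 50 seeded Ct tables, and 37- or 29-trace calcium
populations.  These sizes make every ground-truth comparison exact and
every enumeration feasible while exercising the same code paths a
full-scale run would use.

## Known limitations

* The lift maps windows, not exons: the hull convention would be wrong
  for spliced features.
* Q3 depends on the full window set; screening a subset of receptors
  changes the filter, which is faithful to the method but surprises users
  who expect a per-window statistic.
* The parsimony search is a heuristic; optimality is only guaranteed
  where exhaustive enumeration is feasible (≤ ~8 taxa).
* `classify_tss_position` reports the first matching class in a fixed
  precedence order; a TSS could satisfy several geometric descriptions.
* The responder criterion and shape thresholds are conventions; results
  downstream of them should be read with their parameter values in hand
  (both are echoed into run metadata).
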