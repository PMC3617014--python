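# Methods

This note documents the models, parameter choices and numerical
conventions behind `tritract`, and what the synthetic data can and cannot
establish about real genomes.

## Tract scoring and detection

A candidate tract is scored by global wraparound alignment against
indefinite repetition of a repeat unit (period 1–3). The dynamic program
keeps one state per unit phase; start and end phase are free, every
sequence nucleotide is consumed (match `+match_weight`, mismatch
`−mismatch_penalty`, insertion/deletion `−indel_penalty` per nucleotide),
and within-row deletion edges are relaxed twice around the phase ring.
Defaults are match 2, mismatch 7, indel 7, reporting threshold 40 and
maximum period 3, under which the shortest reportable pure tract is
⌈40/2⌉ = 20 nt. `N` never matches, so tracts cannot begin or end on `N`.

Detection is organized as *seed, then solve exactly*:

1. **Seeding.** The sequence is compared against itself at offsets 1–3; a
   Kadane-style local score (match +2, mismatch −7, computable in O(n)
   with cumulative sums) marks self-similar positions at a low threshold
   (10, far below the reporting threshold of 40), which are padded by
   60 nt and merged into candidate regions.
2. **Exact search.** Within each region, a local wraparound DP is run for
   every canonical unit class (4 mononucleotide, 6 dinucleotide, 20
   trinucleotide rotation classes). The best candidate across all units is
   extracted with traceback, the region splits at its boundaries, and the
   procedure recurses — equivalent to greedily selecting non-overlapping
   candidates in order of (score, length, start, canonical unit), which
   the test suite verifies against exhaustive enumeration of every
   (substring, unit class) candidate on randomized inputs.

Tie-breaking is deterministic: higher score, then longer tract, then
smaller start, then lexicographically smaller canonical unit (this also
assigns homopolymeric tracts period 1 rather than a disguised period 2 or
3). The period filter afterwards keeps tracts whose assigned period is 3,
whose unit has at least two distinct bases, and which no period-1/2 unit
explains with a higher score.

*Known limitation.* Seeding assumes a reportable tract contains at least a
short stretch of exact periodicity. A tract whose errors are spaced so
densely that no seed window survives (roughly one mismatch every ≤ 5
columns, sustained over ≥ 100 nt) could be missed; such tracts score
barely above threshold and do not occur under the generator's planted
conditions. Start-coordinate choice among equal-scoring alignments scans
leftwards over a contiguous score plateau; a plateau interrupted by a
score dip that later returns to the optimum (requiring an exact 7-match /
2-indel balance) would stop early.

## Order-2 background and unit profile

The background counts every overlapping (dinucleotide, next-base)
occurrence, skipping windows that contain non-ACGT symbols and never
wrapping across sequence boundaries. Expected unit probabilities are
P(ab)·P(c|ab), renormalized over the profiled support (default: the units
observed after period filtering). The χ² test pools categories with
expected count < 5 into one before testing (df = categories − 1); if
pooling would leave fewer than two categories, the unpooled table is
tested instead. Log-ratios are base-2 by default; units observed zero
times are reported as absent rather than as −∞. The background is fitted
from the whole genome *including* repeat tracts; a zero-probability unit
in the support is floored at 1/(10·total context count) so observed units
always have positive expectation. Fitting uses pseudocount 0 by default.

## Gene regions

One splice variant is kept per gene — the longest CDS by default,
`first_listed` for annotation sets without canonical transcripts. Region
classes are mutually exclusive with precedence exonic > 5′-UTR > 3′-UTR >
intron > upstream > intergenic; the upstream window is 1000 nt (a common
promoter-proxy convention, configurable) abutting the transcription start
on the strand-correct side. Tracts are assigned by majority vote over
per-position classifications, ties resolving by the same precedence; the
precedence order among overlapping genes is a declared convention of this
package, as is majority (rather than any-overlap) assignment.

## Homo-AA tracts and encoding

Runs are maximal single-residue stretches of ≥ 7 residues; ambiguity
codes (X, B, Z, J, U, O) break runs. The identical-codon run deciding the
encoding class is counted strictly within the tract span — codons outside
the run never extend it — and the class threshold is ≥ 7 identical
consecutive codons. Proteins whose recorded CDS does not translate to the
protein sequence are dropped with a warning. Reverse mapping converts the
residue span to a CDS-nucleotide span (×3) and walks the spliced CDS
segments in transcription order, emitting forward-strand genomic
intervals whose lengths sum to 3× the tract length; on the minus strand
the strand-corrected concatenation reverse-complements back to the
residues, which the tests verify for intron-split tracts on both strands.

## Statistics

- **Composition.** For each residue, successes are its repeat-encoded
  tracts, trials its total tracts, and the null success probability is the
  proportion of repeat-encoded homo-AA *proteins* over all homo-AA
  proteins. This tract-vs-protein unit asymmetry is retained deliberately
  as the method's definition; note that when many proteins carry several
  tracts the protein-level proportion exceeds the tract-level rate, which
  a user should keep in mind when choosing simulation settings. The
  two-tailed p uses the minimum-likelihood convention (sum of null
  probabilities of outcomes no more likely than the observed one).
- **Length.** Mann-Whitney U, exact when n₁·n₂ ≤ 400 via a
  tie-aware rank-sum count (midranks doubled to integers; subset counts by
  dynamic programming; two-sided p = min(1, 2·min(tails))), otherwise the
  tie-corrected normal approximation with continuity correction. A pooled
  sample with all values identical returns p = 1.
- **Interactions / conservation.** Degree is the number of distinct
  partners (self-pairs and duplicates ignored; absent proteins score 0).
  The conservation metric per tract is the mean per-base score over its
  genomic loci; bases missing from the track are excluded rather than
  treated as 0, and uncovered tracts are dropped from the test.
- **Multiplicity.** The 20 per-residue tests are reported at raw
  α = 0.05 by design; a Bonferroni flag exists but is off by default.
- **Enrichment.** One-sided (greater) Fisher exact test per term with at
  least one annotated background gene; genes without annotations stay in
  the margins. E-value = p × number of terms tested, uncapped by default
  (a cap flag exists). The study set must be contained in the background;
  comparing repeat-encoded against variant-encoded proteins is expressed
  as background = study ∪ variant set, which leaves study counts identical
  across background choices.

## Synthetic data

The generator emulates the pipeline's inputs with known truth:

- **Genome.** Order-2 Markov background (uniform by default), auto-sized
  to the planted layout unless an explicit length is given. Planted DNA
  tracts carry a chosen unit, copy number and mismatch count; mismatches
  sit ≥ 4 nt from the ends and ≥ 8 nt apart so every pure sub-segment
  contributes positive score and the planted boundaries stay exactly
  maximal; each tract is flanked by three bases absent from its unit so no
  re-phased or indel-bridged extension into the background can gain score.
  Planted features never overlap and keep ≥ 50 nt clearance.
- **Genes.** Stranded, spliced models with 5′/3′ UTRs and 1–2 introns
  (intron positions are biased into planted runs so a fraction of homo-AA
  tracts split across exons); CDS starts ATG, ends with a stop, length
  divisible by 3. Only CDS bases overwrite the background — UTRs and
  introns keep background content, so background-conditional properties
  remain testable outside planted footprints.
- **Homo-AA runs.** Per residue: the probability θ_r that a planted run is
  repeat-encoded, class-specific mean lengths (7-shifted geometric, so the
  ≥ 7 precondition always holds), and a run count. Repeat-encoded runs
  repeat one randomly chosen codon; variant-encoded runs cap any
  identical-codon sub-run at 6 — one below the classification threshold —
  so class labels are unambiguous. Filler residues never repeat, keeping
  planted runs exactly maximal. Defaults mirror the qualitative
  cross-species picture (glutamine θ highest with longer repeat-encoded
  runs; proline lowest) at about 0.1–0.55 and mean lengths 9.5–13.
- **Ontology.** A random is_a/part_of DAG (60 terms, depth 4 by default);
  one planted term is assigned to repeat-carrying genes at a configurable
  odds ratio against a base probability of 0.15; all other terms are
  assigned independently of repeat status.
- **Interactions / conservation.** Erdős–Rényi pairs at a configurable
  mean degree (3 by default); conservation scores are Gaussian
  (mean 0.6, sd 0.15 by default) clipped to [0, 1] over CDS bases.

Exonic planted DNA tracts are realized as in-frame codon repeats and are
the one planted class without the exact-boundary guarantee (their flanks
are real codons); the default planted set uses non-exonic classes only.

**What passing tests do not show.** The generator draws independent
nucleotides and runs; it has no mutational repeat expansion process, no
realistic codon usage or phylogenetic conservation structure, no scale-free
interaction topology, and genomes of ~10⁵ nt rather than 10⁸. Recovery and
calibration results therefore validate the *implementation* (the methods
recover what was planted, at the stated error rates) and not any biological
claim about real proteomes.

## Problem sizes and test design

The suite's simulation scales are chosen for statistical adequacy:
null calibrations use 1000 repetitions each (χ² on multinomial n = 500
over 20 units; exact binomial at n = 500 trials, p₀ = 0.25, where the
discrete test's exact size is 0.0498; Mann-Whitney at n = 25 + 25, the
smallest sizes exercising the asymptotic branch). The poly-Q recovery runs
20 seeded simulations of 200 single-run genes with 140 glutamine runs at
θ_Q = 0.7 against a proteome rate near 0.53, and repeat-encoded mean
length 14 vs 9 — effect sizes with ≥ 99% per-panel power, chosen a priori
from the normal approximation. Scanner–oracle equivalence uses 100 random
300-nt sequences with planted tracts of all periods and 0–1 mismatches.
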