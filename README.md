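# tritract

Cross-species analysis of trinucleotide repeats (TNRs) and the
homo-amino-acid (homo-AA) tracts they encode.

Expansions of trinucleotide repeats underlie a family of inherited
disorders — Huntington's disease and the other poly-glutamine diseases
among them — and coding-region TNRs have repeatedly been associated with
regulatory gene function. A key confound is that an exonic TNR almost
always produces a homo-amino-acid run in the protein, but the converse
fails: thanks to codon redundancy, a poly-Q tract can be encoded either by
a pure CAG·CTG repeat or by a mixture of synonymous codons. `tritract`
implements the analysis that separates these two situations and asks which
one carries the signal: it detects scored repeat tracts in DNA, localizes
them to gene regions, classifies protein homo-AA runs as **repeat-encoded**
(≥ 7 consecutive identical codons) or **variant-encoded**, and runs the
comparison statistics between the two classes. A synthetic-data generator
produces genomes, proteomes, annotations, ontologies, interaction tables
and conservation tracks with planted ground truth, so the whole pipeline
is testable end to end without any external database.

## The model

**Tract scoring.** A tandem repeat tract is scored by a global wraparound
alignment of the observed sequence against indefinite repetition of a unit
of period ≤ 3: each matching nucleotide scores +2, each mismatch −7, each
inserted or deleted nucleotide −7, and a tract is reported when its score
reaches 40. Under these weights the shortest reportable mismatch-free
tract is 20 nt (6⅔ trinucleotide units). Detection is exact under this
scheme — every reported tract is maximal (no extension or trimming
improves its score) and overlaps resolve to the higher-scoring candidate.
Period-1 and period-2 tracts are removed before downstream analysis.

**Background.** Observed repeat-unit frequencies are compared with an
order-2 Markov nucleotide background: P(abc) = P(ab)·P(c|ab) fitted from
the whole genome, tested by Pearson's χ², and summarized per unit as
log₂(observed frequency / expected probability).

**Encoding classification.** A homo-AA tract is a maximal run of ≥ 7
identical residues. From its codons, the tract is *repeat-encoded* when at
least 7 consecutive residues use one identical codon, otherwise
*variant-encoded*. A protein joins the repeat-encoded set if any of its
tracts is repeat-encoded and the variant-encoded set if any is
variant-encoded; the sets may overlap.

**Statistics.** Per residue *r*, the count of repeat-encoded tracts among
all tracts of *r* is tested against the proteome-level proportion of
repeat-encoded homo-AA proteins by an exact two-tailed binomial test
(minimum-likelihood rule); tract lengths are compared between classes by
the Mann-Whitney U test (exact with ties for small samples, tie-corrected
normal approximation otherwise); interaction degree and per-base
conservation of the encoding DNA are compared the same way. Term
over-representation uses the one-sided Fisher exact test over annotations
propagated through the is_a/part_of transitive closure, with Bonferroni
E-values (p × number of terms tested).

## Worked example

Run the whole study on a synthetic dataset:

```sh
tritract run-all --seed 1 --out demo/
```

prints

```json
{
  "n_trinucleotide_tracts": 21,
  "tract_region_counts": {
    "exonic": 11, "utr5": 0, "utr3": 1,
    "intron": 2, "upstream": 1, "intergenic": 6
  },
  "protein_sets": {
    "tnr_encoded": 12, "variant_encoded": 28, "all_homoaa": 40
  }
}
```

The scanner found 21 genuine period-3 tracts; the default generator plants
ten DNA tracts (six intergenic, two intronic, one upstream, one 3′-UTR —
all recovered at their exact coordinates) and the remaining exonic tracts
are the DNA footprints of repeat-encoded homo-AA runs. Of 40 homo-AA
proteins, 12 carry a repeat-encoded tract and 28 a variant-encoded one
(a protein can carry both, so the per-class counts may exceed the total).
`demo/report.json` holds the full battery; for glutamine in this run:

```
Q composition: 8/12 tracts repeat-encoded vs p0 = 0.30, p = 0.0095, log2 ratio +2.32
Q length:      mean 12.9 (repeat-encoded, n=8) vs 10.5 (variant, n=4), p = 0.53
```

i.e. at this small scale the planted poly-Q encoding bias is already
significant while the length difference is not — the dedicated recovery
test (`tests/test_acceptance.py`) demonstrates both panels at n = 140
tracts. Every stage is also available separately (`tritract simulate`,
`scan-dna`, `background`, `unit-profile`, `localize`, `scan-protein`,
`stats`, `enrich`), reading and writing plain TSV/FASTA/GFF3/OBO/bedGraph.

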