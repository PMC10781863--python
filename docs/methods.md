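# Methods

## Overview

`ddradmap` models one complete experimental design: two fully inbred
parental lines differing by scattered SNPs/InDels, one of which is a
recessive causal stop-codon SNP; reduced-representation sequencing of
PacI+NlaIII double-digest fragment libraries; presence/absence genotyping
of biallelic RAD-tag markers in a selfed F2; two-point linkage mapping;
recombinant-count placement of the binary trait; CAPS marker discovery;
and coding-consequence classification.  Every stage is deterministic
under a single seed, split hierarchically per stage (seed + CRC32 of a
stage label), so stages reproduce identically whether run standalone or
through `run_all`.

## Synthetic-data model

**Genome.** Chromosomes are i.i.d. base draws with configurable GC
content, default 0.40.  The AT-rich composition matters: the PacI site
(TTAATTAA) then occurs at roughly one site per 15 kb, giving a realistic
reduced-representation density, whereas a uniform-composition genome
would yield almost no PacI sites at megabase scale.

**Parents.** The reference carries the dominant (black-seed) alleles.
Divergence sites are sampled per base at `divergence_rate` (default
0.005 — the upper end of cultivar-pair divergence, chosen so a desk-scale
genome yields tens of markers per chromosome), each assigned to one
parent, 90% SNP / 5% insertion / 5% deletion (1–3 bp), spaced ≥ 10 bp so
anchored indels never overlap.  Parent A is the white (recessive) parent
and privately carries the causal SNP.

**Causal locus.** The causal gene is a designed cassette placed
mid-chromosome-1: a short single-exon CDS containing a PacI site at a
codon boundary, with the TGA stop codon ~22 bp downstream of the PacI cut
so the causal site sits inside the 100-bp tag footprint; a HinfI site
(GANTC) spans the stop codon in the dominant allele (context `TGA·ATC`)
and is destroyed by the causal A→G substitution (`TGG·ATC`), which also
removes the stop.  Downstream of the stop the cassette provides 25
stop-free in-frame codons followed by TAA, so read-through extends the
protein by exactly 78 nt / 26 residues; an NlaIII site is placed so the
PacI→NlaIII fragment falls mid-window.  Divergence sampling is excluded
within ±150 bp of the cassette.  The constructor re-draws random codons
until no stray PacI/NlaIII/HinfI site violates these constraints.

**Digestion and libraries.** Fragments are maximal intervals between
adjacent top-strand cut positions; only mixed-end (one cut per enzyme)
fragments inside the size window (default 200–600 bp, chosen so 100-bp
reads never span a fragment) are retained.  Read 1 is the first L bases
from the rare-cutter end, read 2 the first L bases of the opposite end on
the other strand.  Pair counts per fragment are Poisson(coverage);
coverage defaults to 25, mirroring the reads-per-tag ratio of real ddRAD
parent libraries (order 10⁷ reads over ~3×10⁵ tags).  Substitution errors
are applied per base at 0.001; FASTQ is 4-line Phred+33 with constant
quality.

**F2 and panel.** Each F2 individual is two independent F1 gametes; each
gamete gets Poisson(`crossover_rate`) crossovers per chromosome with
uniform placement and no interference.  The default rate of 1.0 per
gamete per chromosome (~100 cM) matches the per-linkage-group scale of
real integrated lettuce maps (~110 cM on average).  Phenotype is white
exactly when both gametes carry the recessive parent's causal allele.
The cultivar panel is homozygous at every site; the causal-allele count
follows `panel_alt_freq` exactly (default 45/84), and non-causal marker
sites start fully linked then have 10% of cultivars flipped per site, so
only the causal-site marker is completely associated with the phenotype.

**What the generator does not model:** base-quality profiles, PCR
duplicates, adapter read-through, allele-specific amplification bias,
residual parental heterozygosity, polyploidy, crossover interference, and
reference-genome assembly error.  Passing tests therefore demonstrate the
correctness of the algorithms under idealised sequencing noise, not
robustness to every artefact of real libraries.

## Tag genotyping

Tags are the first L bases of read 1 (read 2 optionally included);
orientation is fixed by the cut site, so tags are not
reverse-complement-collapsed.  The count threshold is strict: "more than
2 reads" ⇒ `min_count = 3`, exposed as a knob.  Placement uses pigeonhole
seeding — `max_edit + 1` non-overlapping exact segments, so any placement
within `max_edit` edits is guaranteed a seed hit — verified with banded
edit distance (edlib) in a window; the best placement must be unique,
with equal-score locations whose starts differ by ≤ `max_edit` merged as
indel wobble.  Ambiguous tags are discarded (determinism over
sensitivity).  Genotypes follow the presence/absence truth table with
`presence_min = 1` on top of the already-thresholded tag sets.

Co-segregating loci (identical call vectors across all individuals) are
collapsed after genotyping — collapsing by reference position alone would
not guarantee co-segregation — keeping the smallest-coordinate locus as
representative; loci with any missing call are then dropped
(`max_missing = 0`), both orders of magnitude smaller than, but
structurally identical to, the biallelic-tag → co-dominant-marker →
complete-data reductions of a real experiment.

## Linkage mapping

With inbred parents the phase is known, so the F2 two-point likelihood
has nine observable classes; only the double heterozygote mixes parental
and recombinant configurations.  EM iterates the expected recombinant
gamete count (initial r = 0.25, absolute tolerance 1e-8, ≤ 200
iterations), clamps to [0, 0.5], and reports LOD against r = 0.5.  Pairs
with fewer than two complete observations are flagged undefined.

Grouping is single-linkage transitive closure (defaults LOD ≥ 4.0,
r ≤ 0.35 — conventional for ~96 F2).  Ordering minimises the sum of
adjacent recombination fractions via greedy nearest-neighbour
construction plus 2-opt refinement with deterministic coordinate
tie-breaks; orientation is canonicalised by the end loci's coordinates.
This is deliberate: multipoint/HMM ordering is out of scope, and SARF +
2-opt recovers the true order (up to reversal) at the simulated marker
densities.  Kosambi is the default mapping function (Haldane selectable);
the map summary reports per-group marker counts, lengths, and mean
interval = length / marker count, rounded to one decimal for display
only.

## Trait placement and panel concordance

The segregation test is uncorrected Pearson chi-square: on 74:22 vs 3:1
this gives p = 0.64, whereas a Yates-corrected test gives ≈ 0.72 — the
uncorrected convention is therefore fixed by the published value.  An
individual is discordant at a locus iff (white and not homozygous for the
recessive parent's allele) or (black and homozygous for it); missing
calls are uninformative.  Heterozygous calls in black individuals are
concordant — the only reading under which a co-dominant marker can show
complete co-segregation.  The trait is never inserted into the map as a
pseudo-marker; placement is purely by recombinant counting, with flanks
taken along the linkage-group order.  In the panel, heterozygous or
failed genotypes are counted in an "other" class and excluded from the
discordance count.

## CAPS and consequences

Restriction sites are matched on the top strand only; the built-in
enzymes (PacI, NlaIII, HinfI, EcoRI) are palindromic or, like GANTC,
self-reverse-complementary, so top-strand scanning finds every site.
Cut offsets are table data (TTAAT^TAA, CATG^, G^ANTC, G^AATTC).  In-silico
PCR requires unique exact primer matches (thermodynamics out of scope).
CAPS discovery aligns the two alleles globally (edlib), and for each
difference tests each enzyme for a differing site count within a ±50 bp
window, emitting both alleles' digestion patterns; candidates must
actually differ in pattern.  Marker names render the genome position in
Mbp floored (not rounded) to three decimals — names are coordinates, not
measurements — with the enzyme suffixed for CAPS.

Consequence classification: substitutions in the terminal stop codon that
destroy it are stop-loss, with the extension translated through the
downstream genomic sequence to the next in-frame stop (extension_nt =
3 × extension_aa counts the translated former stop codon; a missing
downstream stop is flagged "open-ended"); length changes are frameshift
(not a multiple of 3; peptide translated to the first stop) or in-frame
indels; other substitutions are compared through the codon table.

## Numerical and degenerate-input choices

* Coordinates are 1-based closed intervals throughout.
* Single-marker linkage groups have length 0 and mean interval 0 by
  convention; a single-observation pigment group has undefined SE
  (`None`, with a logged warning).
* Mapping functions clamp r at 0.499999 to stay finite.
* Group numbering: descending marker count, then smallest reference
  coordinate; marker ids are `chrom:pos` with lexicographic allele-A
  tie-breaks.  All orderings that could depend on hash or insertion order
  are explicitly sorted, so outputs are byte-reproducible.

## Problem sizes

The study-scale configuration used by the end-to-end tests and the
acceptance script is 3 chromosomes × 1 Mbp, 96 F2 individuals, coverage
25 — about 40 s on one CPU, yielding ~150 retained fragments, ~110
parent-unique tags, and ~40 collapsed complete-data markers in three
linkage groups.  Estimator calibration uses 500 replicate locus pairs per
recombination fraction and 2,000 null simulations for the chi-square
type-I rate.

## Known limitations

* Presence/absence genotyping has no genotype-likelihood model; at very
  low coverage allele dropout appears as missing data or false
  homozygotes rather than soft uncertainty.
* A crossover falling inside a tag footprint makes that tag chimeric;
  single-point truth does not apply there (the tests account for this).
* Two-point ordering can transpose near-coincident loci at small sample
  sizes; no error-robust multipoint refinement is attempted.
* In-silico PCR is exact-match; primer mismatch tolerance and melting
  temperature are out of scope, as are dCAPS design and non-palindromic
  enzyme support.
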