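# ddradmap

Map a recessive qualitative trait — modelled on the black/white seed-colour
locus of a lettuce biparental cross — all the way from double-digest RAD
sequencing (ddRAD-seq) reads to a mapped locus, a diagnostic CAPS marker,
and a coding-consequence call.  A seeded synthetic-data generator emulates
the entire study design (inbred parents, PacI+NlaIII fragment libraries,
100 bp paired-end reads, an F2 of 96, a cultivar panel), so every stage of
the pipeline is verifiable against machine-readable truth without any
external sequencing data.

The package is aimed at plant-genetics and breeding-informatics users who
want a desk-scale, fully reproducible model of tag-based genotyping and
single-locus trait mapping.

## What it computes

* **RAD-tags** — fixed-length read-1 prefixes anchored at the rare-cutter
  end, counted per sample and thresholded (default: count > 2); the two
  parents' tag sets are partitioned into shared and parent-unique tags.
* **Biallelic tag markers** — parent-unique tags placed on the reference
  (k-mer pigeonhole seeding + edit-distance verification, multi-mappers
  discarded) and paired across parents at overlapping loci; each pair is a
  co-dominant marker whose SNP/InDel difference is classified by pairwise
  alignment.  F2 individuals are genotyped by allelic-tag
  presence/absence: `AA`, `AB`, `BB`, or missing.
* **Linkage map** — two-point recombination fractions *r* by EM over the
  nine F2 genotype classes (the double heterozygote mixes phases), with
  LOD = log10 L(r̂)/L(0.5); single-linkage grouping (LOD ≥ 4, r ≤ 0.35);
  within-group ordering by minimum sum of adjacent recombination fractions
  (greedy + 2-opt); cM spacing by Kosambi
  d = 25 ln((1+2r)/(1−2r)) or Haldane d = −50 ln(1−2r).
* **Trait placement** — Pearson chi-square segregation test against 3:1,
  then recombinant counting: a locus completely co-segregates when zero
  individuals disagree with the recessive single-locus model; the flanking
  interval is given by the nearest discordant loci along the group order.
  A cultivar panel is cross-classified per marker (phenotype × genotype),
  mirroring a marker-association table.
* **CAPS marker & consequence** — alleles are aligned, and each sequence
  difference is tested for a restriction site present in exactly one
  allele (in-silico digestion patterns per allele); coding variants are
  classified synonymous / missense / nonsense / frameshift / in-frame /
  stop-loss, with read-through extension to the next in-frame stop.

## Worked example

```python
from ddradmap import RunConfig, SimConfig, run_all

rc = RunConfig(sim=SimConfig(seed=7, n_chromosomes=3,
                             chromosome_length=300_000, n_f2=48))
manifest = run_all(rc, "demo_run")
```

or, equivalently, `ddradmap run-all --seed 7 --config cfg.json --out demo_run`.
The run writes FASTA/FASTQ/TSV/JSON outputs per stage plus a hashed
manifest.  With the seed above, `demo_run/trait/trait.json` reads

```json
{
  "best_locus": "chr1:150030",
  "cosegregating": ["chr1:150030"],
  "flanking": ["chr1:119480", "chr1:195306"],
  "segregation_p": 0.18242243945173198
}
```

i.e. exactly one marker locus (at reference position 150,030, the RAD-tag
covering the planted stop codon at 150,054) co-segregates perfectly with
the white phenotype, flanked by the nearest markers showing recombinants;
the 32:16 phenotype split is consistent with 3:1 (p = 0.18).  The CAPS
scan (`demo_run/caps/caps_candidates.tsv`) recovers the planted
polymorphism — the dominant allele carries a HinfI site spanning the stop
codon, the recessive allele does not:

```
marker_name            enzyme  ref_pos  fragments_allele_a  fragments_allele_b
LG1_v1_0.150Mbp_HinfI  HinfI   150054   534                 113,421
```

and `demo_run/consequence/consequence.json` classifies the causal variant
as a stop-loss that extends the protein by 78 nt / 26 residues before the
next in-frame stop:

```json
{"kind": "stop_loss", "extension_nt": 78, "extension_aa": 26, ...}
```

## Layout

```
src/ddradmap/
  enzymes.py     IUPAC restriction-site table and scanner
  simdata.py     synthetic genomes, parents, libraries, F2s, panels
  radtags.py     tag extraction, counting, thresholds, partitioning
  markers.py     tag placement, biallelic pairing, genotyping, collapsing
  linkmap.py     rf EM, LOD, grouping, ordering, map summaries
  traitmap.py    segregation test, trait placement, panel concordance
  candidate.py   CAPS discovery, in-silico PCR/digestion, consequences
  pipeline.py    staged orchestration with hashed manifests
  cli.py         `ddradmap` command-line interface
```

See `docs/methods.md` for the model, parameter defaults and limitations.
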