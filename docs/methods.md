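# Methods

This note documents the models, parameter choices and numerical decisions
behind `polymine`, in the spirit of a methods supplement: what is computed,
under which assumptions, and where the design was genuinely open.

## Study model

The pipeline targets EST/RNA-Seq SNP mining in highly heterozygous
polyploids without a reference genome. A *sample set* is a pooled group of
individuals (default: two tetraploid parents of a mapping population).
Within a set, reads from all individuals are mapped to one reference
transcriptome assembled from the individuals' retained transcripts, so a
polymorphic site can reflect up to `ploidy × n_individuals` haplotypes
(8 by default). The central quantity is the **reliable SNP**: a biallelic
site whose two most frequent alleles each have at least
`min_reads_per_allele = 5` supporting reads *and* are each the consensus of
at least one surviving haplotype cluster, on a transcript whose apparent
haplotype count does not exceed the ploidy ceiling.

## Haplotype clustering

Reads are grouped into fragments (mate pairs share an id). Each fragment
contributes an allele vector over the candidate sites it covers, with two
hygiene rules:

* **allele floor** — a base seen fewer than 5 times at a site is not an
  allele of that site; such observations are sequencing noise and are
  excluded from vectors (they would otherwise seed spurious 2–3 read
  clusters and inflate the haplotype count past the ceiling);
* **mate conflicts** — mates disagreeing at a site drop that site from
  their fragment's vector.

Candidate sites co-covered by at least one fragment form *linkage
components*. Within a component, identical vectors are collapsed and then
agglomerated by **complete linkage**: the similarity of two clusters is the
minimum defined pairwise similarity of their member vectors (agreement
fraction over co-covered sites, undefined below `min_shared_sites` shared
sites), merged highest-similarity-first while ≥ `sim_min = 0.8`, with ties
preferring pairs that share more sites and more reads, then the smaller
cluster index. Complete linkage matters: with average-style linkage,
partial read windows that merely *look* compatible on one or two shared
sites chain distinct haplotypes into chimeric clusters. Clusters with fewer
than 2 fragments are discarded as noise.

`min_shared_sites` defaults to 1. With short paired reads at the default
SNP density (~0.5/100 bp) most fragments cover a single polymorphic site;
requiring two shared sites would leave nearly all fragments unclusterable
and collapse recall. Panels with long reads or denser variation can raise
it in the configuration.

After agglomeration, clusters in the same component whose consensus
vectors agree on every co-covered site are **consolidated**: nothing in
the data distinguishes them as haplotypes, so they must not count twice.
(Complete linkage errs toward splitting; consolidation merges back exactly
the splits that carry no conflicting evidence. Chaining is impossible
because a merge unions the site sets.)

**Haplotype counting.** The per-transcript haplotype count compared
against the ploidy ceiling is the maximum, over candidate sites, of the
number of surviving clusters covering that site. Short window-limited
fragments make whole-transcript phasing underdetermined — clusters can
legitimately combine left-window and right-window patterns in more ways
than there are haplotypes — so summing clusters per component (or per
transcript) would overstate the haplotype count and discard ordinary
transcripts. At any single site, however, every cluster covering it is a
distinct putative haplotype. A collapsed paralog pair — dense, fully
linked differences — still exceeds the ceiling at its divergent sites and
is discarded with all its SNPs. Transcripts whose window structure is
genuinely unresolvable (many equally-supported chimeric combinations) may
still be discarded conservatively; at the default density this affects
roughly one transcript per hundred genes.

**Allele dose consistency.** With a ploidy model present, each allele of a
reliable SNP must be statistically consistent with being carried by at
least one haplotype of the pool: with N passing reads at a site and h
pooled haplotypes, an allele on one haplotype draws ~Binomial(N, 1/h)
reads; counts in the extreme lower tail (default significance 1e-3) are
rejected. At ~240x pooled depth this removes the "five coincident
sequencing errors" calls that the raw 5-read floor admits, without
touching genuine single-haplotype alleles (expected dose ~30 reads).

## Read mapping and the mapping-quality surrogate

The batch mapper seeds exact 15-mers, scores candidate diagonals gaplessly,
and rescues sub-90%-identity placements with an affine-gap DP around the
seed. Mapping quality is a score-gap surrogate: the probability that the
best placement is wrong is modelled as halving per score point separating
best from runner-up, `mapq = min(60, round(-10·log10(2^-(s1-s2))))`
≈ 3.01·(s1−s2). An unambiguous placement maps at 60; an exact tie at 0.
With the default scores (+2/−3), two diagnostic bases against an 85%
paralog yield mapq 30, comfortably above the pass threshold (> 25), while
reads that cannot distinguish two references are excluded from pileups.

## Alignment presets

BLAST-style e-value cut-offs depend on database size and Karlin–Altschul
statistics this artifact does not model. Significance is instead expressed
as named `(min_identity, min_matched_length)` presets: `loose` (0.80, 50),
`standard` (0.85, 60), `strict` (0.90, 100), `probe` (0.95, 60). The
paralog filter uses `strict`, the chloroplast screen `loose`, ortholog
grouping `loose`, the reciprocal check `standard`; all are configurable.

## Marker cascade numerics

* Context: 71-mer (35-nt flanks), rejected near transcript ends, when any
  other candidate variant falls inside the window, or when the window
  contains an ambiguous base.
* "Two or more hits" in the paralog filter counts the expected self-hit, so
  any second reference hit fails the marker (a flag switches to counting
  non-self hits only).
* Splice screen: the matched length is the longest gap-free run of aligned
  columns of the best genomic hit (mismatches count, indels break the run);
  a run below ⌈0.95 × 71⌉ = 68 indicates an exon junction inside the
  window; *no* genomic hit passes. Summing across all aligned blocks is
  available behind a flag.
* Cross-set redundancy: contexts identical on either strand with matching
  (complemented) alleles; the surviving copy follows set priority
  K > G > M > D, then lexicographic id.
* Probe-similarity screen: near-identical but non-identical contexts (the
  `probe` preset) cross-hybridise; the lower-priority marker is dropped.
* Array: ids `{set}_{transcript#}_{snp#}` with transcript numbers assigned
  per set in first-appearance order; two probes per SNP, one per strand.

## Overlap assembler

A greedy overlap-layout-consensus assembler stands in for CAP3: pairwise
dovetail/containment overlaps (either strand) of ≥ 40 columns at ≥ 97%
identity (the `-p 97` setting) are merged best-score-first; the consensus
takes the per-column majority with ties to the alphabetically smaller base.
Sequences are pre-partitioned into 16-mer-sharing components so the greedy
all-pairs stage stays near-linear. Insertions private to the sequence being
folded into a deeper profile are dropped; with sub-3% divergent inputs the
consensus is substitution-dominated and this loses nothing in practice.
A contig is never shorter than its longest member.

## Orthology-guided assembly

ORFs require an ATG start (a stop-to-stop mode exists behind a flag)
because the full-length call is anchored on the start codon. The
full-length criterion — starts with ATG, ends with a stop, translation
aligns over ≥ `flcov = 0.9` of the guide protein — fills a gap the source
procedure leaves open; 0.9 tolerates minor terminal divergence between the
target species and its guide while rejecting 5'-truncated assemblies, and
is configurable. Final sequences are named `{guide}.m{k}` with `k` by
descending length. Grouping singletons are discarded as unverifiable.

## Synthetic data: what it emulates, and what it does not

The generator plants, per sample set: Bernoulli SNP positions at
`snp_density = 0.005/bp` over each gene's expressed sequence; alternative
alleles assigned to 1…7 of the 8 pooled haplotypes; a 60% transition
fraction **calibrated against stop-codon feasibility** (positions where a
transition would create a premature stop fall back to transversions, so the
raw Bernoulli rate is adjusted in a first pass to keep the realised
fraction on target); paralog partners at 92% identity with evenly spaced
substitutions (every read-length window carries diagnostic bases, as
between genuinely diverged gene-family copies — purely random placement
would leave windows that are unresolvable in principle); exon-skipping
splice variants on unfragmented multi-exon genes at 10% read weight;
30% 5'-truncated genes (not full-length by construction); 50% of genes
delivered as two overlapping transcript fragments; non-overlapping
chloroplast slices and back-translated fungal proteins as decoys; a toy
genome with GT…AG introns. Reads are uniform-start paired-end (75 bp,
~260 bp inserts) with a flat 0.5% substitution rate rising linearly
toward the 3' end; the long-read regime is single-end ~350 bp with
indel-biased errors.

A SNP's truth label *junction-spanning* is decided by aligning its
reference context against the gene's genomic locus and checking the best
contiguous match against the 68-bp threshold — i.e. by the screen's own
geometric definition, including coincidental run-on of exon sequence into
the intron — rather than by exon arithmetic alone, which mislabels
boundary windows.

Not emulated: realistic expression-level variation (uniform coverage per
haplotype), fragmentation/GC bias, quality-score miscalibration, adapter
contamination, allele-specific expression, and real homology structure in
decoys. Passing recovery tests therefore demonstrates the pipeline's logic
under its stated statistical assumptions, not robustness to every artefact
of real libraries.

## Problem sizes and verification

The default verification configuration is 100 genes (~1 kb), one sample
set of two tetraploid individuals, 30× per-haplotype coverage and 0.5%
error — about 320k reads — which one CPU core processes end-to-end in a
few minutes. On it, the suite checks SNP precision ≥ 0.95 and recall
≥ 0.90 against planted truth, zero chloroplast/paralog/junction decoys on
the array, ≥ 90% ortholog recovery with ≥ 95% correct full-length flags,
and byte-identical reruns under a fixed seed. Alignment, ORF and
component-grouping kernels are additionally property-tested against
exhaustive oracles (full DP, span enumeration, union-find).

## Known limitations

* The assembler is a stand-in for CAP3's full algorithm: greedy pairwise
  consensus, no iterative realignment; indel-rich inputs (uncorrected
  long-read data) will produce rougher consensi.
* QualitySNPng's internal confidence scoring is not published; the
  reimplementation honours its stated knobs (similarity 0.8, 5 reads per
  allele, haplotype ceiling) plus the cluster-support rule, and may differ
  on inputs where the unpublished scoring dominates.
* Component abundance splits multi-mapped reads equally rather than by
  expectation-maximisation; only the 1% IsoPct rule depends on it.
* The mapq surrogate is monotone in the score gap but not calibrated to
  any aligner's error probabilities; only the "> 25" contract is honoured.
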