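# Methods

## The scientific question

Consecutive codons in coding sequences tend to be identical or
*isoaccepting* — decodable by the same tRNA anticodon — more often than
chance predicts.  The proposed benefit is tRNA recycling: a tRNA leaving
the ribosome E site is recharged nearby and immediately reused if the
next codon accepts it.  If that benefit is real, selection should treat
synonymous mutations differently depending on their neighbourhood: in a
stretch of isoaccepting codons, a synonymous change that *preserves* the
shared anticodon (an isoaccepting mutation) is tolerated or favoured,
while one that switches the tRNA (a nonisoaccepting synonymous mutation)
breaks the stretch and should be suppressed.  The package tests this in
two ways on polymorphic coding-sequence mutations:

1. **iso% enrichment** — among synonymous mutations, the fraction that
   are isoaccepting (iso%) is compared between codon contexts with a
   two-sided Fisher's exact test (iso context vs noniso context).
2. **MAF spectra** — the minor allele frequency (MAF) distribution of a
   mutation class is compared across contexts with two-sided Wilcoxon
   rank-sum tests; higher MAF in a class's "own" context indicates the
   class is better tolerated there.

## Wobble model and the isoacceptor relation

Anticodons are written 5'→3', so the wobble base (position 34) comes
first; positions 35/36 pair strict Watson–Crick with codon positions 2
and 1.  Position 34 pairs the codon's third base as

| anticodon 34 | codon 3rd base |
|---|---|
| G | C, T |
| C | G |
| U | A, G |
| A (read as inosine) | T, C, A |

An anticodon is *admissible* only when every codon it decodes is a sense
codon of one amino acid.  This excludes, e.g., the A34 anticodon of the
TTN box (it would span Phe and Leu) and the U34 anticodon of the ATN box
(Ile/Met).  Fifty-three anticodons survive; they are the shipped FULL
inventory.  The shipped Zea mays inventory is FULL minus the glycine
A34/inosine anticodon, the one absence that changes the relation: the
four-way isoacceptor group of the Gly box collapses to GGA↔GGG and
GGC↔GGT.  Both fixture inventories are plain GtRNAdb-style TSVs
(amino_acid, anticodon, gene_count) and any species inventory in that
format can be substituted.  Inventory entries whose anticodon decodes
mixed amino acids, or whose declared amino acid disagrees with the
decoded one, are excluded with a warning.

Two distinct sense codons are isoaccepting when they are synonymous and
share at least one decoding anticodon.  Identical codons are treated as
isoaccepting (they trivially share every tRNA), which is what makes runs
of the same codon count as co-occurrence.  Stop codons have no
decoding tRNA here: any codon pair involving a stop is nonsynonymous.
The relation is symmetric, within-amino-acid, and each codon has at most
three partners; the species relation is always a subset of the
all-possible one.

## Classification and the census

Coordinates are 1-based on the CDS (codon index = ⌈pos/3⌉).  A mutation's
*functional type* compares the mutated codon with the reference codon:
nonsense (stop gain), nonsynonymous, isoaccepting, or nonisoaccepting
synonymous.  Mutations inside the terminal stop codon (stop-loss) fit
none of the four categories and are excluded from tallies, with a log.

A mutation's *context* is the relation between the codon containing it
(the focal codon, reference allele by default — context is a property of
the genomic neighbourhood, not of the derived allele; `use_alt_focal`
flips this) and the immediately upstream codon.  A site in the first
codon has no context; a site whose upstream codon itself carries a
polymorphism is excluded from context analysis.

The genome census classifies every codon except the first of each CDS
against its predecessor.  Terminal stop codons participate (their pair
is nonsynonymous), and pairs touching an N-containing codon are counted
as ambiguous.  This yields an exact bookkeeping identity on any input:

    n_iso + n_noniso + n_nonsyn + n_ambiguous + n_genes = n_codons

because each gene contributes exactly one unclassified first codon.

## Site filters

The variant table (TSV or VCF with INFO/AF) is filtered in this order,
each dropped site carrying one primary reason: reference-mismatch
(unknown gene or disagreeing ref base), non-biallelic / non-SNV records,
alternative-allele level outside [0.02, 0.98] (sequencing-error guard;
both bounds inclusive), and finally clustering — among the survivors,
*every* member of a pair of sites in the same or adjacent codons of one
gene is removed, since a clustered neighbour makes both the codon and
its context ambiguous.  Clustering is detected after the other filters;
a site already dropped for its level does not evict its neighbour.  MAF
is min(x, 1−x) of the level x, defined on 0 < x < 1.  One record per
gene is kept from the FASTA (longest CDS; length ties break
lexicographically by transcript id); records that are not a multiple of
three, contain non-ACGTN characters, or carry an internal stop are
flagged and excluded rather than raising, since real annotation files
contain such records.

## Statistics

* Fisher's exact test: two-sided (sum of hypergeometric probabilities
  not exceeding the observed table's), via `scipy.stats.fisher_exact`.
  The reported odds ratio is the sample odds ratio, with a 0.5 Haldane
  correction only when a cell is zero (flagged).  A zero margin raises.
  The nonsynonymous-context column is descriptive only; the formal test
  is iso context vs noniso context.
* Wilcoxon rank-sum: exact permutation null over mid-ranks when both
  groups have ≤ 8 observations or the pooled sample has ≤ 10, otherwise
  the normal approximation with tie and continuity corrections
  (`scipy.stats.mannwhitneyu`).  The exact branch is enumerated in-house
  because the library's exact method declines tied data.
* Two-sided tests throughout; raw p-values, no multiple-testing
  correction (each comparison is planned).
* The CpG robustness arm repeats the whole analysis on sites whose
  reference base lies outside any CG dinucleotide, since mutation
  spectra differ at CpG sites.  Observed CpG content is CG dinucleotides
  over all within-CDS adjacent pairs; expected is f(C)·f(G) from pooled
  mononucleotide frequencies.

## Read-backed linkage disequilibrium

For two biallelic sites, reads covering both are tallied by allele
combination into RR, RM, MR, MM (N = their sum).  With marginals
P1 = (RR+RM)/N, Q1 = (MR+MM)/N, P2 = (RR+MR)/N, Q2 = (RM+MM)/N,

    D  = (RR·MM − RM·MR) / N²,    r² = D² / (P1·Q1·P2·Q2) ∈ [0, 1].

Reads covering one site, or showing a third allele at either site, are
excluded from N and tallied separately; a pair with N = 0, or
monomorphic among its covering reads, is non-computable (NA).  Paired
end mates sharing a read id count as one fragment by default
(`mate_mode="read"` keeps them separate).  High r² between sites on the
same fragments indicates co-inherited DNA variants rather than
independent errors, which is what licenses calling variants from
RNA-seq in the first place.

## The synthetic-data generator

The generator emulates the study inputs — a CDS FASTA, a variant table,
and per-read allele observations — so every stage is testable offline.

**Genome.** Each gene is ATG + interior codons + a uniform stop.  Each
interior codon is drawn from its predecessor's isoacceptor set including
the identical codon (probability `pi_iso`), from its nonisoaccepting
synonymous codons (`pi_noniso`), or uniformly from all 61 sense codons.
A predecessor with no partners of the requested kind falls back to the
identical codon.  Defaults: 50 genes, geometric lengths with mean 300
codons, `pi_iso = 0.15`, `pi_noniso = 0.10`.  These clustering rates are
deliberately exaggerated relative to real genomes (the maize census has
roughly 2.4% iso and 6.5% noniso context) so that a 50-gene miniature
yields all three contexts at statistically usable counts.

**Mutations.** Target codons are sampled uniformly over interior sense
codons, with the same-/adjacent-codon exclusion enforced by
construction.  The mutation type is drawn from a context-conditional
plan, then realized by choosing among the focal codon's nine single-base
changes.  Because not every type is achievable at every codon (a
two-codon box has no nonisoaccepting single-base change; few codons are
one base from a stop), the plan is restricted to achievable types before
drawing — with the rule that the isoaccepting and nonisoaccepting
entries are removed *jointly* when not both achievable.  That rule makes
the iso : noniso ratio conditional on a synonymous draw equal the plan
ratio at every contributing codon, so the planted enrichment is exact
and a context-uniform plan is an exact null for the Fisher test.  The
requested plan shares are therefore set above the intended realized
shares (achievability renormalization shifts them); the defaults realize
roughly the study-like breakdown of ~0.4 synonymous, ~0.6 nonsynonymous
and a small nonsense share, with iso fraction 0.8 in the iso context vs
0.4 elsewhere.

Allele levels are Beta draws rescaled into [0.02, 0.98] so the level
filter is exercised but not binding; per-class means plant the
purifying-selection ordering and the context-dependent MAF shift:
isoaccepting-in-iso-context Beta(3, 7) (mean 0.30) vs other synonymous
Beta(2, 8) (mean 0.20), nonsynonymous Beta(1.9, 9.1), nonsense
Beta(1.4, 9.6).  Ground-truth labels are written by the generator's own
labelling logic, not by the classifier, so label recovery is a real
round trip.

**Reads.** For each LD site pair, `depth` reads are a multinomial draw
over the four haplotypes; each observed allele is flipped to a random
other base with probability `error_rate` (default 0.005).  The default
haplotype frequencies (0.5, 0, 0, 0.5) plant perfect linkage, matching
the situation where called variants are genuine DNA mutations.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: codon usage bias and GC/CpG enrichment (its
CpG content is at chance, so the CpG arm is a consistency check, not a
confounder test), expression-level variation and per-library pooling,
position-dependent sequencing error, indels, isoform structure, and any
linkage between the planted mutation sites themselves.

## Problem sizes and numerical choices

The shipped verification suite runs the enrichment/MAF recovery on a
seeded bundle of 50 genes × ~300 codons with 2,000 planted mutations,
the type-I control on 200 replicates of 1,000 mutations over one fixed
genome, the Fisher-vs-enumeration agreement exhaustively for all 2×2
tables with N ≤ 30 plus a 2,000-table sample at 30 < N ≤ 60, the
Wilcoxon-vs-enumeration agreement for all group shapes with n₁+n₂ ≤ 10
(tied and untied), and r² bounds over 10⁵ random count vectors.  The
acceptance script (`scripts/acceptance.py`) regenerates the 2,000-site
bundle from its `--seed` and recomputes every reported quantity from
scratch.

Degenerate inputs are answered rather than crashed on wherever a
scientist would expect it: empty FASTA → empty set with a warning,
contexts with no synonymous mutations → NA iso%, empty comparison
groups → NA p-value with a warning, monomorphic LD pairs → NA r².
Determinism everywhere comes from a single `numpy` Generator per entry
point; identical configs (including seed) give byte-identical outputs.

## Known limitations

* The wobble rules are a deliberately coarse model (A34 always read as
  inosine; no modified-base chemistry beyond that); they are exactly the
  rules that reproduce the published per-codon isoacceptor listing, and
  no more.
* The species fixture inventory is idealized (every admissible anticodon
  except Gly A34), not a full GtRNAdb gene-count table; anticodon copy
  numbers are ignored (presence/absence only).
* Context is defined by the upstream codon only, and stretches longer
  than two codons are not modelled.
* The pipeline consumes variant tables with one pooled allele level per
  site; read alignment, pileup and genotype likelihoods are upstream of
  this package.
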