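# isocooc

Isoaccepting-codon co-occurrence analysis of synonymous mutations in
coding sequences.

Consecutive codons in a CDS are often identical or *isoaccepting* —
decodable by the same tRNA anticodon — which lets the ribosome reuse a
just-recharged tRNA and speeds translation elongation.  If that benefit
is under selection, synonymous mutations should be treated differently
depending on their neighbourhood: in an isoaccepting stretch, a change
that keeps the shared anticodon (an *isoaccepting mutation*) is
tolerated, while one that switches the tRNA (*nonisoaccepting*) breaks
the stretch and should be suppressed.  `isocooc` is for population /
evolutionary genomicists who want to test this signal in polymorphism
data called on CDS references (e.g. from RNA-seq), or to prototype the
analysis on fully synthetic data.

The package provides:

* **codon model** — the isoaccepting relation over all 61 sense codons,
  derived from explicit wobble rules (G34:C/T, C34:G, U34:A/G, A34 read
  as inosine:T/C/A; strict Watson–Crick at 35/36) and restricted by a
  species tRNA inventory (GtRNAdb-style TSV; idealized FULL and
  *Zea mays* fixtures ship with the package);
* **ingestion** — longest-CDS-per-gene FASTA reading, variant tables
  (TSV or VCF), and the polymorphism filters: biallelic SNVs only,
  allele level x ∈ [0.02, 0.98], no two mutations in the same or
  adjacent codons; MAF = min(x, 1−x);
* **classification** — mutation types (isoaccepting / nonisoaccepting
  synonymous / nonsynonymous / nonsense) and codon contexts (relation of
  the focal codon to its upstream codon), plus a genome-wide census
  satisfying the exact identity
  `n_iso + n_noniso + n_nonsyn + n_ambiguous + n_genes = n_codons`;
* **statistics** — iso% per context with a two-sided Fisher's exact
  test (iso vs noniso context), MAF-spectrum comparisons with Wilcoxon
  rank-sum tests (exact for small groups), and a CpG-excluded
  robustness arm;
* **read-backed LD** — for sites co-covered by single reads/fragments,
  `D = (RR·MM − RM·MR)/N²` and `r² = D²/(P1·Q1·P2·Q2)` from the
  RR/RM/MR/MM read tallies, to check that called variants behave like
  co-inherited DNA mutations;
* **synthetic data** — a generator for CDS sets with tunable
  isoacceptor clustering, planted mutations with context-conditional
  type composition and Beta-distributed allele levels, and
  multinomial read-allele tables; every planted label is recoverable by
  the pipeline.

See `docs/methods.md` for the model, parameter defaults, and design
choices.

## Worked example

Generate a miniature study and run the whole pipeline from the shell:

```sh
isocooc simulate --seed 5 --out fix
isocooc ingest   --cds fix/cds.fa --variants fix/variants.tsv \
                 --out kept.tsv --dropped dropped.tsv
isocooc classify --cds fix/cds.fa --kept kept.tsv --out classified.tsv
isocooc census   --cds fix/cds.fa --out census.tsv
isocooc analyze  --classified classified.tsv --cpg-robustness --out report
isocooc ld       --alleles fix/ld_reads.tsv --sites fix/ld_sites.tsv --out ld.tsv
```

which prints (abridged):

```
wrote bundle to fix: 50 genes, 500 mutations, 10 LD pairs
kept 500 site(s), dropped 0
classified 500 site(s)
50 genes, 13536 codons; identity holds: True
{
  "all": {
    "n_sites": 500,
    "medians_by_type": {
      "SYNONYMOUS": 0.201283,
      "NONSYNONYMOUS": 0.173905,
      "NONSENSE": 0.111818
    },
    "fisher_odds_ratio": 14.0,
    "fisher_p": 0.00019886833056924615
  },
  ...
}
{
  "n_pairs": 10,
  "n_noncomputable": 0,
  "median_r2": 0.9801076655398688
}
```

Reading the output: the median MAF ordering nonsense < nonsynonymous <
synonymous reflects purifying selection against the more damaging
classes; the Fisher p-value (~2e-4) says the fraction of isoaccepting
mutations among synonymous ones is significantly higher in an
isoaccepting context than in a nonisoaccepting context (odds ratio 14
on this bundle — the generator plants iso fractions of 0.8 vs 0.4); and
the median pairwise r² near 1 says the simulated site pairs behave like
fully linked DNA variants.  On this synthetic bundle all three signals
are planted, and the pipeline recovers them.

The same analyses are available as library functions
(`isocooc.read_cds_fasta`, `filter_variants`, `classify_mutations`,
`run_full_analysis`, `pairwise_ld`, ...) operating on pandas frames.

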