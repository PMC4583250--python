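# mitoburden

Variant post-processing and gene-level enrichment analysis for targeted
sequencing of the human mitochondrial genome.

Studies that deep-sequence the 16.6 kb circular mtDNA of a patient cohort
face three problems this package solves after variant calling:

1. **Haploid-aware filtering.** mtDNA is effectively haploid, so a
   heterozygous-looking call is a signature of heteroplasmy or sequencing
   noise rather than a germline variant; and semiconductor platforms produce
   strand-biased false calls, especially indels in homopolymer tracts.
   `mitoburden` removes heterozygous calls and calls whose weaker strand
   carries less than 10% of the alt-supporting reads
   (`f = min(alt_fwd, alt_rev) / (alt_fwd + alt_rev) < 0.10`), then
   aggregates the survivors into study-wide variants with carrier counts.
2. **Annotation.** Gene context on a circular genome with overlapping ORFs,
   variant type, membership in a MITOMAP-like known-variant catalog,
   conservation flags, homopolymer context, SIFT/PolyPhen concordance, and
   codon / amino-acid changes under the **vertebrate mitochondrial genetic
   code** (ATA→Met, TGA→Trp, AGA/AGG→stop), rendered in the field's
   conventional style (`aAc/aGc`, altered base uppercase).
3. **Per-gene enrichment.** For gene *x* of length *l_x* bp with *N_x*
   distinct variants, the *global variant enrichment rate* is

       r_g = N_x / l_x × 1000   [variants/Mb]

   and, with *n_i* the carrier count of the gene's *i*-th variant, the
   *weighted variant enrichment rate* is

       r_w = Σ_i n_i / l_x      [per bp; ×1000 optional]

   computed for all genes except tRNAs (too short to give stable rates),
   with a Shapiro–Wilk normality check on the per-gene `r_g` values and
   percentile placement of individual genes.

A synthetic-data module simulates a haploid cohort (common, rare and
reference-minor variants; Poisson depth with binomial strand split) with
labelled artifact injection, so every stage is testable without any
external download. A 15-gene human mtDNA gene model with published per-gene
variant counts from a 436-genome breast-cancer cohort study is bundled as a
fixture.

## Worked example

```sh
python examples/gene_enrichment.py
```

```
top genes by global enrichment rate (variants/Mb):
  MT-ATP6   r_g =  86.5  (N_x = 59, l_x = 682 bp)
  MT-CYB    r_g =  84.1  (N_x = 96, l_x = 1142 bp)
  MT-CO3    r_g =  76.4  (N_x = 60, l_x = 785 bp)

mean r_g over the 15 genes: 64.1 variants/Mb
mean r_w (per-bp scale):    0.45
Shapiro-Wilk on r_g:        W = 0.933, p = 0.30
MT-ATP6: 93.5th percentile of the fitted normal distribution
MT-CYB: 91.1th percentile of the fitted normal distribution
```

`MT-ATP6` and `MT-CYB` carry the most distinct variants per Mb of any
mitochondrial gene in the bundled cohort table; the Shapiro–Wilk p-value
well above 0.05 says the 15 per-gene rates are consistent with a normal
distribution, which licenses reading the two genes' rates as upper-tail
percentiles of that distribution.

The other examples cover filtering (`examples/filter_calls.py`),
codon annotation on both strands (`examples/annotate_codons.py`) and the
full simulate → filter → annotate → enrich pipeline
(`examples/simulate_and_run.py`).

## Command line

A thin CLI wraps the library:

```sh
mitoburden simulate --out sim/ --seed 7            # synthetic bundle
mitoburden filter   --vcf sim/calls.vcf --out filtered.vcf --log discards.tsv
mitoburden run      --vcf sim/calls.vcf --genes sim/genes.tsv \
                    --ref sim/ref.fa --out run/    # end-to-end with manifest
mitoburden enrich   --from-counts genes.tsv --out enrichment.tsv
mitoburden summarize --annotated run/annotated.tsv
```

VCF dialect: per-sample FORMAT fields `SAF`/`SAR` carry the strand-split
alternate-allele depths; haploid genotypes are written as single-allele GT
and diploid-style input is accepted.

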