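# Methods

## Scope and data model

`mitoburden` operates downstream of read alignment and variant calling: its
inputs are per-sample variant calls (VCF with strand-split alt depths), a
gene model of the circular mitochondrial genome, and optional side tables
(reference FASTA, known-variant catalog, conserved positions, external
SIFT/PolyPhen categories, rsid map). Read-level processing, the predictors
themselves, catalog curation and heteroplasmy quantification are out of
scope; predictor and catalog outputs are consumed as data.

Coordinates are 1-based inclusive on the heavy strand; a feature with
`end < start` spans the replication origin. Overlapping genes are
first-class: position lookup returns every covering gene, and a variant in
an overlap contributes once to each overlapping gene's tally (mtDNA's
overlapping ORFs make any single-gene tie-break arbitrary; per-gene tallies
are the downstream quantity of interest).

Two gene lengths coexist deliberately. `printed_length` is carried verbatim
from the input gene table and is the enrichment denominator; the
coordinate span (`end − start + 1`, circular) drives interval and codon
logic only. In the bundled 15-gene human model the published lengths exceed
the standard-annotation spans slightly (usually by 1); reproducing the
published rates requires using the published lengths verbatim, so they are
never recomputed.

## Filters

* **Genotype filter.** Only hom-alt calls pass. Heterozygous-looking calls
  are heteroplasmy/noise signatures on a haploid genome and are logged as
  `het_genotype`; missing genotypes as `missing_genotype`; hom-ref entries
  are not variant calls and are dropped silently.
* **Strand-balance filter.** With `f = min(alt_fwd, alt_rev) /
  (alt_fwd + alt_rev)`, a call fails (`strand_imbalance`) iff
  `f < min_fraction` (default 0.10). The comparison is strict, so a call
  exactly at the threshold passes. The denominator is alt-supporting reads
  only: at a reference-heavy site, total depth would dilute the imbalance
  signal. Zero alt support fails with its own reason (`no_alt_support`) to
  keep discard logs interpretable.

Both filters act per sample-call; a variant stays in the study while at
least one of its calls survives. The filters are idempotent, return subsets
of their input, commute with each other, and the strand filter is monotone
in its threshold — these algebraic properties are enforced by property
tests.

Aggregation keys calls by (position, ref, alt); carrier counts are distinct
samples (duplicate calls by one sample count once).

## Annotation

Variant type is decided purely on the allele pair (equal length 1 →
substitution; prefix relations → insertion/deletion; otherwise complex).
Codon context applies to substitutions in protein-coding genes: the reading
frame is anchored at the gene's coordinate start, the containing codon is
extracted on the coding strand (heavy-strand alleles are complemented for
light-strand genes), and both codons are translated under NCBI genetic code
table 2 (via biopython). Effects: synonymous, missense, nonsense (alt codon
is stop), stop-loss (ref codon is stop). Codons rendered lowercase with the
altered base uppercase, matching the conventional presentation. When coding
genes overlap, the singular codon fields use the first overlapping coding
gene in model order. A substitution whose codon is truncated by the gene
boundary (incomplete terminal codons exist in real mtDNA annotation) gets
no codon fields and no effect call rather than a guess. Coding indels are
labelled `frameshift_candidate`; full consequence modelling of indels is
intentionally absent.

Homopolymer context flags a position lying in or immediately adjacent to a
run of ≥ 4 identical bases (circular wrap respected) — the locus class where
semiconductor sequencing misestimates run lengths, so passing indels there
deserve suspicion even when strand-balanced.

The concordance filter keeps variants rated `deleterious` (SIFT) **and**
`probably_damaging` (PolyPhen); an NA on either side excludes.

## Enrichment statistics

`r_g = N_x / l_x × 1000` variants/Mb; `r_w = Σ n_i / l_x`. The weighted
rate's default scale is **per bp** because the published per-gene table this
package bundles prints values on that scale (e.g. 0.92 for a gene with
carrier-sum ≈ 627 over 682 bp, which is numerically impossible under a
×1000 reading); `per_Mb` is available and the report records the scale
used. Genes of excluded biotypes (default `Mt_tRNA`) are dropped before any
mean; genes with zero variants are kept with zeros so the denominator of
the means is explicit. Internal computation is at full precision; display
rounding is r_g 1 decimal, r_w 2 decimals.

Normality of the per-gene r_g values is tested with scipy's Shapiro–Wilk
(≥ 3 non-identical values required; constant input is an error, not p = 1).
Percentile placement defaults to the **normal model**, 100·Φ((x − mean)/sd)
with sample sd, consistent with justifying percentiles by a passed
normality test. Three rank conventions (strict-empirical, Hazen, Weibull)
are exposed because published percentile figures in this literature rarely
state their convention and no single convention reproduces every printed
value; the bundled table's two headline genes land at ≈ 93.5 and ≈ 91.2
under the normal model. Ranking sorts by r_g descending with alphabetical
tie-break.

One bundled-table caveat is reproduced, not repaired: the rRNA gene
MT-RNR2's printed rate (37.2) is inconsistent with its own printed count
and length (57/1561 × 1000 = 36.5). Recomputation therefore matches 14 of
the 15 printed rates; the tests document the discrepant row explicitly.

## Synthetic data

The generator emulates a targeted haploid-cohort resequencing experiment;
defaults are the bundled study's scale: 436 samples, ~1200 distinct
variants (200 common with allele frequencies 0.05–0.5, 1000 rare with 1–3
carriers, 2 reference-minor sites with alt frequency ≥ 0.95 enforced as a
floor), mean depth 198×. Toy genomes are random sequence with planted
structure: ≥ 1 light-strand gene, one overlapping coding pair, rRNA- and
tRNA-like features, ≥ 3 homopolymer runs of length ≥ 4; accidental runs are
broken so run positions are controlled. True calls are hom-alt with
Poisson-total, binomial(0.5)-split strand depths. Artifacts are injected as
*extra* calls at positions carrying no true variant, with per-call binomial
counts at the configured rates: heterozygous-looking calls (balanced
support, caught by the genotype filter), single-strand calls (caught by the
strand filter), and homopolymer indels given *balanced* support — they
survive read-support filtering, as such indels do on real data, and must be
caught by sequence context. Everything is deterministic given the config
seed; bundle writes are byte-stable.

What the simulation does **not** model: phylogenetic (haplogroup)
correlation between variants, position-dependent coverage profiles,
reference-biased alignment loss, true heteroplasmy mixtures, and
multi-nucleotide error processes. Filter-recovery results on synthetic data
therefore demonstrate correctness of the decision rules under the stated
noise model, not field performance on any particular platform.

## Problem sizes and numerical choices

The test suite runs most scenarios on 2.5–6 kb genomes with 30–60 samples;
one end-to-end test and the simulation examples use the full default scale
(436 samples, ~30 000 calls), which completes in seconds. The enrichment
rank-recovery property uses 100 replicates of a two-gene design with
per-base densities 0.05 vs 0.01 on a 2.5 kb genome. Strand-fraction
comparisons are plain float division with a strict `<`; at the default
threshold the boundary case 5/50 evaluates exactly. Shapiro–Wilk and the
normal CDF come from scipy; the genetic code from biopython's table 2 —
none of these are reimplemented.

## Known limitations

* The annotated-table schema is this package's own; there is no canonical
  published schema for study-level mtDNA variant lists.
* Conservation is a plain position-set membership; the package does not
  compute alignments across species.
* `enrich --annotated` reconstructs carriers from the `counts` column, so
  sample identities are not preserved through that path (the end-to-end
  `run` path preserves them).
* No case-control statistics: the intended study design has no controls,
  and none are implemented.
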