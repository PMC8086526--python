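# Methods

## Problem setting

Two populations descended from a common ancestor are compared at biallelic
SNPs. Sites where allele frequencies have drifted (or been driven) far apart
carry high F_ST; the analysis asks whether such *highly differentiated* (HD)
variants concentrate in functional sequence classes — promoters, enhancers,
exons — and which genes they implicate. The package implements the scan, the
region construction, the enrichment statistics, target-gene assignment and
gene-set enrichment as separately testable stages, plus a generator that
plants known structure for verification.

## F_ST estimation

**Weir–Cockerham (default).** The 1984 two-population per-site estimator
`theta = a / (a + b + c)` from the among-population (a), between-individual
(b) and within-individual (c) variance components, with sample sizes in
diploid individuals `n_i = called_i / 2`. The substrate is per-population
allele counts, so the observed heterozygote frequency required by b and c is
not available; it is replaced by its Hardy–Weinberg expectation
`h_i = 2 p_i (1 - p_i)`. Consequences: for synthetic data the substitution is
exact in distribution (genotypes are binomial draws); for real data with
inbreeding or Wahlund substructure within populations the estimate will
differ from genotype-aware implementations. Algebraically the substitution
preserves the two anchor cases — opposite fixation gives exactly 1 (the b
term vanishes identically: with p1=1, p2=0, `pbar*(1-pbar) = s2/2`), and
equal sample frequencies give a negative numerator, clamping to 0.

**Hudson (flag).** `N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)`,
`D = p1(1-p2) + p2(1-p1)`, sample sizes in chromosomes. Genome-wide or
per-class summaries use the ratio of averages `sum(N)/sum(D)`, which is the
low-bias way to combine sites; per-site ratios are reported for ranking only.

Handling rules: monomorphic combined sites dropped (logged); sites with < 2
called chromosomes in a population dropped, not imputed; half-called
genotypes treated as missing; negative per-site estimates clamped to 0 with
the raw ratio retained; WC is additionally undefined when both populations
hold a single diploid (nbar = 1) and such records drop. Sex chromosomes and
the mitochondrion are excluded by default (autosomal scan); a parameter
admits them.

**Selection and binning.** HD = the `ceil(q*N)` highest F_ST records
(default q = 0.01), with all records tied at the realized threshold included
— conservative and order-independent. Strata for reporting are left-closed
bins on `[0, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]` with the exact value 1 split out
as its own `=1` stratum, since fixed differences are a qualitatively distinct
class.

## Region classes

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive) is
converted at the boundary, BED passes through natively. Interval algebra
(merge/subtract/intersect/complement) is implemented directly on sorted
int64 arrays and validated against per-base bitmap oracles on randomized toy
genomes.

* **Promoters**: a window per distinct protein-coding TSS, 1,000 bp upstream
  and 500 bp downstream. The downstream stretch *includes* the TSS base, so
  every window is exactly 1,500 bp on either strand (`[tss-1000, tss+500)` on
  +, `[tss-499, tss+1001)` on −). Duplicate TSSs are deduplicated. Two views
  are kept: per-TSS windows (for promoter counting and per-gene variant
  lookup) and the merged set (for overlap arithmetic).
* **Enhancers**: union of all peak sets (the inclusive reading of open
  chromatin "and/or" H3K27Ac), minus promoters. No minimum fragment length.
* **Exons**: merged union of CDS segments.

Promoter/enhancer are disjoint by construction; exons are deliberately not
subtracted from either, so a variant may belong to promoter and exon at
once — enrichment rows count it in both classes.

## Enrichment

For a stratum of variants and a class, `fold = (n_hd_in/n_hd)/(n_all_in/n_all)`
with the **variant-count baseline**: the fraction of all tested variants in
the class, not the class's genomic base fraction. Constrained sequence
carries systematically fewer SNPs, so the base-fraction baseline would
conflate depressed variant density with enrichment; both baselines are
reported, the variant-count one is primary. Significance is the one-sided
upper-tail hypergeometric probability (drawing `n_hd` variants from the
tested universe), computed via `logsf` so extreme tails (1e-258 and beyond)
survive; `log10_p` is reported next to `p`. Report percentages round to
whole numbers at ≥ 10% and one decimal below.

## Target assignment

* **Density filter**: an enhancer is kept iff `hd_count / length >= 1/500`
  (boundary kept; zero-HD enhancers always dropped). The phrase "one variant
  in every 500 bases" is read as a per-enhancer rate — the weaker, more
  inclusive reading; a strict sliding-window mode (`sliding_window=True`:
  no 500-bp stretch without a variant) is available.
* **Regulatory domains**: per gene, a strand-aware basal window (5 kb
  upstream, 1 kb downstream of the TSS), extended on each side by up to 1 Mb
  from the basal edge but truncated at the nearest other gene's basal
  boundary and clipped to the chromosome — the published basal-plus-extension
  default of the GREAT tool, re-implemented geometrically (the
  expression-aware refinements of the original service are not reproducible
  from coordinates alone). A neighbour whose basal window overlaps the
  gene's own basal is ignored for truncation (the basal window is never
  shrunk).
* **Assignment**: enhancer → gene iff the enhancer overlaps the gene's
  extended domain by ≥ 1 base; enhancers overlapping no domain are recorded
  as unassigned. Promoter-side gene lists collect genes with ≥ 1 HD variant
  in ≥ 1 of their per-TSS windows; the qualifying-window count is reported
  separately since one gene can have several.

## Gene-set enrichment

Flat GMT collections; no ontology-graph propagation. Each term: one-sided
hypergeometric on the overlap between the query and the term within the
universe, members outside the universe dropped with a log line. The
**universe** defaults to all annotated genes reachable by the same machinery
from all *tested* variants in any analyzed region (promoter windows +
regulatory domains of enhancers carrying any variant) — i.e. the selection
frame of the scan. Enrichment results are universe-sensitive and the choice
is surfaced in the pipeline config. BH-FDR via the standard step-up
(statsmodels); default report thresholds 0.05 or 0.01 with a 30-term cap,
all configurable. Enriched terms are clustered by Jaccard distance
`1 - |A∩B|/|A∪B|` on query-restricted member genes, average linkage (a
config field), term names sorted pre-clustering so ties break
deterministically; output is newick.

## Synthetic data generator

The generator emulates the *shape* of a mammalian two-population scan at
desk scale. Defaults: 2 chromosomes × 5 Mb; 120 non-overlapping stranded
genes (bodies 3–12 kb, 1–3 coding exons of 600–1,800 bp total); peaks
pooled at 18/Mb with lengths U(1000, 5000) — expected union coverage
18 × 3,000 / 1e6 ≈ 5.4% of the genome, matching the scale of a real
open-chromatin/H3K27Ac compendium; promoters ≈ 1.8% and exons ≈ 1.4% of the
genome; 38 + 41 diploid samples (the real study's sizes); background
divergence F = 0.2 (a realistic genome-wide value for a domesticate/wild
pair); ancestral frequencies U(0.05, 0.95).

Placement uses Dirichlet-distributed gaps, so blocks never overlap and an
infeasible request (genes that cannot fit) raises an explicit error. Each
gene gets a 5' UTR of ≥ 600 bp between TSS and first coding base: promoter
windows (downstream 500) and coding exons are thereby disjoint by
construction, so a planted promoter effect cannot leak into the exon
stratum and the two classes remain cleanly separable in recovery tests.

Sites are placed uniformly (optional per-class density multipliers via
rejection), deduplicated, labelled with precedence
promoter > exon > enhancer > background (only promoter/exon overlap would be
ambiguous, and that is empty by the UTR rule). Per site: ancestral `p` ~
U(range), divergence `F` from `f_by_class` or the background, then two
independent Balding–Nichols draws `Beta(p(1-F)/F, (1-p)(1-F)/F)` — mean `p`,
variance `p(1-p)F`. Genotypes are Binomial(2, p_pop) per diploid; sites
monomorphic across the combined sample are re-drawn (frequencies and
genotypes, up to 100 times, count recorded) because F_ST is undefined there;
missingness is masked afterwards at `missing_rate`. Outputs are VCF v4.2
(GT-only), GFF3, BED, chrom-sizes TSV, sample lists and a planted-truth TSV;
identical configs give byte-identical files.

**Not emulated** (so passing tests do not speak to these): linkage
disequilibrium (every site independent — real top-1% selections are locally
correlated), realistic site-frequency spectra, QC/filtering artifacts,
multi-transcript genes, indels/multiallelics, sequencing error, variable
chromosome sizes.

## Numerical and design choices

* Hypergeometric tails in log space; p may underflow to 0 but log10_p is
  always finite.
* Ties at the HD threshold: all included (set may exceed the nominal count;
  logged).
* Interval sets merge abutting intervals; region membership of a variant at
  1-based `pos` is `start <= pos-1 < end`.
* Estimator choice is a recorded config field; which estimator (and which
  QC) produced any given published variant table is generally unstated, so
  both are provided and the default follows the community default of the
  study era (Weir–Cockerham).
* Determinism: every stage derives its RNG from (seed, stage-id); pipeline
  manifests record sha256 checksums, and re-runs with the same config are
  checksum-identical.
* Problem sizes in the shipped tests and the acceptance script (1e5-site
  recovery runs, 200-replicate calibration at 4,000 sites, 100 bitmap toy
  genomes) were chosen as the smallest scales at which the Monte-Carlo
  tolerances (3 SE) are informative.

## Known limitations

* The WC heterozygosity substitution (above) makes the estimator exact under
  within-population HWE only.
* The hypergeometric enrichment test treats variants as exchangeable; with
  LD the effective number of independent HD variants is smaller and p-values
  on real data are anti-conservative. An LD-aware or MAF-matched permutation
  null is a documented extension point, not implemented.
* GREAT-style assignment here is purely geometric; expression-aware target
  curation is out of scope.
* Published headline numbers from any specific real dataset (fold values,
  thresholds, gene counts) depend on that dataset and its annotation; the
  pipeline reports their analogues on whatever inputs it is given.
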