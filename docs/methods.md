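# Methods

## Model

A dikaryon mixes two haploid nucleotypes at proportion *p* (nucleotype
1) and 1 − *p*. At a divergent (biallelic) site, sequencing reads carry
the nucleotype-1 allele with probability

    q = p(1 − e) + (1 − p)e,

where *e* is a symmetric per-read allele-flip error. Observed allele
counts at a site with depth *n* are Binomial(*n*, *q*); the reference
assembly carries the nucleotype-1 allele at a random half of sites, so
the reference-allele frequency distribution over sites is the mirror
mixture {q, 1 − q}. Estimating *p* therefore means locating the modes
of that distribution (or its median after orienting each site by which
nucleotype supplied the reference allele, which the simulator's truth
table makes possible).

Transcription of a gene distributes reads over the two alleles with a
nucleotype-1 share *s*:

- neutral gene: s = p (transcription mirrors nuclear dosage),
- cis-acting allelic imbalance: logit(s) = logit(p) ± β·ln 2, so β is
  the planted log2 fold-effect (β = 1 at p = 0.5 gives a 2:1 ratio and
  log2 aFC = 1),
- monoallelically silenced gene: s ∈ {0, 1} (one nucleotype's copy is
  off) and total expression is scaled by a multiplier < 1.

## Pipeline stages and their parameters

**Cohort filter** (broad survey regime): biallelic SNP records with
minor-allele frequency ≥ 0.10 and depth ≥ 20, present in ≥ 60% of a
line's biological replicates (ceiling rounding: 2 of 3). Presence is
counted on biological replicates by default; a flag switches to
technical replicates, since with duplicate library preparations per
biological replicate either reading is defensible.

**Strict (focal-line) filter**: two stages. Stage 1 removes
repeat-overlapping records (BED mask), Phred quality < 30, scaffolds
≤ 1 kb (strict >), coverage ≤ 10 (strict >) and records where both
alleles are not actually observed, then requires detection in all of
the line's replicates (6 = 3 biological × 2 technical). "Detected"
means both alleles seen with sufficient coverage in that replicate —
the biallelic observation itself, since the pipeline consumes caller
output rather than re-calling. Stage 2 computes per-replicate quartiles
of candidate site depths (linear-interpolation, type-7; boundaries
inclusive) and keeps site-replicates with Q1 ≤ depth ≤ Q3 and ≥ 20
reads; a site survives with ≥ 5 passing replicates.

**Pooling**: a site's replicate (ref, alt) counts are pooled into a
single frequency only when a chi-squared homogeneity test across
replicates gives P > 0.05; heterogeneous sites are excluded from
frequency analyses but reported and counted, so the gate is auditable.

**Mode detection**: Gaussian KDE on [0, 1] with boundary reflection;
bandwidth by Silverman's rule (0.9·min(sd, IQR/1.349)·n^(−1/5)),
overridable. Local maxima with prominence ≥ 10% of the global maximum
and pairwise separation ≥ 0.05 count as modes; 1/2/≥3 modes classify
the distribution as unimodal/bimodal/multimodal. The detector is a
reproducible surrogate for by-eye classification and is validated on
simulated diploid (one mode at 0.5) and tetraploid (modes at
0.25/0.5/0.75, weights 0.25/0.5/0.25 by default) controls. Mode
analysis requires ≥ 50 frequencies; below that the distribution shape
is undefined and an error is raised.

**Shift tests**: per common site, a 2×2 Pearson chi-squared compares
parent and offspring (ref, alt) counts (no continuity correction by
default, matching the classic closed form N(ad−bc)²/(r₁r₂c₁c₂);
Yates correction is a flag). The aggregate shift takes
Δf_ref = f_offspring − f_parent at sites significant at α = 0.05
(raw p by default, Holm optional), tests the deltas against zero with
a one-sample t test, and compares the full f_ref vectors with an
unpaired Mann-Whitney test. A direction (increase/decrease) is reported
only when the t test rejects. Because the simulator assigns the
reference allele to nucleotype 1 at exactly half the sites, per-site
shifts in a proportion-shifted line are large but symmetric, so the
*count* of significant sites — not the signed mean — carries the
dikaryon signal; real assemblies can be systematically closer to one
nucleotype, which would add a signed component.

**Qualitative side**: samples with ≥ 4000 SNPs (configurable) enter a
presence/absence matrix over the union of loci, missing = absent.
Distances are binary (Jaccard): mismatches over the union of present
loci; clustering is agglomerative with average linkage (UPGMA) by
default, exported as newick. PCA (on presence calls or on allele
frequencies at common sites) is column-centred, unscaled, via SVD.

**Statistics**: the six tests used (2×2 chi-squared, k×2 homogeneity,
Mann-Whitney U, one-sample t, Pearson r, OLS slope) are implemented
from their defining formulas with scipy supplying only distribution
functions; each is tested against an independent oracle (scipy's test
implementations, statsmodels' Holm, exact enumeration). Mann-Whitney is
exact by enumeration of all C(n+m, n) assignments when n + m ≤ 16 with
no ties, otherwise a normal approximation with tie and continuity
correction. All tests are two-sided by default with a sidedness
parameter. Holm adjustment is step-down with monotonicity enforcement.

**Transcriptome side**: per gene, aFC uses the highest-coverage
passing biallelic site with counts pooled across the line's replicates
(per-replicate mode available); |log2(aFC)| > 0.5 (strict) flags AI,
equivalent to a major-allele share > √2/(1+√2) ≈ 0.5858. A zero count
on either allele leaves aFC undefined; such genes are excluded from AI
proportions (counted) and handled by the MA classifier. AI proportions
across lines are compared with a k-sample proportion chi-squared and
all pairwise 2×2 tests with Holm adjustment (no continuity correction
by default, so pairwise statistics match the closed-form oracle).
MA/BA classification works per replicate: a genomically biallelic site
with RNA depth ≥ 25 is informative, MA if exactly one of its two
genomic alleles is observed, BA if both; a replicate's gene call is BA
if any site is BA, and the consensus requires all informative
replicates to agree. FPKM = count·10⁹/(length·total) with summed CDS
length as the length (the simulator has no transcript models; this
diverges from transcript-length FPKM and is documented). MA-vs-BA
contrasts are Mann-Whitney on log2(FPKM+1) of per-gene mean FPKM and
on SNP density (1000 × CDS biallelic sites / CDS length).

## The synthetic cohort generator

The generator emulates the statistical structure of a
reduced-representation + RNA study of clonal sibling lines. Defaults
(one integer seed drives everything; fixed seed ⇒ byte-identical
files):

| parameter | default | rationale |
|---|---|---|
| scaffolds × length | 8 × 100 kb | desk-scale genome, ~800 divergent sites |
| snp_density | 1 /kb | within the range reported for dikaryon nucleotype divergence |
| parent_p / offspring_p | 0.5 / (0.4, 0.5, 0.5, 0.5, 0.6) | parent near 1:1; drift to 2:3 and 3:2 observed in real siblings |
| replicates | 3 biological × 2 technical | the emulated design |
| dna_depth_mean | 80× | typical reduced-representation site depth |
| rna_depth_mean | 100× | typical transcript site depth |
| base_error_rate | 0.005 | post-filter sequencing error |
| site_depth_sigma | 0.4 | lognormal per-site capture efficiency |
| bio_rep_sigma | 0.2 | lognormal biological expression variation |
| frac_ai / ai_log2_effect | 0.10 / 1.0 | planted cis-imbalance genes |
| frac_ma / density × / expression × | 0.10 / 3.0 / 0.3 | silenced genes: more divergent, less expressed |

DNA depth at a site is Poisson around dna_depth_mean times a
per-site lognormal capture factor shared across replicates and lines —
the fragment/restriction-site efficiency that dominates
reduced-representation coverage. This factor is what makes the
depth-IQR filter behave realistically: without it, middle-quartile
membership is independent across replicates and almost no site passes
in ≥ 5 of 6 replicates, and cross-line common-site sets collapse.
Technical replicates resample reads only; biological replicates
additionally resample gene expression factors (the emulated study
pooled several culture plates per biological replicate, which we model
as a modest σ = 0.2). The error model is a symmetric allele flip; no
indels or multi-nucleotide variants are simulated by default.

What the generator does **not** emulate: mapping bias toward the
reference allele, library-level batch effects, PCR duplicates,
assembly errors and repeat families beyond the planted BED intervals,
and any recombination between nucleotypes (deliberately absent — the
organism shows no evidence of it). Passing tests therefore demonstrate
the pipeline's operating characteristics under clean binomial
sampling, not robustness to alignment artefacts.

## Numerical choices and degenerate inputs

- Internal coordinates are 0-based half-open everywhere; only VCF I/O
  is 1-based, converted exactly once at the boundary.
- Site identity across samples is (scaffold, position, allele pair)
  with the allele pair order-normalized.
- Zero-variance detection for the t test uses exact constancy of the
  data (max − min = 0), not the computed sd, which can pick up
  summation dust of order 1e−17 on constant inputs.
- Homogeneity tests drop zero-total replicate rows with a warning and
  reduce the degrees of freedom; a 2×2 with a zero marginal raises a
  degenerate-table error naming the marginal.
- The IQR filter raises if a replicate has fewer than 4 candidate
  sites (quartiles undefined) rather than guessing.
- Rarefaction of common sites enumerates all subsets of size k when
  C(n, k) ≤ 200, otherwise 200 seeded random subsets.
- KDE reflection at 0 and 1 triples the sample; the density is
  rescaled by 3 so prominence thresholds refer to the [0, 1] mass.
- Mann-Whitney with all observations identical returns p = 1 (zero
  variance of U means no evidence either way).

## Known limitations

- The MA/BA consensus is deliberately strict ("any site BA" per
  replicate, unanimity across replicates): under sequencing error a
  single stray read flips a truly silenced site to BA, so with e > 0
  most silenced genes become discordant rather than MA. The error-free
  operating characteristics — P(MA) = 1 for silenced genes, BA genes
  misread as MA at exactly (1 − m)^n for minor share m and depth n —
  are what the tests pin down; the (1 − m)^n identity also quantifies
  how far low expression can hide a second allele.
- aFC orientation is reference/alternate; AI status is
  orientation-invariant, signs are not comparable across sites whose
  reference alleles come from different nucleotypes.
- The per-site chi-squared shift tests use raw p < 0.05 by default
  (Holm available); with hundreds of sites the significant-site count
  includes a predictable false-positive floor, visible in the 1:1
  simulated lines.
- FPKM uses CDS length; comparisons between genes of very different
  UTR content would be biased in real data.
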