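# Methods

`dhewscan` implements a population-genetic screen for recent selective
sweeps and recurrent adaptive protein divergence in per-gene coding-sequence
alignments, using matched genomic control genes to separate locus-specific
selection from the shared effects of demography, chromosomal position and
recombination environment. This note records the models, the numerical
conventions, and the design decisions taken where the construction was
genuinely open.

## Preprocessing

Per-gene in-frame CDS alignments are read from FASTA; outgroup sequences are
carried alongside the in-group haplotypes. When a genome and GFF3 are
supplied, the CDS of the isoform with the longest total CDS is spliced in
transcription order (minus-strand genes reverse-complemented), ties broken
by lexicographically smallest transcript id for determinism.

Missing data are handled in two stages. First, any in-group sequence whose
fraction of missing characters (`N` or gap) exceeds 10% is removed. Second,
any remaining column that still carries missing data in a retained sequence
is excluded from *all* statistics (complete-case columns). This keeps the
per-site sample size constant, which the neutrality statistics assume; the
uniform per-gene n is then enforced by random subsampling of lines (default
149, or 14 in the small-sample species mode), deterministic given a seed.
Gaps are always treated as missing, never as a fifth allele.

## Site-frequency-spectrum and haplotype statistics

For each gene with n haplotypes and S segregating (complete-case) sites:

- pi — mean pairwise differences, summed over sites; at a site with allele
  counts c_k, the contribution is (n² − Σc_k²)/(n(n−1)). Multiallelic
  sites are included.
- θ_w = S / a₁ with a₁ = Σ_{i<n} 1/i. pi and θ_w are reported per gene
  (summed over sites), matching the magnitude a screen of 0.3–3 kb genes
  produces (roughly 1–15 per gene here), not per site.
- Tajima's D = (pi − θ_w)/√(e₁S + e₂S(S−1)) with the standard constants.
  Undefined (NaN, never 0) when S = 0.
- Normalised Fay & Wu H: derived-allele counts come from strict-parsimony
  polarization — a site is polarized only if it is biallelic, every named
  outgroup carries the same unambiguous base, and that base is one of the
  in-group alleles; everything else counts as unpolarized and is excluded
  from H. With ξ_i the polarized counts, θ_L = (n−1)⁻¹ Σ i·ξ_i and
  H = (pi − θ_L)/√Var, where Var is the Zeng et al. (2006) variance with
  θ estimated by θ_w and θ² by S(S−1)/(a₁²+a₂). Negative H marks an excess
  of high-frequency derived alleles. pi, S and θ inside H refer to the
  polarized sites only, keeping numerator and variance consistent.
- Ewens–Watterson homozygosity F = Σ p_i² over haplotype frequencies, with
  haplotypes built over segregating complete-case columns only (invariant
  columns cannot change F).

## Neutral nulls and the DHEW compound test

Null distributions of (D, H, F) are generated per (n, S) cell from the
standard Kingman coalescent without recombination: exchangeable pairwise
coalescence at rate k(k−1)/2, and exactly S mutations placed on branches
with probability proportional to branch length (fixed-S conditioning, the
standard practice for this test family; the root state is ancestral, so
simulated sites are perfectly polarized). Cells are cached and their seeds
derived from (global seed, n, S) so results are independent of gene order.

One-sided Monte-Carlo p-values use a +1 pseudocount: p = (1 + #extreme)/
(reps + 1), lower tail for D and H, upper tail for F. Cell size defaults to
10,000 replicates.

The compound DHEW test is calibrated in two stages. For a p-vector
v = (p_D, p_H, p_F), define its dominance count T(v) = number of null
replicates whose own (leave-one-out) p-vector is component-wise ≤ v. T is
small when the triple is jointly extreme toward the sweep tails. The
compound p-value is the pseudocounted fraction of null replicates whose own
dominance count is ≤ the observed T. The second stage matters: the raw
dominance fraction behaves like a product of uniform p-values and would
reject a nominal 5% test about a quarter of the time; the percentile of T
within its own null is calibrated (measured type-I error ≈ 0.05 at
n = 20, S = 20). The exact combination rule used by the original compound-
test software is not published in reusable form; this construction is the
package's own, chosen for empirical calibration, and ties in the discrete
dominance counts only make it conservative.

## McDonald–Kreitman test and DoS

MK counts are taken codon by codon from an alignment of focal samples, one
or more sister-species sequences and an outgroup. A codon is analyzable
(counted in `MKcodons`) only when all sequences are unambiguous there and
at most one of its three positions varies in any way — within the focal
species, within the sister, or between the species. Codons with two or more
variable/divergent positions are excluded entirely: the mutational pathway
through such codons is ambiguous, and exclusion is deterministic and
conservative. Within analyzable codons:

- a focal-species polymorphism is classified synonymous/non-synonymous
  against the codon context (Pn/Ps);
- a fixed inter-species difference is polarized by strict parsimony: the
  lineage whose allele differs from the outgroup base carries the
  substitution; if the outgroup matches neither allele the substitution is
  left unassigned. Only focal-lineage substitutions enter Dn/Ds.
- polymorphism in the sister species at the same position voids a fixed-
  difference call (fixed means monomorphic in both species);
- variants creating a stop codon are not counted (nonsense changes are not
  comparable to missense for this contrast);
- a triallelic single position is excluded as parsimony-ambiguous.

The test is a two-sided Fisher's exact test on [[Dn, Ds], [Pn, Ps]]
(undefined when either row margin is empty), and
DoS = Dn/(Dn+Ds) − Pn/(Pn+Ps), positive under adaptive divergence.
Benjamini–Hochberg correction is applied per statistic across the focal
gene set.

## The matched-control comparison framework

Controls must lie within ±60 kb of the focal gene's start and have CDS
length within 0.5–2× of the focal CDS; focal genes with fewer than three
qualifying controls are dropped. The comparison score of a statistic is
focal value − median(control values). Group-level departure of the mean
score from 0 is tested with a one-sample t-test and a one-sample Wilcoxon
signed-rank test; the Wilcoxon report includes the Hodges–Lehmann
pseudomedian and its signed-rank confidence interval, computed from Walsh
averages with exact signed-rank quantiles (dynamic programming) up to
n = 300 and a normal approximation beyond. Significance is read as the 95%
CI excluding 0.

Per-gene extremeness uses an orientation-aware convention: for each
statistic the direction that signals selection (most negative for D and H
scores, most positive for DoS) maps to percentile 100. Ranks use
min-ranking so ties share the smaller (less extreme) rank. The permutation
null ("rank against null") lets control genes act as pseudo-focals scored
against the remaining controls of their pairing; the default mode
enumerates every control exactly once (≈3–4 pseudo-scores per pairing,
matching the pooled null sizes such a design produces), with a Monte-Carlo
mode as an option. The true score's percentile within the pooled
pseudo-score distribution is reported.

A gene is called a sweep candidate iff (1) its DHEW compound p < 0.05,
(2) BH-corrected p-values are significant for at least two of D, H and EW,
and (3) at least one of its D, H or DoS comparison scores is in the top
10% of the rank distribution *and* the top 5% of the rank-against-null
distribution. Adaptive divergence is called iff the BH-corrected MK p is
< 0.05 and DoS > 0. Genes missing a required component are reported as
not-callable, distinct from a negative call. All thresholds are
configurable; 0.05 is the default wherever a threshold is needed.

## Synthetic data generator

The generator emulates the data regime the screen targets: per-gene CDS
alignments of 149 haplotypes (or 14 in the second-species mode), 68 focal
genes with 3–4 matched controls on a synthetic chromosome, CDS lengths
0.3–3 kb, one sister sequence and one outgroup, and ~0.1% missing bases.

- **Mutation model.** Genealogies come from the same Kingman sampler as
  the null module. The per-gene mutation supply is θ = θ_site × L with
  θ_site = 0.004 by default (observed per-gene θ_w then spans roughly 1–12,
  the magnitude regime of a *Drosophila*-scale screen); an explicit
  per-gene θ value or range can be supplied instead. Each mutation event
  picks an unhit codon and position and draws its base among the three
  alternatives with purifying weights (synonymous 1, non-synonymous ω = 0.1,
  stop 0). Every event yields exactly one substitution, so E[S] = θ·a₁
  exactly, and the accepted non-synonymous fraction is identical in
  distribution for polymorphism and divergence — which makes E[DoS] = 0
  exact when nothing adaptive is planted. One event per codon (single-hit
  codons) keeps the planted counts identical to what the MK classifier
  recovers.
- **Sweeps** are modeled by forced partial coalescence: a fraction f
  (default 0.9) of lineages merges into one ancestor at time τ = 0.005,
  with standard coalescence above. This parameter-sparse caricature
  produces the full hard-sweep triad (D ≈ −2, strongly negative H,
  F ≈ 0.8 at f = 0.9) without forward simulation.
- **Divergence** places fixed substitutions on the focal and sister
  lineages (θ/2 × divergence time each, default 6 coalescent units) and a
  longer outgroup branch (default 18). Adaptive divergence adds Poisson-
  distributed extra non-synonymous focal-lineage substitutions sized so a
  fraction `alpha_adaptive` of focal non-synonymous fixations is adaptive.
- **Controls** share the focal gene's per-site mutation rate; their
  lengths are drawn log-uniformly within the 0.5–2× matching band (the
  band is symmetric on the log scale, so the ratio's median is exactly 1 —
  a linear-uniform ratio would make controls systematically longer, bias
  EW comparison scores positive and break the null calibration of the
  group test). Control starts are uniform within ±55 kb, so every
  generated pairing passes the validator by construction. Truth tables of
  planted signals are mandatory outputs.

What the generator deliberately omits: intragenic recombination,
demographic history (bottlenecks, expansion, admixture), linked selection,
soft sweeps, alignment error and segmental missingness. Passing tests
therefore show that the statistics, calibration and calling machinery
behave correctly under the idealized neutral/sweep/divergence models — not
that the screen is robust to demographic confounding in real data, which
is precisely why the matched-control design exists.

## Numerical conventions and problem sizes

Undefined statistics are NaN, never 0, and propagate to not-callable calls
rather than being imputed. Monte-Carlo p-values are pseudocounted and can
never be 0. Seeds: a single global seed is expanded with
`numpy.random.SeedSequence` into per-gene and per-(n, S) streams, so
results are independent of iteration order; derived seeds are reduced
below 2³¹.

The test suite runs its simulation-based checks at sizes chosen to give
stable verdicts on a single CPU in minutes: 10,000-replicate nulls with
2,000 neutral trials for calibration; 50 bundle replicates of the
68-pairing study per arm for the pathway-level EW recovery; 1,000 pairings
for permutation calibration; 200 genes for DoS calibration. The
acceptance script's reference quantities are deterministic worked examples
and run in well under a second.

## Known limitations

- The fixed-S null conditions on the observed number of segregating
  sites; genes with S = 0 are uninformative and reported as such.
- The EW and DHEW p-values inherit discreteness from haplotype counts and
  dominance ties; both resolve conservatively.
- The comparison-score group test assumes focal and control statistic
  values are comparable in distribution; statistics that depend strongly
  on CDS length (θ_w, F) make it sensitive to systematic length mismatch
  between focal and control genes, which the 0.5–2× matching band only
  bounds, not removes.
- MK counts ignore codons with multiple hits, slightly undercounting
  divergence in fast-evolving genes; `MKcodons` records the analyzable
  denominator.
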