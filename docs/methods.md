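# Methods

This note documents the models, estimators, numerical choices and defaults
behind `radmut`, and what the synthetic-data tests do and do not establish.

## Orientation and the mutational spectrum

**Orientation rule.** Within a sister pair, a site is polarised by parsimony
from the two species' observed allele sets: exactly one shared allele makes
that allele ancestral and every other allele derived for the species
carrying it. An empty intersection (`discarded_no_shared`) or an
intersection of two or more alleles (`discarded_ambiguous`) discards the
site. The rule uses only the two in-pair species; no outgroup is consulted.
Orientation is symmetric in the two species except for the
derived-by-species labels. Sites covered in only one species are skipped
because the rule needs both allele sets.

**Counting.** For a species' spectrum, `N_anc(i)` counts every oriented
site with ancestral base i — monomorphic shared sites included. This is
deliberate: the correction denominator is the ancestral base frequency over
all analysed sites. Restricting it to polymorphic sites would turn
p(i→j | f(i)anc) into a quantity conditional on polymorphism and destroy
the μ-dependence that the subsequent normalisation removes. When a species
carries several derived alleles at one site, each contributes one mutation
record. A `third` position filter restricts both numerator and denominator
to codon position 3 (1-based within codon, from the alignment reading
frame).

**Spectrum.** p_dir(i→j) = N(i→j)/N_anc(i); p_norm divides p_dir by the sum
of all twelve entries; the six pooled classes sum the two complementary
p_norm entries. Pooling is applied after normalisation — not pooled counts
over pooled ancestral totals — because the two differ under skewed base
composition and only the former matches the normalised-proportion
definition of the spectrum. Degenerate inputs: all-zero directed counts are
an error (the spectrum is undefined), as is a positive count with a zero
ancestral total.

**Pair contrasts.** π per pooled class is log(p_high / p_low), natural log
by default (the base only rescales bar plots); a zero proportion on either
side yields NaN for that class rather than an exception, so one degenerate
class does not abort a report.

## Ordered χ² forward selection

Counts are pooled across the species of each habitat group (not stratified
by pair). Each 2×2 table (habitat × {target class, pooled rest}) gets a
Pearson chi-square with df = 1 and no continuity correction by default; a
Yates flag is available, but with mutation counts in the hundreds to
thousands the uncorrected statistic is the canonical choice. Classes are
ranked by their unordered p-values, ties broken by descending total count
and then class name so output is deterministic. Rank r (2..5) is retested
against the pool of strictly lower-ranked classes; the last class is tested
against rank 5 alone, which is the same 2×2 table as the rank-5 test — the
two last ranks therefore always share a p-value. Degenerate sub-tables
yield NaN with a warning record instead of aborting the sequence.

The Holm adjustment takes an explicit family size k that may exceed the
number of supplied p-values (default 18 = 6 classes × 3 radioactivity
proxies in the spectrum-regression family):
adjusted(r) = min(1, max_{r'≤r} (k − r' + 1) p_(r')).

## Phylogenetic GLS

**Covariance.** Under Brownian motion V[i,j] is the root-to-MRCA path
length and V[i,i] the tip depth. Alternative structures are transforms of
the Brownian matrix: Pagel multiplies off-diagonals by λ ∈ [0,1]; Martins
sets correlation exp(−α·d_ij) with d_ij the patristic distance (variances
preserved), α ≥ 0; Blomberg's ACDC lets the Brownian rate vary as exp(g·t)
in time, so shared-path covariances become (exp(g·V) − 1)/g elementwise,
with g → 0 recovering Brownian motion. Model parameters are fixed by
configuration (robustness-sweep defaults λ = 0.5, α = 1, g = 0.5); they are
not profiled, because a likelihood-ratio test on a fixed-effects term is
only clean when the covariance family is held fixed across the two models.

**Fitting.** Always maximum likelihood, never REML: the likelihood-ratio
tests compare models differing in fixed effects, which is invalid under
REML. The fit whitens y and X with the Cholesky factor of V (solves, no
explicit inverses), solves the least-squares problem, and uses
σ̂² = RSS_w/n and ℓ = −(n/2)log(2πσ̂²) − ½log|V| − n/2. A non-positive-
definite V is an error (Cholesky with no jitter, no silent regularisation),
as is a rank-deficient design. One predictor per model plus an intercept;
joint multi-predictor fits are intentionally not offered because the three
radioactivity proxies are strongly collinear and joint coefficients would
be uninterpretable.

**LRT and pseudo-R².** Λ = 2Δℓ (clamped at 0 against floating-point
negatives), p from the χ² upper tail with df = Δparameters, and
Cox–Snell R² = 1 − exp(−Λ/n). The n is an explicit argument: rate analyses
use the fitted row count; spectrum-proportion analyses use the full
pair-species count (12 in the 6-pair design) even when site-specific
proxies exclude tips — this reporting convention matches how such tables
are printed, where the R² column stays on the common pair-species scale.

**Diagnostics.** Whitened residuals L⁻¹(y − Xβ) feed a Shapiro–Wilk test
and a fitted-vs-residual table; responses are log-transformed when a
Shapiro check rejects normality of the raw response (rule configurable:
auto/always/never). The jackknife refits the regression leaving out one
tip at a time — pruning the tree, merging the resulting degree-2 node with
summed branch lengths while retaining the root, rebuilding V — and flags
changes of slope sign or of significance at 0.05.

## Effective number of codons

Wright's estimator: per amino acid with k synonymous codons observed N ≥ 2
times, F̂ = (N·Σp_c² − 1)/(N − 1); class means over amino acids sharing k;
ENC = (number of 1-fold amino acids) + Σ_k n_k/F̄_k, capped at the code's
sense-codon count (61 for the standard code). Amino acids observed fewer
than twice, and those with F̂ ≤ 0 (possible at tiny N), are skipped from
their class mean; an absent 3-fold class is imputed by Wright's fallback
F̄₃ ≈ (F̄₂ + F̄₄)/2; any other empty class is an error rather than a guess.
Degeneracy classes are derived from the configured NCBI code table, so the
invertebrate mitochondrial code (table 5, with its 8-fold serine family)
is handled by the same formula. ENC is exactly 20 when one codon is used
per amino acid and approaches 61 under uniform usage; it is only
asymptotically invariant to scaling all counts, because F̂ depends on N.
Both per-gene and concatenated modes are provided; concatenated is the
default (per-gene ENC is undefined for very short genes that miss entire
degeneracy classes).

## The synthetic-data generator

The generator emulates the comparative design, not the sequencing pipeline:

- **Tree.** 6 sister pairs (cherries) plus 2 unpaired tips on an
  ultrametric tree of depth 1 (time rescaled to root age). Pair splits are
  drawn in the shallow 5–35% of the depth, deeper joins in 40–100% with the
  root at exactly the full depth. Unpaired tips attach at random join
  times; the real data's unresolved four-species clade is not reproduced,
  since pairs are the unit of the spectrum analysis.
- **Covariates.** One random member of each pair is low-regime, the other
  high-regime; α activity is lognormal around the regime means 0.357 and
  1.259 Bq/g (the observed habitat means; within-regime CV 0.25 is a free
  parameter chosen to keep regimes well separated at a ≥3× contrast).
  Received dose is a noisy power law in α and λ15 a noisy logistic in
  log α — a shared latent factor that makes the three proxies collinear
  (R² > 0.6) while keeping λ15 in [0,1] by construction.
- **Polymorphism.** Per gene and site an ancestral base is drawn from the
  base composition (default mildly AT-rich coding composition
  0.28/0.22/0.22/0.28); each species is independently polymorphic with
  probability θ (default 0.01 per site, a typical transcriptome-level
  diversity) and receives one derived allele: a pooled class is drawn from
  the species' spectrum restricted to the classes compatible with the
  ancestral base, which then fixes the directed mutation deterministically.
  Sites are biallelic per species by construction. The default baseline
  spectrum (0.10, 0.08, 0.32, 0.08, 0.08, 0.34) is transition-biased
  (~2/3 transitions) and strand-group balanced; the C:G→A:T class shifts
  additively by 0.013 per unit log α (the scale of the observed spectrum
  slopes), with the other classes rescaled proportionally.
- **Tip rates.** log(dS/ra) is multivariate normal with mean
  log(rate_root) + β·log α and covariance σ²·V (Brownian motion plus a
  covariate effect). Defaults β = 0.22 nuclear and 0.44 mitochondrial
  reproduce the observed ≈30% nuclear / ≈60% mitochondrial rate increase
  over the ≈3.5× radioactivity contrast; σ² = 0.05 per unit time gives a
  realistic spread of tip rates.
- **Reproducibility.** All randomness derives from one master seed;
  per-gene streams are sub-seeded by (seed, pair, gene index), so changing
  the gene count does not reshuffle earlier genes, and reruns are
  byte-identical.

**An analytic property worth knowing.** Because the pooled class is drawn
conditionally on compatibility with the already-drawn ancestral base, the
expected estimated pooled proportion under uniform base composition is
q_c / (2·S(c)), where S(c) is the generating mass of c's strand group
(C:G-sourced vs A:T-sourced classes). This equals the generating q_c
exactly when the spectrum is strand-group balanced — as the default
baseline is — and the consistency tests use this expectation
(`expected_pooled_spectrum`) as their oracle rather than assuming q_c.

**What the generator does not emulate:** sequencing and SNP-calling error,
selection, biased gene conversion, demography, multi-allelic sites, and
radioactive-decay physics. Passing tests therefore demonstrate correctness
of the inference chain under the assumed sampling model, not robustness to
those real-data complications.

## Problem sizes in the tests and acceptance script

The test suite and `scripts/acceptance.py` run the machinery at sizes
chosen to make Monte-Carlo error small relative to each check's tolerance:
14-tip trees with 1000 replicates for slope recovery and 10000 replicates
for the type-I-error estimate (the ML likelihood-ratio χ² test at n = 14
has exact level 0.0754 at nominal 0.05 — the usual small-sample
anticonservatism — and the larger replicate count makes the Monte-Carlo
error small relative to that margin); 10⁵ sites per species for spectrum
consistency; 500 replicates of 500 mutations per habitat for the ordered-χ²
power check; and a 14-tip, 300-gene end-to-end synthetic run. Statistical
checks are asserted at 3 standard errors; exact identities (Cox–Snell,
whitened-OLS equivalence, hand-computed covariances, ENC limits) at
numerical precision or the printed precision of the reference values.

## Known limitations

- The ordered forward procedure follows its prose description literally,
  including the final m5-vs-m6 step; variants of the original
  forward-selection recipe may differ in detail.
- Whether N_anc should count a site once per species or once per pair is
  not derivable from the method's description; spectra here are computed
  per species independently (each species' derived alleles against the
  shared ancestral totals).
- Correlation-model parameters are fixed, not estimated; the robustness
  sweep is a sensitivity analysis, not model selection.
- Cox–Snell R² depends on the n convention (see above); both policies are
  exposed and the choice is recorded in every report row.
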