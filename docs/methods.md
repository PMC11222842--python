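# Methods

This note documents the models, conventions and design choices behind
`ileotype`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Enterotype model

Enterotypes are treated as a hard partition of samples in genus
relative-abundance space, not as a mixture model: the procedure is
distance-based (root Jensen–Shannon divergence + PAM), mirroring the
canonical enterotyping lineage. Model-based alternatives
(Dirichlet-multinomial mixtures) are deliberately out of scope.

**Distance.** For relative-abundance vectors P, Q the package uses the
metric form sqrt(JSD) with natural logarithms and the 0·ln(0/m) = 0
convention. No pseudocounts are added: the mixture M = (P+Q)/2 is
positive wherever either argument is, so every term is finite. The
matrix routine evaluates JSD(P,Q) = H(M) − (H(P)+H(Q))/2 in vectorised
blocks; entries are bounded by √(ln 2) ≈ 0.8326.

**Clustering.** PAM minimises the total distance of samples to their
cluster medoid. Two regimes, both deterministic:

- *Exact*: when the number of candidate medoid subsets C(n, k) is at
  most 1000, the optimum is found by enumeration (lexicographically
  first subset on cost ties). Greedy BUILD + single-swap SWAP is a local
  search, and on degenerate small configurations it can converge a few
  percent above the optimum with no improving single exchange left;
  enumeration is trivially cheap there, so the exact answer is
  preferred.
- *Heuristic*: otherwise, classic BUILD seeding followed by
  steepest-descent SWAP (the single best improving exchange per
  iteration, strict improvement required, so termination is guaranteed).
  All ties break toward the lowest sample index; assignments to
  equidistant medoids go to the lowest medoid index. A 200-sample
  cohort always uses this path.

**k selection.** Because JSD space has no coordinates, the
Calinski–Harabasz index is computed on squared medoid distances: W is
the sum of squared distances to cluster medoids, B weights each medoid's
squared distance to the overall medoid (the sample minimising total
squared distance) by cluster size, and CH = (B/(k−1))/(W/(n−k)). k is
searched over 2..10 by default; ties break toward smaller k (parsimony).
Degenerate clusterings with W = 0 return +inf. Silhouette widths use
the standard (b−a)/max(a,b) with s = 0 for singleton clusters; values
are reported without any pass/fail cut, since no robustness threshold
is part of the procedure.

**Labelling.** Clusters are renamed 1..k by decreasing size (ties by
medoid index), so "ET1" is always the largest enterotype, and each
cluster is annotated with its *driver genus* — the genus of maximal mean
relative abundance within the cluster.

**Genus filtering.** No low-abundance filter is applied before
clustering by default; `Enterotyper(min_mean_abundance=...)` provides
one for sensitivity analyses.

## Alpha diversity

Computed per sample from raw counts; estimator arithmetic is delegated
to scikit-bio. Conventions: bias-corrected Chao1; ACE with rare-taxon
cutoff 10 and the coefficient-of-variation term floored at zero; Shannon
in bits by default (base switchable); Simpson reported as 1 − Σp²
(probability of interspecific encounter). When every rare taxon is a
singleton the ACE coverage estimate is zero and the estimator is
undefined; the package falls back to bias-corrected Chao1 and records
the affected samples in the result metadata. No rarefaction is performed
— per-sample depths differ and the output metadata flags this — so
between-group richness contrasts inherit depth variation as a caveat.

## Differential abundance (LEfSe-style cascade)

Inputs are total-sum scaled to 10⁶ per sample, making counts and
relative abundances interchangeable. Gates, in order:

1. Kruskal–Wallis across all classes, α = 0.05.
2. Strict all-against-all consistency: the candidate enriched class
   (largest mean) must have the larger mean *and* a pairwise Wilcoxon
   p < α against every other class separately. A one-against-all
   variant (candidate vs all other samples pooled) is available behind
   a flag.
3. Effect size ≥ 4.0 on the log10 scale.

The effect size is defined exactly so results are reproducible: over 30
bootstrap iterations, ⌈2n_c/3⌉ samples per class are drawn without
replacement (indices keyed to the lexicographic order of sample ids, so
sample permutation cannot change the result for a given seed); a linear
discriminant axis w is fitted on the surviving taxa by solving
S_b w = λ S_w w with a ridge of 1e-6·trace(S_w) (raised to 1e-3 if still
singular), scaled to unit pooled within-class variance; the per-taxon
per-iteration effect is ½(Δraw_f + |w_f|·Δproj), where Δraw_f is the
largest class-pair difference of the taxon's class means and Δproj the
largest class-pair difference of projected class means; the score is
log10(1 + mean effect). This is a documented variant in the spirit of
the published LEfSe algorithm, not a byte-level port of any release;
scores for taxa eliminated before stage 3 are reported as 0. No subclass
stratification is implemented (single-factor cohort designs need none).

## Rank statistics and associations

Engines are scipy's, pinned to these conventions: Spearman ρ is the
Pearson correlation of mid-ranks with a two-sided t-approximation
p-value on n−2 df (adequate at cohort scale; the t-approximation is the
documented choice, so small-n p-values are approximate); Kruskal–Wallis
uses the tie-corrected H against χ²(g−1); the Wilcoxon rank-sum test
enumerates exactly when n_a + n_b ≤ 12 without ties and otherwise uses
the tie-corrected normal approximation with 0.5 continuity correction;
trait contrasts use Welch's unequal-variance t-test for every trait ×
enterotype pair, with star tiers (* p < 0.05, ** p < 0.01) and **no**
multiple-testing correction — uncorrected per-pair tests are the
convention this pipeline reproduces — flagged as `corrected=False` in
the output.

Co-abundance networks take the top 15 genera by mean relative abundance
(configurable) and keep undirected edges with |ρ| > 0.6 and p < 0.01.
At n = 200 these joint thresholds make chance edges vanishingly rare,
which the test suite verifies by Monte-Carlo.

## Synthetic cohort generator

The generator emulates the cohort the analysis expects, with known
ground truth. What is matched to the study conditions:

- three components of 76/67/57 samples (200 total);
- dominant-genus means: Streptococcus 0.1740 and Vibrio 0.1220 in
  component 1, Candidatus Arthromitus 0.3339 in component 2,
  Bacteroides 0.3094 in component 3;
- sequencing depth uniform on [21 243, 59 481];
- component 3 is the high-diversity enterotype (30 extra rare genera at
  mean 1e-4 plus the flattest abundance tail);
- no enterotype effect on body weight; an additive leg-muscle-weight
  advantage for component 3; positive Lactococcus couplings to
  leg-muscle weight, dressed weight and eviscerated yield, and a
  positive Bradyrhizobium coupling to eviscerated yield.

Counts follow a Dirichlet-multinomial: sample proportions are
Dirichlet(θ·mean) draws (taxa with zero template mean stay exactly
zero), counts multinomial at the sampled depth. θ defaults to 60 —
separable but realistically noisy communities; θ = 100 yields
well-separated ones. The 30 rare "boost" genera of component 3 enter
the proportion vector as a fixed 1e-4 admixture *outside* the Dirichlet:
with θ·1e-4 as a Dirichlet concentration they would almost never be
observed, whereas the study design requires them to seed nonzero counts
(they produce the singletons/doubletons that raise Chao1).

The non-dominant mass is allocated by a deterministic rule: 45% to the
other named genera with geometric decay 0.55 (order rotated per
component so each community has distinct co-dominants) and 55% to 100
filler genera with geometric tails of ratio 0.85/0.85/0.98 per
component. The ratios were chosen once so the generated cohorts display
the study's qualitative structure — three CH-separable communities at
θ = 60 and the third one richest and most even — and are exposed as
module constants rather than user parameters.

Phenotypes: body weight ~ N(2400, 180²) g shared by all components
(Muscovy females at slaughter age); dressed/eviscerated/muscle weights
are body weight times noisy fractions (0.88, 0.74, 0.11, 0.15 with SDs
0.012/0.012/0.008/0.010); the component-3 leg shift defaults to +30 g
(≈1.4 pooled SD — detectable but not caricatural). Genus-trait
couplings use a Gaussian copula: abundance ranks are mapped to normal
scores and mixed into the fraction noise with loading r = 2·sin(πρ_s/6)
for target Spearman ρ_s (defaults 0.35/0.30/0.25 for Lactococcus and
0.40 for Bradyrhizobium). Realised correlations on *weight* traits are
attenuated because body-weight variance dominates the product; on
percentage traits the target is realised almost exactly. The effect
sizes and trait variances are free parameters of the generator, chosen
once for realism.

All randomness flows from a single integer seed; the count stage,
phenotype stage and copula-pair helper use fixed sub-stream offsets
(10/20/30) of `numpy`'s `default_rng`, so cohorts are bit-reproducible.

**What the generator does not emulate:** taxonomic misclassification,
chimeras and depth-dependent noise of real 16S processing; phylogenetic
correlation among genera; compositional covariance beyond the Dirichlet;
batch or cage effects. Passing recovery tests on these cohorts shows the
pipeline's statistical machinery is correct under the stated model, not
that the biological claims of any particular dataset would replicate.

## Numerical choices and degenerate inputs

- Relative-abundance columns must sum to 1 within 1e-9; all-zero
  samples are rejected by name.
- JSD clamps tiny negative round-off to zero before the square root and
  symmetrises the matrix at 1e-12.
- CH returns +inf when W = 0; silhouette returns 0 when both cohesion
  and separation vanish.
- Carcass percentages: dressed% and eviscerated-yield% over live body
  weight, muscle% over eviscerated weight — the NY/T 823-2004
  denominator convention, fixed here and documented.
- Taxonomic collapse pools taxa lacking the requested rank into a fixed
  `unclassified` bucket and sorts output taxa lexicographically.
- The pipeline writes UTF-8, tab-delimited, LF-terminated files; the
  JSON summary embeds the config hash and seed, and identical configs
  reproduce identical bytes.

## Problem sizes used in validation

The test suite exercises full-size cohorts (200 samples, 144 genera)
for single-run checks, 100-seed batteries for recovery/calibration
claims (enterotype recovery, LEfSe null behaviour, network calibration,
copula coupling recovery), 10,000-replicate null batteries for test
sizes, and exhaustive enumeration oracles at n ≤ 8 for PAM and n ≤ 9
for the rank-sum test. These sizes make every stochastic claim directly
measurable at desk scale.

## Known limitations

- The LEfSe effect size is a stated variant; absolute scores are
  comparable within this package, not across LEfSe implementations
  (gate decisions, being rank-based, transfer better).
- Spearman p-values use the t-approximation even at small n (exact
  permutation is sensible below n ≈ 10 but is not the default).
- No multiple-testing control anywhere in the trait/correlation
  surface, by design fidelity; downstream users should treat isolated
  significant pairs accordingly.
- Alpha diversity on unrarefied counts conflates depth with richness
  when depths differ systematically between groups; the synthetic
  generator draws depths independently of component, so its contrasts
  are clean, but real data may not be.
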