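# Methods

This note documents the statistical model, the defaults and why they
were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open. It
states no result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Junction representation and annotation

A junction is the genomic interval of its intron — first and last
intron base, 1-based inclusive, STAR's convention — with strand coded
0/1/2 (undefined/plus/minus). Counts are uniquely-mapping junction
reads; multi-mappers are excluded as a conservative choice since their
assignment is ambiguous.

The intron index is built from consecutive exon pairs of each GTF
transcript (intron = upstream exon end + 1 … downstream exon start − 1),
de-duplicated across transcripts. Gene assignment is resolved in
priority order: exact intron match, then a shared splice site (donor or
acceptor) with an annotated intron, then containment within a gene's
exon span; strand code 0 is compatible with either strand, and ties go
to the lexicographically smallest gene id purely for determinism —
multi-gene loci have no principled winner at this level of information.
Junctions matching no intron are *novel*; a novel junction sharing one
splice site with a known intron typically indicates an unannotated exon
inside a known gene.

## Differential expression and usage model

Counts are filtered (mean raw count ≥ 10 by default; inclusive
boundary), transformed to logCPM with offsets +0.5 on the count and +1
on the library — small-sample stabilizers that also cancel exactly at
0.5 counts per million. Observation weights follow the mean–variance
trend: the quarter-root residual SD of an unweighted per-junction fit is
smoothed against average log2 count (LOWESS, span 0.5), each
observation's trend prediction at its fitted log-count is interpolated
(constant beyond the trend's range), and the weight is prediction^−4,
i.e. an inverse predicted variance. The trend needs support — at least
10 junctions — or the code directs the user to an unweighted analysis.

Per junction, weighted least squares gives the coefficient of interest
β̂ (test minus control by construction of the two-group design), its
unscaled standard error u, and the residual variance s² on d = n − p
degrees of freedom. Empirical-Bayes moderation estimates the prior
(d₀, s₀²) by the method of moments on log s²: the excess variance of
log s² beyond trigamma(d/2) determines d₀ through the inverse trigamma,
and s₀² comes from the mean equation with the digamma correction. When
the excess variance is non-positive the prior is infinitely
concentrated; the pooled variance is then the geometric mean of the
observed variances, so identical variances shrink to exactly their
common value. Moderated t uses the posterior variance on d₀ + d degrees
of freedom; all tests are two-sided and BH is the only multiplicity
procedure.

**Relative usage.** The relative logFC of junction j is
β̂ⱼ − mⱼ, where mⱼ is the precision-weighted (1/u²) mean of the *other*
junctions of the gene. Leave-one-out is deliberate: including the target
in the average dilutes its own signal, badly so in short genes. Its
standard error is √(uⱼ² + 1/Σ_{k≠j}vₖ), scaled by the posterior SD.
Genes need ≥ 2 fitted junctions; single-junction genes get nulls, not
errors. Gene-level p-values combine a gene's junction p-values by Simes,
which is valid under positive dependence and reduces to the single
p-value for one tested junction.

**Group classification.** Let D = rel − abs logFC. Over the doubly
significant junctions (both effects pass FDR < 0.05 and |logFC| > 1),
σ_D is the *population* SD of D. Doubly significant junctions with
|D| < 2σ_D are Group 1, the rest Group 3; exactly one significant effect
is Group 2; neither is Group 0. D is the natural one-dimensional
reduction of the rel-vs-abs scatter: Group 1 lies on the diagonal,
Group 3 off it. With fewer than three doubly significant junctions the
spread is undefined and they default to Group 1 with a warning.

**Neojunctions** require zero counts in *every* control sample and
detection (count > 0) in at least ⌈0.25 · n_test⌉ test samples; the
prevalence floor keeps single-sample artifacts from being called
condition-specific. "Expressing a junction" means raw count > 0.

## Trait association

Correlations are pairwise-complete with Student-t p-values on
n_used − 2 df; the biweight midcorrelation uses the canonical 9·MAD
scaling with weights (1 − u²)² (raw MAD, no consistency constant — the
9·MAD form absorbs it) and falls back to Pearson with a warning at zero
MAD. Covariate-adjusted associations residualize both expression and
trait on [intercept | covariates] via QR and correlate the residuals;
t = r·√((n − c − 2)/(1 − r²)). BH families are per trait across
junctions, matching the screening use-case. Top associations for radar
display keep traits with FDR < 0.05 and |ρ| > 0.2 for at least one
selected junction, ranked by maximal |ρ|.

## Co-expression networks

Unsigned adjacency |cor|^β (signed: ((1+cor)/2)^β) with unit diagonal;
candidate powers 1–20. The scale-free fit index bins connectivities into
10 equal-width bins and regresses log₁₀ p(k) on log₁₀ mean k, with the
sign flipped for positive slopes so that genuine scale-free decay scores
near +1. Powers whose mean connectivity falls below 1 are reported but
ineligible for selection: a near-empty network's connectivity tail fits
a power law spuriously, and without the guard pure noise "achieves"
scale-free topology at high powers. The chosen power is the smallest
eligible one reaching R² ≥ 0.8, else the best-fitting eligible power,
flagged. Note the tension between the scale-free criterion and module
detection: very high powers drive topological overlap toward zero and
flatten the dendrogram, so for module-detection-centric analyses a
moderate power (the classic unsigned default 6) can be preferable even
when the fit index favours more.

Topological overlap is
TOMᵢⱼ = (Σ_{u≠i,j} aᵢᵤaᵤⱼ + aᵢⱼ)/(min(kᵢ,kⱼ) + 1 − aᵢⱼ), computed by
matrix products with the u = i, j terms subtracted explicitly. Modules
come from average-linkage clustering of 1 − TOM with a static branch cut
at height {0.99, 0.97, 0.95, 0.93, 0.91} for deepSplit 0–4 — a
deliberate approximation of the published hybrid dynamic tree cut, whose
contract here is planted-structure recovery rather than label-identical
output to the reference implementation. Clusters under 20 junctions are
unassigned (label 0); modules whose eigengenes correlate above
1 − 0.25 merge iteratively; labels are renumbered by decreasing size.
Eigengenes are the first right singular vector of the standardized
member matrix, sign-oriented to correlate positively with the mean
member profile; var_explained is the first squared singular value over
the total.

**2-pass filter.** Junction significance (GS, |correlation with the
trait|) is regressed on host-gene significance (host-gene expression =
sum of the gene's junction counts, then logCPM — the simplest proxy
consistent with the input data). Junctions with standardized residual
|z| ≥ 2 carry trait signal not explained by their gene and are kept for
network re-construction. Both tails are kept: a junction significantly
*less* trait-correlated than its gene predicts is also a splicing-driven
signal (e.g. an isoform excluded from the trait-linked pool). Under a
null trait the rule keeps ≈ 2·P(z ≥ 2) ≈ 4.6% by construction. Perfect
collinearity (zero residual SD) is a degenerate-input error.

Sample outliers are pruned by average-linkage clustering on Euclidean
distance, cutting at mean + 2.5 SD of merge heights and keeping the
largest cluster. At least 15 samples per condition are recommended for
any correlation-based analysis.

## The synthetic-data generator

Counts are negative binomial with mean
libsize · gene_cpm · usage / 10⁶ and dispersion 0.05 (a typical
cell-line-scale value); gene baselines are log-normal (median 80 CPM,
log-SD 1), usage proportions Dirichlet (concentration 10), library
sizes uniform on 4–6 million junction reads, and the default cohort is
15 + 15 samples. An optional per-(gene, sample) log-normal factor
(log2 SD 0.5) adds biological co-variation of a gene's junctions; it is
off in the differential-expression scenarios (isolating condition
effects) and on in correlation-based scenarios, which need
within-condition variability to be meaningful.

Spiked events construct each Group class exactly. Usage shifts fix the
target junction's control usage at 0.06 and solve the usage multiplier
from the requested relative logFC at constant gene total — a small
usage share makes absolute and relative logFC nearly coincide, the
Group 1 signature. Gene-DE events scale all junctions ±2 log2.
Combined events pin the gene baseline at 10 CPM and add a +6 log2
gene change on top of a ±2 usage shift, so |rel − abs| ≈ 6 clearly
exceeds the 2σ_D rule when the three doubly-significant classes
contribute in roughly equal numbers. Neojunctions are exon-skipping
junctions with 12% test-condition usage and structurally zero control
counts. Spiked genes are floored at 60 CPM and given ≥ 6 junctions so
events are detectable above the count filter and the leave-one-out
average is stable. Because CPM normalization presumes approximately
balanced composition, the spiked scenario also downregulates 320
background genes (−3 log2) — real cohorts show bidirectional
differential expression, and without this ballast the spiked-in mass
would shift every logFC estimate.

What the generator does **not** emulate: within-condition usage
variability (except in the dedicated 2-pass scenario, where the latent
trait modulates one junction's logit usage and one gene's expression,
and background genes carry small random trait slopes so the GS
regression is anchored across its range); splice-site sequence content;
read-level effects (mapping bias, overhang filters); outlier samples;
batch structure; and correlated dispersion between junctions of a gene.
Passing tests therefore demonstrate the statistics behave correctly
under a clean NB splicing model, not robustness to alignment artifacts
or confounding in real cohorts.

## Numerical choices and degenerate inputs

Inverse trigamma by Newton iteration from the 0.5 + 1/y start;
LOWESS-trend predictions clamped at 10⁻⁴ before the −4 power; weights
must be strictly positive and finite; rank-deficient designs are errors
at construction; zero library sizes, all-zero variances and empty
filter results raise informative errors rather than NaNs. All pipeline
stages are deterministic given their inputs; the only randomness in the
package is the simulator's generator, fully determined by its seed.

## Problem sizes

The bundled scenarios are desk-scale by design: the spiked cohort is
~2,160 genes / ~12,000 junctions × 30 samples, the null cohort ~2,000
junctions, network fixtures are 60–600 junctions × 30–60 samples, and
oracle comparisons use 20–50 features. These sizes give every estimator
enough support (variance trends, σ_D, scale-free bins) while keeping
the whole suite and the acceptance script fast on a single CPU.

## Known limitations

Intron retention is out of scope (it needs intron and exon–intron
boundary counts, which junction files do not carry). The static branch
cut is less adaptive than hybrid dynamic tree cutting on dendrograms
with nested structure. The 2-pass keep rule treats both residual tails
symmetrically; if only excess junction signal is of interest the upper
tail alone would be stricter. Gene assignment for junctions spanning
multiple overlapping genes is heuristic. The scale-free fit index is
unstable below ~50 junctions and the code warns accordingly.
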