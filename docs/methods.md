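# Methods

## Design and data model

The unit of analysis is a paired 2×2 within-subject experiment: for each
of *n* subjects (default 5), pools of typified slow- and fast-twitch
muscle fibers are quantified before (PRE) and after (POST) an
intervention, giving 4*n* samples. Protein quantification is a
MaxQuant-style LFQ matrix (protein groups × samples, linear arbitrary
units); a zero or empty entry means "not quantified" and is normalised to
missing on read. All inference happens on the log2 scale. A protein group
is identified by the first accession of its majority-accession list; for
annotation joins a group carries a term if any member accession does,
because group members share peptide evidence.

## Filtering and fiber exclusivity

A "group" is a (fiber type, timepoint) cell. A protein enters a
comparison when it has at least `min_valid` (default 3) observed values in
at least one of that comparison's groups; an alternative fraction mode
(≥ 50 % observed over all samples) is provided for descriptive dataset
definitions. A protein is *exclusive* to one fiber type when it reaches
`min_valid` in some group of that fiber type and in no group of the
other. Exclusive proteins cannot support a between-fiber comparison of
training responses, so the interaction contrast is restricted to proteins
quantified in both fiber types; exclusive proteins are instead analysed
within their own fiber and reported with their counts.

## Missing values: downshift imputation

LFQ missingness is predominantly abundance-dependent (censoring near the
detection limit), so missing cells are imputed from a narrowed,
left-shifted Gaussian. For target column *j* with observed mean μ_j and
observed SD σ_j (sample SD, n−1 denominator, non-imputed cells only),
each missing cell receives an independent draw from

  Normal(μ_j − d·σ_j, (w·σ_j)²),  d = 1.0, w = 0.3 by default.

Imputation is per sample column by default (each sample has its own
detection behaviour); a whole-matrix (`global`) scope is available
because the convention differs between analysts. The shift d = 1.0
follows the one-SD-downshift convention for this kind of analysis; the
widely used Perseus default is d = 1.8, and both are reachable through
`AnalysisConfig`. Observed cells are never altered; every imputed cell is
flagged and exported in an audit table. Columns needing imputation must
have ≥ 2 observed values, otherwise σ_j is undefined and the run fails
naming the sample. Differential statistics run on the imputed matrix;
percentage-abundance statistics run on raw intensities (imputation exists
for test validity, not for signal description).

## Paired contrasts and the fusion score

Four contrasts are defined as per-subject log2 differences: fiber at
baseline (slow−fast at PRE), training within each fiber (POST−PRE), and
the interaction, the per-subject difference of training responses
(slowPOST−slowPRE)−(fastPOST−fastPRE). Each reduces to a one-sample
t-test on *n* differences: t = d̄/(s_d/√n), df = n−1, two-sided p.
Subjects missing a required sample are dropped with a warning; fewer than
two usable subjects is an error. The log2FC is the arithmetic mean of the
per-subject differences. No empirical-Bayes variance moderation is
applied — the model is the minimal paired linear model.

Proteins are ranked and called by the fold-change/p-value fusion score

  π = |log2FC| · (−log10 p),  s = 10^(−π) = p^|log2FC|,

with the single decision rule s ≤ 0.05. Properties: s ∈ (0, 1]; s = p
exactly when |log2FC| = 1 (returned exactly, not through the power
round-trip); s = 1 when log2FC = 0; s is non-increasing in |log2FC| at
fixed p and non-decreasing in p at fixed |log2FC|; for |log2FC| ≤ 1,
s ≥ p, so the fusion rule never calls a small-fold-change protein that a
plain paired t-test would not. p is clamped below at 1e-300 before the
logarithm and s at 1e-300 after, preserving ordering without infinities.
If all differences are identical the t statistic is undefined; a constant
zero difference is treated as no evidence (p = 1) and a constant nonzero
shift as maximal evidence (p at the clamp).

The score's null operating characteristic matters for interpretation:
with n = 5 and a per-sample noise SD of 0.5 log2 units (paired-difference
SD ≈ 0.71), Monte Carlo gives P(s ≤ 0.05) ≈ 1.1 % under the null —
roughly five-fold stricter than p ≤ 0.05, but not an FDR guarantee. No
additional multiple-testing correction is applied on top of the score;
that is the decision rule this pipeline implements.

## Abundance statistics

Percent protein abundance is 100·I_ij / Σ_k I_kj with missing treated as
zero in sums; per-sample percents total 100 by construction. Category
abundance sums the member percents of an annotation term (categories are
disjointly additive; summing percents rather than raw intensities keeps
the quantity scale-free across samples — the choice where either reading
was possible). Isoform families whose members share most of their
sequence (MYH7/MYH2/MYH1; AMPK subunits) are quantified only from
peptides mapping to exactly one family member; shared peptides are
excluded, and a sample with no unique-peptide signal is undefined rather
than zero.

Category and isoform responses in the 2×2 design are tested with the
classical two-factor repeated-measures decomposition: each main effect
and the interaction is tested against its own effect-by-subject error
term, F with df = (1, n−1). The fiber and exercise main-effect F equal
the squared paired t on collapsed subject means — an identity used as a
cross-check. Tukey's post hoc compares the four cell means with
q = |Δmean|/√(MS_err/n) against the studentized range (k = 4, df = n−1).
The 2×2 within design has no single pooled error term, so each pair uses
the error matching the factors it crosses (fiber-by-subject,
exercise-by-subject, or the pooled within-subject error for diagonal
pairs); an unadjusted companion p from the same statistic (q/√2 as a t)
makes the conservativeness of the adjustment explicit.

## Clustering, enrichment, PCA, QC

Significantly different proteins are z-scored per row across all samples
(population SD; constant rows dropped with a warning), medians are taken
within each of the four groups, and the 4-dimensional profiles are
clustered agglomeratively (Euclidean distance, average linkage, tree cut
at 2 clusters by default — the distance/linkage is a documented default,
not a claim about the original analysis). Term enrichment of clusters or
regulated sets uses the two-sided Fisher exact test against the full
quantified matrix as background (which suppresses noise relative to a
genome-wide universe), labels direction by the odds ratio, and adjusts
with Benjamini–Hochberg within each annotation namespace separately —
terms from different ontologies are not exchangeable hypotheses.
Cluster-level calls use FDR < 0.02; flat GO-BP enrichment of regulated
sets uses FDR ≤ 0.05.

PCA runs on the imputed matrix with per-protein centring and no scaling;
components come from the SVD of the centred samples × proteins matrix and
variance explained is the squared-singular-value share. Reproducibility
is summarised as pairwise Pearson correlation between samples on
pairwise-complete observed (non-imputed) log2 values, with the median
over within-group pairs as the headline number; pairs sharing fewer than
3 proteins are undefined.

## Synthetic experiments

The generator produces data with the statistical structure the analysis
assumes, plus ground truth. Log2 intensity for protein i, subject s,
fiber f, time t:

  x = log2(base_i) + u_s + fiber_i·[f=slow] + train_{i,f}·[t=POST] + ε,

with u_s ~ N(0, 0.3²) shared across a subject's samples (this creates the
pairing) and ε ~ N(0, 0.5²). The paper-scale defaults are 5 subjects and
2200 proteins; the noise magnitudes are not reported anywhere for such
data and 0.5/0.3 log2 units were chosen once as a realistic LFQ
within/between split. The abundance backbone places ten dominant proteins
as a geometric cascade scaled so they carry exactly half of the summed
signal, over a log2-normal tail (mean 20, SD 2 log2 units). Effects
(defaults 300 fiber, 150/110 training, 80 interaction, |log2FC| = 1) are
planted outside the top-10 with random signs; interaction proteins
receive their full training effect in one random fiber, so the planted
interaction equals ±effect exactly and the ground-truth identity
interaction = train_slow − train_fast holds by construction. Missingness
follows a logistic detection model P(observed) = σ(a + b·x), b = 0.8 per
log2 unit, with a calibrated by bisection to hit the 25 % overall target;
this is the MNAR structure the downshift imputation assumes. Annotation
terms (size 40) are assigned with configurable coupling (default 0.5) of
named terms — mitochondrion, metabolic process, sarcomere, muscle
contraction, Secreted — to the matching effect classes. A
myosin-heavy-chain peptide family is generated with pool compositions of
~90 % MYH7 in slow and ~80/20 MYH2/MYH1 in fast samples; per-peptide
response factors are normalised per isoform so that noise-free mixtures
are recovered exactly from unique-peptide sums.

What the generator does *not* emulate: correlated protein modules,
peptide-level quantification noise propagating into protein groups,
sample-to-sample normalisation artefacts, batch effects, or
heavier-than-Gaussian LFQ tails. Tests passing on these simulations
therefore validate the statistical machinery and its calibration under
the assumed model, not robustness to every pathology of real LFQ data.

## Problem sizes and numerics

The test suite and the acceptance script use the study-scale matrix
(2200 × 20) for end-to-end runs, 2000-protein simulations for
calibration and recovery, 10⁴–10⁵ draws for distributional checks, and
exhaustive enumeration up to N = 30 for the Fisher oracle. The recovery
experiment plants |log2FC| = 2 effects and runs without missingness so
that recovery measures the differential method rather than the
missingness process (with 25 % MNAR missingness a fifth of planted
proteins never reach the valid-value filter, bounding sensitivity at
~0.8 for any method; realized sensitivity under those harder conditions
is reported by the pipeline's ground-truth comparison, not asserted).
Ties in sorting are broken by stable mergesort; all written tables use
17-significant-digit floats so read(write(T)) is exact; a single master
seed drives every random draw through numpy Generators, making whole
pipeline runs byte-reproducible.

## Known limitations

- With n = 5 the t-test has df = 4; the fusion score's null rate (~1 %)
  is an empirical property, not a controlled error rate, and the
  false-discovery proportion among calls grows with the null fraction.
- Downshift imputation deliberately biases missing cells low; contrasts
  on proteins with many imputed cells mix real and synthetic variance and
  can show inflated fold changes at modest p (visible in the worked
  example), which the fusion score only partially discounts.
- The RM-ANOVA is the 2×2 special case only; larger factorial layouts are
  out of scope.
- Enrichment treats terms as flat sets; no GO-hierarchy traversal or
  redundancy reduction is attempted.
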