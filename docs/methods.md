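# Methods

`duosig` implements a dual-cohort islet transcriptomics analysis: two
independently collected cohorts — islets isolated enzymatically from organ
donors (OD) and islets captured by laser microdissection from surgical
specimens of phenotyped pancreatectomised patients (PPP) — are analysed in
parallel, and the type 2 diabetes signature is defined as the genes called
differentially expressed *in both cohorts with the same direction*. The
intersection design trades sensitivity for robustness: any effect driven by
the isolation procedure, tissue source or collection centre is unlikely to
replicate across both cohorts.

## Quality control

Two sample-exclusion rules run before anything else. Samples without a
diabetes history (ND, IGT) are dropped when blood fructosamine exceeds
285 μmol/l or glucose exceeds 11.1 mmol/l — metabolic evidence of
undiagnosed dysglycaemia that would contaminate the non-diabetic reference.
Samples whose insulin-secretion measure falls below the within-(cohort,
group) mean minus one sample SD are dropped as low secretors; the rule is
read as one-sided (low side) because its purpose is to remove functionally
compromised preparations. Samples missing a field are skipped for that rule
with a logged warning, never silently excluded.

The expression filter then keeps a gene iff, in at least one diagnostic
group, its intensity strictly exceeds τ — the pooled 75th-percentile
intensity of the cohort — in at least 25% of that group's samples. The
">75%" criterion is ambiguous between a distribution percentile and a
fraction of scanner range; the percentile reading is implemented, and τ is
an explicit argument of `filter_expressed`, so the other reading is a
one-line change. Note a structural consequence: because τ is the pooled
upper quartile, roughly the top quarter of genes by baseline survive —
the filter defines an *expressed universe*, not a light trim. That universe
(the union across cohorts) is the background N for every downstream
hypergeometric test.

PCA diagnostics run on centred, unscaled log2 values with samples as
observations (the intensities share a scale, so variable scaling would only
inflate noise genes).

## Batch adjustment

Location–scale empirical-Bayes adjustment in the parametric flavour: per
gene, data are standardized against a batch-free model (batch-proportion-
weighted grand mean plus protected covariates — the diagnostic group enters
the design so disease signal cannot be absorbed into batch terms); per-
(gene, batch) locations γ̂ and scales δ̂² are shrunk across genes toward
normal / inverse-gamma priors whose hyperparameters come from method of
moments; the shrunken pair solves the standard fixed point, iterated to a
maximum absolute change below 1e-4 (cap 100 iterations). A single batch is
an exact identity. Degenerate moment estimates (zero across-gene variance
of δ̂²) disable scale shrinkage rather than dividing by zero. The
implementation is verified in the test suite against the R reference
implementation of the same procedure (sva's parametric ComBat) to 1e-8.

## Differential expression

Per-gene two-group OLS on log2 values gives the effect β̂ (log2 mean
difference, test − reference), residual variance s² and df d = n₁+n₂−2.
The variance prior (d₀, s₀²) is moment-matched on e = log s² − ψ(d/2) +
log(d/2), with d₀ recovered by Newton inversion of the trigamma function
(tolerance 1e-8) and d₀ = ∞ when the excess variance of e is non-positive
(all genes then share s₀², and the reference distribution is normal).
Posterior variances s̃² = (d₀s₀² + d s²)/(d₀ + d) feed the moderated
t = β̂/(s̃√(1/n₁+1/n₂)) on d₀+d df. The suite checks the d₀ = 0 limit
(classical pooled t, < 1e-10), parameter recovery from scaled inverse-χ²
simulations (within 25% relative), and exact agreement with R limma's
`eBayes` on shared matrices.

Multiplicity is controlled by Benjamini–Hochberg (via statsmodels, cross-
checked against a literal step-up evaluation). A gene is called when
q ≤ 0.05 and max(r, 1/r) ≥ 1.5, where r = 2^β̂ is the linear-scale ratio of
geometric group means; the TF-focused call relaxes the ratio cut-off to
1.2. Directions are down for r < 1, up otherwise. When probe-level data are
supplied, `collapse_probes` keeps the smallest-q probe per gene; the
simulated data are already gene-level.

## Cross-cohort signature

Genes called in both cohorts form the overlap; a gene is concordant iff
sign(r_OD − 1) = sign(r_PPP − 1). The chance of an overlap at least as
large as observed is the inclusive upper-tail hypergeometric probability
P(X ≥ k) for k shared genes between lists of sizes K and n over the
expressed universe N (inclusive upper tail — the standard over-
representation convention; the suite checks it against exhaustive
enumeration for every parameter tuple with N ≤ 30). The packaged worked
example reruns the classification on the published 23-gene dual-cohort
table: 19 concordant (15 down, 4 up), 4 discordant, minimum OD ratio 0.273,
and overlap probability 9.2e-12 for (k=23, K=444, n=136, N=15,165).

The condition profile tabulates the concordant genes' ratios for the
IGT / T3cD / T2D contrasts against the shared ND reference and counts genes
beyond a reporting fold change (default 1.2). Genes absent from a contrast
are reported missing, never imputed.

## Co-expression modules

Standard weighted-network construction on the non-diabetic samples of each
cohort: unsigned adjacency a = |cor|^β with β = 6 by default (an optional
chooser picks the smallest β whose connectivity distribution fits a
scale-free law with R² ≥ 0.8), topological overlap
ω_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij), average-linkage
clustering of 1 − ω, static cut. The default cut height is 0.9: for a
planted block with within-module correlation 0.8 at β = 6, within-module
TOM dissimilarity is ≈ 0.74 while between-module dissimilarity is ≈ 1.0, so
any cut in (0.8, 0.99) separates blocks — 0.9 sits in the middle of that
window. (Cut heights far below ~0.75 leave every gene a singleton at these
correlations; they would only suit near-duplicate probes.) Clusters below
20 genes are unassigned. Module labels are ordered by size, making the
partition deterministic and permutation-invariant up to renaming.

Eigengenes are the first right singular vector of the standardized module
expression, unit variance, sign-oriented so mean own-module kME ≥ 0; kME is
each gene's Pearson correlation with each eigengene; hubs are the top 10
own-module genes by |kME| (the hub count is a convention, exposed in
config). Cross-cohort module preservation is a hypergeometric overlap per
module pair with BH across pairs; trait networks and the TF sequence
channel use only preserved modules (q ≤ 0.05), mirroring the dual-cohort
logic of the signature. Module–trait association is a Pearson correlation
of eigengene vs trait with the exact t reference on n−2 df; |r| = 1 and
constant traits are flagged rather than silently propagated.

## Upstream regulators

The literature channel scores a regulator's signed causal edges (activation
+1 / repression −1, user-supplied TSV standing in for any curated causal
knowledge base) against the observed DE directions with the unweighted
sign-consistency statistic z = Σ s_e·d_t/√n over the regulator's DE-called
targets. Restricting to called targets is deliberate — the direction of a
non-significant gene is noise; an all-measured-targets mode exists for
sensitivity analyses. |z| ≥ 2 is the conventional significance line, and a
hypergeometric overlap p (targets ∩ called vs the universe) guards against
trivially small regulons; a regulator must pass both gates to contribute
edges. Under random directions z is a scaled symmetric binomial, so the
|z| ≥ 2 rate is the exact binomial tail — about 2.1% at n = 10 and
approaching the nominal 4.6% only for large regulons (4.64% at n = 1000);
the calibration tests compare against the exact tail, not the asymptote.

The sequence channel consumes motif-target annotations (by convention,
predicted binding sites within TSS ± 5 kb, supplied as GMT — motif scanning
itself is out of scope) and tests each regulator's target set for over-
representation in each preserved module; enriched regulators (BH q ≤ 0.05)
contribute edges to their targets inside the module. The intersection
network keeps exactly the (tf, target) edges present in both channels —
a set intersection, tested as such (commutative, associative, idempotent) —
and carries per-TF scores from both parents. The exported tables are
unfiltered; display-only filters (e.g. dropping single-edge non-TF nodes
for hive plots) are the consumer's choice, supported by the exported
degree/axis table.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical* structure the pipeline assumes,
at the published group sizes (OD 84/19; PPP 32/36/15/20): per-gene Gaussian
baselines (background N(7, 1.5), planted signal genes uniform in 10.5–12
log2 units — signature genes must be expressed genes, or the expression
filter would remove the truth being tested); four 100-gene one-factor
modules with loading 0.3 against residual sd 0.15 (within-module
correlation 0.8, the same operating point as the planted-block example);
concordant (30), OD-only (40) and PPP-only (30) effects drawn uniformly
from ±[log2 1.5, log2 3]; IGT and T3cD samples receiving 0.25× and 0.6× the
concordant T2D effect (cohort-specific effects stay T2D-only); per-
(gene, batch) shifts at sd 0.3 over two batches per cohort; two traits
driven linearly by module factors (slopes ±1, noise sd 0.5); twenty
25-gene regulons, three of them active with module-resident, direction-
coherent targets, observed through a motif channel with 10% false
positives/negatives (spurious count ~ Binomial(regulon size, rate)) and a
signed literature channel with 5% sign flips; and injected QC violations
(5% of eligible samples per rule) flagged in the truth table. Insulin
secretion exists only for OD samples; PPP carries missing values, which
exercises the rule-skipping path.

One root seed is split into independent per-cohort/per-channel streams
(`numpy.random.SeedSequence.spawn`), so regenerating one cohort never
perturbs the other and identical (config, seed) pairs are bit-identical.

What passing tests do **not** show about real data: effects here are
Gaussian shifts on independent genes (no heavy tails, no correlated
technical artefacts beyond the planted batch term), the trait model is
linear in a single factor (the joint distribution of clinical traits and
islet expression is not characterised by any published source — this is an
assumption, recorded as such), regulons are disjoint within modules, and
fold-change magnitudes start exactly at the calling threshold, which makes
recall intrinsically imperfect at the boundary. Recovery numbers on this
generator are upper bounds on what the same pipeline could do on arrays.

## Numerical choices and degenerate inputs

- Hypergeometric tails via the log-space-stable scipy survival function;
  k = 0 returns exactly 1.
- Trigamma inversion by Newton with the standard asymptotic fallbacks
  (1/√y above 1e7, 1/y below 1e-6).
- Zero-variance genes: excluded from the variance-prior fit; with an
  unshrunk posterior (d₀ = 0) they yield ±∞ t, p = 0 and a flag. The
  co-expression builder rejects them outright (no correlation is defined).
- Batch adjustment aborts on confounded designs (rank test) and singleton
  batches; convergence is absolute-change < 1e-4, cap 100 iterations.
- Module detection ties are broken by first-member position after sorting
  by size; `detect_modules` on fewer genes than min_size returns all
  unassigned.
- All statistical tables are written at %.6g; expression matrices at %.12g
  (round-trips preserve 12 significant digits).

## Problem sizes

The default synthetic study uses 2,000 genes × 206 samples; a full pipeline
run takes well under a second, the whole test suite under half a minute,
and `scripts/acceptance.py` about ten seconds. These sizes were chosen so
that every planted structure is comfortably identifiable while the entire
analysis remains instant to re-run; nothing in the method depends on them.

## Known limitations

- Only the parametric variant of the batch adjustment is implemented (no
  non-parametric priors, no reference-batch mode, no surrogate variables).
- Two-group contrasts only; no covariate-adjusted DE.
- Static tree cut only; dynamic tree cutting and eigengene-similarity
  module merging are out of scope, so the module count on real data will
  differ from tools that use them.
- The activation score is the unweighted sign-consistency statistic;
  curated edge weights or confidence tiers are not modelled.
- The pipeline consumes normalised log2 matrices; array preprocessing
  (RMA, CEL parsing) and sequencing-based DE are out of scope.
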