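# Methods

`traitnet` reconstructs co-regulation structure among metabolite and enzyme
traits measured on a replicated inbred panel. The analysis proceeds in five
stages: (1) normalization of raw observations, (2) completion of missing
cells, (3) reduction of replicates to per-line genetic values (BLUPs) with
variance-component profiling, (4) construction of a thresholded Spearman
correlation network, and (5) community and node-level inference on that
network. A synthetic-data generator with fully known ground truth backs
every stage's tests.

## Preprocessing

**Metabolite normalization.** Raw metabolite intensities from a
chromatography run drift with instrument response. Each value is divided by
the internal-standard (ribitol-type control) intensity recorded for the
same chromatogram, i.e. the same line × replicate sample. A missing or
non-positive control is a hard error naming the offending samples.

**Enzyme standardization.** Enzyme activities are assayed in plates with
plate-level offsets. Step 1 standardizes each value by the mean of all
enzyme measurements on its plate; step 2 subtracts, per enzyme, the overall
mean of the standardized values, leaving each enzyme centred at zero.
Whether step 1 divides or subtracts the plate mean is configurable
(`plate_method="divide"` default, `"subtract"` available); division is the
default because it makes step 2's "difference from the overall mean"
meaningful on a ratio scale. A consequence of the centring is that
coefficients of variation for enzymes sit on a near-zero mean and are not
comparable with metabolite CVs; CV ordering is informative within the
metabolite class.

**Missing-value imputation.** Missing cells (the generator's default
emulates 5.7% completely-at-random missingness) are completed by an
EM-style low-rank PCA reconstruction: missing cells start at column means,
then each sweep re-centres the matrix, takes the truncated SVD at rank
`n_components` (default 3), and overwrites only the missing cells with the
reconstruction, until the relative change of the imputed cells falls below
1e-6 (at most 500 sweeps; non-convergence warns and returns the best
iterate). Observed cells are returned bit-identical. Rank 3 is a
deliberately conservative choice for a 56-feature panel whose correlation
is dominated by a few co-regulation blocks; it recovers a rank-1 matrix
with one deleted cell to machine precision and, on correlated synthetic
panels, beats column-mean imputation. No imputer can beat the residual
noise floor: the expected squared error of any prediction is at least the
within-line residual variance, because replicate noise is independent of
everything the imputer can condition on.

**Variance components and heritability.** Each feature is modelled with
the one-way random-effects model y_ij = μ + g_i + e_ij (line effect g_i,
residual e_ij), fitted by REML. Balanced complete designs use the
closed-form estimator (REML coincides with the ANOVA expected-mean-squares
solution there); unbalanced designs go through `statsmodels`' MixedLM.
Negative component estimates are clipped at zero, so broad-sense
heritability H² = σ²_g/(σ²_g+σ²_e) stays in [0, 1] and a feature whose
replicates are identical within every line reports H² = 1 exactly.
Constant features are flagged degenerate and their H² reported as missing,
not zero. H² here is per-observation ("plot basis"); an entry-mean basis
would divide σ²_e by the replicate count and is intentionally not the
default, since the per-observation ratio is what the generator plants.
H² values are binned into ten 0.1-wide intervals (the top bin closed at
1.0) for the heritability histogram.

**BLUPs.** The per-line value carried into all network computation is the
best linear unbiased prediction of the line effect:
BLUP_i = [σ²_g/(σ²_g + σ²_e/n_i)] · (ȳ_i − μ̂), with n_i the line's
replicate count and μ̂ the unweighted mean of line means. Shrinkage is
therefore exact for balanced designs and per-line for unbalanced ones;
σ²_g = 0 yields all-zero BLUPs, and |BLUP| never exceeds the raw line-mean
deviation. CVs are computed on BLUP + grand mean (the measurement scale),
because BLUP deviations are centred at zero and sd/mean would otherwise be
undefined.

## Network construction

All feature pairs are correlated with Spearman's rank correlation
(average ranks for ties; two-sided p from the t approximation with n − 2
degrees of freedom — adequate at ~100 lines and far cheaper than exact
permutation). Two thresholds gate an edge:

- **p-cutoff** — the Benjamini–Hochberg step-up cutoff at target FDR
  q = 0.05 over the m upper-triangle p-values: the largest sorted p_(i)
  with p_(i) ≤ (i/m)·q (0 if none).
- **r-cutoff** — chosen by a stability scan: for each candidate r (default
  grid 0.10–0.60 in steps of 0.05), networks are built at every p in
  {0.01, …, 0.05} and four global properties computed (average degree 2E/N,
  mean local clustering with degree-<2 nodes contributing 0, density,
  diameter of the largest connected component). A candidate is stable when
  the relative range of the first three across the p-grid is ≤ 1% and the
  diameter's absolute range is ≤ 0 (diameter is integer, so "did not
  change" is taken literally). The smallest stable candidate wins. The
  grid granularity and the 1% tolerance are explicit package choices; the
  scan table is persisted so any other reading can be applied post hoc.

An edge is kept iff |ρ| ≥ r-cutoff **and** p ≤ p-cutoff; the absolute
value matters because anti-correlated traits are biologically informative
and carried as negatively signed edges. Isolated features leave the node
set. Edge count is monotone in both cutoffs by construction.

## Community analysis

Communities come from the Pons–Latapy walktrap algorithm on the
**unweighted** graph (t = 4 random-walk steps, dendrogram cut at maximum
modularity — the original authors' defaults), via python-igraph with
deterministic node ordering.

Each community with **more than four nodes** is tested for structural
salience with a paired degree comparison: for every member, the degree
inside the isolated community subgraph (internal) is paired with the
degree the member retains in the full network once all community-internal
edges are deleted (residual); internal + residual equals the full degree,
always. A one-sided Wilcoxon signed-rank test (internal > residual;
zero differences dropped; exact null for ≤ 25 informative pairs, normal
approximation with continuity correction above) yields the community
p-value. The test is one-sided because the question — is this subgraph
denser than its embedding? — is directional. Smaller communities return a
"not tested" marker, never a p-value.

Non-significant (p > α = 0.05) or untestable communities are merged, one
at a time, into the significant community with which they share the most
edges (ties broken toward the larger community, then the lowest id), and
significance is recomputed after every merge. A non-significant community
with no edge to any significant one is left standalone and flagged. The
loop terminates because every merge strictly decreases the community
count.

## Node statistics and edge validation

**Betweenness** is Freeman's unnormalized fractional count over unordered
pairs: node v scores Σ σ_st(v)/σ_st, so values are fractional (a node on
one of four tied geodesics earns 0.25) and scale with network size.

**Permutation significance.** The default null ("profiles" mode) permutes
every feature's BLUP vector across lines independently in each of n_iter
iterations (default 10,000), destroying all inter-feature association
while preserving every marginal distribution, rebuilds the network with
the *same fixed* cutoffs, and records each node's degree and betweenness
(zero if the node drops out). p = (1 + #{permuted ≥ observed})/(1 + n_iter),
so p ∈ (0, 1], the smallest attainable value is 1/(1+n_iter), and an
observed statistic of zero gives p = 1. Because degree and betweenness are
discrete, these p-values are conservative (super-uniform) under the null;
a `tie_randomized` variant breaks observed/permuted ties uniformly at
random, which is exactly uniform under exchangeability and is what the
calibration checks use. A degree-preserving edge-rewiring null ("rewire"
mode) is available as a structural alternative; it preserves degrees, so
only betweenness p-values are informative there.

**Edge validation.** Every retained edge is re-examined with the Pearson
correlation of the same BLUP vectors: r measures linear dependency and
r² the shared variance. Edges are binned with lower-closed boundaries
(|r| ≤ 0.4, 0.4 < |r| ≤ 0.6, |r| > 0.6; r² ≤ 20%, 20% < r² ≤ 40%,
r² > 40%); bins always sum to the edge count, and an edge with a constant
endpoint is flagged rather than binned.

## Synthetic-data generator

The generator emulates the target study design: 101 lines × 5 replicates,
43 metabolites + 13 enzymes, 5.7% missing cells. Per line, a latent
genetic vector is drawn from a multivariate normal whose correlation
matrix is block-diagonal: features inside a planted block share a common
latent correlation (the ground-truth communities); the matrix is checked
for positive semi-definiteness and factored by eigendecomposition.
Replicates add independent normal residuals scaled so that
σ²_g/(σ²_g+σ²_e) equals each feature's target H² (total phenotypic
variance 1 around a baseline trait level of 10, keeping CVs positive and
finite). Metabolite observations are multiplied by a per-chromatogram
internal-standard intensity (lognormal, mean 1000, CV 0.2 — lognormal so
division is always defined), which downstream normalization must divide
out; enzyme observations receive an additive plate offset (N(0, 0.5²),
drawn once per plate, plates assigned round-robin over samples), which
makes plate standardization consequential. Missingness is completely at
random — the emulated study reports only a missing percentage, no
mechanism, so MCAR is an explicit assumption. Identical configs (including
the seed) are bit-reproducible.

The study-scale default (`study_scale_config`) plants three blocks — a
mixed enzyme/metabolite block (ρ = 0.60), an amino-acid-like block
(ρ = 0.55) and an organic-acid/sugar-like block (ρ = 0.50) — and draws
per-feature H² once from Beta(1.4, 2.6) floored at 0.15: positively
skewed with most features below 0.5, matching the heritability profile of
leaf central metabolism in inbred panels, while the floor keeps line-level
signal detectable at five replicates.

What the generator does **not** emulate: chromatogram-level artifacts
(retention drift, co-elution), non-normal trait distributions, structured
(feature- or sample-biased) missingness, genetic relatedness among lines,
or enzyme kinetics. Tests passing on this generator therefore demonstrate
correctness of the estimators and calibration of the inference under a
clean additive world, not robustness to those real-data complications —
the Spearman machinery downstream deliberately does not rely on the
generator's normality.

## Numerical choices and degenerate inputs

- Deterministic tie-breaking throughout (lexicographic node ids; sorted
  vertex order into igraph) so identical seeds give byte-identical output.
- Spearman requires ≥ 5 lines and ≥ 2 non-constant features; constant
  features are excluded with a warning before correlation and flagged
  degenerate in variance-component fitting.
- BH cutoff of an all-null list is 0, which the pipeline treats as "no
  significant edges" and aborts network construction with a clear error.
- Graph statistics: empty graphs report missing properties; the diameter
  of a single-node component is 0.
- TSV artifacts are written at 17 significant digits and read with
  round-trip float parsing, so a report regenerated from persisted
  intermediates is bit-identical.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on generated data:
the full pipeline at study scale (101 × 5, 56 features), heritability
recovery at 100 lines × 5 replicates × 50 features over 10 seeds,
community recovery on 30-node two-block graphs over 50 seeds, null-panel
error control over 20 seeds, and permutation calibration at 1,000
iterations (the pipeline default remains 10,000). Exhaustive oracles cover
all 1,252 non-isomorphic graphs on ≤ 7 nodes for betweenness.

## Known limitations

- The REML fit assumes a single random line effect; replicate-level batch
  structure (beyond enzyme plates) is not modelled.
- The stability criterion for the r-cutoff depends on its tolerance and
  candidate grid; both are exposed, and the persisted scan table makes any
  alternative choice auditable.
- The community-significance test conditions on the detected partition;
  its p-values are calibrated for a fixed node set, not corrected for the
  selection performed by walktrap itself.
- Permutation p-values with the add-one rule are conservative for discrete
  statistics; use `tie_randomized=True` for calibration work.
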