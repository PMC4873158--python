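# Methods

This note documents the statistical procedures implemented in
`pathconcord`, the synthetic data model used to validate them, the
parameters that matter, and the design choices made where the analysis was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Analysis chain

### Ingestion and normalization

Expression matrices are read features × samples from TSV or from the table
fenced by `!series_matrix_table_begin/end` in GEO series-matrix text files
(offline only; sample annotations always come from a sidecar TSV with
`sample_id` and either `group` ∈ {case, control} or `subject`/`timepoint`
∈ {early, late}). Features with any missing value are dropped and counted —
imputation is deliberately avoided as the simplest defensible rule. If the
matrix maximum exceeds 30 the data are assumed to be raw intensities and
are log2(x+1)-transformed (public matrices arrive in mixed scales; the
threshold is far above any plausible log-scale value and far below any
plausible raw scale).

Quantile normalization replaces each column's rank-r value with the
across-column mean of the rank-r order statistics. Ranks are assigned with
a stable sort, so ties keep their original order and the transform is
exactly idempotent — a property the tests check bitwise.

Probe collapsing keeps, per gene symbol, the probe with the smallest
differential-expression p-value computed on the uncollapsed matrix; ties
break by larger |t|, then lexicographic probe id (a total order, so the
result is unique and reproducible). Probes without a symbol mapping are
dropped and logged.

### Differential expression

Unpaired designs use the Welch (unequal-variance) t per gene, oriented
case − control, with Satterthwaite degrees of freedom. The pooled-variance
t would be nearly identical at these sample sizes; Welch is the safer
default. Paired designs use the one-sample t on within-subject
late − early differences. Genes with no variance anywhere (possible after
quantile normalization of degenerate inputs) are reported with t = 0,
p = 1 and logged rather than dropped, keeping the gene universe stable for
downstream joins. The α for counting differentially expressed genes
defaults to 0.05.

### Permutation enrichment

The observed statistic per gene set is k = #{mapped members with p < α}.
The default null (`label_permutation`) permutes the case/control labels —
or sign-flips each subject's difference vector in paired designs, the
exact exchangeability unit for paired data — and recomputes every per-gene
test each round, which preserves the gene–gene correlation structure that
makes naive binomial counts anti-conservative. One shared permutation per
round serves all sets, keeping the joint structure of overlapping sets.
`gene_sampling` (drawing m genes at random from the mapped universe per
round) is available as a competitive alternative. The permutation p-value
uses +1 smoothing, `(1 + #{k_null ≥ k_obs})/(B + 1)`, so it can never be
zero; values at the floor are displayed explicitly as `< 1/(B+1)`.
Default B = 1000; a seed is required. No multiple-testing correction is
applied across sets (the motivating analysis has three).

Proportions are displayed as `"k/m (pct%)"` with half-up rounding of the
percentage, and both the nominal set size (GMT) and the mapped size m
(intersection with the study's features) are always reported, because the
two differ per platform.

### Cross-study concordance

Concordance is the Pearson correlation of per-gene t statistics between two
studies, within each gene set, over the genes mapped in both studies
(n_common always reported). t statistics — not fold changes — are
correlated because they pool effect size with precision. The p-value uses
the exact t transform of r with df = n − 2, not a permutation; Spearman is
available as a sensitivity flag. Per-set min–max ranges across the study
pairs are formatted to two decimals.

### Co-expression networks

Unsigned adjacency `a_ij = |cor|^β` (signed variant `((1+cor)/2)^β` behind
a flag) and the standard min-denominator topological overlap:

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(K_i, K_j) + 1 − a_ij)

with `K_i = Σ_{u≠i} a_iu`, diagonal stored as 1 and excluded from the
connectivity `k_i = Σ_{j≠i} TOM_ij`. For unsigned adjacency TOM is provably
in [0, 1]; the implementation is verified element-wise (1e-10) against an
independent brute-force triple loop on random instances.

The network is restricted to the union of the pathway genes present in the
study: the scientific question is the immune-pathway subnetwork, and
whole-transcriptome module detection (dendrogram cutting, eigengenes) is
out of scope. "Modules" are reported as connected components of the called
edge set.

Soft power selection: for each candidate β the adjacency connectivities are
binned (10 equal-width bins) and log10 frequency is regressed on log10 mean
bin connectivity; a scale-free network shows a linear decay. The chosen β
is the smallest candidate with fit R² ≥ 0.8, with two guards motivated by
the behavior of pure-noise data: (1) a candidate is only eligible while the
mean connectivity stays ≥ 1 — once the network has collapsed (k → 0 for
almost all genes) the log-log histogram of near-zero values turns
spuriously linear, and noise data would otherwise "pass" at high powers;
(2) eligibility also requires a negative slope. If no eligible candidate
reaches 0.8, the argmax-R² eligible candidate is used when its fit is at
least 0.5; below that the fit is indistinguishable from noise and the
conventional default β = 6 is used with a warning.

Edge calling: the top-quantile rule ranks the P off-diagonal TOM values and
keeps the top `round(top_q·P)` pairs, keeping all pairs tied at the cutoff
(the realized percentage is logged). The FDR rule builds a null by B rounds
of independently permuting each gene's sample order (destroying all
gene–gene correlation while preserving marginals; a circular-shift variant
is available), pools the null TOM values across all pairs to push the
empirical-p floor down to `1/(B·P + 1)` (per-pair resolution alone could
never reach q < 0.001), and applies Benjamini–Hochberg. The combined rule —
the default pipeline behavior — intersects the top 3% with q < 0.001.

A practical consequence the default simulation exposes: at 18 pairs
(36 arrays) the permutation null of |cor|^β is heavy-tailed enough that no
pair reaches q < 0.001 after multiplicity, so the combined rule yields an
empty edge set for the paired cohort while the two larger cohorts retain
their full top-3%. This is honest behavior of the chosen null at that
sample size, not an implementation artifact; the top-quantile rule alone
still ranks the paired cohort's edges.

The hub report is the per-gene table (k, −log10 p, DE class
up-/down-/not-significant at α) sorted by k, and the headline statistic is
the Pearson correlation between k and −log10 p.

### Regulator analysis

Pearson correlation (same kernel as the concordance module, shared code
path) between the regulator transcript and every pathway gene, computed
across all samples pooled — restricting to one arm is available behind a
`group` flag for sensitivity analysis, since the motivating analysis does
not state the restriction. Genes are ranked by |r| with sign reported, and
per-set summaries give mean r and the fraction of positive correlations.
The regulator's own DE row is reported with a decreased/increased label.

## Synthetic data model

Per study and sample, gene g is

    x_g = μ_g + σ·( Σ_s l_{g,s} F_s + σ_g ε_g ) + σ·shift_g·1[case/late]

with standard-normal factors F_s (one per gene set, drawn per sample) and
noise; l_{g,s} = √ρ_hub for the set's hub genes (the first n_hubs members),
√ρ_nonhub for other members; σ_g balances total variance to σ² (summed
squared loadings are capped at 0.95 for overlapping sets). Planted shifts
are drawn **once per design** — shared by every study, so concordance is
planted — as `δ_g = max(0, Normal(δ, (0.6·δ)²))` per member, signed by the
set's direction. The dispersion matters: with a constant per-set shift the
between-gene variance of the true effect would be zero and cross-study
concordance of t statistics would vanish; 0.6 gives attenuation-predicted
r around 0.6–0.7 at the default sizes (`r ≈ var(ncp)/(var(ncp)+1)`).
Setting `effect_dispersion = 0` recovers an exact constant shift.
Hub members can carry a multiple of the set's mean effect
(`hub_effect_multiplier`, default 1); the default three-cohort design uses
2, reflecting the motivating observation that network hubs (CD81, the
TCR-CD3ζ complex) were among the most differentially expressed genes —
this is what produces the connectivity-versus-significance association in
the emulation. `effect_scope = "hubs"` confines effects to hubs entirely.

Paired studies add a per-subject intercept b_j ~ N(0, σ) to both of a
subject's samples: within-subject differences cancel it (so paired tests
gain power), while cross-sample correlation keeps the co-expression
analysis honest about shared-sample structure. The regulator gene is
`Σ_s c_s F_s + √(1 − Σc²) ε` (unit variance), giving
corr(regulator, gene in s) = c_s·√ρ_g with the chosen sign, plus its own
planted shift.

Determinism: one integer seed; per-study substreams derive from
(seed, CRC32(study name)), and the shared effect draws from a separate
(seed, constant) stream, so adding or reordering studies never changes
another study's data.

The default design (`three_cohort_design`) emulates the three-cohort
structure: 5 000 genes; unpaired 50 + 50 ("atherosclerosis") and 40 + 24
("stroke") cohorts and a paired 18-subject cohort ("mi", the stated size of
the motivating MI study); sets of 106/104/72 genes (the nominal TLR/TCR/BCR
sizes) planted +1/−1/−1 with mean effects 0.4/0.5/0.5 sd, 10 hubs each at
ρ_hub = 0.6 over ρ_nonhub = 0.2; a DNMT1-labelled regulator coupled
−0.4/+0.5/+0.4 and planted down 0.8 sd. Effect sizes and correlations are
in the range typical of whole-blood microarray case/control contrasts and
were fixed as the package's study conditions.

What the generator does **not** emulate: probe-level noise beyond an
optional k-probes-per-gene replication, platform-specific intensity
distributions, batch effects, correlated null genes outside the planted
sets, and non-Gaussian expression. Passing tests therefore demonstrate
correctness and calibration of the statistical machinery under the stated
model, not robustness to every failure mode of real microarray data.

## Numerical choices and degenerate inputs

- p-values are clipped away from exact 0 (to the smallest positive float)
  so −log10 p is always finite.
- Zero-variance genes: dropped (with a logged count) before network
  construction; reported as t = 0, p = 1 in DE.
- Zero-variance regulator or t vectors: an error, not a silent NaN.
- Constant connectivity is detected with a relative tolerance (1e-9), since
  row sums of identical values differ by floating-point round-off.
- Top-quantile ties are all kept and logged; BH is taken from statsmodels.
- Permutation p-values everywhere use +1 smoothing.

## Scale of the shipped validation

The test suite and acceptance script run entirely on synthetic data at
sizes chosen for completeness of the statistical checks: 500 null
set-tests at B = 200 for enrichment calibration, 20 seeds at B = 1000 for
planted-enrichment power, 200 null study pairs for concordance error
rates, 50 random instances for the TOM oracle, and the 5 000-gene
three-cohort emulation for the end-to-end pipeline. These sizes give the
binomial bands quoted in the tests their stated coverage while keeping a
full run in the tens of seconds.

## Known limitations

- The enrichment test reports raw permutation p-values; with many sets a
  cross-set correction would be needed.
- The edge-FDR null (independent per-gene sample permutation) destroys all
  inter-gene structure; it is a self-contained choice, documented here, and
  other nulls (e.g. module-preserving) would be stricter.
- The paired-cohort network analysis correlates across both timepoints,
  so subject-level intercepts contribute to co-expression; within-subject
  centering is not applied, matching common practice for WGCNA on repeated
  measures but worth remembering when interpreting paired-cohort edges.
- No moderated (empirical-Bayes) t, covariate adjustment, meta-analytic
  pooling, or raw-array (CEL/IDAT) preprocessing.
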