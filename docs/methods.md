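# Methods

This note documents the statistical models, the synthetic data-generating
process, the numerical choices, and the known limits of what the test
suite demonstrates.

## Count model and region screen

Per-region c-Fos+ cell counts `Y_i` across animals are modeled with
log-link quasi-Poisson GLMs. The nuisance ("null") model is

    log μ_i = β0 + β1 S_i + β2 T_i + β3 T_i² + β4 B_i

with sex S coded 0/1 (reference female), timepoint T the raw ordinal
1..4 (coding 0, 2.5, 6, 22 hr of cohabitation; the quadratic term
captures the 2.5/6-hr-peaked "bond formation" profile), and block B a
single linear numeric term 1..6. The bonding model adds partner type P
(0/1, reference sibling) and its interactions:

    ... + β5 P_i + β6 P_i·S_i + β7 P_i·T_i + β8 P_i·T_i²

Quasi-Poisson point estimates coincide with Poisson maximum likelihood;
the fitting routine is an IRLS on the Poisson score equations, vectorized
across regions (all regions share one design matrix, so the weighted
normal equations batch into one `(R, p, p)` solve). The two models are
compared with the quasi-likelihood ANOVA statistic

    F = [(D_null − D_full) / df_num] / φ̂_full,

where D is the Poisson deviance (with `y log(y/μ) := 0` at `y = 0`) and
φ̂ = Pearson χ²/(n−p) from the fuller model. Forcing φ = 1 reduces F to
the likelihood-ratio χ²/df, which the tests verify.

**Permutation calibration.** Parametric F reference distributions are not
trusted for overdispersed counts at this scale; instead the partner-label
vector is shuffled across animals, one shared shuffle per draw for every
region, and both models are conceptually refit. Because the nuisance
model contains no partner term its deviance is invariant under the
shuffle and is computed once — an exact shortcut, not an approximation.
p-values use the plus-one rule `p = (1 + #{F* ≥ F_obs}) / (1 + n_perm)`,
which never returns zero and is valid at finite n_perm; q-values are
Benjamini–Hochberg across the screened family, with q < 0.1 as the
significance threshold. Shuffling the tested factor while leaving the
nuisance design intact is the standard choice when the text of a
permutation protocol does not pin down what was permuted.

The partner × sex screen compares the bonding model against the same
model without the P·S term, permuting sex labels *within* partner groups
(both models contain sex terms, so both are refit per draw); its reported
direction is the sign of the P·S coefficient.

**Direction.** The screen reports the sign of the partner main-effect
coefficient in the bonding model. With raw-polynomial T interactions this
coefficient is the partner offset extrapolated to T = 0, so for regions
whose partner effect is carried mainly by the interactions the sign can
differ from the mean mate−sibling difference; it is reported as defined,
not post-processed.

**Degenerate inputs.** Regions whose counts are all zero are skipped and
reported with a reason; constant-count regions fit both models exactly
and get F = 0, p = 1. Rank-deficient designs (e.g. any P term on an
all-sibling design) raise an error naming the collinear columns, after a
warning at design-construction time.

## Mutually exclusive region selection

"Overlap" is the ancestor/descendant relation in the atlas ontology —
regions nest by construction, and spatial partial overlap is out of
scope. Among the q < 0.1 regions, the selection repeatedly takes the
highest-F region, adds it, and removes its ancestors and descendants from
contention. The higher F always wins, whether it sits on the parent or
the child; ties break toward the smaller (more localized) region by atlas
volume, then lexicographic id, making the output independent of input
order. The result is an antichain, verified against an independent greedy
oracle on fuzzed instances.

## Clustering, embedding, connectivity

Activity profiles are each chosen region's count vector across animals,
z-scored per region with the sample (n−1) standard deviation — the R
`scale()` convention. Scaling is the default because clustering should
group regions by activation *pattern*, not by baseline expression level;
a flag disables it. Clustering is Ward.D2 on the Euclidean distance
matrix (scipy's `linkage(method="ward")`, which equals R
`hclust(method="ward.D2")` on Euclidean input), cut into k groups; k
defaults to 8, matching the circuit granularity such studies report, and
is a parameter because the cut is a judgment call, not an algorithm. The
2-D embedding is non-metric MDS minimizing Kruskal stress-1, best of
`n_restarts` seeded starts, coordinates centered.

The connectivity test maps each chosen region onto the connectome —
itself if present, else the nearest available atlas ancestor ("next
inclusive region") — and computes the unweighted mean over clusters of
the mean density across ordered member pairs (diagonal and shared-mapping
self-pairs excluded; the ordered-pair mean equals the unordered mean of
symmetrized densities). The null shuffles only the row labels of the
mapped submatrix, preserving the asymmetric origin→target semantics.
Clusters with fewer than two distinct mapped members are excluded with a
warning (configurable to a hard error).

One calibration subtlety, verified empirically: under random cluster
labels on a *modular* matrix the observed statistic disrupts rows and
columns jointly, which the row-only shuffle cannot mimic, so null
p-values are uniform only when the matrix itself is unstructured; the
calibration test uses an iid matrix for exactly that reason. On
block-diagonal matrices, row shuffles that happen to preserve every block
tie the observed statistic, so the attainable minimum p is exactly
1/(n_perm+1) only when that probability is negligible (4+ blocks of 3).

## Brain–behavior statistics

CCA standardizes both sets (canonical correlations are scale-invariant;
standardization makes weights comparable), whitens each covariance by its
inverse symmetric square root, and takes the SVD of the whitened
cross-covariance. Factor scores have unit sample variance and are
mutually uncorrelated within a set; each factor is oriented so its
largest-|loading| behavioral variable loads positively. Factor k is
tested with Wilk's Λ_k = Π_{j≥k}(1 − r_j²) and Bartlett's
χ² = −[n − 1 − (p+q+1)/2]·ln Λ_k on (p−k+1)(q−k+1) df. Loadings are
plain Pearson correlations of raw variables with factor scores;
zero-variance variables yield undefined (NaN) loadings rather than being
dropped silently.

Pair similarity correlates, across mate pairs, the female member's count
in region i with the male member's count in region j (the diagonal is the
same-region coordination profile); raw counts are used since Pearson
correlation is invariant to per-variable linear scaling. The partial
version applies `r_xy·z = (r_xy − r_xz r_yz) / √[(1−r_xz²)(1−r_yz²)]`
cellwise with z the per-pair covariate (tested equivalent to
regress-out-then-correlate); cells with |r_xz| = 1 or |r_yz| = 1 are
flagged undefined. Timepoints 2–3 pool as the bond-formation window,
with 1 (pre-pairing) and 4 (established bond) analyzable separately.

Behavioral group tests are Welch two-sample t (mates vs siblings, at the
animal or dyad level according to each measure's declared level) and
paired t (female vs male within mate pairs), BH-corrected as a family at
q = 0.05, with optional per-timepoint follow-ups.

## Synthetic data generator

The generator emulates the study conditions: 12 mate pairs and 12
sibling pairs (half FF, half MM) per timepoint — 192 animals, 96 of each
sex — distributed round-robin over 6 blocks. Region counts are negative
binomial (the standard generative counterpart of the quasi-Poisson
mean–variance assumption) with size θ ("dispersion") and log-mean

    η = baseline + nuisance(S, T, B)
        + [bonding regions, mates only] partner_effect
          + quad_time_effect·1{T ∈ {2,3}} + shared pair term
        + cluster / idiosyncratic noise.

Defaults and their rationale:

- `baseline_log_mean = log 50`, `dispersion θ = 8`: order-of-magnitude
  choices for regional c-Fos counts (no per-region magnitudes are
  published); both user-configurable.
- `partner_effect = quad_time_effect = 0.16`: sized so one region's
  parametric model comparison has power ≈ 0.9 at the study's sample size
  (measured 0.90 by simulation over 4 seeds × 28 regions). At this
  power, the BH-corrected permutation screen attains sensitivity
  ~0.86–0.96 with empirical FDR ~0.05–0.11.
- nuisance (sex/time/block) coefficients default to 10% of
  `partner_effect`, keeping the planted signal identifiable at desk
  scale.
- `cluster_noise_sd = 0.5`: bonding regions in a planted cluster share a
  per-animal latent of this scale (null regions get independent noise of
  the same scale, so their dispersion matches). This puts within-cluster
  profile correlation well above between-cluster correlation and yields
  ARI 1.0 for Ward.D2 recovery at k = truth.
- shared pair term: `pair_factor_scale · (z_e + jitter·u_p)`, where z_e
  is the pair's ejaculation count standardized across mate pairs and
  u_p ~ N(0,1) is a per-pair latent. Both members of a mate pair receive
  the same value in every bonding region. The ejaculation count itself
  (not a latent multiplied by it) must carry most of the shared variance:
  a pure product z·u is linearly uncorrelated with z, so partialing the
  ejaculation count out would *not* attenuate the within-pair
  correlation, contradicting the phenomenon being modeled. The jitter
  term keeps a small ejaculation-independent component.
- ejaculation counts: Poisson(6) for mate pairs at timepoints 2–3, zero
  otherwise (mating is absent before pairing and rare after bond
  stabilization, and absent in sibling pairs).
- connectivity: off-diagonal densities Normal(within 0.3 / between 0.05,
  sd 0.05) clipped to [0,1]; the diagonal carries a NaN sentinel.

Two presets document alternative study conditions. `null_config()` zeroes
every planted knob (partner, quad-time, pair factor, cluster noise) for
type-I calibration — per-region permutation p-values are valid with
cluster noise on, but cross-region dependence would inflate the variance
of the pooled rejection fraction, so calibration uses the fully
exchangeable null. `coordination_config()` (100 mate pairs in the
bond-formation window, `pair_factor_scale = 0.33`, jitter 0.05, θ = 60,
baseline log 80, cluster noise 0.04) is the shared-factor condition: raw
within-pair diagonal correlation ≈ 0.73, collapsing to ≈ 0.12 mean |r|
when ejaculation is partialed out. Two quantitative facts shaped this
preset: with only 24 pairs the sampling floor of mean |partial r| is
already ≈ 0.17 (E|N(0, 1/√21)|), so demonstrating "the correlation is
abolished" needs ~100 pairs; and because the shared term enters the
log-mean, counts are *convex* in the ejaculation count, leaving a
residual (c⁴-order) shared component that linear partialing cannot
remove — which caps how large `pair_factor_scale` can usefully be.

**What the generator does not emulate:** spatial autocorrelation between
neighboring regions, registration and segmentation error, per-animal
global staining efficiency factors, heavy-tailed count contamination, or
any voxel-level structure. Passing recovery tests therefore shows the
statistics behave correctly under the model's own assumptions, not that
real imaging data satisfies those assumptions.

## Auxiliary analyses

Region-volume comparisons fit per-region negative-binomial regressions
(statsmodels ML, with estimated shape) of voxel volumes on a two-level
group, reporting the Wald z for the group coefficient with BH correction;
`relative=True` adds a log whole-brain-volume offset so the coefficient
tests relative volume. The outlier screen is Rosner's generalized ESD
test on per-animal whole-brain counts: iteratively remove the most
studentized-extreme point, compare each R_i to the two-sided t-based
critical value λ_i, and flag up to the largest i with R_i > λ_i.

## Pipeline and reproducibility

`run_pipeline` executes simulate → screen → select → cluster →
connectivity → CCA → pair-similarity with stage toggles and dependency
checks. One root seed is split per stage via SHA-256, so a stage rerun in
isolation reproduces its in-pipeline result; identical config + seed
gives byte-identical outputs (tested). Logs go to stderr and `run.log`;
results are never interleaved with logs. The run report records the seed
and a hash of the analysis-relevant config (the output path is excluded
from the hash).

Problem sizes used by the test suite and the acceptance script — 192
animals, 68–250 regions, 500–2,000 permutation draws, 10–20 replicate
seeds — were chosen to make every check complete comfortably on a single
CPU while keeping each assertion's Monte-Carlo error well below its
margin; the batched IRLS makes the 10,000-shuffle screens of a real
analysis equally practical.

## Known limitations

- The permutation protocol shuffles partner labels across animals,
  ignoring the pair structure (both members of a pair always share a
  partner label in reality); under the global null this is exchangeable,
  but a pair-level shuffle would be the conservative alternative if
  pair-correlated noise were present in *null* regions.
- Wilk's lambda uses Bartlett's χ² approximation (Rao's F not
  implemented); fine at n ≈ 190, optimistic for very small n.
- The NB volume comparison relies on statsmodels convergence; degenerate
  regions (zero variance) are reported as skipped rather than tested.
- Ward.D2 label numbering follows scipy's cut ordering; only the
  partition (not label values) is guaranteed stable across input
  orderings.
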