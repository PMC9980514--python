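# Methods

This note documents the models and procedures implemented in `milkgut`,
the choices made where the methodology was genuinely open, and what the
synthetic-data tests do and do not establish.

## Subspecies typing from pangenome markers

A metagenome's *B. longum* population is summarized by two marker
statistics computed on binarized gene detection: the fraction
*f*<sub>HMO</sub> of HMO-cluster genes (Blon_2331–Blon_2361, 31 gene
families in the default panel) detected, and ara detection (*araA* and
*araD*). The stratification rule is

| condition | class |
|---|---|
| *f* ≥ θ_full, no ara | exclusive *infantis* |
| θ_partial ≤ *f* < θ_full, no ara | putative *infantis* |
| *f* ≥ θ_partial, ara | co-existence |
| *f* < θ_partial, ara | exclusive *longum* |
| *f* < θ_partial, no ara | unclassified |

θ_full = 0.9 and θ_partial = 0.25 are defaults, not field constants: the
phenomenon being encoded is "almost all cluster genes" vs "partial
detection", and both thresholds are exposed in the configuration. The
ara rule defaults to requiring **both** genes (they co-occur in *longum*
genomes, so the joint requirement is the conservative *longum* call);
`ara_rule="any"` is available for sensitivity analysis. The rule is total:
every (*f*, ara) pair maps to exactly one class (enumeration-tested).
Heatmap-style sample ordering uses complete-linkage clustering on
Euclidean distances between 0/1 marker profiles; samples are pre-sorted
lexicographically so merge order is reproducible under input reordering.

The LNT-transporter statistic is the fraction, among samples in the
three HMO-cluster-positive classes, carrying at least 2 of the 3
transporter genes (Blon_2175–2177).

## Dirichlet-multinomial mixture (DMM) community typing

Counts *x* for a sample with total *N* under component *k* follow the
Dirichlet-multinomial with parameter vector α_k (A = Σ_j α_kj):

log P(x | α) = log C(N; x) + logΓ(A) − logΓ(N+A) + Σ_j [logΓ(x_j+α_j) − logΓ(α_j)].

Fitting is EM: responsibilities ∝ π_k exp(log P(x|α_k)) in the E-step;
π_k = mean responsibility and α_k = argmax of the responsibility-weighted
DM log-likelihood (L-BFGS in log-α with the analytic gradient, bounds
10⁻⁶ ≤ α ≤ 10⁶) in the M-step. Initialization is k-means on
CLR-transformed proportions; a component whose responsibility mass
vanishes is re-seeded from the worst-fit sample (at most three times —
the observed-data log-likelihood is non-decreasing across plain EM
iterations and this is property-tested with 10⁻⁸ slack). Convergence:
relative change in observed log-likelihood below 10⁻⁶ (default cap 500
iterations).

**Model selection.** K is chosen by minimizing a Laplace approximation to
the negative log evidence,

−log Ẑ = −[log L(θ̂) + log p(θ̂) + (d/2) log 2π − ½ log |H|],

with d = K·J parameters (the log-α's; mixture weights are profiled, not
integrated — a deliberate simplification), prior log α ~ N(0, 3²) per
parameter, and H the negative Hessian of the log posterior, computed
block-diagonally per component with E-step weights frozen (central
differences of the analytic gradient; eigenvalues floored at 10⁻⁸ before
the log-determinant). The reference DMM methodology names only "Laplace";
the prior and the block-diagonal Hessian are this package's documented
choices. On well-separated synthetic mixtures the criterion selects the
true K (acceptance-tested: 5/5 master seeds at K = 3); its absolute
values are not comparable to other implementations.

Relative-abundance input is converted to integer pseudo-counts
(largest-remainder rounding to a configurable total, default 10,000)
because the DM likelihood needs counts. GMC labels are re-indexed by
decreasing prevalence so "type 1" is always the most common community.
Ties in the argmax assignment go to the lower component index.

## Diversity and PERMANOVA

Rarefaction subsamples without replacement (multivariate hypergeometric)
to the minimum sample total by default, dropping shallower samples with a
warning. Richness counts taxa with positive counts; Shannon uses natural
logs; inverse Simpson is 1/Σp². Bray–Curtis comes from
`scipy.spatial.distance`. PERMANOVA uses the sums-of-squared-distances
pseudo-F (verified against scikit-bio to 10⁻¹⁰) with the permutation
p-value (1 + #{F* ≥ F}) / (1 + n_perm); permutations are vectorized.

## HMO quantification and milk typing

Per peak, SNR = raw area / per-sample noise (the noise level is estimated
upstream from the late-migration region of the electropherogram and
carried in the sample table — per-sample, not global). With LOQ = SNR 10
and LOD = SNR 3:

- SNR ≥ 10 → nPA = 100 · area / IS area (percent of internal standard);
- 3 ≤ SNR < 10 → nPA = 100 · (10 · noise) / IS / √2, i.e. the
  LOQ-equivalent nPA over √2 (mean of a triangular distribution on
  [0, LOQ]), flagged imputed;
- SNR < 3 → absent, nPA = 0.

Typing uses **confidently quantified** peaks only (imputed peaks do not
count as "present"; configurable). The marker sets are fixed by the
chemistry — α1-2-fucosylated 2'-FL, DFL, LNFP I for secretor; α1-4
LNFP II, LNDFH II for Lewis — but no published rule states how many
markers make a call. The defaults are quorums: ≥ 2 of 3 Se markers,
≥ 1 of 2 Le markers, robust to a single peak dropout and exposed in the
configuration. Group prevalences are reported at 0.1% resolution and the
secretor/Lewis rollups at integer percent, matching the conventional
reporting style. Unassigned peaks are quantified but never typed.

## Association statistics and networks

Kruskal–Wallis (tie-corrected, via scipy), Dunn's post-hoc z-tests on the
joint ranks with the tie term Σ(t³−t)/(12(N−1)), two-sided throughout,
Mann–Whitney (exact when n ≤ 16 without ties, otherwise normal
approximation with tie and continuity correction), Pearson chi-squared
without Yates correction. BH-FDR is the step-up q_(i) = min_{j≥i} p_(j)
m/j, one family per analysis table. Degenerate all-tied inputs return
p = 1 rather than NaN.

SparCC estimates basis variances from the log-ratio variation matrix
t_ij = var(log((x_i+pc)/(x_j+pc))) (fixed pseudocount 0.5 — no Bayesian
resampling, so the estimate is deterministic), solves the linear system
under the sparsity assumption, converts to correlations, and iteratively
excludes the strongest pair above 0.1 (up to 10 rounds, stopping early
and refusing to disconnect a taxon from the solvable system). Networks
keep taxa with prevalence ≥ 25%, the top 20 by mean relative abundance,
and edges with |ρ| ≥ 0.2 in absolute value (negative edges are kept, with
sign recorded).

## Synthetic cohort: what it emulates, and what a green test shows

The generator encodes the cohort it stands in for: 105 infants aged
8.31 ± 1.38 months, 90 milk samples; subspecies class frequencies
39/12/46/4 % (renormalized — the printed percentages sum to 101 from
rounding); GMC prevalences 50.5/40.0/9.5 % with genus profiles built to
match the described types (type 1 most Bifidobacterium-dominant, type 3
Enterobacteriaceae-enriched and most diverse); fecal pH means
5.01/5.70/5.68 per GMC type (common sd 0.8, a pooled stand-in for the
per-type sds); HM group frequencies 48.9/22.2/22.2/6.7 %; an 80%
LNT-transporter quorum; and two planted positive species-correlation
blocks (ρ = 0.6) mirroring the reported Bifidobacterium subnetworks.
Values the source material does not state were fixed once at realistic
scales: marker coverage uniform in [1, 10), marker flip noise 2%,
"present" milk peaks at 20–200× noise and "absent" ones below 2× noise,
IS areas ~10³, calprotectin log-normal around 150 µg/g (independent of
GMC type, a planted null), sequencing depth 10⁴ (genus) / 5·10⁴
(species).

What this does **not** establish: recovery of the study's actual
cohort-level numbers (those require the deposited raw reads), realistic
inter-taxon noise (real profiles are not exactly Dirichlet-multinomial),
electropherogram artifacts (migration-time alignment and peak calling are
upstream of this package), or DMM behavior on overlapping communities —
the acceptance checks use well-separated mixtures by design; on the
default cohort, whose planted types overlap, assignment ARI is ~0.7.

## Numerical notes and limitations

- All generators are pure functions of (parameters, seed); a run's single
  seed is split into independent substreams per stage.
- The correlation bound in the SparCC null check is an order-statistics
  question: with 190 taxon pairs at n = 300 the *maximum* null estimate
  concentrates near 0.17–0.19 (sd ≈ 1/√n per pair) even for the exact
  basis correlations, so tight per-pair bounds on the maximum are
  seed-sensitive; unit tests therefore use a 5-sd envelope.
- Coverage binarization treats the threshold as a closed lower bound;
  threshold 0 means "any positive coverage", so 0/1 matrices pass through.
- A panel gene missing from the input matrix is treated as undetected
  (coverage 0) rather than an error, since profiler versions differ in
  which gene families they emit; only a matrix sharing *no* panel gene is
  rejected.
- Chi-squared refuses tables with expected counts below 1 and warns
  below 5.
- The DMM Laplace score is a relative criterion only, and the EM can hit
  local optima for K well above the truth; restarts (default 2–3) with
  the best likelihood retained per K are the mitigation.
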