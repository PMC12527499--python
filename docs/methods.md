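# Methods

This note documents the statistical models, the synthetic-study generator,
the numerical choices, and the limits of what the test suite establishes.

## Group morphometry

**Thinning map.** Per region, ordinary least squares of thickness (mm) on a
group indicator plus sex, age (years), education (years) and ICV (mm³).
The indicator is coded so a positive coefficient means patients are
thinner; t = coefficient / SE at residual degrees of freedom; two-tailed p;
significance at the Bonferroni level 0.05 / n_regions. Covariates that are
constant across subjects are dropped, which makes the statistic collapse
exactly to the pooled two-sample t (verified against the closed form to
1e-8).

**t→z.** z = sign(t) · Φ⁻¹(1 − p_two/2). The inversion runs in log space
(`t.logsf` + `ndtri_exp`), so extreme t maps to a large finite z rather
than overflowing — a saturating, monotone, odd transform with z → t as
df → ∞.

**W-scores.** The normative model (same covariates, intercept included) is
fit on controls only; the per-region scale is the df-corrected residual SD
of the control fit. `W = (predicted − observed) / scale`, so thinner than
expected ⇒ W > 0. The alternative denominator — the SE of the predicted
mean — would shrink with n and inflate W; residual SD is standard W-score
practice and is the default (the in-sample control sd of W is then
√((n−p)/(n−1)) ≈ 0.99 at n = 200).

## Connectome models

**SMN.** Pearson correlation of each pair of region columns across control
subjects, |r| capped at 0.999999 before the Fisher transform so degenerate
(collinear) fixtures stay finite. Raw thickness is used (no covariate
residualization), matching common practice for covariance networks.

**Degree centrality.** Signed row sums. For SC all weights are
non-negative; FC/SMN sums may include negative entries.

**Neighbor aggregation.** Structural neighborhoods always come from
`sc > 0` (self-connections excluded). The weighted form divides by the sum
of weights by default — a proper weighted mean that is scale-free in the
weights and reduces exactly to the unweighted mean for equal weights; a
`count` mode (divide by the neighbor count) implements the literal
degree-normalized reading, and both are tested against a brute-force
double-loop oracle to 1e-10. Negative FC/SMN weights are clamped to zero
by default (weights read as connection strength); a `signed` mode keeps
them, erroring if a weight sum turns negative. Isolated regions propagate
as missing (NaN) with a warning and are excluded pairwise downstream. The
implementation uses the mean-centered form
`T = m + W(t − m)/Σw`, which is algebraically identical but exact for
constant maps under floating point.

## Spin tests

Each spin draws one uniform random 3D rotation, applies it to the
left-hemisphere centroids and its x-mirrored counterpart to the right
(standard for bilateral atlases; hemisphere assignment never mixes), and
each region takes the value of the nearest original parcel by great-circle
distance (duplicates allowed). Empirical p-values use
`(#exceedances + 1)/(n_spins + 1)` so p is never 0; a raw-proportion mode
exists. In correlation tests the empirical (thinning) map rotates and the
normative map stays fixed. Type-I error, measured with independent smooth
bilateral maps (Gaussian-process draws on the hemisphere sphere with a
shared bilateral component), is ≈ 0.06 at the nominal 0.05 over 500 draws
of 500 spins.

## Epicenter mapping

Rank 1 = greatest thinning, ties averaged. The mean of the own rank and
the morphology-weighted neighbor rank is the epicenter likelihood (lower =
more epicenter-like): an epicenter is both strongly thinned and surrounded
by strongly thinned neighbors. Wording conventions differ on whether
"high" or "low" rankings are reported; this implementation anchors the
semantics (rank 1 = most thinned, minimum mean rank = epicenter) and keeps
the reporting order explicit in the output table. Per-region significance:
the thinning map is spun, the neighbor map and mean ranks recomputed per
spin, and p is the left-tail probability of a mean rank at least as small.

## System enrichment

Arithmetic means within Yeo-7 / Von Economo / custom systems. The default
null spins the map (preserving spatial autocorrelation); label shuffling
is a sensitivity mode. Two-sided p doubles the smaller one-sided tail
(with the +1 correction) instead of comparing |null| to |observed|,
because null system means inherit the map's global mean and are not
centered at zero — the magnitude form would be miscalibrated for thinning
maps. The packaged Desikan-Killiany lookup table is an approximate
majority-vote assignment assembled for this package; supply your own table
for careful real-data enrichment.

## Behavioral PLS

Columns of both blocks are z-scored (correlation PLS); R = XᵀY/(n−1);
SVD R = USVᵀ. Covariance explained uses σ²-normalization (σ-normalization
available). Sign convention: each latent variable is flipped so its
largest-|entry| behavior salience is positive — more severe symptoms give
positive behavior scores. Rows with any missing clinical value are dropped
listwise. Significance permutes rows of Y and compares singular values
position-wise with the +1 correction. Behavior loadings are Pearson
correlations between each measure and the LV's brain scores.

## Biotyping

Patient similarity = Pearson correlation between network-weighted W-score
profiles. K-means (Euclidean) runs on the similarity-matrix rows (the
literal construction; clustering the raw profiles is a sensitivity mode),
best of 100 restarts per k, k = 2..10 scored by mean silhouette, smallest
k winning ties; labels are relabeled so biotype 1 is the larger subgroup,
and a maximum silhouette below 0.25 flags weak structure. Subgroup
contrasts use Student's pooled two-sample t (Welch optional).

## The synthetic study generator

The generator's defaults are the study conditions for every test: 119
controls, 139 patients, 68 regions (34 per hemisphere).

**Geometry.** Fibonacci-lattice centroids on the left-hemisphere unit
sphere (seeded random rotation), mirrored in x to the right, so regions
form homotopic pairs.

**Structural connectome.** Log edge weights combine exponential distance
decay (length scale 0.75 in sphere-embedding units), Gaussian noise,
a within-community bonus (six bilateral geometric communities), a
homotopic mirror-pair bonus, and a per-endpoint bonus for a bilateral
rich-club subset (20% of regions) — reproducing, statistically, the
distance dependence, modularity, homotopy and hub interconnectivity of
tractography-derived networks. The strongest edges are kept to 15%
density (bridged if disconnected) and the weight range is compressed
(square-root temper) so degree is not dominated by single outlier edges.
One community — the most hub-dense, by analogy with association cortex —
is designated the *core*: its edges and factor loadings are boosted, and
the default epicenters are a connected hub trio inside it (a homotopic
hub pair plus their most strongly connected fellow hub). This co-location
of hubs, high covariance and vulnerability is the phenomenon the analysis
chain targets; placing epicenters elsewhere (the `epicenters` config
field) weakens the planted hub-thinning correlation accordingly.

**FC and thickness covariance.** A latent-factor model with one factor per
community plus a global factor; loading magnitude grows with SC degree
rank, hubs additionally load weakly on every community factor (connector
behavior), and core loadings are boosted. FC is the implied correlation
matrix; control thickness uses the same mixing scaled to mm, with unique
noise chosen so every region's total variance is noise_sd² + factor_sd²
(0.08² + 0.12²) — loadings shift the variance composition, not its
magnitude, so strongly covarying regions are not penalized in the group
GLM.

**Atrophy.** beta = atrophy_scale · normalize((1−w)·spread + w·hubness),
with spread the truncated diffusion Σ_{k≤10} ρᵏ Sᵏ e of the epicenter
indicator on the symmetrically normalized SC (ρ = 0.85) followed by two
neighbor-averaging passes, and hubness the min-max-scaled SC degree
(w = 0.4). The two terms implement the two planted mechanisms — network
spread and hub stress. Patient thickness subtracts severity_i · beta_j;
atrophy_scale = 0.3 mm at the peak region gives a widespread thinning map
(≈ 15–40 of 68 regions significant) comparable to reported case-control
studies.

**Severity, clinical scores, biotypes.** Severity is linear in z-scored
log-duration and log-dose (coupling 0.5 each) plus N(0, 0.3²) noise,
centered at cohort mean 1. Clinical scores are baseline + loading ×
severity + noise with loadings (0, 8, 4, 4) for (craving, PANSS, HARS,
HDRS) — craving is unrelated by design — and noise calibrated so each
related score correlates ≈ 0.5 with severity. The low-exposure biotype
(fraction 45/139) draws both drug variables lower, sized so its severity
is shifted by d = 1.5 standard deviations of the full severity mixture
(the self-consistent solution requires d < 1/√(f(1−f))).

**A known recovery limit.** Because biotype affects thickness *only*
through severity, biotype-label recovery by clustering is bounded by the
Bayes error of the one-dimensional severity mixture: at d = 1.5 the
within-group overlap leaves ≈ 15% irreducible misassignment per side,
capping the adjusted Rand index near 0.5 regardless of sample size or
algorithm (an oracle threshold on the *true* severity reaches only
ARI ≈ 0.3–0.5 across seeds; the pipeline performs comparably). The
cluster-count selection (k = 2) and the duration/dose contrasts are
recovered essentially always; the label-agreement test documents this
ceiling by failing at its nominal ARI ≥ 0.8 threshold.

**What the generator does not emulate.** No tractography or BOLD
dynamics; no site or scanner effects; no covariate-group confounding
(education differs between groups in real cohorts); Gaussian thickness
noise without outliers or missing regions; clinical scores with a single
latent dimension (which is why the first PLS latent variable explains
nearly all the covariance here, far more than in real data). Passing
tests therefore demonstrate correctness and calibration of the methods
under a structured but idealized data-generating process, not performance
on real MRI-derived measurements.

## Problem sizes in the test suite

Monte-Carlo tests use the sizes that make their claims meaningful while
keeping the default suite fast: 25 seeds × 500 spins for the planted
recovery and epicenter checks (at n = 100 + 100), 500 draws × 500 spins
for spin calibration, 20 seeds × 500 permutations for PLS recovery
(n = 150 patients), 200 runs × 200 permutations for PLS null calibration,
and 25 seeds at the full study size for biotyping. `scripts/acceptance.py`
uses 5000 spins and 5000 permutations, mirroring standard practice.
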