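# Methods

`netlag` re-implements, as a tested pipeline over synthetic data, a
resting-state fMRI connectivity analysis for a three-group genetic
parkinsonism design: healthy controls (HC, n=22) and heterozygous (HET,
n=12) / homozygous (HOM, n=8) carriers of PINK1 or Park2 mutations. The
analysis graph is: BOLD preprocessing → temporal-concatenation group
spatial ICA with back-reconstruction → voxelwise intra-network group
statistics with permutation cluster FWE → inter-network *constrained
maximal lagged correlation* with Fisher-z group ANCOVA and
brain–behaviour correlations.

## The synthetic cohort

No data are downloaded; every stage is validated against a generator with
known ground truth.

**Geometry and timing.** Subjects share one voxel grid (desk-scale default
20×24×20 voxels at 3 mm; the analysis drivers use 14×16×14) and acquire
`T = 220` volumes at `TR = 2.08 s`. The acquisition duration printed in
the source setting (7 min 20 s) implies ≈212 volumes at this TR; `T` is
explicit configuration and the default remains 220.

**Networks.** Five canonical networks (DMN, SN, ExN, rFP, lFP) are 3D
Gaussian blobs (σ = 5 mm), peak-normalised, rejection-placed so that any
two different networks correlate spatially below r = 0.3. The default is
one compact node per network. This is deliberate: if a multi-blob network
carries a group-varying amplitude on one blob only, the network spans two
spatial directions in the concatenated data and spatial ICA *correctly*
splits it into per-blob components — after which no single component can
match the summed network map closely. Single-node networks keep every
network a rank-one spatial source, the regime in which component recovery
is well defined. Multi-blob networks (with per-blob amplitude multipliers)
remain supported and are exercised at the GLM level.

**Time courses.** Network time courses are generated in the frequency
domain: at every DFT bin inside the 0.01–0.08 Hz band the five complex
spectra are drawn jointly Gaussian with coherence matrix
`C_ab(m) = c_ab · exp(2πi·m·k_ab/T)` (unit diagonal), via a Cholesky
factor; out-of-band bins are zero. This realizes, exactly in expectation,
a circular cross-correlation between networks a and b that peaks at the
integer lag `k_ab` (TR units) with value `c_ab`, for an *arbitrary*
jointly realizable coupling matrix. The commonly used shared-noise
construction caps the per-network total coupling at Σ|c| < 1 and cannot
reach the default coupling magnitudes.

A caveat discovered while calibrating the defaults: group *tables* of
mean maximal lagged correlations (one value per pair) need not form a
jointly consistent correlation structure — the HET and HOM default
matrices, taken at face value, have cross-spectral matrices with negative
eigenvalues. `shrink_to_feasible()` scales each group's off-diagonal
couplings by the largest factor that keeps the smallest in-band eigenvalue
≥ 0.1 (shrink ≈ 0.81 for HET, ≈ 0.87 for HOM, none for HC). The injected
lag pattern is unchanged.

**BOLD signal.** Each subject's run is
`Σ_networks (group- and blob-scaled map ⊗ time course) + AR(1) noise +
linear drift`, with voxelwise AR(1) noise (ρ = 0.3, marginal SD 1.0) and
per-voxel random linear drift (amplitude 0.5). The AR(1)+drift model is
the minimal structure that makes the 0.01–0.08 Hz band-pass meaningful.
No haemodynamic convolution, motion, or physiological noise is modelled —
consequences below. Per-subject RNG streams derive from
`sha256(master_seed:subject_id)`, so cohorts are reproducible and
subjects independent.

**Phenotypes.** Age, education and sex ratios are drawn per group from
the study's demographic table (HC 47.0±12.2 y, 14.7±3.2 y education,
10M/12F; HET 41.9±14.8, 12.3±2.1, 5M/7F; HOM 51.4±8.1, 11.4±2.3, 6M/2F).
Where the demographics table and the participant-text disagree (HET/HOM
sex ratios, HET age), the table's column values are used. Corsi span
(HET ≈ 4.6±0.5, HOM ≈ 3.9±0.3) and MoCA exist for carriers only; LEDD
(590.9±358.1, clipped at 0) for the treated HOM group only. Total
grey-matter volume is an arbitrary-unit covariate with a mild atrophy
gradient (HC 640, HET 625, HOM 600, SD 55).

**Injected group effects.** Intra-network amplitude deficits follow the
published contrast pattern: DMN reduced in both carrier groups (HET 0.75,
HOM 0.70), ExN and rFP reduced in HOM only (0.65). Inter-network
couplings per group follow the published pair table (signs and
magnitudes, lags rounded to integers), including the anticorrelated
DMN–task-positive pairs in controls, sign-flipped positive DMN couplings
in HET, and the HOM-specific SN–rFP increase.

## Preprocessing

Discard the first 4 volumes (T1 equilibration; 220 → 216), then band-pass
0.01–0.08 Hz, then smooth at 8 mm FWHM ("8 mm³" in the source is read as
8 mm isotropic, standard usage). "Phase-insensitive" filtering is a
forward–backward (zero-phase) order-4 Butterworth; an FFT brick-wall
filter is available behind `filter_method="fft"`. The per-voxel mean is
removed. Filter contracts are steady-state properties: the passband gain
at 0.04 Hz is within 5 %, the 0.2 Hz gain below 10 %, measured over the
central half of the series (finite-length zero-phase filtering leaves
edge transients that are not part of the amplitude response). Smoothing
is per-frame 3D Gaussian, σ = FWHM/(2√(2 ln 2)) per axis converted to
voxels, reflect padding (preserves frame means to <1 % on small grids).
Motion realignment and slice-timing flags exist but are warning no-ops:
synthetic data need neither.

## Group ICA

GIFT-lineage two-stage reduction: each subject's centred (T × V) matrix
is reduced to `k_subject = 30` temporal principal components (economy
SVD); the reduced stacks are concatenated and a second PCA (randomized
SVD, seeded) brings the group data to the model order (20). FastICA
(scikit-learn; logcosh contrast, tol 1e-6, max 500 iterations, seeded)
unmixes the *spatial* dimension. Non-convergence warns by default
(`on_nonconvergence="raise"` available): with 15 of 20 components
modelling noise, the last fixed-point digits legitimately wobble without
affecting the recovered networks. Component sign is fixed so every map
has positive skewness (networks are sparse positive activations); group
maps are z-scored over the mask.

Back-reconstruction is the GICA-style projection through the stored
reduction matrices (subject time courses `F_i G_i A`, subject maps
`pinv(G_i A) R_i`); dual regression is available as
`back_reconstruction="dual_regression"`. Time courses entering the
inter-network stage are normalised to unit variance per subject (the
choice the source setting leaves open).

Network identification automates the visual review: an optimal injective
bipartite assignment (Hungarian algorithm) between template maps and
components by spatial correlation, ties broken toward the lower component
index, with every match r recorded and matches below 0.3 flagged.

## Intra-network statistics

Subject-specific network maps enter a voxelwise OLS GLM with a
cell-means group factor and centred nuisance covariates (total GM volume,
education). The group main effect is the partial F (full vs
nuisance-only model); pairwise group contrasts are t statistics.

Cluster inference replaces parametric random-field FWE with a
label-permutation maximal-cluster-size test: clusters form at a voxelwise
threshold (default p < 0.001 two-sided, 26-connectivity); permutations
shuffle the group labels against data and nuisance; each observed
cluster's corrected p is `(1 + #{perm max size ≥ observed})/(n_perm+1)`.
This is exact under exchangeability and needs no smoothness estimation.
Two practical notes: (i) cluster-*size* permutation tests are
conservative on spatially rough statistic images, where supra-threshold
sets shatter into heavily tied 1–2-voxel clusters — the familywise error
calibration is therefore assessed on spatially smooth null maps (as
back-reconstructed subject maps are) with clusters formed at p < 0.01;
(ii) an empty cluster list is a valid result, not an error.

The Corsi analysis fits, over carriers with a recorded span, group
indicators plus group-specific centred Corsi slopes with GM volume and
mutated gene as nuisance (the gene column is dropped with a warning if
only one gene is present), and reports positive-slope clusters per
carrier group; groups with fewer than 4 scored subjects are skipped.

## Inter-network statistic

For every pair of detrended (least-squares line removed) network time
courses, the Pearson correlation is evaluated at all 25 integer lags in
[−12, 12], the lagged series *circularly shifted* so every lag uses all T
samples. The optimal lag minimizes the correlation p value — for fixed T,
equivalently maximizes |r|; ties break toward smaller |lag|, then the
negative lag. The correlation is Fisher-transformed (z = atanh r). The
naive p uses the t transform with df = T−2, matching apparent practice in
the source analysis; because the maximum over 25 lags inflates naive
significance, a circular-rotation permutation p (`rotation_null_p`, 1000
rotations) is provided alongside.

Group inference per pair: ANCOVA F for the group factor on z with
education and GM volume as nuisance; Bonferroni over the pairs actually
tested (10 for five networks); covariate-adjusted pairwise t contrasts
with shared residual variance. Group tables report means of the integer
per-subject optimal lags to 3 decimals. Brain–behaviour coupling is a
partial Pearson correlation of z with the cognitive score, both
residualized on GM volume (df = n−3), complete cases only. The LEDD
sensitivity check correlates dopaminergic dose with per-network FC
summaries in the treated group, uncorrected.

**Statistical behaviour worth knowing.** On 0.01–0.08 Hz band-limited
series of length 216 at TR 2.08 s there are only ≈31 independent spectral
bins, so the per-subject z of the *maximal* lagged correlation has SD
≈ 0.19–0.28 (floor 1/√62 ≈ 0.13 plus lag-selection noise; at moderate
coupling the scan occasionally selects an opposite-sign noise peak). Two
consequences, both measured by the acceptance suite: the variance-
stabilized SD 1/√(T−3) applies only at a fixed lag, and the power to
detect a Δr ≈ 0.2 group increase (n = 22 vs 8) is high for the adjusted
HOM>HC contrast (~90 %) and the uncorrected ANOVA (~80 %) but low
(~25 %) once Bonferroni-corrected over 10 pairs.

## Pipeline and reproducibility

`RunConfig` (YAML-serializable) drives simulate → preprocess → ICA →
intra → inter → report; per-stage seeds derive from
`sha256(master_seed:stage)`; each run directory carries its config and a
sha256 checksum manifest. The numbered drivers under `analysis/` run the
same stages from disk artifacts.

## Problem sizes

Tests and the acceptance script scale the simulations to a desk: grids of
10³–14×16×14 voxels, cohorts of 14–42 subjects, 120–500 permutations,
20–40 simulation seeds per power/calibration estimate, and 1000 datasets
for the ANOVA type-I rate. The statistics under test are grid- and
scale-agnostic; these sizes were chosen so a full run completes in
minutes on one CPU.

## What the synthetic data do not show

Passing tests demonstrate correctness of the statistics and recovery of
effects *under the generator's assumptions*: linear mixing of rank-one
spatial sources, Gaussian AR(1) noise, no haemodynamics, no motion, no
registration error, groups differing exactly and only in the injected
parameters. They do not validate ICA model-order choice on real BOLD,
robustness to motion or physiological artefacts, anatomical localization,
or the clinical interpretation of any contrast.
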