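# Methods

## Model

Each resting-state frame is a standardized activity pattern on a
two-hemisphere cortical surface.  A deterministic *geometric reformatting*
moves it to a regular two-channel image: per hemisphere, vertices are
projected to the plane with a Lambert azimuthal equal-area projection centred
on the lateral pole and assigned one-to-one to grid cells, globally greedy by
projection distance (ties broken by lower vertex index).  The assignment is
injective, so the inverse reformatting recovers vertex values exactly; cells
holding no vertex are zero and masked everywhere downstream.  This scheme
trades replication of any particular published pixel layout for provable
invertibility — the analyses only require a faithful, invertible
reformatting.  Medial-wall vertices are excluded from analysis and from the
grid.

The encoder applies five convolutions (kernel 4, stride 2, leaky-ReLU 0.2,
channels 32→64→128→256→256) and two dense heads producing the posterior mean
μ_z and log-variance of 256 latent variables; the decoder mirrors it with a
dense layer and five transposed convolutions (twelve layers in all).
Training minimizes

    L(x) = ‖x − x′‖² + β · D_KL( N(μ_z, σ_z) ‖ N(0, I) )

with reparameterized sampling (z = μ + σ·ε) and Adam.  The reconstruction
term is masked to valid grid cells.  Defaults: β = 9, learning rate 1e-4,
batch size 128.  After training, all analyses use the posterior mean μ_z —
sampling at inference would make every downstream quantity stochastic for no
benefit; σ_z is retained for the loss.

**Desk-scale β.**  β balances a reconstruction term summed over grid cells
against a KL term summed over 256 latents, so the appropriate β scales with
the number of valid cells.  The default β = 9 corresponds to full-resolution
cortical input (~59k vertices); the test suite and examples train on ~1.2k
valid cells and therefore use β = 9 × 1220/59412 ≈ 0.2 together with a
learning rate of 1e-3 suited to short 20-epoch schedules.  With β left at 9
at desk scale the KL term dominates and the posterior collapses to the
prior — the rescaling preserves the intended balance rather than loosening
it.  The network is pure NumPy: im2col convolutions, hand-derived
backpropagation (verified against central finite differences in float64),
and a standard Adam implementation; float32 by default.

## Evaluation

*Reconstruction degree* is the Pearson correlation between an original and a
reconstructed cortical pattern, per frame, over non-medial vertices; frames
with zero variance have no defined correlation and are dropped with a
warning, never zero-filled.  Averages over frames or subjects go through
Fisher's z (values clipped at ±(1−1e−7)).

*Smoothing profiles* compare a model's reconstruction against the original
data explicitly smoothed at FWHM 1..10 mm (1 mm steps); the argmax is the
model's effective smoothing, flagged when it sits on the grid boundary.
Surface smoothing is a row-normalized geodesic Gaussian (sd = FWHM/2.355)
with distances approximated by edge-graph shortest paths, truncated at 3 sd;
exact geodesics are out of scope.  On the subdivision-3 test mesh (edge
length ≈ 5.5 mm at radius 40 mm) kernels below ~5 mm are under the mesh
resolution, so sub-5 mm ordering tests use the subdivision-4 mesh.

*Inter-session consistency*: scores of paired scans are residualized on
their own session's age, then correlated (the p-value uses n−3 degrees of
freedom) and summarized with ICC(2,1) — two-way random effects, absolute
agreement, single measure — computed via pingouin.  A variable perfectly
explained by its covariates has residuals that are numerically zero; its
partial correlation is defined as 0 rather than left to roundoff noise.

## Age prediction

Features are the 256×255/2 = 32,640 upper-triangle entries of the latent
covariance matrix (correlation mode is available for parcel/IC features).
The tenfold protocol: per fold, 10% test; of the remainder, 15% validation
(13.5% overall) and the rest training (76.5%) — at a 409-scan cohort this is
the 314/55/40 split.  Feature selection (per-edge Pearson correlation with
age, Benjamini–Hochberg FDR at 0.05; the single-group variant uses
uncorrected p < 0.01) and the linear ε-insensitive SVR (C = 1, ε = 0.1,
features standardized by training-fold statistics) see the training fold
only.  Bias adjustment fits actual = a·predicted + b on the validation fold
and applies the affine map to test predictions; when the bias is exactly
affine this inverts it exactly.  Folds with empty selections are skipped and
logged.  The cross-acquisition protocol draws half the training cohort per
repeat, splits it 85/15, sums the significant positively age-correlated
edges into one global-network-strength feature, fits ordinary least squares,
bias-adjusts on the 15%, and evaluates on the full second cohort; 100
repeats by default.

The percentage of FC edges passing selection is reported as the share of the
latent space carrying age information; the per-latent-dimension count is
recoverable from the selection mask.

## Network mapping and group contrasts

Latent timecourses are concatenated over subjects, reduced by PCA to 30
components, and unmixed with extended Infomax (via mne); components are
rescaled to unit temporal variance, ordered by the latent-space variance
they explain, and are defined up to permutation and sign.  Each latent basis
is rendered on the cortex by the random-scaling covariance method: decode
s·b for n = 1000 standard-normal factors s and take, per vertex, the sample
covariance between s and the decoded activity.  Factors are drawn
antithetically (each draw paired with its negation), which halves the
Monte-Carlo variance contributed by even decoder components and makes the
map of −b exactly the negation of the map of b; for a linear decoder the map
is proportional to D·b.  Maps are sign-fixed so the strongest-|value| vertex
is positive (ties to the lower index) and thresholded at 15% of the maximal
absolute value for display.

Cross-group comparison pairs bases greedily by absolute Pearson correlation
(strongest remaining pair first); an optimal-assignment variant exists as an
oracle for small component counts, and the two agree on signed permutations.
Reproducibility curves repeat ICA with independent seeds per group and
average the top-k matched |r|.

Group contrasts: per-subject component variance is the sample variance of
W·μ_z; variances are correlated with age across subjects with BH-FDR over
components.  Age groups default to young ≤ 39 weeks and old ≥ 43 weeks
(thresholds inclusive).  Dual regression is ordinary least squares of each
subject's latent timeseries on that subject's component timecourses
(variance-normalized per subject, so a louder component shows up in the
spatial weights), averaged over the group for the chosen component; group
differences are taken between latent bases *before* decoding.

## Synthetic data: what it emulates, and what it does not

The generator stands in for two access-restricted infant cohorts.  A
subdivision-s icosphere per hemisphere (V = 10·4^s + 2 vertices each; right
hemisphere a mirrored copy; radius 40 mm; 5% of vertices nearest the medial
pole masked) carries K unit-norm smooth random network maps (white noise
smoothed at 10 mm FWHM).  Per subject: age uniform in 24.29–44.87 weeks;
network timecourses are stationary Gaussian AR(1) with coefficient 0.3
(mimicking BOLD autocorrelation and making bandpass behaviour observable)
and marginal covariance

    Σ(age) = base_cov + (age − age₀) · age_effect ,   age₀ = range midpoint;

vertex data are maps-projected timecourses plus white noise, standardized
per vertex.  base_cov is the identity plus a 0.2 coupling of the first two
networks.  The age effect is a dense symmetric slope matrix: a uniform
positive drift on the couplings (developmental connectivity predominantly
strengthens) plus random per-pair variation, scaled so its largest
eigenvalue magnitude is 0.04/week — since Σ(age) is linear in age and the
PSD cone is convex, validity at the range endpoints guarantees validity
everywhere, and 10.3 × 0.04 stays below the baseline's smallest eigenvalue.
This magnitude makes the chance-normalized cross-validated age-prediction
error land around one half, a clear but not dominant developmental signal.
Acquisition profiles: `dhcp_like` (T = 1400, TR = 0.392 s, noise sd 0.04)
and `dbi_like` (T = 150, TR = 2.0 s, noise sd 0.08).

Not emulated: hemodynamic forward modelling, motion artifacts beyond a
synthetic framewise-displacement series, volumetric preprocessing,
registration error, and any nonlinearity in the mapping from networks to
vertices (the generative model is linear; the VAE's advantage over a k-rank
linear basis on these data comes from capacity, not from nonlinear
structure).  Passing tests therefore demonstrate correct mechanics and
recoverability of known structure, not performance levels on real infant
data.

## Problem sizes and numerical choices

The test suite trains two models of the full architecture on 2,000 frames
(10 subjects × 200 frames, 32×32 grids) for 20 epochs — one on a K = 5
cohort for network-recovery and group-contrast tests, one on a K = 40 cohort
for the reconstruction-ordering test (a rank-30 linear basis is near-optimal
on rank-5 data, so the ordering against a 256-latent model is only
informative when the data dimensionality exceeds the basis rank).  Age
prediction uses a 300-scan cohort at T = 250.  The leakage guard runs the
pipeline on a cohort whose generative age effect is exactly zero, with
uncorrected feature selection — BH-FDR correctly selects nothing on null
data, which would leave no model to probe — and requires the pooled MAE not
to beat 1000 age permutations.

Normalization uses the population variance convention (divide by T);
constant series standardize to zero.  Bandpass is a zero-phase
forward–backward Butterworth of order 4.  Vertex order is left hemisphere
then right, 0-based.  Motion selection keeps the n smallest framewise
displacements with ties to the earlier frame.  The internal container is
HDF5 with a JSON metadata attribute (schema versioned); CIFTI-2 and GIFTI
readers/writers use nibabel and store float32 payloads.  Checkpoints
(npz + JSON sidecar) round-trip encodings bit-exactly.

## Known limitations

Geodesic distances are edge-graph approximations; smoothing kernels within
one edge length of the mesh resolution degenerate toward the identity.  The
Infomax implementation is delegated to mne and is deterministic only per
seed.  The NumPy network trains single-threaded BLAS-bound; full-resolution
(192×192) training is possible but slow, and the package ships no pretrained
weights.  The single-feature transfer model presumes globally increasing
connectivity with age; cohorts dominated by decreasing couplings would need
the sign convention flipped.
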