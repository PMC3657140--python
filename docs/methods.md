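# Methods

`emoconn` re-implements, as a tested pipeline on synthetic data, an
effective-connectivity analysis of emotional face processing in a
four-region right-hemisphere network — primary visual cortex (V1), fusiform
gyrus (FG), amygdala (AMY) and lateral orbitofrontal cortex (OFC) — in two
cohorts: healthy controls (HC) and remitted major depressive disorder
(rMDD). The scientific claim the synthetic ground truth encodes is a
group-by-valence *reversal*: the modulation pattern HC show for sad faces
(bidirectional OFC–AMY and OFC–FG coupling changes) is the pattern rMDD
show for happy faces, and vice versa (a single FG–OFC connection, backward
OFC→FG in HC-happy, forward FG→OFC in rMDD-sad).

## Task design

The task is a fixed pseudorandom block design over neutral (N), happy (H),
sad (S), fearful (F) faces and rest (R): order `NHNSNFNRSNHNFNRFNSNHNR`,
22 blocks of 21 s (six faces per block, 3 s each with a 500 ms gap), 462 s
total. Volumes are sampled at TR = 2.1 s; the default acquisition is 218
volumes (457.8 s), truncating the final rest block, with a flag for full
220-volume coverage. Input functions are unit boxcars on a microtime grid
of 16 bins per TR: an all-faces driving input (active on the 19 non-rest
blocks, 399 s in total) and one modulator per emotion. Fear blocks exist in
the design but carry no modulation in any generative truth and are not
analysed; whether button-press events should enter as nuisance regressors
is unknowable from the design alone, and they are omitted.

## Generative model

Neural dynamics are the single-state bilinear form

    dx/dt = (A + Σ_j u_j B_j) x + C u,

with `A` intrinsic coupling (Hz; strictly negative self-connections), `B_j`
the change in coupling under modulatory input `u_j`, and `C` driving-input
gains. Each region's BOLD signal follows the balloon–windkessel model
(vasodilatory signal s, flow f, venous volume v, deoxyhemoglobin q):

    ds/dt = x − κs − γ(f − 1)        df/dt = s
    dv/dt = (f − v^{1/α}) / τ        dq/dt = (f·E(f,E0)/E0 − v^{1/α} q/v) / τ

with E(f, E0) = 1 − (1 − E0)^{1/f}, and observation
y = 100·V0·ε·[k1(1−q) + k2(1−q/v) + k3(1−v)] with 1.5 T coefficients
k1 = 7E0, k2 = 2, k3 = 2E0 − 0.2, V0 = 0.04, reported in
percent-signal-change-like units. Defaults: κ = 0.64 s⁻¹, γ = 0.32 s⁻¹,
τ = 2.0 s, α = 0.32, E0 = 0.4, ε = 1.

**Integration.** Task inputs are piecewise constant, so the neural
subsystem is piecewise LTI: each microtime bin is advanced by the exact
matrix-exponential propagator of its input configuration (computed once per
distinct configuration via a scaled-Taylor expm of the affine-augmented
matrix, including the exact half-bin state). The hemodynamic states use
classical RK4 driven by the exact neural values at the bin endpoints and
midpoint. The compiled loop reproduces a high-accuracy adaptive ODE solve
to ~1e-5 relative error at 16 bins/TR, and halving the resolution changes
the output by well under 1e-3 relative. Unstable coupling configurations
(any eigenvalue of A + Σ u_j B_j with non-negative real part) are rejected
with the offending eigenvalue named.

## Synthetic cohorts

Each subject's couplings are drawn from population Gaussians
(between-subject SD 0.1 Hz) truncated to dynamical stability (at most 100
redraws). The modulatory truth per cohort and emotion follows the reversal
above; the all-faces drive has mean C = 0.8 Hz into V1. Modulation is
asymmetric by direction: mean +0.7 Hz on forward (up-hierarchy) modulated
edges and +0.5 Hz on backward ones. Two considerations fix these values.
Detectability: at noise equal to the signal (SNR 1), a modulated edge must
contribute clearly more evidence per subject than its Occam cost
(~1–2 nats) for an eight-subject fixed-effects selection to be stable,
which rules out weak uniform modulation. Stability: strong *uniform*
positive modulation of reciprocal pairs destabilizes the mean
configuration itself (truncated sampling would then draw from a biased
tail), while forward-dominant modulation keeps the effective coupling
near-skew; every attained mean configuration is stable, with the tightest
(the four-edge bidirectional pattern) at spectral abscissa −0.11, so
occasional per-subject redraws occur but the sampled population stays
close to its nominal distribution. All modulated edges remain positive — couplings strengthen
during the emotion's blocks — which the PPI group-difference directions
rely on. These are one-time design choices of the synthetic population,
not fitted quantities.

The intrinsic means are heterogeneous by design. Two structural facts force
this. First, a fully connected network with uniform +0.3 Hz couplings and
−0.5 Hz self-connections is *unstable* (the adjacency spectral radius
exceeds the self-inhibition), so feedback (down-hierarchy) connections are
made inhibitory — consistent with the inhibitory top-down cortico–limbic
coupling this literature describes — giving a near-skew, robustly stable
coupling matrix. Second, if AMY and OFC have symmetric in/out couplings
their neural time courses are nearly collinear, and no amount of data can
attribute a modulated afferent of FG to its source region (the "which
single edge" question the model space asks). The default per-edge means
(V1→FG 0.40, FG→V1 −0.15, FG→AMY 0.30, AMY→FG −0.25, FG→OFC 0.20, OFC→FG
−0.35, AMY→OFC 0.35, OFC→AMY −0.20 Hz) and per-region self-connections
(V1 −0.6, FG −0.5, AMY −0.9, OFC −0.35 Hz; fast transient amygdala, slow
integrating OFC) break both degeneracies while keeping every region's
evoked response strong enough for the activation-based inclusion rule. These are one-time choices of
realistic magnitude, not quantities fitted to any outcome.

Observation noise is i.i.d. Gaussian calibrated per subject so that
std(noiseless signal)/noise SD equals the cohort `snr` (default 1), plus a
random second-order Legendre drift. MADRS-like symptom scores are
half-normal (σ = 1.5 HC, σ = 3.5 rMDD), echoing the groups' ordering
without claiming exact moments. A configurable fraction (default 25%) of
subjects receives a ten-fold attenuation of OFC afferents so the
activation-based inclusion rule has real work, mirroring the study's
retention of 21/29 and 22/30 subjects. The manifest (subject id, group,
cohort seed, subject index, symptom score) regenerates every series
bit-for-bit.

What the generator does *not* emulate: spatial acquisition and motion,
physiological (cardiac/respiratory) noise, AR(1) temporal autocorrelation
(an option, off by default), scanner drift beyond second-order polynomials,
and any regional heterogeneity of the hemodynamic response beyond the
parameters above. Passing tests therefore demonstrate internal validity of
the pipeline under the stated model, not performance on real fMRI.

## Region extraction and inclusion

The high-pass cutoff is "twice the maximum stimulus repetition time", read
as 2× the longest interval between consecutive onsets of the same stimulus
condition (378 s for the published order); filtering regresses out the
discrete-cosine components with longer periods and the mean. Activation is
an OLS t test of the faces-versus-rest contrast (mean of the four condition
regressors, canonical double-gamma HRF) with drift columns as nuisance; a
subject is included iff every region shows p < .05 (one-sided) activation
with a local maximum within 14 mm of the group maximum. At patch scale the
group coordinates are fixed labels. Sphere extraction takes the first
right-singular direction of the centered time×voxel matrix, scaled to the
mean voxel SD, sign-aligned with the sphere-mean series.

## Model space

Stage 1 holds seven structural candidates (serial feedforward, skip and
feedback variants, and the fully interconnected winner with V1↔FG and all
six directed edges among FG/AMY/OFC), all driven at V1. Stage 2 places 21
modulation profiles on the winner, in seven families: F1 the six
single-edge models (model 2 = forward FG→OFC, model 5 = backward OFC→FG);
F2–F4 the three single bidirectional pairs; F5–F6 nine two-edge
non-reciprocal patterns split by amygdala involvement; F7 the three
double-bidirectional models (model 21 = OFC↔AMY + OFC↔FG). The printed
constraints pin F1, F7 and models 2/5/21; the remaining family memberships
are a documented default in a table-driven builder, so an alternative
enumeration is a data edit rather than a code change.

## Inversion (variational Laplace)

The observation model per subject and candidate is y = g(θ) + X0·β + ε with
g the forward model, X0 Legendre confounds (projected out of data and
prediction; degrees of freedom adjusted), and ε i.i.d. Gaussian with one
precision hyperparameter shared across regions. Priors are zero-mean
shrinkage Gaussians: variance 0.25 Hz² for intrinsic, modulatory and
driving rates; self-connections −0.5·exp(θ), θ ~ N(0, 0.0625); global
log-scales on κ, τ, ε ~ N(0, 0.0625); remaining balloon constants pinned
(zero prior variance pins any parameter).

Fitting is Gauss-Newton ascent on the free energy F with Levenberg damping
(step accepted only if F does not decrease; damping ×4 on rejection, ×0.4
on acceptance) alternated with the closed-form EM update of the noise
precision π = Ñ/(‖e‖² + tr(JᵀJ·Cθ)). Convergence: ΔF < 0.01 nat on three
consecutive accepted steps, max 64 iterations. The Jacobian uses central
finite differences (step 1e-3); forward differences are offered but were
observed to stall on shallow plateaus several nats below the optimum, which
is fatal when model evidences are compared. F is exact for a linear-Gaussian
model, which the tests verify against the closed-form marginal likelihood;
the accepted-step F trace is monotone by construction.

Model scoring fits each of the 21 candidates per subject and emotion with
the *complementary* emotion included as a free nuisance modulator on all
six candidate edges — identical across candidates, so evidence differences
isolate the emotion of interest. Leaving the other emotion unmodelled was
shown to bias selection toward wrong single-edge models even on noiseless
data; the single-modulator variant remains available
(`RunConfig.nuisance_other_emotions = False`). Inversion inside the
pipeline integrates at 8 microtime bins per TR (data are simulated at 16);
the induced model error is common to all candidates.

Candidates are fitted up the model lattice with dual initialization: an
unmodulated null model first (which settles the intrinsic couplings,
drive and hemodynamics), then the 21 candidates in order of increasing
edge count, each fitted twice — once cold from the prior mean and once
warm from the posterior of its best-fitting strict subset — keeping the
better optimum. This matters because the free-energy landscape is
multimodal: started cold at the zero prior mean, a multi-edge candidate
must raise its modulatory rates while the intrinsic couplings are still
near zero — a region where strong reciprocal modulation is dynamically
unstable — so the ascent stalls and the candidate's evidence is
understated by 5–20 nats; conversely a single rich reference fit can
misassign modulation between edges and propagate the error to every
warm start, and for some data realizations the cold start is the one
that finds the better basin. The dual schedule is identical for every
candidate, so it does not bias the comparison.

## Bayesian model selection

Fixed effects by default: group log evidence is the sum of per-subject free
energies; model posteriors are a log-sum-exp-stable softmax of log prior +
group evidence. Family inference gives each family a uniform prior split
equally among members (family size therefore does not bias selection), sums
member posteriors into family posteriors, picks the winning family, and
renormalizes within it for the winning model. A random-effects alternative
(variational Dirichlet over model frequencies) is available. Log-evidence
differences are labelled weak/positive/strong/very strong at 1.1/3/5 nats
(closed lower bounds).

## PPI

The psychological vector is +1 on the contrast emotion's volumes, −1 on
neutral volumes, 0 elsewhere; the interaction regressor is its elementwise
product with the amygdala seed series, which is used directly as the
"neuronal" series (an optional Wiener deconvolution by the canonical HRF is
provided but off by default). The interaction beta is OLS with the
physiological and psychological mains and drift partialled out. The group
comparison is a two-sample t test per target with Bonferroni correction
over the composite FG + OFC set (random-field FWE requires whole-brain
geometry, out of scope); symptom correlations are Pearson r with exact
t-based p in the rMDD group.

## Problem sizes and numerical choices

Desk-scale defaults, chosen once as the package's own study conditions:

- parameter recovery: 20 subjects, true sad model 21 (happy truth as
  its true profile or nuisance), snr 1, full 218-volume design;
- reversal selection: 6 subjects per group, one seeded replicate per
  group × emotion cell, weak-OFC fraction 0 (the inclusion rule is
  exercised separately), 4 × 21 model fits per subject;
- PPI calibration: 200 planted-beta replicates, 400 null group
  comparisons; GLM type-I calibration: 1000 null fits.

Degenerate inputs are rejected loudly: empty or malformed block orders name
the offending position, unstable parameter draws name the subject, missing
evidence cells name subject and model, tampered evidence caches raise a
provenance error. Ties in BMS resolve to the lowest model id via argmax;
the eigenvariate sign convention follows the sphere mean.

## Known limitations

- Free energies depend mildly on the inversion's integrator resolution;
  comparisons are valid because all candidates share one setting.
- Single-edge source attribution (model 4 vs 5) is near the identifiability
  limit at snr 1: after the rival model co-adapts its other parameters, the
  residual evidence for the true source is ~0.3 nats per subject, so group
  pooling, not single subjects, carries the claim.
- Local optimization is the binding accuracy limit for model comparison.
  The free-energy landscape under strong modulation contains basins,
  separated by gradient barriers, that attribute an emotion's signal to
  different edges. The dual-initialization lattice reaches the correct
  basin for most subject-model pairs, but occasionally a subject's
  true-model fit stalls 10–40 nats below its optimum while rival fits
  reach theirs, and a fixed-effects group sum inherits that asymmetry:
  one such subject can flip a group selection toward a superset
  neighbour of the true model even though, at the actual optima, the
  models differ by only a few nats. Verifications with
  true-parameter-initialized fits show the correct group ordering would
  be recovered by a global optimizer. Multistart beyond the dual schedule
  would reduce (not eliminate) the effect at proportional compute cost.
- The generator's effect sizes are stated choices; no claim is made that
  they match the original study's (unpublished) parameter scales.
- The RFX implementation estimates expected model frequencies only; no
  exceedance probabilities.
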