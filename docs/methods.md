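# Methods

This note records the models implemented, the defaults and why they were
chosen, what the synthetic generators do and do not emulate, and the places
where the design was genuinely open.

## Spectral model and quantification

Edited spectra are modeled with Gaussian lineshapes only: GABA+ as a single
Gaussian at 3.0 ppm (present in editing-ON acquisitions only) and Glx as a
symmetric two-Gaussian doublet centered at 3.75 ppm with a 0.08 ppm split.
No J-evolution, basis sets, Lorentzian/Voigt shapes, phase errors or
eddy-current effects are simulated: the generator's purpose is to provide
spectra whose difference-peak areas are *exactly* proportional to known
concentrations, so the downstream fitter can be validated against closed
forms (Gaussian area = amplitude · σ · √(2π)). In the generator the Glx
doublet appears in both ON (1.5×) and OFF (0.5×) so the ON−OFF difference
carries exactly one area-per-unit-concentration; the GABA+ peak is ON-only.

Fitting uses nonlinear least squares of (Gaussian + linear baseline) over
2.8–3.2 ppm for GABA+ and (doublet + linear baseline) over 3.55–3.95 ppm for
Glx. Quality metrics follow the Gannet-style conventions: fit error = 100 ×
SD(residual)/amplitude over the fit window; SNR = amplitude / (2 × SD of the
detrended 9–10 ppm noise region). These definitions are stand-ins with the
right scaling behavior; they are not numerically comparable to any specific
Gannet version's output. Non-convergence never raises — the FitResult is
flagged with infinite fit error so QC can act on it.

Water-referenced quantification uses

    conc = (area / water_area) · 55,556 mM
           · (f_GM·0.78 + f_WM·0.65 + f_CSF·0.97) / (1 − f_CSF)

with the standard relative water visibilities per tissue class. Relaxation
(T1/T2) correction is omitted; it cancels in the EIB ratio, which is the
quantity of interest throughout. MM correction reports 55% of GABA+ (45%
macromolecular contribution). Frequency alignment is a cross-correlation
shift within ±0.1 ppm against the first spectrum, ties broken toward zero
shift; time-domain spectral registration is out of scope.

QC exclusion standardizes each quality metric per (metric, session) cell
across subjects and excludes a subject once ≥2 cells reach |z| ≥ 1 — two
different metrics, or the same metric in two sessions, both trip the same
counter. Per-cell (rather than pooled-session) standardization was chosen so
the "same metric in two sessions" route remains meaningful.

## Sliding-window kinetics

One ON/OFF pair spans 2 TR = 4 s; pair k's midpoint is (k − ½)·4 s. Windows
are 60 pairs long and advance 3 pairs (12 s): 112 task pairs → 18 frames.
The 96-pair rest session is reduced to the shared 12-frame dimension by
discarding *leading* pairs — exactly the 3 pairs the 12-window grid cannot
cover, so the grid ends flush with the session. Leading (not trailing)
trimming reflects the steady-state rationale: the first seconds of a rest
acquisition are the least stationary.

Per frame, EIB is computed from that frame's own Glx and GABA+ fits, *then*
the EIB curve is cleaned and normalized; deriving EIB from separately
normalized metabolite curves gives a different (and rejected) quantity, so
the order is fixed. Outlier frames deviate from the curve median by more
than 2.0 robust SDs (1.4826 × MAD) and are replaced by the median of their
original neighbors (single neighbor at endpoints), which makes the operation
idempotent and order-independent. Normalization divides by the first frame;
AUC integrates (normalized − 1) by trapezoid with unit spacing so a flat
curve scores exactly 0. Time-to-peak/slope/zero-crossing metrics are
deliberately absent: with 12–18 frames they are dominated by transients.

## Visibility-graph features

The natural visibility criterion is strict (collinear points do not see each
other), applied with the running-maximum-slope formulation, O(n²) worst
case. Uniform frame spacing is assumed; the spacing constant cancels.
Degree distributions include the boundary nodes (first node in-degree 0,
last node out-degree 0); excluding them is a config choice that was
considered and rejected as the default because every frame carries
information at these series lengths. The KLD restricts both degree
distributions to their common support and renormalizes before summing
P̃_out ln(P̃_out/P̃_in): this guarantees a finite, non-negative divergence
(Gibbs) without arbitrary zero-bin smoothing. Exactness caveat: visibility
involves strict comparisons of slopes, so symmetry properties (time
reversal, affine invariance) hold exactly in exact arithmetic and are tested
with integer-valued series where IEEE division is exact enough to preserve
every tie.

## CAP analysis

The seed is a sphere in mm space; a voxel belongs to the mask when its
center lies within the radius (10 mm default; 171 voxels on a 3 mm grid
centered on a voxel). Frame selection uses the *positive* tail (z > 1) by
default — these are activation CAPs; a two-sided switch exists. Selected
frames are row-normalized to zero mean/unit norm before Euclidean k-means
(n_init = 20, fixed seed), which makes assignment correlation-driven; CAP
maps are arithmetic means of the raw member frames, z-maps divide by the
standard error. Clusters are renumbered by descending size for determinism.

k is selected by consensus clustering: 100 subsample replicates (80% of
frames) per candidate k, consensus matrix of co-assignment frequencies among
co-sampled pairs, stability = 1 − PAC with the ambiguous band (0.1, 0.9).
**Tie-break: equal stability goes to the larger k.** Merging well-separated
clusters is itself perfectly stable (under-clustering produces no ambiguous
pairs — a known degeneracy of PAC), so among equally stable candidates only
the finest partition recovers planted structure; non-tied cases are
unaffected.

Temporal metrics over T frames and T−1 transitions: occurrences (% of
frames), resilience (self-transitions / (T−1)), in-degree (entries / (T−1)),
out-degree (exits / (T−1)), and betweenness centrality of the state's node
in the directed transition-count graph with distance 1/count, normalized
(K(K−1) ordered pairs for K+1 nodes), CAP₀ included. Persistence curves
evaluate, per fMRS-matched window (window boundaries rescaled
proportionally from pair indices to frame indices), the probability
#(cap→cap)/#(transitions starting in cap), 0 when the CAP never starts a
transition — the conditional-self-transition reading; a per-window occupancy
variant would measure something else and is not the default.

Template matching is plain Pearson correlation over voxels on an identical
grid (no silent resampling), accepted strictly above r = 0.3.

## PLSC

R = YᵀX/(n−1) on column-z-scored blocks; SVD gives paired loading vectors,
scores are the block projections. X defaults to 5 CAP metrics × 4 sessions
(20 columns), Y to 2 EIB visibility features × 4 sessions (8 columns),
metric-major order; both-features mode is the default and a KLD-only mode
exists, since which "EIB temporal scores" enter the block is genuinely open.
Permutation shuffles Y's rows and compares each component's singular value
to its own null (no Procrustes realignment — a documented limitation for
components beyond the first); the add-one estimator keeps p > 0. Bootstrap
resamples subjects, sign-aligns replicate loadings to the original by inner
product, and reports percentile 95% CIs; a loading is "reliable" when its CI
excludes 0. Sign convention: the largest-|loading| X entry of each component
is positive.

## Behavior

d′ = Φ⁻¹(hit rate) − Φ⁻¹(FA rate) with the log-linear adjustment
(x + 0.5)/(n + 1) applied to *all* rates, not only perfect ones — the
continuous variant avoids a discontinuity between 35/36 and 36/36; the
perfect-scores-only mode is available. Trial scores: RTn clamps
(RT − 400)/400 into [0, 1]; hit = 1 − RTn (slow hits can reach the miss
floor 0; a configurable hit floor can lift them), miss = 0, correct
rejection = 1, false alarm = 0.25 × (1 − RTn) so the fastest FA scores 0.25
and slower FAs score lower. Windowed behavioral curves reuse the fMRS window
boundaries mapped onto the trial timeline (trial t starts at (t−1) × 2.5 s,
blocks concatenated); empty windows carry the previous value forward with a
warning; the AUC baseline is the first window, mirroring the kinetics
normalization.

## Group inference

Kruskal–Wallis H (tie-corrected, χ² reference with g−1 df, reported in the
χ²(df, N) convention). Post hoc: Dunn z-tests on pooled mean-rank
differences with the tie-corrected rank variance, FDR (Benjamini–Hochberg)
adjusted by default, Bonferroni available. The post hoc method is pinned to
Dunn because mean-rank differences are the reported effect measure.

## Synthetic generators: what they emulate and what they do not

* **Metabolite kinetics**: programmable relative-concentration shapes
  (flat, step, ramp-plateau for the rapid excitatory Glx response, biphasic
  rise-then-decline for GABA), i.i.d. Gaussian pair noise, and pair-level
  outliers injected at |z| = 6 (a nominal 5%-of-baseline scale keeps them
  injectable in noiseless runs). Not emulated: scanner drift, motion,
  lipid/MM baselines, hardware instabilities — so passing recovery tests
  shows the *estimator chain* is correct, not that real-data nuisance is
  handled.
* **BOLD sessions**: a latent Markov chain over CAP₀ + K spatial patterns
  with Gaussian emission noise and an additive seed-sphere boost during
  active states. The default chain is hub-dominated (sticky CAP₀, active
  states decaying back to it) so that supra-threshold seed frames are a
  minority, as in real seed-based CAP analysis. No hemodynamic convolution,
  spatial autocorrelation, or physiological noise. One structural
  consequence: with 1/count distances every shortest path routes through
  the dominant CAP₀ hub, so active-CAP betweenness is constantly 0 in this
  regime; the pipeline drops zero-variance metrics from the PLSC block
  rather than impute (recorded in `plsc_result.json`).
* **Behavior**: exact design constants (4 blocks × 44 trials, 9 congruent
  per block), Bernoulli hit/FA responses, truncated-Gaussian RTs. No
  sequential dependencies, learning or fatigue.

All generators are pure functions of (parameters, seed).

## Validation problem sizes

The validation suite uses desk-scale sizes chosen to make each check
statistically decisive: visibility-graph equivalence against an O(n³)
brute-force oracle on 200 random series of length ≤ 50 (one third of them
integer-valued to stress ties); PLSC permutation type-I calibration over
500 null simulations at 200 permutations (n = 20), compared with 0.05
within 3 binomial SDs; Kruskal–Wallis null calibration over 1000
simulations of 4 × 12 Gaussian groups; CAP planted-model recovery from one
1200-frame session on a 6×6×6 grid with 4 patterns at emission noise 0.5
(Monte-Carlo SDs for occupancy/resilience estimated from 300 independent
chain replicates); noiseless spectral recovery to <1%; conservation
identities on 1000 random state sequences; and directional recovery of a
15% 2-Back Glx increase (4% noise, 2% between-subject jitter, 2% outlier
rate) in ≥80 of 100 simulated 12-subject cohorts. The bundled pipeline
demo (12 subjects, consensus over k = 2…6 with 30 subsamples) completes in
about a minute on one core.

## Known limitations

* The spectral fitter inverts only the lineshapes the generator emits;
  real MEGA-PRESS spectra need a full-featured fitter upstream.
* Permutation p-values beyond the first latent component ignore axis
  rotation under permutation.
* The fMRS→fMRI window mapping assumes the two modalities cover the same
  session timeline proportionally.
* Tissue fractions are inputs; segmentation/coregistration are out of
  scope, as are voxel-wise mass-univariate fMRI statistics.
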