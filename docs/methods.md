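# Methods

This note records the models implemented in `forkstat`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the underlying procedures
are conventionally under-specified.

## Coordinate and unit conventions

Positions are continuous nanometres with the origin at the outer corner of
camera pixel (0, 0); pixel (i, j) spans [j·a, (j+1)·a) × [i·a, (i+1)·a)
nm for pixel size a (default 65 nm), so a pixel centre is at
((j+0.5)·a, (i+0.5)·a). This single convention is used by the simulator,
the fitter and all spatial statistics. SMLM tables are always nm, fiber
tables always µm (1 µm = 2.59 kb of DNA), dose tables µM; the unit is
stated in each CSV dialect header. Distance histograms use half-open
(lo, hi] bins, which makes self-pairs (distance exactly 0) drop out of the
auto pair-correlation without a special case.

## Synthetic SMLM movies

Each emitter is rendered as a **pixel-integrated** 2D Gaussian: the photon
fraction in a pixel is the product of error-function differences across
the pixel edges, not a centre-sampled density. At 65 nm pixels and
σ = 143 nm, centre sampling would misallocate photons by several percent;
integration conserves photons to the PSF tail clipped at the field border
(emitters within 3σ of an edge are flagged `clipped` in the truth table).
A uniform background is added and per-pixel Poisson noise applied. Camera
read noise is deliberately omitted: the fitter and the CRLB below assume
pure Poisson statistics, and adding a read-noise model without also
changing the likelihood would make the ground truth inconsistent with the
estimator.

Blinking is a two-state per-frame Markov chain (on→off with probability
`blink_off_rate`, off→on with `blink_on_rate`), started from its
stationary distribution. No published photophysics parameters exist for
the dyes as imaged, so defaults are chosen for testability: the linking
benchmark uses on_rate = 0.005, off_rate = 0.98 over 2000 frames — a mean
on-time of about one 30 ms frame, which is in the range of a fast-cycling
STORM dye and, importantly, makes the ground-truth "blinking event" count
well-defined (see *Linking* for why long on-times and a 2.5×-precision
gate are fundamentally in tension).

All generators are pure functions of (configuration, seed): identical
inputs give bit-identical outputs.

### What the generator does not emulate

Spectral crosstalk, stage drift, sCMOS pixel-dependent noise, astigmatic
3D PSFs, dipole-orientation PSF distortions, and non-uniform background.
Tests passing on this generator therefore demonstrate correctness of the
estimators under their stated model, not robustness to every real-world
artefact.

## Detection

Frames are filtered with two Gaussian kernels (σ = 143 nm and 286 nm —
the PSF scale and twice it); the large-kernel image is subtracted from the
small one and strict 8-neighbourhood local maxima of this band-pass above
`dog_threshold` become candidates. The threshold is in photon units of
the DoG response; the default 2.0 sits ≈10 standard deviations above the
band-pass shot noise of a 5 photon/px background (noise σ ≈ √b·‖h₅−h₁₀‖₂
≈ 0.19 photons) while a 1000-photon emitter peaks near 10 photons, so the
operating point is far from both failure modes. Candidates closer than
the ROI half-width (4 px) to an edge are skipped and counted in QC.

## Multi-emitter MLE fitting

Each 9×9 ROI is fitted with μ = b + Σₖ Nₖ·G(x−xₖ, y−yₖ; σ), G the
pixel-integrated Gaussian with **σ held fixed** at the configured PSF
width. Fitting σ jointly would couple it to the multi-emitter model
selection and destabilize the likelihood-ratio gate; a per-dataset σ can
be calibrated separately if the optical PSF differs.

Optimization is damped Fisher scoring (Gauss–Newton on the Poisson
log-likelihood with the expected information matrix), analytic first
derivatives, step-halving on likelihood decrease, convergence when
positions move < 10⁻⁴ px, at most 100 iterations. The procedure has no
internal randomness: the same ROI and initialization give the same fit.

Model selection is greedy: starting from the background-only model,
emitters are added one at a time, each initialized at the largest positive
residual pixel, and an addition is kept only if 2ΔlogL exceeds the
χ²(3 dof) critical value (α = 0.05 by default, configurable). On pure
background this bounds the false-emitter rate at ≈α, verified by Monte
Carlo. Fits whose position leaves the ROI and ROIs that fail to converge
are discarded with QC counts. Emitters fitted from overlapping ROIs
within 1 px in the same frame are de-duplicated keeping the
higher-likelihood fit.

## CRLB and the precision calibration

The per-localization precision is the Cramér–Rao lower bound of the same
pixel-integrated Poisson model: the Fisher information over the fitted
parameters (positions, photon counts, background) is inverted and the
square roots of the position diagonal reported in nm.

Two grids matter. The bound attainable *from a 9×9 ROI* is what the fit
reports — truncating the PSF tails discards position information, so this
value sits well above the infinite-grid bound (≈19% at b→0). The
standalone `crlb()` defaults instead to a grid covering ±6σ, where the
bound has converged; in the b→0 limit it approaches σ/√N up to the
irreducible pixelation penalty, 0.86% at 65 nm pixels and σ = 143 nm
(the classic √(σ²+a²/12) effect). Monte-Carlo RMSE of the fitter sits
within [0.9, 1.3]× the mean reported (ROI-grid) CRLB across N ∈ {500,
1000, 5000}.

The pooled per-localization precisions (mean of the x and y CRLB) are
fitted with a skew-normal by maximum likelihood; the reported "average
localization precision" is the **mode** of that distribution. The raw
location parameter ξ is retained in the calibration object; the phrase
"centre" of a skew distribution is ambiguous between the two, and the
mode is the value a histogram reader would point to. Degenerate all-equal
inputs short-circuit to that value with shape 0.

## Linking localizations into blinking events

A localization in frame f+1 within R = 2.5 × (average precision) of an
active chain's photon-weighted mean extends the chain; chains without a
continuation terminate and emit one event with photon-weighted mean
coordinates. Localizations in the same frame never merge. Ambiguous
continuations resolve nearest-first, ties by photon count then input
order (no assignment rule is conventionally specified). Gating on the
chain mean rather than the last position damps random-walk drift of long
chains; `gate_on="last"` is available.

One structural property is worth stating plainly: with a gate of 2.5× the
per-axis precision σ, the distance between two consecutive localizations
of the same molecule is Rayleigh with scale ≈ √2·σ, so each link step
fails with probability ≈ exp(−2.5²/2·(1+1/k)⁻¹) ≈ 0.2 *regardless of
SNR* — brighter emitters shrink both the jitter and the gate. Chain
splitting is therefore controlled by the number of link steps, i.e. by
the dye's on-time distribution, not by photon count. The linking
benchmark consequently uses fast-switching photophysics (mean on-time ≈ 1
frame), under which the event count matches the ground-truth on-interval
count to within 2% and Σ n_locs over events equals the input localization
count exactly (a conservation invariant, tested).

## Channel alignment

A least-squares affine transform (2×2 linear part + translation) is
fitted from ≥3 matched, non-collinear fiducial pairs; collinearity is
detected from the singular values of the centred moving set. Residual RMS
is reported; generate-and-recover tests hold it ≤2 nm at 1 nm fiducial
noise.

## Pair correlation and "density of A at B"

All A–B pair distances up to r_max are histogrammed (KD-tree cumulative
counts, exact — verified bin-for-bin against an O(n²) scan). Each bin is
normalized by the annulus area summed over reference (B) points, **clipped
to the ROI**: for rectangles the disc–rectangle intersection area is
computed in closed form (signed quadrant decomposition, vectorized); for
polygon ROIs via constructive geometry. This local-area edge correction
makes the CSR expectation flat and the scalar

  density_at_B = mean over B of [count of A within r₀] / area(disc(r₀) ∩ ROI)

equal to the global density of A under CSR (verified within 3 SE over a
20-seed panel). The stored `pdf` is the same edge-corrected profile
normalized to integrate to 1 over the binned range. The integration
radius r₀ defaults to 50 nm — of the order of two localization-precision
FWHMs, small enough to read nanoscale co-assembly, large enough to
average localization jitter; it is configurable because no standard value
exists.

The CSR flatness check (`csr_flatness_pvalue`) performs a χ² test of the
observed bin counts against edge-corrected annulus areas, halving auto
counts to unordered pairs first — ordered double-counting doubles the
count variance and would inflate the statistic. The test is meaningful in
the sparse regime (few neighbours per point within r_max); dense patterns
violate the independence assumption through pair-count correlations.

Auto pair-correlation is the cross form with A = B; half-open bins remove
self-pairs without a correction term.

## Foci and per-nucleus summaries

Foci are DBSCAN clusters (radius eps, minimum neighbours min_pts,
scikit-learn's convention of counting the point itself), with density =
members / convex-hull area; clusters with degenerate hulls are dropped
and counted. The implementation is checked against a brute-force
density-connectivity reference on small inputs. A nucleus enters the
summary only if PCNA-positive — called when its PCNA event density
exceeds 3× the slide background density, a reproducible proxy for the
visual S-phase call — and the per-nucleus statistic is the unweighted
mean focus density; focus-free and PCNA-negative nuclei are skipped with
QC counts. Condition comparisons use the percent-change convention:
per replicate, condition means are divided by the smallest condition
mean; normalized values are averaged across replicates and reported as
percent change against a stated reference condition.

## Fiber assay model

Tract lengths are lognormal per condition in the generator (σ_log = 0.35,
in the range of published fiber-length spreads); a stalled fraction gets
CldU = 0; ssDNA gaps arrive along the CldU segment as a Poisson process
with exponential lengths, trimmed to stay disjoint and inside the
segment. Only IdU-positive tracts are scored. The S1 digestion model cuts
the CldU tract at every gap and reports the junction-attached fragment —
fiber scoring requires the dual-colour junction, so that is the fragment
a measurer would trace; the longest-fragment alternative is a switch.
S1 never lengthens a tract and is the identity on gap-free tables (both
tested as invariants). At the study's design size of 180 fibers per arm,
the simulate → ratio → rank-sum pipeline detects a 2× median ratio
difference at p < 0.001 in ≥95% of 100 seeded runs.

## Rank-sum and t statistics

The Mann–Whitney U test uses midranks; the exact two-tailed p-value is
computed from the U count distribution (Gaussian-binomial recurrence)
when min(n, m) ≤ 8 and no ties are present — the recurrence keeps this
cheap even with a large opposing arm — and equals full enumeration for
every layout with n+m ≤ 10 (tested). Otherwise a normal approximation
with tie correction and 0.5 continuity correction is used; zero rank
variance returns p = 1. No multiple-testing correction is applied
anywhere: per-comparison p-values are the convention for these assays.
The unpaired t-test defaults to the Welch form with
Welch–Satterthwaite degrees of freedom (pooled form available) and
matches direct quadrature of the t density to 10⁻¹⁰.

## Dose-response fitting

The 4PL (variable-slope) model is fitted by Levenberg–Marquardt least
squares with EC50 parameterized as log₁₀EC50 — the scale on which the
curve is symmetric and the CI is well-behaved; the 95% EC50 interval
comes from the parameter covariance at the optimum mapped back through
10^x. Initialization: floor/ceiling from the response extremes, Hill 1,
EC50 at the concentration nearest the response midpoint. Noiseless
curves are recovered to ≥6 significant digits; flat data is flagged
rather than rejected; fitting is scale-equivariant in concentration.

## Problem sizes in the acceptance script

`scripts/acceptance.py` uses 500 fitted ROIs for estimator efficiency, a
20-frame × 10-emitter panel for detection, one 2000-frame 20-emitter
movie for linking, 20/10/5-seed panels for the CSR, flatness and
colocalization statistics, 100 runs for fiber power and EC50 recovery —
sizes at which the Monte-Carlo error of each reported quantity is well
inside the margins discussed above, while the whole script completes in
under a minute on one CPU. All randomness derives from the single
`--seed` argument.
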