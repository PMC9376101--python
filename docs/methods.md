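# Methods

## Measurement model

A fluorophore localized with independent per-axis Gaussian error
σ<sub>xy</sub> at each of two time points, with true in-plane separation
*s*, yields a measured distance *d* distributed as a noncentral χ with
2 degrees of freedom. The difference vector of the two localizations has
per-axis standard deviation √2·σ<sub>xy</sub>, so `d ~ Rice(s, √2 σ_xy)`
and E[d²] = s² + 4σ<sub>xy</sub>². This convention — σ quoted per
localization, per axis — is used everywhere; the Rice scale is always
√2·σ.

Real datasets show punctum-to-punctum variation in localization quality.
We model it as a two-component mixture assigned **per localization**: each
localization draws σ ∈ {σ₁ (probability f₁), σ₂}. Because a displacement
combines two endpoints, its exact law is a *three*-component Rice mixture
with weights (f₁², 2f₁(1−f₁), (1−f₁)²) and per-axis scales
(√(2σ₁²), √(σ₁²+σ₂²), √(2σ₂²)). This endpoint-consistent law
(`measured_distance_pdf`) is what the calibration likelihood and the
forward model use: it is exactly the law of the sampler and of the noise
injected into jump-process simulations, so generate-and-refit recovery is
well-posed. The compact displacement-level two-component form
(`mixture_measured_pdf`), in which a whole displacement is assigned one
error class, is also provided; at the calibrated parameters the two laws
differ by a Kolmogorov–Smirnov distance of about 0.02, which is why the
package does not fit with the two-component form.

**Calibration** fixes s = 0 (fixed, immobile specimens) and maximizes the
likelihood of (f₁, σ₁, σ₂) in unconstrained coordinates (logit f₁,
log σ), Nelder–Mead with 6 starts seeded around the single-component
moment estimate σ² = E[d²]/4. σ₁ ≤ σ₂ is enforced by relabeling (the law
is invariant under component swap). 95% CIs are normal-approximation
intervals from the inverse observed information with a delta-method
transform. When (σ₂−σ₁)/σ₂ < 0.02 the mixture is unidentifiable in its
components (though not at the pdf level) and the single-component fit is
flagged as preferred. Exactly two components are fit; the single-component
log-likelihood is reported alongside for goodness-of-fit comparison.

## True-displacement families

Over one observation timescale τ the true displacement s ≥ 0 is modeled
by one of: exponential (scale, nm), folded Gaussian (μ, σ — half-normal
at μ = 0), Rayleigh (σ), Weibull (k, λ) with density
(k/λ)(s/λ)^{k−1} e^{−(s/λ)^k} — the standard negative-exponent form,
which nests exponential (k=1) and Rayleigh (k=2) — Rice (ν, σ) for
diffusion with drift (ν the drift distance over the lag, σ the
dispersion; fit per timescale without enforcing τ-scaling), and the
analytic 1-D jump law. The jump law is compound Poisson: with mean jump
count m = τ/T and mean jump length L, displacement is zero with
probability e^{−m} (an atom, independent of L) and otherwise has density
e^{−m−s/L} √(m/(sL)) I₁(2√(ms/L)), the closed form of the
Poisson-weighted gamma mixture; the CDF uses the series truncated where
the Poisson tail falls below 1e−10.

## Forward convolution and fitting

The measured-distance density is
f_d(d) = ∫₀^∞ f_d(d|s=S) f_s(S) dS, evaluated by Gauss–Legendre
quadrature (256 nodes by default) over the truth distribution's own
quantile range (10⁻¹⁰ to 1−10⁻¹⁰). Integrating over the truth's support
rather than a fixed interval keeps sharply peaked candidates (e.g. large
Weibull shape) fully resolved, which matters because an under-resolved
spike corrupts the likelihood surface and can manufacture spurious
optima. For the jump family the range is (0, max(d) + 6σ₂), grown by
1.5× until the tail mass beyond it is below 1e−9, and the atom
contributes atom × (pure-noise pdf). Halving or doubling the node count
changes total log-likelihoods by well under 1e−3.

Fitting is two-stage: a least-squares fit of the forward pdf to the
binned histogram (Freedman–Diaconis bins by default; a fixed 30 nm bin
width is available to match the simulation convention) seeds a
Nelder–Mead MLE in unconstrained coordinates, with 3 starts. Exact zero
distances are impossible under the model (density 0 at d = 0) and are
dropped with a warning. CIs are normal-approximation as above. Model
comparison is the likelihood ratio exp(Δ loglik), reported with its
log₁₀; distance fits are rescaled to velocity distributions by dividing
scale-type parameters by τ (shape parameters unchanged). Fits at
different timescales are independent; only the jump-process module fits
across timescales jointly.

## Jump process simulation and global fit

The Gillespie simulator draws waiting times Exp(T) and jump lengths
Exp(L); each jump's direction flips from the previous jump's with
probability P_switch, the first jump taking a random ±1 direction (it has
no predecessor, so no reversal applies). Positions are recorded on the
observation grid 0, 2, …, 40 s. Displacements for the simulation
likelihood are **anchored** at the time-0 observation — one displacement
per particle per timescale — so that the pdf normalization N in the
zero-bin floor 1/(N·w) is literally the particle count; all-pairs lag
extraction remains available (`anchored=False`) and is the default for
*track* data, where pooling all pairs is standard (overlapping pairs are
statistically dependent; a non-overlapping option exists).

Simulated displacements are histogrammed at w = 30 nm; empty bins are
floored at 1/(N·w) to bound rare-event likelihoods. Observed
displacements (subsampled once to ≤1000 per timescale with a fixed seed)
are scored by linear interpolation of the binned density, with the floor
beyond the last bin; all timescales enter with equal weight. The
objective averages the negative log-likelihood over 2 independent
simulations of 10,000 particles with a fixed seed pair per restart —
common random numbers make the stochastic objective a deterministic
function of the parameters (the optimizer cannot chase Monte-Carlo
noise), and averaging two realizations halves the bias any single
realization would impose. Optimization is differential evolution within
bounds (L ∈ [1, 500] nm, T ∈ [0.5, 200] s, P_switch ∈ [0, 1]) plus a
Nelder–Mead polish, with 3 restarts under fresh seed pairs (the restart
count is configurable; more restarts buy robustness at proportional
cost); the best restart wins.

**Profile-likelihood CIs.** Each parameter is scanned on a grid around
its optimum (7 points per side, half-width 20% of the value, 0.15 for
P_switch); the other two parameters are re-optimized at each scan point
(Nelder–Mead, warm-started from the neighboring scan point's solution,
common random numbers; the scan center is first re-polished under the
same seed so it is the true local minimum of the profiled objective). A
parabola with its minimum pinned at the best fit is least-squares-fit to
the negative log₁₀-likelihoods, and the 95% interval is where it rises
0.8338 log₁₀ units (= χ²₁(0.95)/2 in natural log units; on an exactly
quadratic likelihood this reproduces the 1.96σ normal interval to
<0.1%). The parabola is fit only to scan points within 3 log₁₀ units of
the minimum, so far-field anharmonicity of the profile cannot distort
the interval; a non-bracketing or non-convex scan is widened once, then
flagged.

Model pdfs for presentation are rendered from 100,000-particle noise-free
simulations plus the analytic atom e^{−τ/T}; velocity densities are
distance densities rescaled by τ.

## Track pipeline

Localizations are accepted when the subpixel fit center moved ≤2 px and
the fitted spot σ lies within 1.5× of σ₀ = 0.25λ/NA (113.3 nm at
λ = 675 nm, NA = 1.49, giving the band [75.5, 169.9] nm). Per-frame
drift (from an external drift estimator; a constant/linear generator
exists for synthetic fixtures) is subtracted before displacement
computation. Masks: cell = mean threshold of the adhesion-marker image
(closed/opened, small holes removed — a morphological stand-in for
spline boundary smoothing, cosmetic for displacement statistics);
adhesion = Otsu threshold after rolling-ball background subtraction
(radius 50 px default); stress fiber = brightest 2% of the actin time
projection; cytosol by exclusion. Tracks are labeled by the nearest
pixel of their first localization (pixel (0,0) centered at (0,0) nm),
into stress-fiber-only, adhesion-only, both, cortical (inside cell,
neither mask), or unclassified (outside the cell).

Lifetimes are fit as a right-censored exponential (censoring at the
120 s window, left truncation at the minimum detectable lifetime handled
by the memoryless shift): mean = Σ(tᵢ − t_min)/n_events. This is a
reconstruction of a lifetime analysis whose exact original procedure is
not specified; it is exact for exponential turnover and flags degenerate
and all-censored inputs.

## Synthetic data

The generator mirrors the study conditions: 60-frame movies at 2 s
intervals, noise mixture (0.57, 23 nm, 50 nm), exponential lifetimes
(34 s stress fiber, 18 s cortical, 25 s over adhesions), four
populations with jump-process motion at (70 nm, 17 s, 0.3) for stress
fibers and 45–51 nm, 5–10 s, 0.1–0.35 elsewhere, on geometric region
masks (stripes and patches covering all four label combinations). Live
tracks pin their first localization to the source pixel so that
first-point classification recovers labels exactly; all later
localizations carry full noise (the pinning removes noise from a single
point per track and is negligible for displacement statistics beyond
lag-1 pairs that involve the first frame). Multi-timescale jump *study*
data (`simulate_study_displacements`) assigns each simulated particle to
exactly one timescale, so observations are independent within and across
timescales — the regime in which the likelihood's independence
assumption, and hence CI calibration, actually holds. What the generator
does not emulate: spatially varying localization error, photobleaching,
detection/linking failures, track-splitting artifacts, and spatial
correlation of motion between nearby puncta. Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
model, not robustness to those real-data effects.

## Problem sizes and test scaling

The package's own test suite runs calibration recovery at n = 10⁵ × 10
seeds, Weibull deconvolution recovery at 1000 particles × 10 replicates,
the analytic/simulation jump equivalence at 10⁵ particles over a 3×3
parameter grid, and jump-model recovery at the full observation design
(10,000 simulated particles per likelihood evaluation, 20 timescales,
1000 observations per timescale) with 5 seeded replicates and 3 optimizer
restarts per fit — sizes chosen to keep the whole suite in the
tens-of-minutes range on one core while preserving the statistical power
of each check. The acceptance script runs one full chain at the same
per-fit scale.

## Known limitations

- The two-component error mixture is a phenomenological description of
  heterogeneous localization quality; no per-punctum error estimates.
- The jump model is 1-D along an unmodeled orientation; 2-D jump
  geometry and velocity-jump dynamics are out of scope.
- The simulation likelihood treats displacements as independent; for
  all-pairs track data at overlapping lags this is optimistic, and CIs
  there should be read accordingly.
- Profile CIs inherit the Monte-Carlo roughness of the simulated
  likelihood; the parabolic smoothing and common random numbers mitigate
  but do not eliminate it.
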