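# velinfer

Recover true displacement and velocity distributions of tracked
fluorophores from noisy single-particle localizations.

## The problem

Sparse fluorescent labels on slow-moving structures — for example
F-actin fiducials in the cell cortex and in stress fibers — move only a
few tens of nanometers between frames, which is comparable to the
localization error of each fitted spot. The measured planar distance *d*
between two localizations with true separation *s* and per-axis
localization error σ<sub>xy</sub> follows a noncentral χ distribution
with two degrees of freedom (a Rice distribution) with

⟨d²⟩ = s² + 4σ<sub>xy</sub>²,

so raw displacement histograms are biased upward and *stationary*
particles appear to move at √2·σ<sub>xy</sub> per frame. `velinfer`
removes this bias statistically rather than per-track:

1. **Calibrate** the error model from fixed (immobile) specimens. The
   punctum-to-punctum variation in localization quality is captured by a
   two-component mixture: each localization draws its per-axis σ from
   {σ₁ with probability f₁, σ₂ otherwise}.
2. **Deconvolve** by forward modeling: for a candidate true-displacement
   density f<sub>s</sub>(s), the predicted measured density is

   f<sub>d</sub>(d) = ∫₀^∞ f<sub>d</sub>(d | s = S) f<sub>s</sub>(S) dS,

   and the candidate's parameters are fit by maximum likelihood.
   Supported families: exponential, folded Gaussian, Rayleigh, Weibull,
   Rice (diffusion with drift), and the analytic 1-D position-jump law.
3. **Fit physical models across timescales.** A 1-D position-jump
   process — wait an exponential time (mean T), jump an exponential
   distance (mean L), reverse direction with probability
   P<sub>switch</sub> — is simulated with a Gillespie algorithm, pushed
   through the noise model, and fit globally to displacement
   distributions observed at many timescales at once. The fraction of
   particles that have not moved by time τ is exp(−τ/T), independent of
   the jump length. Profile-likelihood 95% confidence intervals use the
   0.8338 log₁₀-likelihood rise rule.

The track pipeline (spot-fit filtering, drift subtraction, region
masking, four-way population classification, multi-lag displacement
extraction, censored lifetime fits) and a synthetic-data generator with
known ground truth round out the toolkit.

## Worked example

```python
import numpy as np
from velinfer import (LocalizationErrorModel, sample_measured_distances,
                      fit_localization_error, DisplacementDistribution,
                      sample_true_displacements, fit_true_distribution,
                      stationary_fraction)

# 1) calibrate the noise model from 100k fixed-cell displacements
truth_noise = LocalizationErrorModel(f1=0.57, sigma1=23.0, sigma2=50.0)
fixed = sample_measured_distances(0.0, truth_noise, 100_000, seed=2)
cal = fit_localization_error(fixed, seed=3)
print(f"f1={cal.model.f1:.3f}  sigma1={cal.model.sigma1:.1f} nm  "
      f"sigma2={cal.model.sigma2:.1f} nm")
# f1=0.586  sigma1=23.5 nm  sigma2=50.5 nm

# 2) deconvolve a Weibull truth from noisy measurements
rng = np.random.default_rng(0)
s = sample_true_displacements(DisplacementDistribution("weibull", (1.5, 1.0)),
                              1000, seed=rng)
unit = LocalizationErrorModel(f1=1.0, sigma1=1.0, sigma2=1.0)
d = np.array([sample_measured_distances(si, unit, 1, seed=rng)[0] for si in s])
fit = fit_true_distribution(d, "weibull", unit, seed=0)
print({k: round(v, 2) for k, v in fit.params.items()},
      tuple(round(v, 2) for v in fit.ci_95["shape"]))
# {'shape': 2.31, 'scale': 1.17} (-0.96, 5.57)

# 3) how much of a stress-fiber-like population is motionless at 2 s?
print(f"{100 * stationary_fraction(17.0, 2.0):.0f}%")   # 89%
```

The first block shows the calibration recovering the generating mixture
(weight and both σ within a few percent at n = 10⁵). The second shows
the forward-convolution MLE on 1000 noisy displacements whose true mean
motion equals the localization error: the scale is pinned down well and
the 95% CI on the weakly identified shape correctly brackets the true
value of 1.5 — the interval width is the honest price of noise the same
size as the motion. The third is the analytic no-jump probability
exp(−2/17): at a
2 s lag, 89% of a population with 17 s mean waiting time has not moved
at all — motion that is invisible in raw histograms because noise fills
in the gap at zero.

A `velinfer` console script exposes the stages (`synth`, `calibrate`,
`classify`, `fit`, `jumpfit`, `jumpsim`, `report`); run
`velinfer --help` for details.

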