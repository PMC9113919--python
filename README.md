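# speedscale

Tools for studying how the visual system estimates stimulus speed from
reflexive tracking eye movements (ocular following responses, OFRs), built
around the idea that motion integration is organised along *speed* and
*scale* axes of the spatiotemporal-frequency plane rather than along spatial
and temporal frequency separately.

The package is aimed at visual/oculomotor scientists and modellers.  It
provides, end to end:

* **Stimulus models** — a packaged catalog of 15 component stimuli
  (drifting gratings, DG, and matched broadband motion clouds, MC) tiling
  the frequency plane along five iso-velocity lines, plus 9 composite
  patterns; spectral envelopes in log-frequency coordinates; desk-scale
  movie synthesis (random-phase Gabor sums for clouds, analytic sinusoids
  for gratings) at controlled RMS contrast.
* **Eye-trace analysis** — Butterworth filtering, central-difference
  differentiation, artifact rejection, blank subtraction, and per-condition
  Gaussian statistics of mean eye velocity over five 50-ms windows,
  including the variability law σ = √μ and its deviation σ_d = σ − √μ.
* **Tuning surfaces** — quadric fits R(x,t) = q0 + q1x + q2t + q3x² +
  q4xt + q5t² over (x,t) = (log₂ sf, log₂ tf), with the separability index
  **Q = −(1 + q4/2q5)** (0 = speed tuned, −1 = separable) and the Θ
  (max speed–scale locus) and Φ (main axis) angles.
* **Nonlinearity analysis** — linear predictions (component-average
  traces), the ratio **R_NL = e_obs/e_pred** per window, separation times
  from 5-ms binned Welch t tests, and a bootstrap trimmed-mean comparison.
* **A dynamic probabilistic channel model** — 722 spatiotemporal channels
  (bivariate Gaussians, ρ = 0.6, weights from a quadratic polynomial
  peaking at 0.21 c/°), a crossed excitatory/inhibitory interaction kernel
  in speed–scale coordinates (excitation along the iso-velocity line,
  inhibition along the scale axis), a population likelihood over log speed,
  and a recursive Bayesian update from a slow-speed prior across 50-ms
  windows — plus maximum-likelihood fitting of its parameters to trial
  velocity distributions and AIC comparison of the with/without-interaction
  variants.
* **Synthetic cohorts** — a generator that emulates the study conditions
  (85 ± 10 ms latency, saturating velocity rise, √μ noise law, ~8%
  artifacts, blank drift), and a model-driven mode that samples trials from
  the channel model's own posteriors for closed-loop parameter recovery.

See `docs/methods.md` for the model, conventions and numerical choices.

## Worked example

```python
import numpy as np
from speedscale import (
    load_catalog, component_map, build_bank, run_windows,
    ParticipantParams, InteractionParams, GroundTruth, generate_cohort,
    process_raw_trials, window_stats, linear_prediction, r_nl, WINDOWS_MS,
)

components, patterns = load_catalog()
cmap = component_map(components)
bank = build_bank()                      # 722 channels, speeds 1-512 deg/s
participant = ParticipantParams(g=0.5)   # gain + slow-speed prior (~12 deg/s)

for label, inter in (("off", None), ("on", InteractionParams.crossed_preset())):
    seq = run_windows(cmap["c1"], participant, inter, bank)
    means = ", ".join(f"{2**seq.mean_log2(w):5.2f}" for w in range(4))
    print(f"c1 posterior mean speed (deg/s), interactions {label}: {means}")

truth = GroundTruth(seed=1)              # phenomenological cohort conditions
cohort = generate_cohort(truth, components, patterns, trials_per_condition=150,
                         conditions=["c2", "c1", "c5", "a"])
trials = process_raw_trials(cohort.trials(0))
print(f"rejected {trials.rejection_fraction:.1%} of trials as artifacts")

stats = {(s.condition_id, s.window): s for s in window_stats(trials)}
pred = linear_prediction(trials.traces, [p for p in patterns if p.id == "a"][0])
for w in WINDOWS_MS[1:]:
    entry = r_nl(stats[("a", w)].mu, pred, w, min_pred=0.5)
    print(f"pattern a, window {w}: R_NL = {entry.r_nl:.3f}")
```

Output:

```
c1 posterior mean speed (deg/s), interactions off: 12.31, 17.39, 17.76, 17.89
c1 posterior mean speed (deg/s), interactions on: 12.31, 18.07, 18.11, 18.13
rejected 7.3% of trials as artifacts
pattern a, window (101, 150): R_NL = 1.005
pattern a, window (151, 200): R_NL = 0.975
pattern a, window (201, 250): R_NL = 1.002
pattern a, window (251, 300): R_NL = 1.007
```

Reading it: the model's speed estimate for the reference stimulus (24 °/s)
starts at the prior mean (12.3 °/s) and sharpens toward the decoded speed
over successive 50-ms windows.  The synthetic cohort's artifact rate lands
near the configured 8%, and because the generator builds pattern responses
as the average of their components, the nonlinearity ratio for pattern `a`
stays at 1 in every window — the null against which real supra/sublinear
integration is measured.

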