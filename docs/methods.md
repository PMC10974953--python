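# Methods

This note records the models, conventions and numerical choices behind
`echovol`, and what its synthetic validation does and does not show.

## Echo model and units

Every trace is modelled as a superposition of Gaussian echoes

    s(t) = β · exp(−α (t − τ)²) · cos(2π f₀ (t − τ) + φ)

with amplitude β (dimensionless), bandwidth factor α ((MHz)²), arrival
time τ (µs), carrier f₀ (MHz) and phase φ (rad, stored wrapped to
(−π, π]). Time is microseconds and frequency MHz throughout, which keeps
exp(−α(t−τ)²) far from float underflow at clinical scales. The
closed-form single-lobe energy E = (β²/2)√(π/(2α)) is valid to <1%
whenever f₀² ≥ 0.2333·α (the neglected spectral cross-term is
exp(−2π²f₀²/α), which equals 1% exactly at that ratio); the function
warns but still answers outside that regime.

A stated spectral bandwidth is mapped to α through the full width at
half maximum of the Gaussian magnitude spectrum, α = π²·BW²/(4·ln 2)
(BW in MHz), so the standard 200 kHz pulse gives α ≈ 0.1424. This is a
convention, not physics; it is invertible (`alpha_to_bandwidth`) and
recorded here because other natural readings (half-power width of the
power spectrum, spectral σ) differ by factors of 2–5.5 and change every
benchmark number downstream.

## Denoising

Traces are decomposed with `bior3.9` (symmetric boundary extension —
near-perfect reconstruction for biorthogonal wavelets; an all-zero
threshold plan reconstructs the input to 1e−10). The default depth is 5
levels for a 500-sample trace at 10 MHz, which places the 1 MHz signal
band in the level-3 details; the hard validity limit is ⌊log₂N⌋, which
is deliberately looser than PyWavelets' advisory maximum because
boundary-padded detail levels below it remain usable.

Thresholds come from a noise-only reference recording of equal length
(transmitter off): per level, σⱼ is the Bessel-corrected sample s.d. of
the reference's detail coefficients and λⱼ = 3σⱼ (the 3σ rule for
Gaussian noise). The adaptive rule's softness exponent is
mⱼ = 1 + 10·Enⱼ/Edⱼ with Enⱼ, Edⱼ the raw sums of squared detail
coefficients of reference and noisy trace (no noise-correction of Edⱼ —
the definition is taken literally). When Enⱼ = 0 the exponent clamps to
m = 1 rather than introducing an epsilon. The transfer function

    |d| < λ:  T = sgn(d)·[ |d|^β/(βλ^{β−1}) + (2(β−1)λ/(πβ))·atan(|d|^m/λ^m) ]
    |d| ≥ λ:  T = d − sgn(d)·(2(β−1)λ/(πβ))·atan(λ^m/|d|^m)

is odd, continuous (T(±λ) = ±λ(β+1)/(2β): 3λ/4 at β = 2, → λ/2 as β
grows), monotone, shrinking, and asymptotically unbiased. β = 10 is the
default shape. The approximation band always passes through unshrunk.

At the benchmark conditions (1 MHz echo, 5 dB input SNR, matched-
variance reference) the adaptive rule gains ≈5.6 dB and dominates both
classical rules; soft thresholding at λ = 3σ is heavily biased (its
output SNR sits ≈2.5 dB below hard), which is the expected behavior of
a 3σ threshold, not a defect. The benchmark echo's amplitude and
arrival (β = 1, τ = 25 µs, φ = 0, mid-window) are fixed conventions of
the harness: SNR is amplitude-invariant, RMSE is not, so reported RMSE
values scale with the chosen β.

## Reference fitting (Gauss–Newton)

The template for cross-correlation is obtained by least-squares fitting
of the single-echo model, residual rᵢ = xᵢ − s(tᵢ; θ), with analytic
Jacobian. Initial values: β̂ and τ̂ from the Hilbert-envelope maximum,
f₀̂ from the discrete-spectrum peak (DC excluded), α̂ = πβ̂⁴/(8Ê²) by
inverting the closed-form energy with Ê the measured trace energy, and
φ̂ = 0 (phase enters smoothly and the optimizer corrects it).

Iteration controls, chosen so the objective is non-increasing across
accepted steps:

* full Gauss–Newton step, backtracking by halving (≤25 times) when the
  objective would increase; if no scale descends, the point is treated
  as stationary;
* a per-iteration relative step cap (no parameter moves by more than
  100% of its scale; τ's scale is max(|τ|, 1 µs)) to prevent wild jumps
  along near-flat directions when the amplitude collapses toward zero;
* Levenberg-style damping μ = 10⁻³·λ_max(JᵀJ) only when cond(JᵀJ) >
  10¹², flagged on the result;
* an admissibility box: τ stays inside the recorded window, α > 0,
  f₀ ∈ (0, fs/2] — an echo outside these bounds is unobservable;
* termination on |f(θₖ) − f(θₖ₊₁)| < 10⁻⁸ or 500 iterations.

Fits that end outside the admissible set raise `FitFailureError`; study
harnesses record such repetitions as failed rather than averaging
nonsense. Estimated initial values converge in ≈5–10 iterations versus
≈12–25 from a generic fixed start; at 5 dB a few percent of repetitions
land in collapsed local minima (near-zero amplitude or a narrow spike on
a noise wiggle) — these are genuine minima of the noisy objective, and
their frequency, not the clean-fit accuracy, dominates the spread of
study means. Phases are reported wrapped; unwrapped optimizer output
can differ by multiples of 2π between runs that are otherwise
identical.

The reference trace is rendered on a grid centered at time zero with
the fitted arrival re-zeroed, so the correlation peak falls directly at
the echo's arrival time.

## Time of flight

Cross-correlation is computed at full lag with an explicit lag-to-time
mapping (autocorrelation peaks at 0 by construction). Peak picking
operates on the Hilbert envelope of the correlation: the two largest
peaks separated by at least `min_separation` (default two carrier
periods, 2/f₀ — an anterior sidelobe guard) and above `threshold_frac`
(default 0.02) of the envelope maximum, in time order, with optional
3-point parabolic sub-sample refinement (at 10 MHz one sample is 74 µm
of range in water; refinement reduces that to a few µm on clean data).
Fewer than two qualifying peaks raises the recoverable
`NoPosteriorEchoError` — the empty-bladder condition. Ranges use
d = c·t/2 with c = 1480 m/s (water bath) by default, 1540 m/s preset
for tissue. Per-peak quality is the normalized correlation coefficient;
channels whose anterior quality falls below 0.2 are treated as carrying
no echo.

## Ellipsoid fitting

Wall points (mm, right-handed probe-local frame, z along the mean beam
direction) are fitted with the quadric ax²+by²+cz²+2dxy+2gyz+2hxz+2px+
2qy+2rz+I = 0 minimizing Σf(a;xᵢ)² subject to the ellipsoid-specific
constraint k·J − I₁² = 1 with I₁ = a+b+c, J = ab+bc+ca−d²−g²−h², k = 4
(guarantees an ellipsoid for any data). Points are centered and scaled
before fitting; the linear/constant block is eliminated through S₂₂
(condition-checked — coplanar or coincident points raise
`RankDeficiencyError`), leaving a 6×6 generalized eigenproblem. The
admissible eigenvector is selected by the sign of the constraint form,
not the sign of the eigenvalue: on exact data the relevant eigenvalue
is numerically ±0. At least 9 points are required. Geometry extraction
solves the gradient-zero system for the center and eigendecomposes the
centered quadratic form; volume is (4/3)πABC with 1000 mm³ = 1 mL.

## The phantom

The synthetic scanner is a two-row arc of 7 + 7 ideal-ray beams
(azimuth ±45°, elevation ±35°), each row converging toward its own
on-axis focal depth (55 and 65 mm), standing ≈30 mm off a default
150 mL ellipsoidal bladder (axis ratios 1.3 : 1 : 0.75, center 60 mm
deep). Two geometry choices are load-bearing and were found the hard
way:

* **Distinct per-row focal depths.** If all 14 beams pass through one
  point, the 28 chord endpoints admit a one-parameter family of
  interpolating quadrics (any quadratic cone through the beam lines can
  be added), and the volume is undetermined.
* **Steep elevation.** With shallow rows (±10°) the wall points barely
  sample curvature in the row direction; one semi-axis is then so
  weakly constrained that 0.05 mm of ranging noise moves the fitted
  volume by ≈25%. At ±35° the same noise moves it by ≈1%.

Each channel holds two Gaussian echoes (1 MHz, 200 kHz bandwidth) at
two-way delays 2·entry/c and 2·exit/c, the posterior scaled by 0.05
(the approximate fraction of the pulse that penetrates a urine-filled
anterior wall), plus seeded white Gaussian noise at the configured SNR
and an independent-substream noise reference track. Trace length is
2048 samples at 10 MHz (204.8 µs), which accommodates a 500 mL bladder
with margin. Everything is deterministic given the config seed.

What the phantom does *not* emulate: refraction, speckle,
frequency-dependent attenuation, beam width (beams are rays), bladder
shapes that are not exact ellipsoids, and motion. Passing the
end-to-end checks therefore demonstrates the correctness and noise
robustness of the *algorithm chain*, not clinical accuracy on real
anatomy; real-tissue error figures cannot be regenerated from synthetic
data and are out of scope.

## Study harnesses and problem sizes

* Denoising benchmark: 100 noise seeds, N = 500 at 10 MHz, 5 dB input;
  soft/hard/adaptive share the same calibrated plan.
* Initial-value study: 100 repetitions per SNR level; both start
  strategies (estimated vs fixed [1, 1, 12, 1, 1]) fit the same noisy
  trace; means are over repetitions whose fit stayed admissible.
* Volume sweep: 50–500 mL in 50 mL steps, default 20 seeds per volume
  at 10 dB; per-volume mean absolute percent error. Noiseless recovery
  is exact to well under 0.1%; at 10 dB the mean error is ≈2%.

All harness randomness flows from one master seed through named
`SeedSequence` substreams, so every table is reproducible bit-for-bit.

## Known limitations

* The single-echo fit treats the posterior echo as a perturbation when
  building the reference; at posterior/anterior ratios far above ~0.3
  a joint two-echo fit would be more appropriate.
* At 5 dB and below, correlation noise peaks compete with the 5%
  posterior peak; wall detection degrades sharply below ~8 dB, and the
  pipeline's accuracy claims are made at ≥10 dB only.
* Soft/hard thresholding results are specific to the λ = 3σ reference
  calibration; classical pipelines often use smaller (universal or
  2σ-scale) thresholds, under which soft shrinkage fares relatively
  better.
* The algebraic (not geometric) distance is minimized in the ellipsoid
  fit; with the well-conditioned default geometry the difference is
  negligible, but for grazing-angle configurations a geometric refit
  would reduce bias.
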