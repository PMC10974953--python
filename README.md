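# echovol

Bladder-volume estimation from A-mode (amplitude-mode) pulse-echo
ultrasound, built for the signal chain of portable multi-transducer
bladder scanners. Each transducer of a scanner head records a 1-D echo
trace; when the bladder holds urine, the trace shows a strong echo from
the anterior wall and a weak one (≈5% amplitude) from the posterior
wall. `echovol` turns a set of such traces into a volume estimate, and
ships a fully synthetic 14-transducer phantom so the whole chain can be
exercised and validated without hardware.

The pipeline:

1. **Adaptive wavelet denoising.** Traces are decomposed with the
   `bior3.9` wavelet; per decomposition level *j* the threshold is
   calibrated from a noise-only reference recording (transmitter off)
   as λ<sub>j</sub> = 3σ<sub>j</sub>, with σ<sub>j</sub> the Bessel
   sample s.d. of the reference's detail coefficients. Detail
   coefficients are shrunk with a variable-softness rule whose exponent
   m<sub>j</sub> = 1 + 10·En<sub>j</sub>/Ed<sub>j</sub> interpolates
   between soft-like and hard-like shrinkage according to the
   noise-to-signal energy ratio of the level.
2. **Reference-signal fitting.** The Gaussian echo model
   s(t) = β·exp(−α(t−τ)²)·cos(2πf₀(t−τ)+φ) is fitted to the denoised
   echo by Gauss–Newton with an analytic Jacobian, started from
   energy/envelope-derived initial values (β̂, τ̂ from the Hilbert
   envelope; f₀̂ from the spectrum; α̂ = πβ̂⁴/(8E²) by inverting the
   closed-form energy E = (β²/2)√(π/2α)).
3. **Time of flight.** The fitted noise-free template is
   cross-correlated with the trace; the Hilbert envelope of the
   correlation yields the anterior/posterior wall delays (with optional
   3-point parabolic sub-sample refinement), converted to ranges by
   d = c·t/2.
4. **Ellipsoid volumetry.** Wall points from all beams are fitted with
   the 10-coefficient quadric by constrained least squares using the
   ellipsoid-specific constraint 4J − I₁² = 1 (Li-type, solved as a
   6×6 generalized eigenproblem), and the volume is (4/3)πABC.

## Worked example

Estimate the volume of a synthetic 150 mL bladder scanned at 10 dB SNR:

```bash
$ echovol estimate-volume --volume-ml 150 --snr-db 10 --seed 3
estimated volume: 156.6 mL (truth 150.0 mL, error 4.40%)
```

The command simulates the 14-channel scan, denoises every channel
against its own noise reference, fits per-channel reference echoes,
extracts both wall delays, and fits the ellipsoid; the printed error is
the absolute deviation from the phantom's ground-truth volume.

The same from Python:

```python
from echovol import (PhantomConfig, default_scan_geometry, ellipsoid_truth,
                     generate_scan, estimate_volume_from_scan)

bundle = generate_scan(
    default_scan_geometry(),
    PhantomConfig(truth=ellipsoid_truth(150.0), noise_snr_db=10.0, seed=3),
)
est = estimate_volume_from_scan(bundle)
print(round(est.volume_ml, 1), est.n_channels_used)   # 156.6 13
```

An empty bladder (no posterior echoes) raises `NoPosteriorEchoError`
instead of returning a number — the physically meaningful outcome.

Other subcommands: `denoise`, `fit-reference`, `tof`, `fit-ellipsoid`,
`simulate`, and `reproduce {table1,table2,volumes}` for the scripted
simulation studies (denoising benchmark, initial-value study, phantom
volume sweep).

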