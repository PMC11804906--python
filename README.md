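# escrtkit

Analysis tools for cryo-EM and TIRF studies of ESCRT-III membrane
remodeling, built around three stages that are usually scripted ad hoc:

1. **Membrane-edge signal subtraction.** Membrane-bound ESCRT-III arrays
   appear in projected micrographs as periodic protein "spikes" riding on a
   strong, diffuse membrane band along the vesicle edge, which frustrates
   particle alignment. The band is estimated and removed by *out-of-phase
   rolling averaging*: pick coordinates along the edge are resampled at an
   interval Δs = d·(w−1)/w chosen so that the w phases relative to the
   protein repeat d sum to zero (roots of unity — e.g. Δs = 20 Å against a
   d = 30 Å repeat for a w = 3 window). A rolling 2D average of the
   extracted boxes along each edge then enhances only the smooth membrane
   signal and cancels the periodic protein signal; subtracting the
   re-projected average leaves the arrays intact. Includes repeat detection
   by an arc-length power spectrum, 15-Å duplicate-pick removal, and
   ground-truth evaluation metrics.
2. **Lattice quantification.** Plot-profile measurements of filament
   arrays on membrane tubes: interfilament spacing from consecutive peak
   distances perpendicular to the filament axis, outer diameter from the
   outermost half-maximum edges, filament orientation as the smaller angle
   between membrane and filament axes, and membrane curvature κ = 2/D.
3. **Polymerization kinetics.** Surface recruitment traces F(t) are fitted
   with a Hill sigmoid F(t) = F₀ + F_max·tⁿ/(t_half ⁿ + tⁿ); lag time (tangent
   at the inflection), linear-region growth rate, and plateau are derived
   from the fit. A stochastic simulator realizes nucleation-and-growth
   kinetics — Poisson nucleation at areal rate J = k_nuc·(C/C_ref)^p with
   disk growth at v = k_g·C — and is validated against the Avrami closed
   form θ(t) = 1 − exp(−π J v² t³/3).

Every stage is testable without external data: synthetic-scene generators
(`make_edge_scene`, `make_tube_scene`, `make_tirf_trace`) emit micrographs,
tube images, and fluorescence traces together with their exact additive
ground-truth decomposition and planted parameters.

Formats: MRC2014 2D maps (via gemmi), STAR particle-coordinate tables
(RELION dialect), CSV for traces and measurements. All public coordinate
APIs are in Å; geometry measurements are reported in nm.

## Worked example

```python
import escrtkit as ek

# render the standard membrane-edge scene (1024 x 1024 at 2.8 A/px)
mic, truth = ek.make_edge_scene(ek.SceneSpec())

# detect the protein repeat along the edge
est = ek.estimate_repeat(mic, truth.path, band_offset_A=60.0,
                         band_halfwidth_A=25.0, period_range_A=(15.0, 60.0))
print(f"detected repeat: {est.period_A:.2f} A (confidence {est.confidence:.0f})")

# subtract the membrane signal and score it against the ground truth
res = ek.subtract_rolling_average(mic, truth.path, repeat_A=est.period_A,
                                  window_len=3, box_size_A=240.0)
print(f"resampling interval: {res.config['interval_A']:.2f} A")
for k, v in ek.evaluate_subtraction(res, truth).items():
    print(f"{k}: {v:.3f}")

# simulate and fit a recruitment trace at 0.5 uM
params = ek.SimParams(concentration_uM=0.5, grid=256, dt_s=5.0,
                      horizon_s=3000.0, seed=1)
fit = ek.fit_hill(ek.simulate_coverage(params))
print(f"t_half = {fit.t_half:.0f} s, n_H = {fit.n_H:.2f}, "
      f"plateau = {ek.plateau(fit):.3f}, lag = {ek.lag_time(fit):.0f} s")
```

Output:

```
detected repeat: 30.00 A (confidence 614)
resampling interval: 20.00 A
membrane_attenuation: 0.933
lattice_retention: 1.000
template_cc_gain: 0.014
t_half = 695 s, n_H = 5.35, plateau = 1.011, lag = 443 s
```

The scene plants a 30-Å spike repeat at signal-to-noise 1; the spectral
estimator reads it back, the cancellation rule maps it to the 20-Å
resampling interval, and the subtraction removes 93% of the membrane-band
power while keeping essentially all of the lattice's spectral peak and
improving the template correlation of the particle boxes. The simulated
half-micromolar trace is sigmoidal (n_H > 1: nucleation-limited), with a
~440-s lag and a plateau at full coverage independent of concentration.

A CLI wraps the same operations for shell pipelines
(`escrtkit simulate | estimate-repeat | subtract | quantify | kinetics-fit |
kinetics-simulate | evaluate`); each run writes a `manifest.json` with its
configuration, seed, and input checksums.

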