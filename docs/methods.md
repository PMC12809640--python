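# Methods

This document records the algorithms and physical model implemented in
`nanopulse`, with the conventions and corrections that matter for
reproducing its numbers.

## 1. Two-sliding-window (TSW) detection

The detector maintains two windows over the incoming current samples:

- **w1** — a long baseline window (default `fs / 100` samples, i.e. 10 ms
  at 500 kS/s) whose median (or mean) estimates the open-pore current
  `I0` and whose spread estimates the baseline noise `σ1`.
- **w2** — a short window (default 50 samples) whose mean `Ī2` and
  standard error track the local current level.

Outside an event, each sample updates both windows. An event **starts**
when the normalized deviation exceeds a threshold:

```
|I − I0| / σ1 > n_σ        (default n_σ = 5)
```

On the start sample, w1 is **frozen**: the baseline and noise estimates
stop updating so the event itself cannot contaminate them. This is the
property that keeps long events (tens to hundreds of milliseconds)
measurable — a moving baseline would absorb the event plateau.

The event **ends** when w2 again becomes statistically consistent with
the frozen baseline, by a z-test on the window mean:

```
z = (Ī2 − I0) / (σ1 / √n2),    end when |z| < z_end   (default 1.96)
```

The z-test is **armed** only after w2 has filled with in-event samples;
otherwise a window still straddling the falling edge could satisfy the
test spuriously. A clog guard terminates events longer than `0.5·fs`
samples and flags them (`clog=True`) rather than silently truncating.

While inside an event, samples are **clamped** to `I0 ± n_σ·σ1` before
entering w2 statistics used for the end test, so a deep blockade does not
delay the end decision. The raw samples are retained for amplitude and
shape analysis.

The hot loop is compiled with numba over flat state arrays and processes
roughly 1.7 MS/s on one core. Processing is exactly **chunk-invariant**:
feeding the trace sample-by-sample, in arbitrary chunks, or all at once
yields identical events (this is property-tested).

## 2. Half-amplitude dwell refinement

Raw start/end indices from the threshold crossings are biased: the
anti-aliasing filter turns square edges into ramps, and a fixed
σ-threshold crosses those ramps at an amplitude-dependent point. The
refined dwell instead uses the **half-amplitude convention**:

1. Estimate the blockade level as the median of *deep* samples (those
   deviating more than `end_band_sigma·σ1` from baseline).
2. Define the half level `(I0 + level) / 2`.
3. Linearly interpolate the first downward and last upward crossing of
   the half level, giving fractional sample positions and a fractional
   dwell.

For a Gaussian low-pass filter the full width at half maximum of a pulse
is invariant under filtering, so this convention removes the first-order
bandwidth bias. Measured on square pulses at 500 kS/s, 50 kHz bandwidth:
median dwell error ≈ +25 % at 10 µs, +7 % at 20 µs, +4 % at 30 µs, and
below 1 % for dwells ≥ 100 µs; under strong intra-event modulation
(σ up to 330 pA on a 500 pA pulse) the error stays within ≈ 1 %.

## 3. Conventional threshold (TS) comparator

The comparison detector is the standard approach: a centered moving
average (window 30 000 samples, 60 ms) estimates the baseline, events are
contiguous runs where the residual exceeds 5× the noise scale, and event
edges are refined by two-point half-amplitude interpolation. The noise
scale is the global residual RMS by default; when the acquisition's
nominal RMS noise is known it can be supplied (`nominal_noise_sd`) so the
threshold is not inflated by the events themselves.

Its characteristic failure is structural: once an event's dwell
approaches the baseline window length, the moving average tracks the
blockade, the residual collapses, and the event is shortened or lost
entirely. Measured: dwell error < 3 % up to 10 ms, then ≈ −99 % at 60 and
128 ms. Under intra-event modulation its dwell shortens progressively
(−0.7 % at σ = 50 pA to −27 % at σ = 330 pA) because modulation excursions
below threshold split or erode the supra-threshold run, while TSW's
frozen-baseline z-test is insensitive to it.

## 4. Ellipsoid blockade model

A dielectric particle of volume `V` in a cylindrical pore of diameter `d`
and length `l` reduces the ionic current by

```
ΔI = I0 · γ(θ) · V / V_eff,      V_eff = (π/4) d² (l + 0.8 d)
```

where `V_eff` is the effective sensing volume including the access-region
end correction (for the default 20 nm × 30 nm pore,
V_eff = 14 451.33 nm³), and `γ` is the electrical shape factor of an
ellipsoid of revolution with axis ratio `m = b/a`:

```
L∥(m) — depolarization factor along the symmetry axis
γ∥ = 1 / (1 − L∥),   L⊥ = (1 − L∥)/2,   γ⊥ = 1 / (1 − L⊥)
γ(θ) = γ⊥ + (γ∥ − γ⊥) cos²θ
```

with `θ` the angle between the symmetry axis and the field. A sphere has
L = 1/3 and γ = 3/2 at any orientation. Oblate particles (m < 1) have
γ∥ > γ⊥; prolate (m > 1) the reverse.

### Intra-event density and the (m, V) fit

As the particle tumbles (rotational diffusion), `cos²θ` for an isotropic
orientation distribution has density `1/(2√u)` on (0, 1), so the blockade
amplitude sweeps a bounded interval `[ΔI_min, ΔI_max]` with an
integrable singularity at one end: at the **minimum** |ΔI| for oblate
particles and at the **maximum** for prolate. Both branches produce the
same interval, which is the fundamental oblate/prolate ambiguity; the fit
chooses the branch whose theoretical CDF better matches the empirical
one (lower CDF residual).

The per-event fit estimates the amplitude extremes robustly from the
in-event sample distribution (noise-deconvolved quantiles), solves

```
ΔI_max / ΔI_min = γ_max(m) / γ_min(m)
```

for `m` by bracketed root-finding, and then reads `V` from either
extreme. Events need a minimum number of deep samples (default 10) to
attempt a fit.

### Band-limited orientation correction

The recorded trace is low-pass filtered, so the observed per-sample
blockade is a local average over the particle's recent orientations. This
*narrows* the observed cos²θ distribution relative to the isotropic one
and biases `m` toward a sphere if ignored. The correction tabulates the
quantiles of the **filtered** cos²θ process — simulated once per
(rotational diffusion, fs, fc) with a fixed internal seed and cached —
and uses those quantiles in place of the ideal ones when inverting the
amplitude extremes. With the correction, pooled recovery on synthetic
translocations gives m ≈ 0.51 for a true 0.5 and m ≈ 1.90 for a true
2.0, with volume within ≈ 1 %.

### Cumulative pooling

Per-event estimates are pooled by a **residence-time-weighted median**:
each event contributes its (m, V) weighted by its dwell, and events
shorter than a minimum dwell (default 150 µs) or with failed fits are
excluded. The cumulative estimate stabilizes after roughly 20 ms of total
in-pore residence.

## 5. Fractional-blockade classification

The Naive Bayes classifier operates on per-sample fractional blockades
`|I − I0| / |I0|` histogrammed into 200 bins with add-one smoothing.
Training can use detected events per class or the theoretical intra-event
density for given (m, V) specs. Prediction sums per-sample log
likelihoods plus a log prior; ties break lexicographically for
determinism, and events whose samples fall wholly outside every class's
support are rejected with an `__unclassifiable__` sentinel. Evaluation
macro-averages precision/recall over the real classes; the reject option
is an abstention, not a class. On a five-protein mixture spanning
(0.3–0.8, 150–300 nm³) the classifier reaches ≈ 95–97 % accuracy.

## 6. Reference geometry from atomic structures

To compare pore measurements with an independent ground truth, the
`structure` module computes:

- **Solvent-excluded volume**: atoms are rasterized on a voxel grid
  (default pitch 0.05 nm), dilated by the probe radius (water,
  0.28 nm diameter) via Euclidean distance transform, external space is
  flood-filled from the border, and the probe-inaccessible envelope is
  eroded back — interior cavities remain part of the volume, as they
  displace electrolyte.
- **Shape**: the minimum-volume enclosing ellipsoid of the atom centers
  (Khachiyan's algorithm) reduced to an ellipsoid of revolution by
  averaging the two most similar semiaxes; `m` is the ratio of the
  distinct semiaxis to the averaged equatorial one.

## 7. Synthetic traces

Generators produce square pulses (optionally with intra-event Gaussian
modulation) and full protein translocations in which each event's
amplitude follows γ(θ(t)) along a simulated orientation random walk
(numba kernel; isotropic stationary distribution, E[cos²θ] = 1/3). All
traces are filtered with a zero-phase Gaussian low-pass whose kernel
sigma is `fs·√(ln 2)/(2π·fc)` (half-amplitude point at fc), with white
Gaussian noise added before filtering. Event counts follow
`rate × duration` exactly; placement jitters events on a slot grid
compressed into the post-warm-up span, so ground truth (start, end,
label) is exact by construction.

## 8. Known limitations

- **Near-sphere degeneracy**: as m → 1 the amplitude interval collapses
  and the oblate/prolate branch choice becomes noise-dominated; `m` is
  then reported near 1 with low confidence rather than a spurious branch.
- **Short dwells**: below ~3× the filter rise time (≈ 30 µs at 50 kHz)
  even half-amplitude dwells are biased high by several percent, and
  shape fits are unreliable (too few deep samples).
- **Very long events**: events beyond 0.5 s are flagged as clogs, not
  analyzed.
- **Orientation correction cache**: the filtered-quantile table assumes
  the rotational diffusion coefficient used in simulation; applying it
  to particles with very different tumbling rates requires regenerating
  the table for that regime.
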