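# Methods

## The physical system being modelled

A rigid bench model of the cynomolgus monkey CSF space (total volume
16.86 ml) is driven by an oscillatory pump reproducing cardiac- and
respiration-synchronous CSF flow with near-zero net component. A
fluorescein bolus is injected at a lumbar level, optionally followed by a
tracer-free flush through the same needle, and the axial spread of the
tracer is imaged every 30 s for 3 h by two cameras with different
exposures. The package reproduces this chain in software: a 1D transport
simulator stands in for the bench, a synthetic camera pair for the
imaging, and the quantification/statistics layers are the same code that
would process real image stacks.

## Geometry

The CSF space is collapsed onto a 1 mm axial grid carrying the per-slice
CSF volume V(z). Coordinates: z = 0 at the foramen magnum, positive
cranially; the extra-axial CSF (eaCSF) occupies z ∈ [0, 60) mm
(half-open, so a slice centered exactly on a boundary belongs to the
region on its cranial side). The default phantom is a tapered spinal
canal with mild cervical and lumbosacral enlargements plus a half-Gaussian
cranial bulge, rescaled to the 16.86 ml total with 62% of the volume in
the cranial compartment. The spinal length (280 mm), the cranial volume
fraction, and the injection-site coordinates are free parameters of the
phantom — they are not anatomical measurements. L4/L5 sits at
z = −250 mm with L3/L4 one vertebral spacing (8 mm) cranial of it.

Profiles can also be derived from a binary segmentation stack
(voxel-count × voxel volume per 1 mm bin; partial end bins are truncated).
`compare_profiles` regresses a measured profile on a reference profile
(OLS of the second argument on the first); we put the design profile
first, so a slope above 1 reads as the fabricated model being slightly
larger than the design.

## Flow waveform

The cardiac component defaults to a zero-mean two-harmonic pulse
(fundamental plus a 0.3-weight, phase-shifted second harmonic giving a
systolic skew). It is a parametric stand-in for a measured cervical
phase-contrast MRI waveform; a sampled one-period series can be supplied
instead and is periodically resampled. The respiratory component is a
sinusoid with amplitude 0.52× the cardiac peak and frequency 1/4.29× the
cardiac frequency (120 bpm → ≈28 breaths/min). Normalization order:
superimpose, remove the record mean, then scale the sum so the stroke
volume equals the 0.2597 ml target (scaling preserves the zero mean, and
stroke volume is homogeneous in amplitude, so the target is hit exactly).

Stroke volume is defined as the per-cardiac-cycle integral of the
positive part of Q, averaged over the whole cycles contained in the
record — the standard phase-contrast MRI convention, chosen because the
source context does not state a definition and this one is closed-form
testable (a sinusoid of amplitude A and period T has SV = A·T/π).
Because 4.29 is irrational with respect to the cycle grid the combined
record is treated as non-periodic; metrics only ever average over whole
cardiac cycles. The printed 0.2597 ml is taken as the stroke volume of
the *combined* waveform (it is stated alongside the combined waveform's
heart and respiration rates), so that is what the normalization targets.

## Transport model

Finite-volume discretization on the geometry grid: cell volumes V(z),
areas A(z) = V(z)/Δz. Two transport mechanisms are separated by time
scale:

* **Oscillatory dispersion** (default `cycle_averaged` mode). The
  zero-net oscillatory flow contributes no advection on the 30 s frame
  scale; its mixing effect is modelled as an effective axial dispersion

      D_eff(z) = D_mol + k · ⟨|u(z,·)|⟩ · h(z),

  with u = Q/A the cross-section-averaged velocity, h = √A a local
  hydraulic length, and k a dimensionless dispersion factor. This is a
  shear-augmented-dispersion closure in the spirit of oscillatory Taylor
  dispersion, not a fitted physical coefficient. The default k = 0.006
  was calibrated **once** and frozen: it is the value at which the
  flushed L4/L5 protocol first delivers ≥ 1 µM to the foramen magnum
  ≈ 34 min post-injection (within the qualitatively plausible 15–45 min
  band for this system); it is a tuning, not a measurement, and the
  simulator's absolute %ID values are therefore not comparable to bench
  values — only orderings and signs of protocol contrasts are meaningful.
  An optional `resolved` mode advects with the instantaneous Q(t)
  (molecular diffusivity only) as a cross-check; it needs dt ≲ 5 ms to
  satisfy the advective CFL bound and is not the default.

* **Slow net flows** — bolus (tracer at the protocol concentration),
  flush (tracer-free), production (tracer-free, 0.018 ml/min at a
  ventricular port), absorption (bulk fluid carrying the local
  concentration, 0.018 ml/min at an intracranial port) — are advective.
  The domain is rigid, so the instantaneous net volume input leaves
  through the two domain ends in proportion to the end areas; end outflow
  carries the local concentration. With the default phantom the cranial
  end is the larger, so most of the injected volume transits the canal
  cranially — this is what makes the flush displace the bolus toward the
  brain.

Numerics: operator splitting per step (default dt = 0.5 s) — explicit
first-order upwind for the net drift with an exact per-regime CFL guard
(the error message names the stability bound), then unconditionally
stable backward-Euler diffusion solved as a tridiagonal system. The
scheme is conservative and positivity-preserving; the tracked mass budget
(injected = in-domain + absorbed + end-outflow) closes to machine
precision and is asserted to 0.5% in tests. The pure-diffusion limit is
verified against the Gaussian heat kernel (< 2% L2 at interior times).

## Synthetic cameras

Linear response with additive Gaussian noise and clipping:
I = clip(offset + gain·C + N(0, σ), 0, 4095) (12-bit). The low-exposure
camera (gain 72 /µM) stays unsaturated past 50 µM; the high-exposure
camera (gain 200 /µM) saturates near 20 µM, providing the fine response
below the 10 µM merge threshold. Frames default to one image row per
1 mm slice × 32 columns; since quantification averages transversely and
per slice, additional rows/columns add cost but no information
(`rows_per_slice` is configurable). Rendering is deterministic per seed.

What the synthetic bench does *not* emulate: vignetting and flat-field
non-uniformity, background drift, refraction through the phantom wall,
camera misregistration, and any 3D structure of the tracer field —
quantification of real stacks assumes those are corrected upstream.
Passing the pipeline tests therefore shows the quantification chain is
self-consistent and unbiased for a linear imaging system, not that it is
robust to real optical artifacts.

## Quantification

Per frame and camera: transverse (per-z-row) mean intensity first, then
conversion through a monotone piecewise-linear calibration map fitted to
(mean intensity, known level) pairs, with saturated levels excluded and
out-of-range intensities clamped to the end levels. Averaging before
mapping is second-order equivalent to per-pixel mapping for near-linear
maps and matches a workflow that reduces to axial profiles early. Merge
rule: points reading strictly below 10 µM on the low-exposure profile are
replaced by the high-exposure reading (ties keep low). %ID at "3 h" uses
the single frame nearest 3 h, not a time average. Region-mean AUC is the
unweighted slice mean by default (a volume-weighted option exists); the
choice matters only if AUC and V(z) covary strongly within the region.

## Statistics

95% bands are 1.96 × SD (the limits-of-agreement convention). This was
chosen over t-based SEM intervals because the reported SD/CI pairs of the
source tables satisfy CI = 1.96·SD to rounding in seven of eight rows
(e.g. 4.34 → 8.51, 2.72 → 5.33), while SEM-based intervals fit none; the
one exception (SD 1.88 with CI 3.79) cannot be produced by any rounding
of either convention and is treated as a printed inconsistency (3.79/1.96
= 1.93 suggests a typo in its SD). %DR = max 95% CI / C_max × 100 with
C_max the maximum of the repetition-mean merged map (the scope of C_max
was otherwise unspecified). The group contrasts use Student's
pooled-variance unpaired t-test at α = 0.05 (Welch optional); degenerate
zero-variance pairs return finite sentinel p-values (1 for equal means, 0
otherwise) rather than raising. The per-protocol group means used for
the delta arithmetic come from the group-comparison table, whose 3G1
entry (18.7) differs by 0.1 from the per-protocol table (18.8); only the
former reproduces all five reported deltas exactly. Reported p-values
are not reproduced: they are not derivable from the published summary
statistics alone.

## Study orchestration

Per-repetition seeds derive from `SeedSequence([base_seed, protocol_index,
repetition])`, so any repetition is reproducible in isolation and seeds
cannot collide within a study. Repetition variability comes from camera
noise plus a seeded ±5 s jitter on injection start. The default study is
8 protocols × 3 repetitions × 3 h at dt = 0.5 s (≈ 40 s total on one
core); tests use shorter durations and smaller phantoms, which changes
problem size but no code path.

## Known limitations

1D transport cannot represent steady streaming around nerve roots, posture
effects, compliance, or drug-specific tissue uptake; the dispersion
closure is a tuned stand-in, so absolute concentrations, %ID and AUC
magnitudes are phantom properties. The repetition variability model
(noise + start jitter) is far simpler than bench variability, so %DR
magnitudes are illustrative only. The CLI covers the simulate / quantify
/ stats / run-study / make-fixtures verbs; hardware control is out of
scope.
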