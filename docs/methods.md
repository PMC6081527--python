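# Methods

`stenoflow` emulates a bench experiment in which a contrast bolus is
pushed through stenotic tube phantoms under pulsatile flow, imaged with a
flat-detector fluoroscopy system, and graded from region-of-interest
time-density curves (TDCs). This note describes the model actually
implemented, the closures it relies on, the parameters that matter, and
what the synthetic data can and cannot show.

## Physical configuration

The phantom is a straight 50 cm tube of 10 mm inner diameter with a 4 mm
long concentric stenosis at the axial origin (stenotic inner diameters
2/4/6/10 mm, i.e. 80/60/40/0 % diameter stenosis). A solenoid valve
produces square-wave pulsatile flow: an 800 ms cycle, 500 ms open at
25 ml/s, 300 ms closed. A 20 ml contrast bolus is injected over 1 s
through a sheath 15 cm proximal to the stenosis. Acquisition runs at
30 frames/s for 12 s with 0.2 mm pixels. All of these are dataclass
defaults (`stenoflow.config`) and can be overridden via YAML.

Analysis follows the clinical protocol: four 10×10 mm ROIs (reference
5 cm proximal; edges abutting the proximal/distal stenosis shoulders;
5 cm distal), baseline-zeroed mean ROI gray value per frame, a 5 %-of-
maximum bolus-arrival trigger on the reference curve, trapezoidal AUC
over 1/3/5/7 s windows, percentage deviation from the reference ROI,
TTP from the trigger to the curve maximum, and an ROI-size sweep
(10/8/6/4 mm at fixed centres).

## Transport model

Bolus transport is one-dimensional: a passive tracer on a 1 mm axial
grid advanced by explicit first-order upwind advection plus central
dispersion, with the time step chosen automatically from a combined
positivity bound (advective Courant number ≤ 0.5 at the peak jet
velocity, plus dispersion and exchange rates). The scheme is
conservative: at every output time the injected volume equals in-domain
volume plus cumulative outflow to round-off, which the tests assert.

The velocity field is `Q(x, t) / A_eff(x)` with four ingredients:

1. **Valve square wave with orifice resistance.** The regulated open-valve
   flow is scaled by `1 / (1 + k ((A0/As)^2 − 1))` with `k = 0.002`,
   the simplest quadratic-resistance law that lets a high-grade stenosis
   reduce delivered flow (factors 0.99/0.93/0.45 for 40/60/80 %).
2. **Injector volume displacement.** The power injector adds its own
   20 ml/s to the flow downstream of the sheath tip while it runs. This
   is an incompressibility requirement, and it is the mechanism behind
   the nonstenotic distal AUC excess: the bolus passes the proximal
   reference ROI during the injector-driven surge (fast, low
   time-density) and the distal ROIs after the surge (slow, high
   time-density). In a flux-conservative 1D model with a single flow
   rate the windowed time-integral of concentration would be identical
   at every cross-section; the transient surge is what breaks that
   degeneracy. A `injection_adds_flow=False` switch recovers the
   massless-source idealization.
3. **Poststenotic jet.** For 12 mm behind the distal shoulder the stream
   is treated as a jet whose effective area widens linearly from the
   stenotic to the full lumen area. Tracer crosses this zone at jet
   speed, which lowers the time-density immediately distal to the
   stenosis in proportion to grade.
4. **Recirculation retention.** From 15 mm to 42 mm behind the shoulder,
   tracer is exchanged into a stagnant recirculation pocket at a
   first-order rate `22 · s^2.5` s⁻¹ (with `s` the relative diameter step
   of the expansion, 0.4/0.6/0.8 for the bench grades) and released back
   at 0.12 s⁻¹. Trapped tracer keeps its axial position and remains
   visible to the detector; its effect on grading is purely kinetic —
   part of the bolus reaches the distal ROI after the integration
   window has closed. Dispersion is additionally elevated tenfold over a
   30 mm mixing length, standing in for jet-collapse mixing.

The jet and pocket are deliberate low-order surrogates for 3D stenotic
flow (flow separation, jet collapse, recirculation); no CFD is
attempted. Their four parameters (jet length, trapping scale, severity
exponent, release rate) together with the resistance constant `k` were
calibrated once so that the simulated grade/deviation pattern
qualitatively reproduces the bench ordering — distal deviations strictly
decreasing with grade, nonstenotic positive, high-grade negative — and
then frozen; they are not fitted to any measured flow.

## Projection and noise

Gray values follow the subtracted-angiography convention: the blank is
zero and gray is linear in the projected contrast path length
(`attenuation = 500` gray per mm of equivalent pure contrast). Each
axial column's tracer is spread laterally by a profile: `parabolic`
(default — contrast rides the faster core of laminar pipe flow,
projection ∝ (r²−y²)^(3/2)), `chord` (uniformly mixed, projection ∝
chord length) or `flat` (control without lateral structure). All
profiles project the same column total, so full-width ROI means — and
therefore every AUC deviation — are profile-independent; only
sub-lumen ROIs (the size sweep) distinguish them. Detector noise is
additive Gaussian per pixel, default SD 2 % of the run's peak
noise-free pixel, clipped at zero and quantized to 16 bit.

Replicates differ in noise realization and in a seeded uniform jitter of
the injection start within one valve cycle (±0.4 s) — the uncontrolled
injector/valve phase is the plausible source of the bench study's
replicate scatter, and it produces distal-deviation SDs of a few
percentage points, comparable to the printed tables.

## Statistical layer

The published tables report only per-group mean, SD and n = 3, so ANOVA
and the Tukey–Kramer post hoc are computed directly from summary
statistics (`SS_between`, `SS_within`, F-tail; studentized-range tail
for the pairwise q) — algebraically identical to raw-data ANOVA, which a
property test asserts against `scipy.stats.f_oneway` and a Tukey test
asserts against statsmodels on constructed replicates. Spearman's rho
uses average ranks; reproducibility is summarized per integration time
as RMSD = √(mean replicate variance over stenosis-model × ROI cells) and
CV = 100·RMSD / grand-mean AUC. The RMSD definition is one consistent
reading of an under-specified quantity and its printed values are not
used as references.

The bundled CSV fixtures transcribe the published summary tables exactly
as printed (one comma-decimal cell normalized, flagged in a provenance
column). `reproduce_printed_anova` recomputes every row's p-value from
its own summary and flags rows at |Δp| > 0.02 as inconsistent: input
rounding (±0.005 on 2-decimal means/SDs) cannot move these p-values that
far. Four AUC-table rows reproduce their printed p to 4 decimals; two
TTP rows (and two further AUC rows) are flagged as irreproducible from
their own printed summaries and are reported, not asserted.

## Numerical choices and degenerate inputs

Trapezoidal integration with linear interpolation at window endpoints;
ties in TTP break to the earliest peak, with a boundary-peak flag for
monotone curves; ROI footprints floor physical mm to 0-based half-open
pixel ranges; the arrival trigger normalizes to the run's own curve
maximum. Degenerate cases raise: occluded stenosis, unstable explicit
time step (with the bound in the message), empty ROI footprint, no
bolus above threshold, zero reference AUC, zero within-group variance
with equal means, constant vectors in Spearman.

## Problem sizes and limitations

The default experiment (4 grades × 3 replicates, 12 s at 30 fps,
0.2 mm pixels) runs in about a minute on one core; unit tests use
shorter, coarser runs. Known limitations of the emulation:

- The high-grade distal deviation is more extreme (≈ −70 %) than the
  bench value (≈ −11 %); the model reproduces signs and orderings, not
  magnitudes.
- A single lateral profile applies to the whole tube, so the ROI-size
  sweep is as strong distal to a high-grade stenosis as in the
  nonstenotic tube, whereas the bench data show the distal effect
  flattened by jet mixing.
- No beam-hardening or scatter physics, no vessel compliance,
  tortuosity or non-Newtonian rheology; water-like transport in a rigid
  straight tube, as in the bench phantom.
- TTP values are generated by the same kinetics and are reported but not
  calibrated against the printed TTP tables, whose own internal
  consistency is partly in doubt (see the reproduction report).

Passing tests therefore demonstrate that the quantification and
statistics chain recovers the patterns such a phantom produces — not
that the transport closures are an accurate fluid-dynamics model.
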