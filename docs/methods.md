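# Methods

`plrkit` models the mouse pupillary light response (PLR) as two phases:
a **transient** phase (the first 30 s after light onset) driven largely by
rod input and glutamatergic ipRGC output, and a **sustained** phase (out to
an hour of continuous light) dominated by melanopsin phototransduction and
PACAPergic output. This note records the models, the parameter choices,
and the numerical decisions behind each module.

## Relative pupil area and endpoints

All analyses operate on relative pupil area (RPA): measured pupil area
divided by the dark-baseline area, so 1 means fully open and smaller
values mean constriction. The baseline is the mean area over all
pre-onset samples; with a single dark frame this reduces to plain
division by that frame. The transient endpoint of a trace is the minimum
of the RPA at 5 s and at 30 s after onset, matched to the nearest sample
within ±0.5 s because video frame times are irregular.

## Intensity-response (EC50) fitting

The intensity-response curve is a variable-slope sigmoid in log10
illuminance,

    rpa(I) = bottom + (top − bottom) / (1 + 10^((logEC50 − log10 I)·h)),

with the top fixed at 1.0 and the bottom constrained to [0, 0.10] —
near-complete constriction — unless the genotype never reaches that
range, in which case the fit automatically falls back to an
unconstrained bottom (it does so when the constrained bottom pins at
0.10 while no observed RPA is below 0.10). The Hill slope h is free in
sign and comes out negative for constriction. Zero-lux points are
excluded (log undefined); they serve only as baseline checks.

Fitting is bounded nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective) with multi-start over h ∈ {−0.5, −1, −2} and five
logEC50 values spanning the data range, keeping the best residual sum of
squares. Convergence tolerances are set near machine precision so that
noiseless curves are recovered to ≤1e−6. EC50 statistics (mean, SD,
geometric mean) are computed on log10 EC50, since EC50s are log-normally
distributed across animals.

## Kinetics

Constriction and decay time courses are fitted with a one-phase
exponential Y(t) = plateau + (y0 − plateau)·exp(−k·(t − t₀)); t₀ is an
optional onset offset (used e.g. with 3 s for the sluggish
melanopsin-only line) and half-life = ln 2 / k. The "two-phase" model is
a general bi-exponential with signed spans, which can describe a pupil
that constricts and then re-dilates within the 30-s recording (cone-only
lines); if the extra phase does not improve the RSS by at least 1%
(relative), the one-phase fit is returned flagged as reduced. Transient
rates are per second; sustained rates per minute, matching the natural
half-life scales (~1 s vs ~2–5 min).

The sustained decay rate varies with illuminance. It is modeled as a
sigmoid in log10 lux whose top and bottom are pinned to the measured
rates at 1 and 100 lux, with midpoint and slope fitted to pass through
the 10-lux rate. Because a single interior point cannot identify both
midpoint and slope separately, any (midpoint, slope) pair passing
through the 10-lux rate is acceptable — every quantity consumed
downstream (the rate at the three calibrated intensities and the clamped
values outside them) is well determined. Evaluation outside 1–100 lux
clamps to the respective plateau; the curve never leaves the interval
between the two calibrated rates.

## Negative-feedback model of PLR decay

Pupil constriction attenuates retinal illumination (retinal lux = RPA ×
environmental lux), closing a negative feedback loop. To bound how much
PLR decay this loop alone could cause, the simulator treats each second
of light as a discrete packet whose constriction depth is read from the
open-loop intensity-response curve at the current retinal illuminance,
distributed over the following 30 s by a temporal weighting ω measured
from a 1-s pulse-chase (constriction peaks at the 6-s lag and ω is
normalized to 1 there). The system is assumed to have **zero temporal
summation**: the pupil always adopts the single deepest weighted packet
(a max, never a sum). This assumption maximizes feedback's leverage, so
the simulated decay is an upper bound.

Per second t over a 956-s horizon:

    C(t)    = max_{s<t} depth_s·ω(t−s)        (ω ≡ 0 beyond lag 30)
    lux_t   = (1 − C(t))·env_lux
    depth_t = 1 − drc(lux_t)
    rpa_t   = 1 − max_{s≤t} depth_s·ω(t−s)

The recursion is implemented directly in O(horizon × lag) rather than as
the equivalent 956×956 packet matrix; the matrix is available as a debug
view. One printed formulation of this model weights the stored RPA value
itself by ω, which taken literally would make small weights imply deep
constriction; the package weights constriction *depth* (1 − rpa), which
matches the verbal description of the procedure and the intent of an
upper bound. Everything here is deterministic.

The default intensity sweep uses nine illuminances, 0.0001–10,000 lux in
decade steps; an extended sweep to 100,000 lux is available. The sweep
reports per-intensity decay magnitude (horizon-end RPA minus the deepest
RPA) and two model EC50s, one fitted to the early minimum RPA and one to
the horizon-end RPA. Feedback can only re-dilate the pupil, so the
horizon-end EC50 is never below the early-minimum EC50, and decay
magnitude vanishes at both saturated ends of the dose-response curve.

## Contribution heat maps

Per genotype, a transient matrix covers 0–30 s (1-s steps) and a
sustained matrix 30 s–60 min (5-s steps), both over 0.001–100,000 lux in
0.25 log-unit steps (all grids configurable). The transient matrix is a
one-phase association from 1 to the transient plateau at each intensity
with a single rapid rate (wild-type rapid kinetics at 100 lux); the
sustained matrix relaxes from the transient plateau toward the sustained
plateau at the intensity-dependent rate. The sustained matrix's first
column is computed in convex-combination form so it equals the transient
plateau *exactly* at the 30-s boundary. Cone-only matrices additionally
receive a relaxation adjustment: past each row's constriction minimum
the remaining depth decays toward 1 at the cone-only transient decay
rate measured at 100 lux, applied at all intensities. The ambiguity
between replacing the rate constant outright and applying a post-hoc
relaxation was resolved in favor of relaxation, which is continuous,
leaves the rate→0 limit unchanged and never deepens constriction.

Necessity of a component is the constriction lost when it is knocked
out, N = clamp(rpa_ko − rpa_wt, 0, 1); this is automatically normalized
by the wild-type constriction available at that cell. Sufficiency is the
absolute constriction of the corresponding "-only" line, S =
clamp(1 − rpa_only, 0, 1) (no wild-type normalization, which the source
convention leaves unspecified). Contribution is the cellwise
max(N, S); for neurotransmitters only necessity is used (no "-only"
line can exist), so contribution equals necessity there. Negative
differences and values above 1 are clamped. RGB composites assign one
component per channel with value round(255·contribution); black means no
contribution. Replicate mutant lines targeting the same component are
combined by cellwise averaging of their matrices before mapping.

## Synthetic data generator

The generator emulates the study's design: per genotype and mouse, 30-s
transient traces and 60-min sustained endpoints across a log-spaced
intensity panel, plus a 1-s pulse-chase profile. A noiseless trace is

* 1 before onset (≥3 dark baseline samples) and during any onset delay;
* a one-phase association to the transient sigmoid plateau at rate k,
  optionally multiplied by exp(−fade·t) to produce the cone-only
  constrict-then-redilate shape;
* from 30 s, a one-phase decay toward the sustained sigmoid plateau at
  the intensity-dependent rate, optionally modulated sinusoidally to
  imitate pulsatile constriction.

Measurement noise is additive Gaussian on RPA (no noise model is
published; SD 0.03 was chosen to resemble the plotted animal-to-animal
spread), truncated at ±4 SD and floored at RPA 0.02, so generated values
stay in [0.02, 1 + 4·SD]. Areas are RPA × a 4 mm² dark baseline (typical
dark-adapted mouse pupil). All randomness derives from one user seed via
`numpy.random.SeedSequence` spawn keys per (genotype, mouse, intensity),
so identical seeds give bit-identical datasets.

Wild-type defaults are anchored to the reported physiology: transient
EC50 0.53 lux, transient half-life 1.1 s (k = ln 2/1.1), sustained EC50
7.9 lux, sustained decay half-lives 2 min at 1 lux and 5 min at 100 lux,
sigmoid bottoms 0.05, Hill slopes −1, pulse-chase constriction peaking
exactly at the 6-s lag (gamma-like profile ((lag/6)·e^(1−lag/6))²). The
eight mutant lines carry qualitative encodings of their reported
phenotypes:

| line | transient | sustained |
|---|---|---|
| rod KO | EC50 53 lux (~2 log-unit loss) | EC50 53 lux (matches melanopsin-only) |
| cone KO | = wild type | = wild type |
| melanopsin KO | = wild type | plateau ≈ 1 everywhere; ~4-min decay |
| rod-only | = wild type | partial (bottom 0.55), EC50 10 lux |
| cone-only | EC50 500 lux, fade 0.12/s | none |
| melanopsin-only | EC50 53 lux, half-life 5 s, 3-s onset delay | EC50 53 lux (no adaptation) |
| ipRGC glutamate KO | EC50 100 lux, half-life 4.8 s, bottom 0.5 | improved (EC50 30 lux, bottom 0.25), pulsatile (120-s period) |
| ipRGC PACAP KO | = wild type | attenuated (EC50 50 lux, bottom 0.4, ~5-min decay) |

The pulsatile glutamate-KO modulation is illustrative only — no
quantitative description of those dynamics exists.

What the generator does **not** emulate: blink/handling artifacts,
autocorrelated measurement error, animal-to-animal parameter variation
(each synthetic mouse differs only by its noise draws), light-history or
circadian effects, and asymmetric detection limits at very small pupils.
Recovery tests passing on this generator therefore demonstrate the
correctness and calibration of the estimators under the assumed noise
model, not robustness to every feature of real video-derived data.

## Problem sizes and tolerances in the test suite

Noiseless recovery is asserted to 1e−6 (relative), against independent
oracles where available: a profiled 2-D zooming grid search for the
sigmoid, closed forms for half-lives, and a pure-python nested-loop
transcription of the feedback recursion (agreement < 1e−12 over a 60-s
horizon at nine intensities). Noisy-recovery checks use 100 replicates
of the 6-mouse × 8-intensity sigmoid design (median |Δlog10 EC50| <
0.1), 200 one-phase traces at 1 Hz/30 s/SD 0.03 (median half-life error
< 10%), and 30 full-pipeline cohort replicates (geometric-mean EC50s
within 20% of the generating values; sustained EC50 above transient in
≥95% of replicates). Feedback bound/saturation checks run at a 300-s
horizon, which is past the deepest transient for every default intensity.

## Known limitations

* The feedback model is an upper bound by construction; it is not fitted
  to data and offers no temporal-summation variant.
* The decay-rate sigmoid's midpoint/slope are not separately
  identifiable from three calibrated rates (see above).
* Group hypothesis testing (ANOVA etc.) is out of scope; only
  descriptive log-scale summaries are provided.
* Genotype parameters other than the wild-type anchors are qualitative;
  comparisons *between* synthetic genotypes are illustrative, not
  quantitative predictions.
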