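# plrkit

Analysis toolkit for the mouse **pupillary light response (PLR)**: the
constriction of the pupil under light, measured as relative pupil area
(RPA = area under light / dark-baseline area). The PLR has two phases —
a *transient* phase within 30 s of light onset and a *sustained* phase
after up to an hour of continuous light — carried by different retinal
inputs (rods, cones, melanopsin) and ipRGC outputs (glutamate, PACAP).
`plrkit` is aimed at pupillometry labs and modelers who want the full
quantitative pipeline for such experiments without the original animal
data: every stage can run on a built-in synthetic generator
parameterized per genotype.

The package provides:

* **`pupil_io`** — pupil-area CSV tables → per-mouse traces, baseline
  normalization, min(5 s, 30 s) transient endpoints.
* **`dose_response`** — constrained variable-slope sigmoid fits
  `rpa(I) = bottom + (top − bottom)/(1 + 10^((logEC50 − log I)·h))` with
  top = 1, bottom ∈ [0, 0.10] (auto-released when never reached), and
  log-scale EC50 statistics.
* **`kinetics`** — one-phase association/decay fits
  `Y = plateau + (Y0 − plateau)·e^(−k t)`, signed-span bi-exponentials,
  half-lives ln 2/k, and the sigmoidal decay-rate-vs-intensity curve.
* **`feedback_model`** — a deterministic "zero-summation packet"
  simulation bounding how much PLR decay pupil-driven feedback
  (retinal lux = RPA × environmental lux) could cause on its own.
* **`heatmap_model`** — time × intensity pupil matrices per genotype and
  necessity / sufficiency / contribution maps
  (contribution = max(necessity, sufficiency)) with RGB composites.
* **`synthetic_data`** — the genotype-parameterized generator (9 mouse
  lines; wild-type anchored at transient EC50 0.53 lux, half-life 1.1 s,
  sustained EC50 7.9 lux).

See `docs/methods.md` for the models, assumptions and parameter choices.

## Worked example

```python
import plrkit.synthetic_data as sd
import plrkit.dose_response as dr
from plrkit import pupil_io, kinetics

lib = sd.default_genotype_library()
wt = lib["wildtype"]

# a cohort of 6 synthetic mice across 6 intensities
cohort = sd.generate_cohort([wt], [0.01, 0.1, 1, 10, 100, 1000],
                            n_per_genotype=6, base_seed=1)
fits = [dr.fit_intensity_response(g["intensity_lux"], g["transient_rpa"])
        for _, g in cohort.endpoints.groupby("mouse_id")]
s = dr.group_ec50_summary(fits)
print(f"transient EC50 geometric mean: {s.geometric_mean:.3f} lux "
      f"(log-SD {s.log_sd:.3f}, n={s.n})")

# constriction kinetics of a noiseless 1000-lux trace
trace = sd.generate_trace(wt, 1000.0, duration=30.0, dt=0.1,
                          seed=1, noise_sd=0.0)
fit = kinetics.fit_one_phase(pupil_io.relative_trace(trace))
print(f"constriction half-life at 1000 lux: {fit.half_life:.2f} s "
      f"(plateau {fit.plateau:.3f})")
```

prints

```
transient EC50 geometric mean: 0.489 lux (log-SD 0.049, n=6)
constriction half-life at 1000 lux: 1.10 s (plateau 0.051)
```

The cohort's geometric-mean EC50 (0.489 lux) recovers the generating
0.53 lux to well within the between-mouse spread, and the one-phase fit
returns the generating 1.1-s half-life; the plateau 0.051 is the nearly
fully constricted pupil at 1000 lux. Running the feedback sweep on the
same wild-type dose-response curve
(`plrkit.feedback_model.feedback_intensity_sweep`) shows feedback alone
re-dilates the pupil by at most ≈0.15 RPA units (at 1 lux, where the
dose-response curve is steepest) — far less than the observed decay at
dim light, which is the model's point.

A `plr` command-line tool wraps the same functionality: `plr synth`,
`plr fit-drc`, `plr fit-kinetics`, `plr simulate-feedback`,
`plr heatmaps` (see `plr --help`).

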