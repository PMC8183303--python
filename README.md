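# pufov — peripheral useful field of view analysis

`pufov` analyses how far into the visual periphery a human observer can
*detect* a change — in color, shape, or motion — while freely viewing a wide
multi-screen display populated with many simultaneous stimuli.  The classical
useful field of view (UFOV) characterises where objects can be *identified*;
the peripheral UFOV (pUFOV) extends this to mere change detection, which
remains possible at far larger eccentricities and differs strongly between
stimulus attributes.  The package targets researchers in visual
psychophysics and driving-simulator studies who need to turn noisy wide-FOV
gaze recordings and keypress logs into eccentricity-dependent detection
profiles.

## What it does

The display is a three-screen simulator (3.05 m x 1.89 m canvases of
1920x1200 px, adjacent planes at 151°, viewer ~3.75 m from the center
screen) showing 150 small objects in a 25x6 grid with 200 px spacing.
During a 5-minute video, 140 events of each change type are scheduled
(visible 1–2 s, same-type events never simultaneous, pauses below 1 s);
the observer fixates the center, looks at a changed object when they notice
it, confirms with a button press, and looks back.

Because tracker noise (mean error ±3.9° horizontal / ±3.4° vertical) is on
the order of the 200 px object spacing, raw gaze samples cannot be assigned
to objects directly.  `pufov` aligns the gaze signal with a Markov model
whose states are the displayed features, combined with a random walk: for a
gaze sample *g_t* the transition weight between features *f_i*, *f_j* is

    T[f_i, f_j] = (1 − e^(−|g_t − f_j|/σ_T)) − (1 − e^(−|g_t − f_i|/σ_T)),

the state vector is updated as *v_t = T v_{t−1}* each sample, and the
aligned fixation *g′_t* is the feature with maximal likelihood.  Changes of
*g′* are saccades; strings of saccades in a similar direction are merged.
Detection, reaction times (change onset → first look, and → keypress) and
saccade amplitudes toward the changed feature are then scored per event,
and a Gaussian perception profile

    p(e) = A · exp(−e² / (2σ²))

is fitted per change type over eccentricity *e*, with *A* the detection
probability at the point of gaze and *σ* the angular width of the
perceptive field.

Because no public gaze data exists for this paradigm, the package ships a
first-class synthetic-participant generator with *known* ground-truth
perception profiles, latencies and per-screen tracker noise, so the entire
pipeline is testable end to end by parameter recovery.

## Worked example

```python
from pufov import StudyConfig, run_study

cfg = StudyConfig(n_participants=5, master_seed=42)
report = run_study(cfg, save_intermediates=False)
for ct, f in report["profile_fits"].items():
    print(f"{ct:>7}: A={f['amplitude']:.3f}  sigma={f['sigma_deg']:.1f} deg")
for row in report["cohort_summary"]:
    print(f"{row['change_type']:>7}: rate={row['detection_rate']:.3f}  "
          f"key RT={row['mean_key_rt_s']:.3f} s  gaze RT={row['mean_gaze_rt_s']:.3f} s")
```

prints

```
  color: A=0.952  sigma=12.5 deg
  shape: A=0.939  sigma=22.7 deg
 motion: A=0.862  sigma=41.9 deg
  color: rate=0.154  key RT=0.743 s  gaze RT=0.354 s
  shape: rate=0.400  key RT=0.757 s  gaze RT=0.402 s
 motion: rate=0.636  key RT=0.752 s  gaze RT=0.417 s
```

Five simulated participants each watch three videos (one instructed change
type per video).  The fitted amplitudes and widths recover the generator's
true profiles — color (0.90, 13°), shape (0.95, 22°), motion (0.90, 45°) —
up to small-cohort noise: color changes are detected almost exclusively
near the gaze direction, motion over a far wider field, mirroring the
ordering seen in human change-detection studies.  Detection rates are the
fraction of instructed events confirmed by a gaze visit plus keypress; the
mean keypress reaction time of ~0.75 s sits in the band typical for this
task.

The same pipeline is available stage by stage from the shell:

```sh
pufov generate --seed 1 --out grid.csv
pufov schedule --grid grid.csv --seed 1 --out events.csv
pufov simulate --grid grid.csv --events events.csv --instructed motion --out session/
pufov align    --grid grid.csv --gaze session/gaze.csv --out aligned.csv
pufov metrics  --grid grid.csv --events events.csv --aligned aligned.csv \
               --keypress session/keypress.csv --instructed motion --out outcomes.csv
pufov fit      --outcomes outcomes.csv --out fits.csv
pufov run-study --seed 5 --participants 10 --out study/
```

All intermediates are plain CSV/JSON, so any stage can be inspected or
replaced; a run is fully reproducible from its config and master seed.

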