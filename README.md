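# gaitrel

Test–retest reliability analysis for markerless motion-capture gait data.

Clinical gait analysis increasingly replaces marker-based optical capture
with video-based markerless systems that output 6-DoF body-segment poses
directly. Before such a system can be trusted diagnostically, its outputs
must be shown to be repeatable — within a session and across sessions days
apart. `gaitrel` implements the complete analysis chain used for that kind
of reliability study, for biomechanists and clinical-movement scientists:

1. **Kinematics** — segment poses (4×4 homogeneous transforms per frame,
   lab axes X = mediolateral, Y = anteroposterior, Z = vertical) are turned
   into joint angles (distal relative to proximal) and segment angles
   (relative to the direction of gait progression) by fixed x-y-z Cardan
   decomposition; frontal/transverse components are negated on the left so
   both limbs share one clinical sign convention.
2. **Gait events** — heel strike and toe off are detected without force
   plates, from zero crossings of the anteroposterior velocity of the
   proximal (heel) and distal (toe) foot points relative to the pelvis.
3. **Spatiotemporal parameters** — per cycle: stance, swing, step, stride
   and double-support times, cadence (steps/min and strides/min), step and
   stride length, stride width and speed, with the identities
   stance + swing = stride and speed × stride time = stride length exact by
   construction.
4. **Waveforms** — each angle curve is time-normalized to 101 points over
   0–100 % of the gait cycle (consecutive ipsilateral heel strikes).
5. **Reliability statistics** — waveform repeatability via the coefficient
   of multiple determination

   CMD = 1 − [Σ(Y_wt − Ȳ_t)² / (T(W−1))] / [Σ(Y_wt − Ȳ)² / (WT−1)],

   scalar repeatability via the two-way mixed-effects consistency
   intraclass correlation ICC(3,k) = (BMS − EMS)/BMS with its F-based 95 %
   CI, SEM = SD·√(1 − ICC(3,1)) and MDC = 1.96·√2·SEM, within sessions
   (subject-session rows × sampled trials) and between sessions (subjects ×
   session means).

A **synthetic gait-study generator** stands in for the capture hardware: it
emulates the reference design (9 subjects × 3 sessions × 5 trials, 100 Hz,
one bilateral gait cycle per trial = 135 trials) with a hierarchical
variance structure (subject / session / trial effects plus frame noise) and
exact programmed ground truth for events, parameters and angle curves, so
the whole pipeline is testable end to end with no motion-capture data.

## Worked example

```python
import gaitrel as g

study = g.generate_study(g.StudyDesign(seed=42))          # 135 trials
report = g.run_study(study, g.AnalysisConfig(sampling_seed=42))

st = report.spatiotemporal_table
row = st.loc["cycle_time_s"]
print(f"cycle time      : {row['mean']:.3f} +/- {row['sd']:.3f} s")
print(f"  within-session ICC(3,k) {row['within_icc']:.3f} "
      f"(SEM {row['within_sem']:.3f} s, MDC {row['within_mdc']:.3f} s)")
```

prints

```
trials analyzed : 135
cycle time      : 1.115 +/- 0.058 s
  within-session ICC(3,k) 0.990 (SEM 0.012 s, MDC 0.034 s)
  between-session ICC(3,k) 0.964 (SEM 0.018 s, MDC 0.051 s)
knee sagittal CMD: within 0.998, between 0.996 (large)
```

Read: across the simulated cohort the mean gait cycle lasts 1.115 s with a
0.058 s between-trial SD; trial-to-trial agreement within a session is
excellent (ICC 0.990), and a change of more than 0.034 s in an individual's
cycle time would exceed same-day measurement error at 95 % confidence.
Sagittal-plane knee curves are nearly identical across repeats (CMD close
to 1), the pattern expected of a reliable capture system.

A shell interface mirrors the same steps:

```sh
gaitrel simulate --out study.json --subjects 9 --sessions 3 --trials 5 --seed 42
gaitrel analyze --in study.json --out report/ --formats csv,markdown
gaitrel report --in report/
```

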