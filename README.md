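# gespeech

Multi-scale analysis of how human communicative behaviour adapts when the
**visual** channel of a conversation is parametrically degraded.  The
package is built for researchers in multimodal communication and gesture
studies who work with video pose-tracking output, gesture annotations and
speech audio from dyadic interaction experiments in which visual quality
is stepped through ten grades of blur (240 s each).

It measures adaptation at three levels:

* **articulator level** — motion energy `E = Σₜ ‖Δp(t)‖` (summed
  frame-to-frame pixel displacement) of torso, head, arms and fingers,
  each corrected for its reference articulator (head/arms by the torso,
  fingers by the arms) by differencing in reference-relative coordinates;
* **system level** — wavelet coherence and phase asynchrony between the
  speech amplitude envelope and hand speed in the 2–8 Hz (125–500 ms)
  syllabic band, with cell-wise surrogate significance (p < 0.05);
* **signal level** — per-gesture kinematics (peak velocity, submovement
  count, hold-time, size, McNeillian space category, depth, nPVI) and
  speech acoustics (intensity in dB, F0 in Hz) split into
  speech-with-gesture vs speech-only samples.

Statistical testing follows a polynomial mixed-model comparison ladder:
for each response *y* and orthogonal polynomials *P₁, P₂* of blur grade,

```
y ~ 1 + (RE)          (null)
y ~ P₁ + (RE)         (linear)
y ~ P₁ + P₂ + (RE)    (quadratic)
```

fitted by maximum likelihood with nested dyad/participant (or global
participant) random effects, optionally a gesture-type intercept.  A
quadratic blur effect is declared only when the quadratic model beats
**both** the null and the linear model by likelihood-ratio test.  Families
are Gaussian, Poisson (submovement counts), Gamma with log link
(strictly positive kinematics) and cumulative-link ordinal (gesture
space).  Explained variance is reported as conditional R²
((σ²_fixed + σ²_random) / σ²_total), ΔR²C over the null, and
R²LR = 1 − exp(−LR/n).  Multiple testing uses the correlation-adjusted
Bonferroni level α/k^(1−r̄) for k tests with mean pairwise correlation r̄.

Because raw recordings of this kind are not redistributable, the package
ships a synthetic dyad generator whose gestures are sequences of
minimum-jerk hand pulses with fully known ground truth (pulse count,
inter-pulse stillness, peak speed 1.875·A/T, spatial extent, forward
reach), speech envelopes coupled to hand speed at a configurable lag, and
blur-grade effect shapes injected as quadratic multipliers.

## Worked example

```python
import numpy as np
from gespeech import GeneratorConfig, adjusted_alpha
from gespeech.synthetic_data import generate_session, simulate_feature_table
from gespeech.kinematics import feature_table
from gespeech.stats import ladder_test

# per-gesture features from one synthetic session
cfg = GeneratorConfig(n_dyads=1, grade_duration_s=24.0, seed=3)
s = generate_session(cfg, dyad=0, member=0)
feats = feature_table(s.front, s.events, s.side)
print(feats[["event_id", "peak_velocity", "submovements", "hold_time",
             "size", "mcneillian_space", "depth"]].head(4).round(1).to_string(index=False))

# blur-grade ladder on a study-scale feature table (20 dyads)
study = simulate_feature_table(GeneratorConfig(n_dyads=20, seed=1))
res = ladder_test(study, "size", family="gamma_log")
print(f"size ~ poly(grade,2): chi2(2) = {res.chi_square:.2f}, p = {res.p:.3g}")
print(f"quadratic coefficient: {res.coefficients['bg2'][0]:.2f}; "
      f"significant: {res.significant}")
print("adjusted alpha, six kinematic tests:", adjusted_alpha(6, 0.283))
```

prints

```
    event_id  peak_velocity  submovements  hold_time    size mcneillian_space  depth
d00p0_ev0000          687.9             2        0.4 24001.5        periphery   55.1
d00p0_ev0001          531.5             1        0.0 66383.5  extra-periphery   63.2
d00p0_ev0002         2417.7             4        0.0 86548.0  extra-periphery  178.4
d00p0_ev0003           70.1             1        0.0 38099.1  extra-periphery   87.3
size ~ poly(grade,2): chi2(2) = 271.60, p = 1.05e-59
quadratic coefficient: -8.52; significant: True
adjusted alpha, six kinematic tests: 0.014
```

Each row is one annotated gesture: peak hand speed in px/s, the number of
ballistic submovements, cumulative hold-time in s, bounding-box size in
px², the most extreme gesture-space region visited, and the side-view
depth in px.  The ladder output shows a strongly significant inverted-U
(negative quadratic) association between blur grade and gesture size —
the generator's injected mid-blur enlargement, recovered by the Gamma
mixed model.  The adjusted alpha is the significance level such a family
of six correlated kinematic tests must beat.

A command-line pipeline mirrors the library:

```sh
gespeech all --config config.yaml --seed 1 --out runs/run0
```

with stages `simulate → extract → align → model → report`, tidy CSV
outputs and a JSON manifest that makes completed stages idempotent.

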