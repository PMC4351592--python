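# choicedecode

Analysis pipeline for chronic motor-cortical ensemble recordings during
directional-choice learning: a rat self-starts a trial, a left or right
light cue appears, and 2 s later the animal reports its choice with a
left or right lever press. `choicedecode` asks how the recorded ensemble
(typically 3–6 simultaneously recorded single units) represents that
choice, and how the representation changes as the association is learned
over weeks of daily sessions.

The package is aimed at systems-neuroscience analysts who have sorted
spike times and trial event tables and want (a) classical ensemble rate
statistics, (b) a resampled linear-classifier readout of single-trial
choice, and (c) session-trend statistics that decide whether either is
changing with learning. A synthetic generator with matched statistical
structure makes every stage testable without recordings.

## The statistics at the core

**Ensemble rate measures.** Trials are labelled `L-L` / `R-R` (correct
left / right choices; `L-R`, `R-L` are errors — cue side first, press
side second). For unit *i* in session *k*, with class-mean window rates
*M<sup>i</sup><sub>L</sub>(k)* and *M<sup>i</sup><sub>R</sub>(k)*
(100 ms boxcar sliding at 20 ms, averaged over an analysis window):

- *M<sup>i</sup>(k)* = (*M<sup>i</sup><sub>L</sub>* + *M<sup>i</sup><sub>R</sub>*)/2,
  *D<sup>i</sup>(k)* = *M<sup>i</sup><sub>L</sub>* − *M<sup>i</sup><sub>R</sub>*
- ensemble mean rate *M(k)* = (1/N) Σ<sub>i</sub> *M<sup>i</sup>(k)*;
  ensemble mean rate difference *D(k)* = (1/N) Σ<sub>i</sub> |*D<sup>i</sup>(k)*|

**Spatiotemporal decoding.** Each trial becomes a spike-count vector:
the cue-on window CO (300–1800 ms after cue) split into three 500 ms
bins per unit, concatenated unit-major (dimension 3 × N). Per session,
100 classifiers are trained and tested: each repeat draws a constant
number of trials per class, holds out 20% as single-trial test samples,
and converts the remaining 80% into trial-averaged training samples
(each the mean of 5 same-class vectors). A linear-kernel SVM (or LDA)
yields the decision function *df(x) = Σ α<sub>i</sub> K(s<sub>i</sub>, x) + b = w·x + b*;
*df ≥ 0* reads out a left choice. Session accuracy is the mean over the
100 repeats, and the discriminability metric is the distance between
class-mean *df* values of test samples. Controls include label-shuffled
training (chance ≈ 50%), single-unit and single-bin decoding, bin-size
sweeps, ensemble-size curves, and a 1-D control that decodes from the
ensemble mean rate alone.

**Learning trends.** Session measures are Z-scored per subject and
regressed on normalized session number (0 → first, 1 → last); the slope
sign is called from its 99% confidence interval (positive / negative /
zero). Stage summaries split sessions into three equal stages, and an
ANCOVA interaction compares slopes of two measures on a common axis.

## Worked example

```python
import numpy as np
from choicedecode import (GeneratorConfig, ProtocolConfig, run_protocol,
    simulate_experiment, unit_and_ensemble_summary, normalize_sessions,
    slope_with_ci, zscore_over_sessions)

cfg = GeneratorConfig(n_sessions=18, pattern_mode="pattern_rotation",
                      tuning_amplitude_schedule=tuple(np.linspace(0.0, 4.0, 18)),
                      seed=42)
sessions = simulate_experiment(cfg)
pc = ProtocolConfig(n_repeats=100, seed=0)
accs = [run_protocol(s, pc).mean_accuracy for s in sessions]
m_k = [unit_and_ensemble_summary(s, "CO").ensemble_mean_rate for s in sessions]
x = normalize_sessions([s.session_index for s in sessions])
reg_acc = slope_with_ci(zscore_over_sessions(accs), x)
reg_m = slope_with_ci(zscore_over_sessions(m_k), x)
```

Output:

```
decoding accuracy session 1: 0.522  session 18: 0.874
Z-scored accuracy slope = 3.03, 99% CI = [2.30, 3.75] -> positive
Z-scored M(k) slope    = 0.91, 99% CI = [-1.32, 3.14] -> zero
```

This is the dissociation the pipeline is built to detect: the generator
redistributes a growing class-difference budget across units and time
bins with zero net rate change (`pattern_rotation`), so the ensemble
mean rate *M(k)* stays flat (sign call `zero`) while spatiotemporal
decoding accuracy climbs from chance to 87% (sign call `positive`).
A `rate_offset` generator instead puts the difference into mean rates,
which both *D(k)* and the decoder pick up.

The same pipeline runs from the shell on the CSV/JSON session
interchange:

```bash
choicedecode report --seed 1 --out-dir out/        # simulate -> rates -> decode -> trends
choicedecode dump-config                           # all defaults, INI format
```

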