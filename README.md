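# vocogaze

Tools for studying **lexical competition in degraded speech** with the
visual-world paradigm and pupillometry. When a listener hears Dutch
*bok…*, both *bok* (goat) and *bokser* (boxer) are briefly active; the
duration of the first syllable is a cue that resolves the competition.
Cochlear-implant users receive a spectrally degraded signal, and the
question is whether such degradation delays the use of durational cues
(visible in gaze to pictured referents) and raises mental effort (visible
in pupil dilation). This package re-implements the full computational
chain of such an experiment as tested, reusable code, and ships a
synthetic-data generator with known ground truth so every stage can be
validated end to end.

## What's inside

| module | role |
|---|---|
| `vocogaze.vocoder` | acoustic CI simulation: 8-channel sinewave vocoder, bands equally spaced on the basilar membrane via Greenwood's map `F(x)=A(10^{ax}−k)`; envelopes by half-wave rectification + 4th-order Butterworth low-pass at 300 Hz |
| `vocogaze.stimuli` | cross-splicing of sentence tokens into target-matching / target-mismatching duration conditions; synthetic 26-pair + 40-filler inventory (duration differences on [20, 120] ms, mean 65 ms) |
| `vocogaze.ocular` | 250-Hz trace cleaning: blink detection, median-anchored linear interpolation (<300 ms), trial/participant screening, baselines, `%ERPD = (obs − base)/base × 100`, epoching, fixation counting |
| `vocogaze.fixation` | 3×3 display grid AOIs, fixation-proportion time curves with 95% CIs, target/competitor crossover detection, lowess display smoother (span 0.5) |
| `vocogaze.gca` | growth-curve analysis on orthogonal polynomials (4th-order logistic for fixations, 3rd-order linear for %ERPD), participant random coefficients, sequential likelihood-ratio model comparison; in-package Laplace GLMM cross-checked against lme4 |
| `vocogaze.simulate` | ground-truth session generator: 62 trials (26 critical), gaze as a Markov dwell process whose occupancy tracks the generating curves exactly, pupil templates recovered exactly by the %ERPD formula, AR(1) noise and blinks |
| `vocogaze.pipeline` / `vocogaze.cli` | one-config reproducible runs and the `vocogaze` command-line tool |

## Worked example

```python
import numpy as np
from vocogaze import (SessionConfig, generate_session, screen_trial, epoch,
                      compute_baseline, erpd, AOILayout, label_epoch,
                      proportion_curves, crossover_time)

layout = AOILayout()
epochs, labels = [], []
for p in range(12):  # twelve simulated participants
    session = generate_session(SessionConfig(presentation="NS", seed=p))
    for trial in session.trials:
        result = screen_trial(trial, session.trace)  # blink rules + click check
        if result.keep and trial.condition != "filler":
            ep = epoch(result.trace, trial, participant=f"p{p:02d}")
            epochs.append(ep)
            labels.append(label_epoch(ep, layout))

curves = proportion_curves(epochs, labels)
for cond in ("target_matching", "target_mismatching"):
    c = curves[(cond, "NS")]
    t = crossover_time(c.time_ms, c.role("target"), c.role("competitor"),
                       persistence_ms=400.0)
    print(f"{cond}: {c.n_trials} trials, target overtakes competitor at {t:.0f} ms")

session = generate_session(SessionConfig(presentation="NS", seed=0))
b2 = compute_baseline(session.trace, kind=2,
                      first_sentence_onset_ms=session.first_sentence_onset_ms)
ep = epoch(session.trace, session.trials[0])
curve = erpd(ep.pupil, b2)
print(f"peak %ERPD {curve.max():.1f}% at {ep.time_ms[np.argmax(curve)]:.0f} ms "
      "after word onset")
```

Output:

```
target_matching: 145 trials, target overtakes competitor at 716 ms
target_mismatching: 143 trials, target overtakes competitor at 800 ms
peak %ERPD 7.2% at 912 ms after word onset
```

When the duration cues mismatch the target, the crossover — the moment the
target picture wins lexical competition — comes later (800 vs 716 ms here;
the generating offset is 120 ms, and a dozen participants estimate it
coarsely), and the session-baseline pupil dilation peaks about 0.9–1 s
after the word, the slow time course typical of effort-related dilation.

From the shell:

```bash
vocogaze vocode --channels 8 in.wav out.wav      # CI simulation
vocogaze simulate --preset DS --seed 7 --out sim/
vocogaze analyze fixations sim/trace_p000.tsv sim/trials_p000.tsv --plot curves.png
```

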