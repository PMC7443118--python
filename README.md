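# whatwhere

A dual foveal–peripheral ("What"/"Where") visual processing model for
saccade selection on cluttered displays.

Biological vision does not scan images pixel by pixel: a high-acuity
fovea inspects one location while a log-polar peripheral code — sharp
at the center of gaze, coarse at the periphery — decides where to look
next.  `whatwhere` implements a complete, trainable model of this
division of labor for a visual search task: find and identify a single
small target (one of 10 classes) hidden in a large band-pass-noise
display.

The model has two pathways, in an actor–critic arrangement:

- **What (critic)** — a convolutional classifier over the 28×28 foveal
  patch with sigmoid outputs; the per-class likelihoods p(y|x) quantify
  both the answer and its confidence.  Its maximum is the *foveal
  accuracy*.
- **Where (actor)** — a fully connected network mapping the
  2,880-coefficient log-polar retinal code of the whole display to a
  240-cell retinotopic *accuracy map* (10 eccentricities × 24
  azimuths, like a collicular motor map): for every possible saccade
  `a`, the predicted probability p(correct | a) that the classifier
  would succeed after executing it.  It is trained against ground-truth
  maps built by translating the classifier's measured shift-accuracy
  transfer curve to the target's position, with per-cell binary
  cross-entropy.

The policy compares the two predictions at every fixation:

    answer     if  max_y p(y|x)  ≥  max_a p(correct|a)
    saccade to argmax_a otherwise,

iterating up to a saccade budget.  Each saccade's benefit is the
information gain `log p(y|x') − log p(y|x)` at the true label.

Everything is generated internally (noise textures, targets, displays);
no data is downloaded.  Tests and the acceptance script use a packaged
synthetic glyph bank; an IDX reader is provided for running the
full-scale protocol on the classic handwritten-digit set.

## Worked example

Train the whole system at reduced scale (~6 minutes on one CPU core)
and measure the value of one saccade:

```python
import numpy as np
from whatwhere import ci_profile, make_glyph_dataset, make_trial, run_pipeline

train_bank, val_bank = make_glyph_dataset(120, seed=0).split(0.2)
profile = ci_profile()
system = run_pipeline(profile, train_bank, val_bank, seed=1, verbose=True)

agent = system.agent()
for ecc in [4, 20, 30]:
    rng = np.random.default_rng([ecc, 99])
    pre = post = 0
    for _ in range(200):
        disp = make_trial(rng, val_bank, (0.7, 0.7), float(ecc), profile.noise)
        pre += agent.run_trial(disp, forced_saccades=0).success
        post += agent.run_trial(disp, forced_saccades=1).success
    print(f"eccentricity {ecc:2d}px: presaccadic {pre/200:.3f}  "
          f"postsaccadic {post/200:.3f}")
```

Output of this exact script:

```
[whatwhere] profile=ci seed=1
[whatwhere] What pathway trained (clean centered val acc: 1.0)
[whatwhere] shift map measured (center=0.31, border=0.10)
[whatwhere] Where pathway trained (BCE 0.3491 -> 0.3327, floor 0.3323)
eccentricity  4px: presaccadic 0.445  postsaccadic 0.295
eccentricity 20px: presaccadic 0.140  postsaccadic 0.290
eccentricity 30px: presaccadic 0.070  postsaccadic 0.280
```

Reading it: the centered-stage classifier is perfect on clean glyphs;
under clutter its accuracy at the fovea is 31% (averaged over contrasts
30–70%) decaying to the 10% chance level with target shift; the Where
loss converges essentially to its Bernoulli-entropy floor.
Behaviorally, a target 4 px from fixation is best answered directly (a
saccade only risks de-centering it), while at 20–30 px — where the
peripheral code can still *detect* the target but the fovea cannot
*identify* it — a single saccade roughly triples accuracy.  That
crossover is the model's central claim.

## Command line

```sh
whatwhere generate --n 10 --contrast 0.7 --seed 0 --out displays/
whatwhere train --profile ci --seed 1 --out trained_system/
whatwhere evaluate --experiment fig4 --system-dir trained_system/ --out results.csv
whatwhere demo-trial --system-dir trained_system/ --eccentricity 24
whatwhere fixtures-export --out glyphs/
```

`--profile paper` selects the full-scale protocol (75-epoch curriculum
of 60,000 samples, 60×60,000 Where training, 1,000 trials per
condition); combine with `--mnist-dir` pointing at local IDX files to
reproduce published-scale numbers (hours of CPU).

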