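# ihhop

Detection of **intermittent high-frequency high-amplitude oximetry patterns
(IHHOP)** in arterial-oxygen-saturation (SaO2) time series, via the **optimal
recurrence threshold** ε_opt computed in rolling windows, together with the
standard oxygen-desaturation metrics (ODI, ODD) and a sleep-apnea screening
harness.

## Who this is for

Intradialytic and overnight pulse-oximetry traces of patients with
sleep-disordered breathing show repetitive sawtooth desaturation trains —
dips of ~3–10 percentage points recurring every few tens of seconds.
Classical detection (oxygen desaturation index and density) hinges on a
baseline and a rigid event template, both fragile in patients whose
saturation is already low or drifting, e.g. during hemodialysis. This
package implements a baseline-free alternative grounded in recurrence
quantification analysis, for researchers working with single-channel SpO2/
SaO2 recordings at 1 Hz or 0.1 Hz.

## The biomarker

For a signal segment x, the recurrence plot is

    R_ij = Θ(ε − |x_i − x_j|),

and determinism is the fraction of recurrent pairs lying on diagonal lines
of at least l_min points,

    DET(ε; l_min) = Σ_{ℓ≥l_min} ℓ P(ℓ, ε) / Σ_{ℓ≥1} ℓ P(ℓ, ε),

where P(ℓ, ε) is the histogram of maximal diagonal line lengths (the line of
identity excluded).  The biomarker is the threshold at which DET rises
fastest,

    ε_opt(l_min) = argmax_ε  d DET(ε; l_min) / dε.

Ordered, quasi-constant saturation reaches high DET at a small threshold
(small ε_opt); segments carrying large irregular oscillations need a much
larger one.  l_min spans about 10 s of signal: 10 samples at 1 Hz, 2 at
0.1 Hz.  ε_opt series are computed in rolling windows (5 min for
distributions and classification, 10 min for comparison with the
desaturation density), each window's three-way class — *no / maybe / with*
IHHOP — cut at Jenks natural-breaks boundaries (reference values 0.33 / 0.73
SaO2 percentage points).

## Worked example

```python
import numpy as np
from ihhop import (Episode, SyntheticConfig, generate_record, preprocess,
                   rolling_eps_opt, compute_baseline, detect_desaturations,
                   odi, classify_ihhop)

cfg = SyntheticConfig(duration_s=3600.0,
                      episodes=[Episode(1500.0, 2400.0, "ihhop")], seed=7)
record, truth = generate_record(cfg)
clean = preprocess(record)                       # clip <75%, 0.25 Hz low-pass
series = rolling_eps_opt(clean, window_s=300.0, step_s=60.0)
baseline = compute_baseline(clean)
events = detect_desaturations(clean, baseline, n_pct=3.0)
```

This prints (via the obvious formatting):

```
baseline      : 94.0 %
desaturations : 13 events, ODI 13.0 /h
eps_opt range : 0.29 - 1.46
peak window   : 2100-2400 s (episode injected at 1500-2400 s), class 'with'
quiet windows : median eps_opt 0.33, class 'no'
```

The rolling ε_opt stays near 0.33 over quiet saturation ("no IHHOP"), and
peaks at 1.46 in a window inside the injected sawtooth episode ("with
IHHOP"); the 13 detected desaturations all fall inside that episode.

The same stages are available from the shell:

```
ihhop simulate --out rec.csv --truth truth.json --seed 7 --duration 3600
ihhop preprocess --in rec.csv --out clean.csv
ihhop epsopt --in rec.csv --out eps.csv --window 300 --step 60
ihhop odd --in rec.csv --out odd.csv --n-pct 3
ihhop classify --segments seg0.csv --segments seg1.csv ... --report report.json
```

sklearn-style estimators (`EpsOptExtractor`, `IhhopClassifier`,
`SasScreener`) expose the same computations for pipeline composition and
model selection.

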