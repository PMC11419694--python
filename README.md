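# mocmask

Closed-loop model of the auditory brainstem and midbrain with medial
olivocochlear (MOC) efferent control of cochlear gain, built to simulate
**forward masking**: the elevation of detection threshold for a brief probe
tone that follows a masker.

## Who this is for

Auditory neuroscientists and psychoacousticians who want a compact,
inspectable simulation of the hypothesis that *efferent gain reduction* — not
persistence of the masker response — underlies much of physiological and
psychophysical forward masking. The package reproduces three experiments at
desk scale:

1. **Growth of masking (GOM)** — masked probe threshold vs masker level
   (100 ms masker, 25 ms probe, 2.83 ms delay, 61% criterion);
2. **Masking vs masker–probe delay** — 200 ms masker at 40 dB SL, 20 ms
   probe, delays 0–150 ms, 70.7% criterion;
3. **Roving masker level** — 200 ms masker fixed at 70 dB SPL or roved per
   interval (Gaussian, SD 6 dB, ±3 SD), on-frequency (4 kHz) or
   off-frequency (2.4 kHz), probe at 4 kHz; thresholds should *not* change
   under the rove.

## The model

A single 4 kHz channel with five stages (all rates in spikes/s):

* **Cochlear filter** — gammatone tip (human sharpness, Q<sub>ERB</sub> ≈ 19)
  whose gain *g(t)* ∈ [−40, 0] dB the MOC loop controls, plus a fixed
  passive tail (−35 dB) that carries off-frequency excitation;
* **IHC / synapse** — rectification, saturation and low-pass, then a
  rate-level sigmoid with depletion-style adaptation
  (dq/dt = (1−q)/τ − q·r/D, output r = q·r_static) for a high-spontaneous-rate
  (HSR) fiber and a wide-dynamic-range (WDR/LSR) fiber;
* **MOC stage** — first-order gain dynamics (τ = 80 ms) driven by the
  rectified-above-spontaneous WDR rate plus a fluctuation-driven bandpass
  modulation-filter IC signal: louder maskers ⇒ deeper gain reduction ⇒
  smaller probe responses;
* **IC SFIE** — same-frequency inhibition–excitation cascade (CN stage, then
  IC stage with an additional slow inhibitory input), onset-dominated, with a
  band-enhanced modulation transfer function peaking at 64 Hz;
* **2IFC decision stage** — two-interval forced choice, method of constant
  stimuli: per interval, the maximum (sliding 5 ms) of a stochastic rate
  realization inside a decision window; a maximum-likelihood logistic fit
  P(c) = 0.5 + 0.5/(1 + e^−(L−m)/s) gives the threshold at the 61% or 70.7%
  criterion.

Trial-to-trial variability is injected as auditory-nerve rate noise (white +
slow drift) and propagated through the SFIE stage for IC decisions; Poisson
spike-count and additive-Gaussian decision noise are available behind the
same interface.

## Worked example

```python
import numpy as np
from mocmask import run_delay_curve

result = run_delay_curve(seed=1, delays=(0.0, 0.15), n_trials=100)
for (stage, eff), dec in result.extras["decrease_db"].items():
    print(f"{stage:>2s} efferents={eff!s:<5}: decrease 0->150 ms = {dec:5.1f} dB")
```

prints (seed 1):

```
an efferents=True : decrease 0->150 ms =  16.1 dB
ic efferents=True : decrease 0->150 ms =  18.1 dB
an efferents=False: decrease 0->150 ms =   6.6 dB
ic efferents=False: decrease 0->150 ms =  12.3 dB
```

i.e. the masked threshold of the IC model with efferents falls by ~18 dB as
the masker–probe delay grows from 0 to 150 ms, while the auditory-nerve model
without efferents — the "anesthetized" configuration — shows only ~7 dB of
forward masking. Enabling the efferent loop roughly triples the masking at
short delays; that gap is the modeled contribution of MOC gain control.
`result.unmasked` holds the probe-in-quiet thresholds (this run: IC 1.0 and
AN 6.5 dB SPL), and `result.table` the per-delay thresholds and suppression
in dB SL.

The same library surface drives the other paradigms
(`run_gom`, `run_rove`, `measure_mtf`), and a thin CLI wraps them:

```bash
mocmask simulate --masker-level 70 --delay 0.003 --efferents   # five stage traces
mocmask mtf                                                    # MTF table + BMF
mocmask delay-curve --seed 1 --outdir results/
mocmask rove --seed 1 --outdir results/
```

Paradigm parameter files live in `configs/` (gom.yaml, delay.yaml,
rove.yaml).

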