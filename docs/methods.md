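# Model and methods

This note documents the science implemented in `mocmask`: the model
equations, the parameters that matter and how their defaults were chosen,
what the stimulus generator does and does not emulate, the numerical
choices, and the known limitations.

## Problem

Forward masking — the elevated detection threshold of a brief probe tone
after a masker — is classically attributed to masker energy persisting into
a temporal integration window. Physiology argues otherwise: at the level of
the inferior colliculus (IC), masking mostly appears as a *reduced probe
response*, not a persistent masker response. The model implemented here
tests the hypothesis that medial olivocochlear (MOC) efferent feedback,
which turns down cochlear-amplifier gain when the periphery is driven,
produces that probe-response reduction: a masker lowers the gain, the gain
recovers slowly (tens of milliseconds), and a probe presented before
recovery is processed at effectively lower level.

## Architecture

One cochlear channel at CF = 4 kHz feeds two auditory-nerve (AN) fibers, a
feedback IC model inside the MOC loop, and an onset-type IC model used for
detection decisions.

### Cochlear filter

The active "tip" is a 4th-order gammatone implemented as a cascaded complex
one-pole resonator, bandwidth set by human-like sharpness
Q_ERB = 19.2 at 4 kHz (ERB ≈ 208 Hz), normalized to unit gain at CF. Its
input is multiplied by the MOC gain factor 10^(g/20), g ∈ [−40, 0] dB.
A second, passive "tail" path (2nd-order resonator, bandwidth 2.5 kHz,
−35 dB re the tip, *not* under efferent control) carries the broadly tuned,
unamplified response of the basilar membrane; it is what lets a 2.4 kHz
masker at high level excite the 4 kHz channel (effective level ≈ 32 dB SPL
for a 70 dB SPL masker) and drive the efferent loop without being attenuated
by the loop's own gain changes.

### IHC and synapse

Transduction is half-wave rectification, a saturating nonlinearity
r/(1 + r/0.2 Pa), and a 4-pole low-pass at 2.5 kHz; the envelope is then
expressed as an equivalent level L(t) in dB SPL (calibrated so a steady CF
tone maps to its own level). Each fiber has a static rate

    r_static(L) = spont + (sat − spont) · σ((L − midpoint)/slope)
                  [+ sloping · max(L − knee, 0)]

and depletion-style adaptation: a releasable resource q ∈ [0, 1] obeys

    dq/dt = (1 − q)/τ_a − q · r_static / D,      r_out = q · r_static,

so onsets from silence are (nearly) undepleted, steady-state rates are
scaled by q_ss = 1/(1 + τ_a·r_static/D), and a probe shortly after a masker
is *multiplicatively* reduced by the still-depleted q — the synaptic
component of forward masking, recovering with τ_a as the masker–probe delay
grows. This multiplicative form was chosen over subtractive (high-pass)
adaptation because only a reduction of the probe response itself produces
forward masking of the size seen in onset-type neurons; subtractive
adaptation largely cancels between the two 2IFC intervals.

Defaults (calibrated; all config-exposed):

| parameter | HSR | WDR/LSR | units |
|---|---|---|---|
| spont | 60 | 1 | sp/s |
| sat | 250 | 120 | sp/s |
| midpoint / slope | 23 / 9 | 45 / 12 | dB SPL / dB |
| sloping saturation | 1.5 above 60 dB SPL | — | sp/s per dB |
| τ_a / D | 80 ms / 14 | — (non-adapting) | s / spikes |

The HSR contract: steady rate saturated at or below 40 dB SPL (steady rates
to 40 vs 70 dB SPL tones agree within 10%; the shallow sloping-saturation
component keeps *onset* responses level-dependent at high levels, as in real
HSR fibers). The LSR fiber is the wide-dynamic-range (WDR) efferent input:
monotone growth over 0–90 dB SPL, no adaptation, so the MOC drive tracks
masker level.

### MOC stage

Gain follows first-order dynamics toward a target set by the rectified
drive,

    target = −clip(w_wdr·(r_wdr − spont)₊ + w_ic·r_icfb, 0, 40 dB),
    dg/dt = (target − g)/τ_moc,

with w_wdr = 0.53 dB/(sp/s), w_ic = 0.05, τ_moc = 80 ms (a single constant;
separate rise/decay constants are supported). The loop runs block-wise with
1 ms blocks (gain constant within a block); MOC dynamics are slow relative
to 1 ms, and with the loop disabled the result is numerically identical to
the open-loop no-efferent model (same filter recursions, gain ≡ 0 dB).
For tone maskers essentially all drive comes from the WDR path; the
fluctuation-driven path (a rectified 2nd-order bandpass at 64 Hz on the HSR
rate) contributes only at onsets. w_wdr and τ_moc were calibrated against
the delay-curve experiment (below); the resulting gain reduction for a
~45 dB SPL masker is ≈ 10–14 dB at masker offset, recovering with τ_moc.

### IC models

Two IC stages with different roles. The *feedback* IC inside the loop is the
simple bandpass modulation filter (it may ring after offset, which is
harmless there). The *decision* IC is the same-frequency
inhibition–excitation (SFIE) cascade: CN stage then IC stage, each computing
excitation minus delayed, slower inhibition (unit-area alpha-function
kernels, impulse-invariant IIR), half-wave rectified. The IC stage carries
an additional **slow inhibitory input** (strength 0.34, τ = 35 ms, same
delay): too sluggish to track modulation near the best modulation frequency,
but integrating recent stimulus history, so a masker's activity suppresses
the IC response to a probe at short delays — a forward-masking component
expressed at the midbrain, distinct from (and on top of) the cochlear-gain
and synaptic components. Without it the no-efferent IC model shows only
about half the forward masking seen in onset-type IC recordings.

SFIE defaults: CN τ_exc/τ_inh/delay/strength = 0.5/2/1 ms/0.6, IC = 1/2/2
ms/0.9, slow inhibition 0.34 at τ = 35 ms. The time constants were tuned so
the modulation transfer function (average rate to 100% AM CF tones, octave
grid 2–512 Hz, carrier 30 dB SPL) is band-enhanced with best modulation
frequency 64 Hz (margin ≈ 10% over the 32 Hz neighbor); onset-to-steady
ratio for a 200 ms tone < 0.2; no post-offset ringing.

### Decision stage

Two-interval forced choice, method of constant stimuli, 100 trials per
probe level, ML logistic fit with chance lower asymptote; threshold at 61%
(GOM, matching the physiological analysis it emulates) or 70.7% (all other
cases). Decision windows:

* physiological — 40 ms starting 5 ms after probe onset, shifted with the
  masker–probe delay (the model's few-ms latency keeps the probe response
  inside and the masker response outside);
* psychophysical — fixed 150–300 ms re stimulus start, never shifted (used
  only for the rove paradigm).

The deterministic closed loop is computed once per unique trial spec and
cached; stochasticity enters per trial. Default noise model: Gaussian rate
noise at the AN — a white component (7.5 sp/s) plus a slow excitability
drift (13 sp/s, one-pole at 1.5 Hz), a two-band stand-in for the
low-frequency-heavy variability of AN discharge — added to the HSR rate and,
for IC decisions, propagated through the SFIE stages. The drift dominates
the AN's window-max statistic (it shifts whole windows between intervals)
while the SFIE's modulation tuning rejects most of it, which is what gives
the IC its ~4 dB unmasked-threshold advantage over the AN. The decision
variable is the maximum over a sliding 5 ms sub-window (a mean-rate variant
exists for contrast analyses); ties are broken by a fair coin. Poisson
spike-count (pool of 40 fibers) and additive-Gaussian variants are available
behind the same interface; the rove-stability property holds under them too.

## Stimulus generator

All inputs are synthesized: raised-cosine-ramped tones, levels in dB SPL
(steady-portion RMS re 20 µPa, exact to <0.1 dB), assembled as
pre-silence | masker | gap | probe-or-silence | post-silence at 100 kHz
(configurable; ≥ 10 samples per CF cycle enforced). Rove levels are drawn
from a truncated Gaussian by rejection (no probability mass piles at ±3 SD)
and quantized to 2 dB for response caching (SD 6 dB ≫ 2 dB). The generator
does **not** emulate noise maskers, off-CF probes, binaural stimuli, or
calibration/transducer errors of real experiments, so passing tests
demonstrate properties of the model under clean tonal stimulation only.
Padding defaults: 50 ms pre (so masker onset responses precede the fixed
psychophysical window), 50–200 ms post depending on the paradigm (enough
for the latest decision window; a warning is raised if a window would
overhang).

## Threshold estimation and experiment drivers

Unless a fixed grid is supplied, a low-trial pilot sweep brackets the
threshold and the final grid is 8 levels in 5 dB steps around it; if the
observed proportions fail to span the criterion the grid is extended once
(8 further levels). A fit that still fails is replaced by the empirical
criterion crossing and flagged. The delay and rove drivers use fixed wide
grids (−10…55 dB SPL in 5 dB steps; −14…26 for unmasked), anchor the
masker's sensation level to a 3×-trials unmasked estimate, and report each
masked threshold as the mean of 3–6 independent 100-trial runs: the per-run
protocol is unchanged; replication reduces the Monte-Carlo error of the
reported statistic (single-run threshold SE is 1–2 dB on the shallow masked
psychometric functions).

Conventions: model thresholds are converted to sensation level by
subtracting the same stage's unmasked threshold; the 15 dB SPL→SL constant
applies only to external psychophysical comparison data and never to model
outputs. The delay paradigm's masker is placed at 40 dB SL per stage
(unmasked thresholds are ≈ 1–6 dB SPL, so SL and SPL nearly coincide, as
they must for the cross-domain comparison to make sense).

## Calibration summary

Free parameters the underlying studies do not pin down (fiber sigmoids,
depletion capacity, MOC weight and τ, SFIE constants, noise magnitudes) were
calibrated once against the experiment-level outcomes the model is supposed
to reproduce — delay-curve threshold decreases of ≈ 19/15/11/6 dB
(IC+efferents / AN+efferents / IC alone / AN alone), unmasked thresholds
≈ 1 dB SPL (IC) and ≈ 5 dB SPL (AN), BMF = 64 Hz — and then frozen; the
tests and the acceptance script rerun the full pipeline against those
values. Problem sizes used throughout (two delays for the decrease
statistic, 8–14 probe levels, 100 trials per level, 3–6 replicates) are the
package's desk-scale defaults; the full 7-delay curve and the 8-point GOM
grid run in a few minutes each.

## Numerical choices

Audio rate 100 kHz, rate signals decimated to 10 kHz after the IHC low-pass;
depletion integrated by forward Euler at 10 kHz (τ ≥ 10 ms ≫ 0.1 ms steps);
loop update 1 ms; all linear stages are streaming IIR filters with carried
state, so block-wise and single-pass processing agree bitwise, and identical
seeds give bit-identical results end to end. Gain-trajectory oscillation
beyond a quarter of the gain range triggers a diagnostic failure rather than
silently returning an unstable simulation. WAV export writes peak-normalized
float32 plus a JSON sidecar (peak scale, landmarks) so absolute pressure is
recoverable.

## Known limitations

* The periphery is phenomenological; it satisfies the stated behavioral
  contracts but none of its internal signals should be read as biophysical
  predictions.
* Forward masking at moderate delays (10–70 ms) is governed by simple
  exponential recovery (τ_a, τ_moc); like the modeling it emulates, the
  model over-suppresses at those delays relative to physiological data.
* The on-frequency rove condition at 0 ms delay pushes the masked IC
  threshold into the sloping-saturation regime (> 100 dB SPL) — far above
  human thresholds in that condition. The rove-*stability* property still
  holds there, but the absolute threshold is not realistic.
* The mean-rate decision-variable contrast (rove robustness lost when the
  decision uses mean rather than maximum rate) is demonstrated with the slow
  drift component disabled: under the full noise model the window-mean
  statistic is dominated by internal drift and the masker-level confound is
  masked by noise rather than by mechanism.
* Single CF channel, monaural, no spike refractoriness, no
  contralateral/LOC efferent pathways, no explicit CN cell types.
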