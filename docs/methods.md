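# Methods

This note documents the models behind `vigilband`, the defaults that
matter, and what the synthetic data does and does not establish.

## Signal model of the synthetic sessions

**ECG.** Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) with a
dominant 1.0 mV R deflection (widths 10–60 ms); this is the minimal
morphology sufficient to exercise R-peak logic, not a physiological 12-lead
model. Beats are laid down at the scheduled rate (first beat half an R-R
interval into the recording, so a constant 60 BPM, 10 s trace holds exactly
10 beats at 1000 ms spacing), and the generator returns the true R instants
in ms. Noise is additive white Gaussian (σ = 0.1 mV at `noise_level` 1)
plus a 0.4 Hz baseline-wander sinusoid (0.3 mV amplitude, random phase),
emulating the heavily contaminated analogue front-end signal. Default
sampling: 250 Hz (a standard single-lead rate; the device's 1 Hz heart-rate
figure refers to the derived HR value, not the raw trace).

**Acceleration.** Idle: resting orientation with gravity on +z, i.e.
(0, 0, 1) g, plus per-axis Gaussian sensor noise σ = 0.02 g. Agitation is
modelled as bouts of violent thrashing: zero-mean bursts with per-axis
σ = 0.6 g superposed on gravity, occupying ≈ 50 % of the agitated time.
The burst *time structure* is multi-second — on/off run lengths uniform in
3–8 s — because agitation in restrained patients is sustained thrashing,
not sub-second twitching; a design-time simulation showed that sub-second
50 %-duty bursts never produce the multi-second excursions of the activity
score that sustained agitation visibly produces, whereas 3–8 s bouts do.
Default IMU rate 10 Hz (torso movement is band-limited well below 5 Hz).

**Environment.** Temperature sits at 36.5 °C with σ = 0.05 °C noise.
Humidity follows first-order relaxation: toward baseline + 20 %RH with time
constant 30 s while agitated (perspiration onset), back toward the 40 %RH
baseline with a slower 120 s constant afterwards (sweat dries slowly);
σ = 0.2 %RH measurement noise. With `noise_level` 0 both channels are
deterministic and humidity is non-decreasing throughout an agitated
segment by construction. Default rate 1 Hz.

**Sessions.** `generate_session` derives one child seed per channel group
from the session seed (`numpy` `SeedSequence`), so sessions are bytewise
reproducible and channels are independently perturbed. Heart rate follows
the schedule: 70 BPM idle, 120 BPM agitated — sinus tachycardia
accompanies agitation, and the agitated value deliberately sits above the
detector's 110 BPM threshold while idle sits well below.

## ECG processing chain

Order-2 Butterworth band-pass, 5–15 Hz — the classical QRS energy band.
Offline processing applies it forward–backward (zero phase) so R timing is
unbiased; the streaming mode applies the causal filter and shifts detected
instants back by the filter's nominal group delay evaluated at the
pass-band's geometric centre (√(5·15) ≈ 8.7 Hz). Binarization uses an
adaptive threshold, 0.6 × the rolling maximum of the filtered signal over
a 2 s window with a 0.2 mV floor (the floor keeps a flat or empty trace
from detecting noise); a detection is a suprathreshold local maximum, and
within any 250 ms refractory window only the largest sample survives
(capping detectable rate at 240 BPM). Beat-to-beat rate is
1000/(TR₁−TR₀)·60; intervals outside 20–300 BPM are flagged implausible
and excluded from smoothing rather than propagated. The 1 Hz heart-rate
channel takes the median of the last 5 plausible beat-to-beat values at
each tick; ticks before the first usable pair are explicitly unavailable
(never a fabricated number) and are encoded downstream as a binary32 NaN
sentinel.

## Fusion and encoding

Frames are built on the accelerometer time base (default 10 Hz). Slower
channels are sample-and-held: each frame repeats the most recent slow
sample; frames preceding a channel's first sample are an error for
measured channels and an explicit unavailable marker for heart rate. The
payload is exactly six binary32 values in the fixed order (temperature,
humidity, heart rate, aX, aY, aZ), little-endian — 24 bytes. The frame
timestamp is *not* part of the 24-byte payload: six 32-bit floats already
occupy all 24 bytes, so the timestamp travels as an 8-byte unsigned ms
header in the binary stream format (`VBF1` magic, then
`(uint64 ts, 24-byte payload)` records) and as the `t` key in JSON.

## Detector

Per frame the detector maintains (a) the activity score — mean |‖a‖ − 1|
over a trailing 2 s window, computed from the frame's raw acceleration;
(b) the latest heart rate (unavailable never exceeds); (c) the humidity
slope — least-squares fit over a trailing 60 s window, in %RH/min. The
agitation rule is a boolean combination: *movement AND (heart rate OR
perspiration)* — activity score > 0.3 g sustained continuously ≥ 3 s,
coincident with HR > 110 BPM or humidity slope > 5 %RH/min. The
corroborating set is configurable, so other combinations are expressible.
After an alert, repeats are suppressed for 60 s. Every alert names the
device and each parameter out of range at trigger time (by construction at
least two). Thresholds are exposed in `DetectorConfig`; the defaults were
chosen once on physiological grounds (0.3 g is far above idle sensor noise
~0.016 g and below the agitated score ~0.4–0.5 g; 110 BPM is mild adult
tachycardia; 5 %RH/min is well above drift) and are deliberately
conservative in the single-modality direction.

The low-battery alarm is latched: one alert per discharge, re-armed only
when the level recovers above threshold (15 %) plus a 5 % hysteresis band.
Battery arithmetic uses the prototype cell: 3.7 V × 2.6 Ah = 9.62 Wh and
2.6 Ah / 0.1 A = 26 h, consistent with a full day on one charge at the
~100 mA average draw.

## Uplink

Frames are batched (default 10 = one second) before delivery, since
per-frame session setup dominates the cost of small uploads. Delivery
retries each batch up to 2 times with a fixed 1 s backoff (injectable for
tests), records per-batch outcomes, and never drops later batches because
an earlier one failed; a batch lost after all retries surfaces a
`DeliveryError` naming the failed sequence numbers. Sinks share a single
`accept(batch)` contract; the HTTP sink keeps one persistent connection
(the keep-alive stand-in), and transport encryption is out of scope — the
ingest server is an in-process store with a thin plain-HTTP wrapper.

## Numerical and degenerate-input choices

- Activity-score and detector windows are trailing and inclusive of their
  older edge; ticks fall at the end of each whole second.
- The humidity ODE is forward-Euler at the channel rate (1 Hz; time
  constants ≥ 30 s, so the integration error is negligible).
- Refractory tie-breaking is by amplitude (largest suprathreshold local
  maximum wins), with left-edge preference on exact plateaus.
- Empty or flat ECG yields empty beat lists, not errors; fewer than two
  beats yields "HR unavailable" everywhere.
- Humidity slope with fewer than two samples (or zero time span) is 0.

## Problem sizes used in the shipped checks

The test suite and acceptance script run entirely on generated data:
60–120 s sessions, 250 Hz ECG, 10 Hz IMU, 1 Hz environment; heart-rate
recovery at 50/80/120/150 BPM over 60 s; detector behaviour over 20
seeded scripted sessions (one 30 s episode each) plus idle-only sessions;
1000-case codec roundtrips. These sizes give stable statistics for every
quantity checked while keeping a full run in seconds.

## Limitations

The simulator is a test harness, not a patient model: ECG morphology is
stylised (no arrhythmia, ectopy, electrode pop or muscle artefact beyond
white noise), agitation is a two-state script rather than a behavioural
continuum, and temperature dynamics (fever) are absent. Passing tests
therefore demonstrate that the processing chain is correct under the
stated signal model — timing, encoding, thresholds, boolean logic,
delivery — not that the default thresholds achieve any particular clinical
sensitivity or specificity on real patients; those would need recorded
patient data and threshold calibration. Clock synchronisation is out of
scope: timestamps are injected by the generators, and the dual-core
firmware task split is modelled as a deterministic single-threaded
pipeline.
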