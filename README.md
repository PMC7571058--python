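# vigilband

A desk-scale software twin of a smart-band monitoring pipeline for
**mechanically restrained psychiatric patients**. Patients under mechanical
restraint can develop severe agitation episodes that staff cannot watch for
continuously; a chest-worn band measuring ECG, 3-axis acceleration, skin
temperature and skin humidity (a perspiration proxy) can raise the alarm
automatically. `vigilband` reproduces that device's entire firmware data
path in pure Python so every stage can be developed, inspected and tested
without hardware:

* **synthetic sessions** — scripted idle/agitated recordings with known
  ground-truth beat instants and agitation labels;
* **ECG → heart rate** — a simplified Pan–Tompkins chain: Butterworth
  band-pass (5–15 Hz, order 2), adaptive threshold binarization of the R
  peaks, then beat-to-beat rate from consecutive R instants TR₀, TR₁:

  HR = 1000 / (TR₁ − TR₀) × 60  [BPM, TR in ms]

* **motion** — the acceleration-vector magnitude ‖a‖ = √(aX² + aY² + aZ²)
  (≈ 1 g at rest, gravity only) and a windowed activity score
  mean |‖a‖ − 1| that is orientation-independent;
* **fusion** — sample-and-hold alignment of the 1 Hz channels onto the
  10 Hz frame timeline and a fixed 24-byte payload per frame: six
  little-endian IEEE-754 binary32 values (temperature, humidity, heart
  rate, aX, aY, aZ), i.e. 240 bytes/s at 10 Hz;
* **detector** — an agitation alert requires *sustained violent movement*
  AND a corroborating physiological excursion (heart rate or humidity
  slope); a single-modality excursion never alerts. Plus a latched
  low-battery alarm and the battery budget (3.7 V × 2.6 Ah = 9.62 Wh;
  2.6 Ah / 100 mA = 26 h);
* **uplink** — frame batching, JSON/binary serialization and delivery with
  retries to pluggable sinks (NDJSON file, binary stream, in-process or
  HTTP mock ingest server).

## Worked example

```sh
vigilband simulate --duration 90 --seed 3 \
    --schedule "idle:0-30,agitated:30-60,idle:60-90" --out session
vigilband process --session session --out frames.vbf
vigilband detect  --frames frames.vbf --alerts alerts.ndjson
vigilband upload  --frames frames.vbf --sink upload.ndjson --batch 10
```

prints (stderr):

```
vigilband: simulate: 130 beats, 900 IMU samples, 90 env samples -> session
vigilband: process: 900 frames (880 with HR) -> frames.vbf
vigilband: detect: 900 frames -> 1 alert(s) -> alerts.ndjson
vigilband: upload: 900 frames in 90 batch(es), 90 accepted, 0 retried
```

and `alerts.ndjson` contains exactly one alert, raised 3.8 s into the
scripted agitation episode, naming both out-of-range parameters:

```json
{"device_id": "vigilband-0", "t": 33800, "kind": "agitation",
 "params": ["acceleration", "heart_rate"],
 "details": "activity 0.516 g sustained >= 3 s; heart_rate out of range"}
```

Reading: the 90 s session holds 130 true beats (70 BPM idle, 120 BPM while
agitated); fusion emits one frame per 100 ms (900 frames, the first 20
before any beat pair exists carry an unavailable heart rate); the detector
fires once, inside the 30–60 s episode, because the activity score
(0.516 g mean deviation from gravity) stayed above 0.3 g for over 3 s
*while* heart rate exceeded 110 BPM — and stays silent for the rest of the
session. The same objects are available as a library:

```python
from vigilband import StateSchedule, generate_session, fuse_session, evaluate_stream
sched = StateSchedule(((0, 30, "idle"), (30, 60, "agitated"), (60, 90, "idle")))
rec = generate_session(sched, 90, seed=3)
alerts = evaluate_stream(fuse_session(rec))
```

An HTTP ingest endpoint is available via `vigilband serve --port 8080` and
`vigilband upload --sink http://127.0.0.1:8080/ingest`.

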