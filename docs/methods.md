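# Methods

## Scope and model

`quarmon` is a streaming re-implementation of a wearable fever monitor
for people in home quarantine. One *session* is a contiguous recording
(tens of minutes, as a battery-bound wearable would produce); sessions
are processed independently, with no cross-session state, and time is
relative seconds within the session. Three asynchronous input streams
feed the pipeline:

| stream  | rate    | content                                   |
|---------|---------|-------------------------------------------|
| accel   | 20 Hz   | Z-axis acceleration, g, full scale ±2 g   |
| temp    | 0.2 Hz  | body temperature, °C, contact or infrared |
| indoor  | 0.2 Hz  | room temperature (°C) and RH (%)          |

The chain is: low-pass filter → spike counting (exercise recognition)
→ activity-adaptive threshold → dwell-timed alerting, with
calibration on the contact-temperature path and a range check on the
indoor path. Everything is deterministic given inputs and
configuration.

## Filtering and calibration

The smoother is the first-order IIR recursion
`y_i = β·x_i + (1−β)·y_{i−1}`. The subscripted form could also be read
as a two-tap FIR on raw inputs, but the recursive (infinite impulse
response) reading is the one adopted, matching the filter's stated
class; the previous *output* is fed back. `β` defaults to 0.5 on both
the temperature and the acceleration path — enough smoothing to kill
single-sample noise while keeping the step response fast (a step is
87.5 % settled after 3 samples). The first sample passes through
unchanged, which avoids inventing a prior output; β = 1 disables
filtering, β = 0 freezes the output (both admitted, since the closed
interval keeps the identity case expressible).

Calibration transfers a wrist reading onto a core-equivalent
reference: after a stabilization wait (default 600 s — the time a
reference glass thermometer and the skin-contact probe need to
equilibrate), the first `N = 50` raw samples are averaged and
`bias = T_ref − T_avg` is added to every subsequent contact reading.
The model is purely additive; it cannot correct gain errors, which is
acceptable over the ~2 °C span of interest. Infrared readings never
pass through the filter or the calibration: they are single-shot spot
checks and are compared to the current threshold as-is.

## Exercise recognition

Spike detection uses the absolute consecutive-sample difference in
milli-g, `|ΔZ|·1000`, on the *filtered* stream. Conventions, chosen
where the constants are stated without strictness, make the published
values the exact boundaries: a spike requires `|ΔZ| ≥ 90 mg`, exercise
requires `count ≥ 24` per window. Windows are tumbling (30 s,
non-overlapping) — matching a per-period decision cadence — and are
anchored at the end of a 30 s warm-up discarded for sensor start-up. A
delta straddling a boundary is credited to the window containing the
later sample, and a stream that ends exactly on a window's last sample
slot still closes that window. A gap longer than two sampling
intervals clears the previous-sample memory so a dropout cannot
fabricate a spike. Only the Z axis is used; X/Y columns in input files
are ignored.

## Threshold and alerting

The threshold manager is a two-state machine: `T_TH = 37.5 °C` while
the latest window verdict is exercise and for `hold = 20 min` after
the end of the last exercise window (each new exercise window restarts
the hold), `37.0 °C` otherwise. Reversion happens at the first
evaluation at or past the hold boundary; the threshold never takes an
intermediate value.

The alert machine keeps the time of the first sample meeting the
current threshold; "continuously" is interpreted at sample resolution,
so a single sub-threshold sample resets the timer. When the
exceedance has lasted `dwell = 12 min`, `alert_raised` fires once per
episode together with `request_infrared_confirmation`; the alert flag
stays 1 until a below-threshold sample emits `alert_cleared`.
Exceedance is re-evaluated against the current threshold at every
sample, so an exercise bout that lifts the threshold above T_body
deliberately clears the timer — the design intent is to excuse
exercise-induced rises. On a uniformly sampled step input the alert
latency is therefore in `[dwell, dwell + sampling interval]`.

Indoor bounds (20–24 °C, 20–60 % RH) are inclusive at both ends and
are applied literally; readings outside them are flagged low/high even
when marginal (e.g. 25 °C reads high). Out-of-range transitions are
logged edge-triggered to keep the event log small.

## Stream fusion and telemetry

The three streams run at independent rates, so the pipeline fuses them
sample-and-hold: a telemetry record every 5 s (the ambient-sensor
update period) carries the latest processed value of each stream, with
the alert and exercise flags encoded 0/1 — the flat payload a
cloud/MQTT uplink would send. At equal timestamps sensor samples are
processed before the telemetry tick, and the exercise flag shown
between windows is the last window's verdict (no debouncing). Session
summaries (min/max/mean/std of T_body) use the population standard
deviation and are exactly recomputable from the telemetry.

## Synthetic streams

The generators emulate just enough structure to exercise every
decision path with provable ground truth:

* **Acceleration** — rest is 1 g plus 2 mg gaussian noise; normal
  activity adds sparse isolated jumps of 20–60 mg at 0.2/s (below the
  spike threshold by construction, and never adjacent so two jump
  edges cannot stack above it); exercise adds a deterministic ±100 mg
  square wave at 1.5 Hz. Each carrier transition survives the β = 0.5
  pre-filter as a ~100 mg first delta, and 1.5 Hz gives ~90
  transitions per window — window counts are guaranteed, not
  probabilistic, which keeps boundary tests exact.
* **Body temperature** — first-order dynamics
  `dT/dt = (target − T)/τ` with τ = 1200 s toward baseline 36.5 °C, or
  baseline + 0.5 °C during exercise (so a long bout plateaus at
  37.0 °C, under the elevated threshold), or a fever target when one
  is set; gaussian measurement noise (default sd 0.2 °C) is added on
  output. τ = 1200 s makes post-exercise recovery essentially complete
  within the 20-minute hold.
* **Indoor** — constant temperature/RH with optional total linear
  drift and small noise at 0.2 Hz.

What the generators do **not** model: biomechanically realistic
gait or exercise spectra, circadian temperature rhythm, sensor drift,
contact-pressure artifacts, or missing-data patterns beyond simple
gaps. Passing tests therefore demonstrate the correctness of the
decision logic under its stated assumptions, not field performance of
the recognition thresholds on real wrist data.

## Numerical choices and degenerate inputs

* Thresholds compare with ≥ throughout; window boundaries close when a
  sample reaches the boundary time.
* Non-finite samples, out-of-order timestamps, out-of-range humidity
  and unknown CSV columns are rejected with line-addressed errors; an
  empty temperature stream is an error, an empty acceleration stream
  runs the session with exercise permanently 0.
* The calibration model enforces `bias = t_ref − t_avg` to 1e-9 (exact
  for models it fits itself; the tolerance only admits hand-built
  models whose decimal fields are not exactly representable).
* CSV floats are written with shortest round-trip `repr`, so
  write→read preserves values exactly; the dialect is fixed (comma,
  dot decimal, UTF-8, mandatory header).

## Problem sizes

Tests and the acceptance script run on desk-scale sessions: 45–90 min
of 20 Hz acceleration (54k–108k samples), 0.2 Hz temperature/indoor
streams, 10 seeded sessions for schedule-recovery checks and 1000
windows for the streaming-vs-oracle equivalence sweep. These sizes
were chosen as representative of single battery-bound wearable
sessions.

## Known limitations

* The additive calibration ignores gain and drift; a session-long
  cooling trend in the probe would bias late readings.
* The two-state threshold manager does not grade intermediate activity
  levels; soft exercise below the spike thresholds gets no threshold
  relief (the constants are user-adjustable for that case).
* Exercise detection latency is up to one window (30 s) plus the
  warm-up at stream start; schedule recovery is only guaranteed to
  ±one window.
* Telemetry before the first indoor sample carries NaN room fields;
  consumers should treat them as "not yet observed".
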