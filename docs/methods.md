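# Methods

## Scope

`reflectsim` reproduces, in software, the computation pipeline of a bench
evaluation of a reflection-based anaesthetic delivery system: a seeded
simulator that emulates the bench recordings (10 Hz dual-channel gas
traces, per-breath device logs, reservoir depletion), and the analysis of
those recordings (breath segmentation, end-tidal extraction, injection
peak quantification, consumption and reflection-efficiency accounting,
agreement and regression statistics). Physical device interfacing, CO₂
reflection quantification, and clinical uptake/leak effects are out of
scope.

## Simulator model and assumptions

**Lung.** A single perfectly mixed compartment of fixed volume 3000 mL
(a 3 L breathing bag), with zero anaesthetic uptake by its walls. During
inspiration the compartment receives VT of gas carrying the reflector's
released store and the injected bolus; during expiration it exhales VT at
its mixed concentration. There is no physiological uptake/distribution
model, and no humidity or temperature physics.

**Reflector.** Two parameters govern capture per breath:
`base_efficiency` (default 0.85, the fraction of presented vapour
captured) and `capacity_per_breath_ml` (default 7.2 mL, a hard ceiling).
Captured vapour is released in full during the next inspiration. Exhaled
vapour is the lung's contribution plus any interface cloud; capture is
`min(efficiency × presented, capacity)` and the remainder is vented, i.e.
irreversibly consumed. The hard ceiling is what makes consumption grow
disproportionately at high concentrations and under spill-over: above
capacity every additional millilitre presented is lost.

The two defaults were set once so that simulated hourly isoflurane
consumption at the long flow time falls in the low single-digit mL/h
range over the clinical targets, with reflection efficiencies in the
80–90 % band that declines as vapour volume per breath approaches
capacity. A single parameterisation is used for both agents; the weaker
carbon adsorption of sevoflurane is not separately modelled (the
parameters are exposed for users who want agent-specific reflectors).

**Injector / target controller.** The real device's algorithm is
proprietary; the controller here is phenomenological and reproduces the
observed behaviour, not the internals. The device's end-tidal estimate is
a first-order filter (weight `ec_filter_alpha`, default 0.16) of the
per-breath device EC — a stand-in for side-stream delay and incomplete
mixing. A series starts when the estimate falls `trigger_hysteresis`
(0.10 vol%) below target, fires one bolus per breath of
`gain × deficit` (gain 0.9) expressed as lung-equivalent vapour volume,
never less than one quantum (`min_bolus_ml`, 3.0 mL) and never more than
the delivery rate (4.0 mL vapour/s) times the inspiration, and stops when
the filtered estimate reaches the target. These defaults were calibrated
once so that, at 1.2 MAC isoflurane and the long flow time, injections
arrive in series of roughly half a dozen with the end-tidal concentration
swinging on the order of ±15 % around the target — they are calibration
defaults, not claims about the device.

**Spill-over.** A bolus requiring more delivery time than the
inspiratory-flow phase spills its excess into an interface cloud during
the pause. The cloud never reaches the lung; it is pushed against the
reflector at that breath's expiration, where it counts toward the same
capacity. At the 0.5 s flow time the per-flow-phase deliverable volume is
only 2 mL, so most boluses spill, and at high targets the cloud plus the
exhaled vapour exceeds capacity — the mechanism behind the short-flow
consumption blow-up.

**Mass balance.** Every millilitre of vapour is tracked:
injected = Δlung + Δreflector store + Δcloud + vented, and the reservoir
(in liquid mL) falls by injected/F. Both identities are tested to 1e-9
relative (they hold to float round-off). If the reservoir runs dry the
simulation stops at that breath with status `reservoir_exhausted`.

**Waveforms.** The CO₂ expirogram rises after expiration onset, crosses
the 34 mmHg marking threshold 0.8 s in, plateaus at an end-tidal value
drawn once per experiment from 35–45 mmHg, and stays supra-threshold for
`interface_retention_time` (1.0 s) into the next inspiration — expired
gas retained in the interface passes the sampling port at early
inspiration, which is also why the inspiratory CO₂ floor is non-zero
(default 3 mmHg). The exact expirogram shape is not load-bearing; only
the threshold-crossing times matter downstream, and they are chosen so a
breath's supra-threshold run spans ≈30 samples and the EC window sits
entirely within the true expiration plateau. The agent channel shows the
previous breath's gas during the retention time, the reflected-gas
baseline for the rest of inspiration, the expiration plateau at the lung
concentration, and — on injection breaths — a peak: the bolus appears at
the port after a 0.5 s transit delay, holds an amplitude of
(delivery rate)/(inspiratory flow) while injecting, and decays with a
0.8 s time constant afterwards; spilled vapour shows as a second,
pause-phase elevation (the biphasic pattern seen at short flow times).
Additive Gaussian noise: agent 0.01 vol% (the monitor resolves to the
second decimal), CO₂ 0.1 mmHg, device EC 0.01 vol% from an independent
sub-stream of the same seed. Identical seeds give bit-identical output.

## Analysis conventions

* Expiration marking uses strict `CO₂ > 34 mmHg` (values exactly at the
  threshold do not count, consistent with "exceeding"). Runs shorter
  than 0.5 s (5 samples) are discarded as noise; the marking is by
  construction approximate and this debounce is our choice.
* EC = arithmetic mean of 20 consecutive agent samples starting 0.2 s
  after a run's first sample. Runs too short for offset + window leave
  the breath flagged incomplete (EC = NaN, excluded from means, counted
  in a warning).
* Peak windows are half-open sample-index intervals from the end of a
  breath's run to the start of the next run; time is sample index × 0.1 s
  (the 10 Hz cadence is asserted, not assumed). The subtrahend is the
  subsequent breath's EC; the final breath uses its own. T‑inj counts
  positive excess samples × 0.1 s; AUC sums them × 0.1. A peak is deemed
  present only with ≥ 2 positive samples and ≥ 0.05 vol% peak excess —
  a gate of our choosing that suppresses noise-only detections.
* Consumption per constant-target period is the reservoir level before
  the period's first breath minus the level after its last, extrapolated
  by 3600/duration; a reservoir increase beyond tolerance is a data
  error. Ascending and descending occurrences of a target are averaged
  arithmetically; the peak target occurs once and passes through. The
  20-min peak period is treated as a single period counted once.
* Steady state is not formally verified (the bench measured during
  staircase transitions); instead a per-period EC drift diagnostic
  (last-quarter mean minus first-quarter mean) is reported. Targets
  below 0.6 MAC are flagged — 10-min consumption scatters too much there
  for reliable REs — but never dropped from raw output.
* Bland-Altman uses the classical 1.96 multiplier and sample SD; no
  repeated-measures correction. Consumption–EC fits default to degree-2
  polynomials (degree exposed). Group contrasts use a pooled OLS of
  consumption on EC powers plus a group indicator, testing the group
  main effect; the covariate structure of the original analysis is not
  public, so this choice is documented rather than claimed. No
  multiple-testing correction; p < 0.05 is the significance convention.

## What the synthetic data does and does not establish

The generator reproduces the waveform geometry, injection phenomenology,
reflector physics and reservoir bookkeeping that the analysis relies on,
under exactly the bench protocol (VT 500 mL, RR 10/min, I:E 1:1, flow
times 2.5/0.5 s, staircase 0.2→1.5→0.2 MAC, 160 min, 1600 breaths,
96 000 samples per channel). Passing tests therefore show that the
analysis recovers what the simulator put in — segmentation counts,
plateau concentrations, injected volumes, reflection efficiencies — and
that the qualitative findings (consumption convex in EC, short-flow
penalty from spill-over) follow from the modelled mechanisms. They do
not validate the simulator against a physical device: absolute
consumption levels depend on the calibrated reflector/controller
defaults, real expirograms and injection transients are messier than the
parametric waveforms, and real monitors drift, lag and re-breathe sampled
gas in ways not modelled here.

## Numerical choices

Volumes are double precision mL of vapour; "exact" conservation means
1e-12 relative in tests (float accumulation over 1600 breaths). CSV
precision is fixed: agent 2 decimals, CO₂ 1 decimal, derived quantities
4 decimals; all writes are atomic (write-then-rename). RE is undefined
at EC = 0 and raises. The degree-2 fit requires degree + 2 points per
group and raises on rank deficiency naming the group. The staircase
generator builds ascending multiples of the step strictly below the peak
fraction, so the terminal 0.0 target ends the recording and contributes
no period — the only reading consistent with 160 min of data from this
staircase. The MAC references (isoflurane 1.2 vol%, sevoflurane
1.9 vol%) are device constants at a 40-year reference age, not an age
model.

## Known limitations

* One reflector parameterisation for both agents by default.
* The controller is behavioural; series lengths, overshoot and injection
  counts match the intended phenomenology only near the calibrated
  operating points.
* Volume-controlled, metronomic breathing only — no spontaneous or
  pressure-supported patterns, so the segmentation needs no spectral or
  flow-based breath detection.
* The spill-over cloud is all-or-nothing per breath and bypasses the
  lung entirely; in reality part of a late bolus still reaches the
  patient side.
* The CO₂e helper multiplies rate reduction × density × warming
  potential × hours; the liquid density is a required explicit argument
  because published per-day equivalents are sensitive to it.
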