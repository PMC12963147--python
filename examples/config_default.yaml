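# Default bench configuration.  Every block and key is optional; anything
# omitted falls back to these values.  Used by the CLI:
#   reflectsim run --config examples/config_default.yaml --seed 1 --out out/

ventilation:
  tidal_volume_ml: 500.0        # VT
  respiratory_rate: 10.0        # RR, breaths/min
  ie_ratio: [1.0, 1.0]          # inspiration:expiration
  inspiratory_flow_lpm: 12.0    # 12 -> 2.5 s flow time; 60 -> 0.5 s
  peep_hpa: 3.0                 # informational
  fio2: 0.21                    # informational

agent:
  name: isoflurane              # or sevoflurane
  # mac_volpct: 1.2             # override the 1.0-MAC reference (vol%)
  # vapour_factor_f: 200        # mL vapour per mL liquid

schedule:                       # either staircase parameters ...
  max_fraction: 1.5             # MAC multiple held for the peak period
  step: 0.2                     # MAC increment per period
  step_duration_s: 600.0
  peak_duration_s: 1200.0
  # ... or an explicit step list:
  # steps: [[0.5, 600], [1.0, 600], [0.5, 600]]

reflector:
  base_efficiency: 0.85         # fraction of presented vapour captured
  capacity_per_breath_ml: 7.2   # capture ceiling per breath
  interface_retention_time_s: 1.0
  co2_reflection_floor_mmhg: 3.0

injector:
  vapour_rate_mls: 4.0          # saturated-vapour delivery rate
  gain: 0.9                     # deficit fraction corrected per injection
  min_bolus_ml: 3.0             # smallest shot fired
  trigger_hysteresis_volpct: 0.10
  ec_filter_alpha: 0.16         # end-tidal filter (controller lag)

simulation:
  noise_sd: 0.01                # monitor agent-channel noise (vol%)
  co2_noise_sd: 0.1             # monitor CO2 noise (mmHg)
  device_noise_sd: 0.01         # device EC measurement noise (vol%)
  reservoir_ml: 250.0           # initial liquid reservoir
  initial_lung_volpct: 0.0
  lung_volume_ml: 3000.0
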