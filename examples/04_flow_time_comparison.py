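"""Long vs short inspiratory-flow time: the spill-over effect.

At a 0.5 s flow time the injector cannot finish delivering large vapour
boluses during the flow phase; the excess forms a cloud in the interface
during the inspiratory pause and is pushed against the reflector at
expiration, overloading its capacity at high targets.  Consumption curves
for the two modes are fitted and contrasted with a pooled linear model.
"""

import pandas as pd

import reflectsim as rs
from reflectsim.stats import fit_consumption

sevo = rs.AgentSpec.sevoflurane()
sched = rs.build_staircase_schedule()

records = []
for flow, label in ((12.0, "long_if"), (60.0, "short_if")):
    vent = rs.VentilationSettings(inspiratory_flow_lpm=flow)
    sim = rs.simulate_experiment(vent, sevo, sched, seed=1)
    breaths = rs.analyze_trace(sim.trace)
    eff = rs.summarize_efficiency(
        breaths, sim.device_log, sched.periods(), vent, sevo, initial_reservoir_ml=250.0
    )
    eff["group"] = label
    records.append(eff)
    spilled = sim.ground_truth["spill_ml"].sum()
    print(
        f"{label}: top-target consumption {eff['hourly_rate_ml_h'].iloc[-1]:.2f} mL/h, "
        f"total spill-over {spilled:.0f} mL vapour"
    )

df = pd.concat(records, ignore_index=True)
fit = fit_consumption(df)
p = fit.contrast_pvalues[("long_if", "short_if")]
print(f"pooled-model contrast long vs short flow time: p = {p:.2g}")
# The short-flow curve lies above the long-flow curve, increasingly so at
# high concentration where the spilled cloud overloads the reflector.  The
# additive group term is a conservative summary here: most of the
# separation sits in the top targets, so the p-value understates an effect
# that is obvious from the curves themselves.
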