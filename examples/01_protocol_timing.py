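"""Protocol arithmetic: breath phases, MAC targets and the staircase.

Shows the deterministic configuration layer: how volume-controlled
ventilation settings determine the inspiratory-flow/pause/expiration split,
how MAC multiples map to vol% targets for each agent, and the shape of the
default up/down target staircase.
"""

import reflectsim as rs

for flow in (12.0, 60.0):
    vent = rs.VentilationSettings(inspiratory_flow_lpm=flow)
    p = rs.phase_durations(vent)
    print(
        f"IF {flow:>4.0f} L/min: flow {p.flow_s:.1f} s, pause {p.pause_s:.1f} s, "
        f"expiration {p.expiration_s:.1f} s  (cycle {p.cycle_s:.0f} s)"
    )

iso, sevo = rs.AgentSpec.isoflurane(), rs.AgentSpec.sevoflurane()
for frac, agent in ((1.2, iso), (1.4, iso), (1.5, sevo)):
    print(f"{frac:.1f} MAC {agent.name:<12s} = {rs.mac_to_volpct(frac, agent):.2f} vol%")

sched = rs.build_staircase_schedule()
print(
    f"staircase: {len(sched.steps)} periods, {sched.total_duration_s / 60:.0f} min recorded, "
    f"{sched.total_duration_s / 6:.0f} breaths at RR 10/min"
)
# The flow phase fills inspiration exactly; a 6 L/min flow cannot, and is rejected:
try:
    rs.VentilationSettings(inspiratory_flow_lpm=6.0)
except ValueError as err:
    print(f"rejected: {err}")
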