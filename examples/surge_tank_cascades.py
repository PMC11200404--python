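"""Surge-tank cascade planning: reverse-order pause and automatic restart.

When a unit fails, upstream units keep producing into their surge tanks and
pause one by one as each tank reaches its maximum weight — in reverse order
along the train.  After the repair, units restart downstream-propagating as
their inlet tanks return to acceptable weight ranges.  Both planners are
pure headspace/rate arithmetic on the current tank states.
"""

from mabtrain import build_topology
from mabtrain.controller import cascade_pause, cascade_restart

topology = build_topology()
weights = {t.id: 400.0 for t in topology.tanks}  # all tanks half full
rates = {u.id: 5.0 for u in topology.units}  # g/min output per unit

print("CEX failure -> reverse-order pause plan (unit, minutes until pause):")
for unit, t_s in cascade_pause(topology, weights, rates, "cex"):
    print(f"  {unit:8s} {t_s / 60.0:8.1f}")

print("\nafter repair of CEX -> downstream restart plan:")
weights["tank_cex_ufdf"] = 120.0  # drained below the restart floor (300 g)
for unit, t_s in cascade_restart(topology, weights, rates, "cex",
                                 one_cycle_mass_g=80.0):
    print(f"  {unit:8s} {t_s / 60.0:8.1f}")
print("(ufdf waits for its inlet tank to refill to the restart range)")
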