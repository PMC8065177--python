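"""Irradiance-response (sensitivity) curves with the inclusion filter.

Simulates the six-intensity protocol (1-s steps, lowest level first) for
two units: one with a graded gain profile and one responding only at a
middle intensity. The filter admits a unit only if its response at the
highest irradiance exceeds baseline + 3 SD; the graded unit passes, the
mid-level-only unit is excluded no matter how strong its level-4 response.
"""

import lightresp as lr
from lightresp.synthetic import default_archetype

levels = tuple(4.21e15 * 10.0**k for k in range(-5, 1))
protocol = lr.StimulusProtocol(irradiance_levels=levels)

for name, gains in (
    ("graded unit", (0, 0, 1, 3, 6, 10)),
    ("mid-level-only unit", (0, 0, 0, 20, 0, 0)),
):
    spec = default_archetype("ON", gain_profile=gains)
    trains = lr.simulate_sensitivity_series(spec, protocol, seed=11)
    curve = lr.sensitivity_curve(trains, protocol)
    deltas = ", ".join(f"{d:5.2f}" for d in curve.delta_rate_hz)
    print(f"{name:20s} included={curve.included!s:5s}  delta rate (spikes/s): {deltas}")

print(
    "\nDelta rate = mean rate over the first 400 ms of the step minus that\n"
    "block's own pre-stimulus baseline. The graded unit's curve follows its\n"
    "generating gains (0,0,1,3,6,10); the mid-level-only unit shows a clear\n"
    "~20 spikes/s response at level 4 yet is excluded because inclusion is\n"
    "decided solely at the top irradiance."
)
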