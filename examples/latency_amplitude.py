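"""Measure response amplitude and latency-to-peak for ON and OFF components.

Simulates strong ON, OFF and ON-OFF units, classifies them, and measures
each unit's component metrics: amplitude on the 100-ms PSTH (edge bin to
window peak) and latency on the Gaussian-smoothed 10-ms PSTH (stimulus
edge to peak rate). Generating values: peak excursion 25 spikes/s, ON
latency 0.32 s, OFF latency 0.35 s.
"""

import lightresp as lr
from lightresp import ResponseClass
from lightresp.synthetic import PopulationSpec, default_archetype

protocol = lr.StimulusProtocol()
config = lr.RunConfig()

pop = PopulationSpec(
    counts={ResponseClass.ON: 10, ResponseClass.OFF: 10, ResponseClass.ON_OFF: 10},
    archetypes={
        cls: default_archetype(cls, amplitude_hz=25.0)
        for cls in (ResponseClass.ON, ResponseClass.OFF, ResponseClass.ON_OFF)
    },
    seed=3,
)
spikes, truth = lr.simulate_retina(pop)
classes = lr.classify_population(spikes, protocol, config)
metrics = lr.metrics_table(spikes, classes, protocol, config)

for comp, sub in metrics.groupby("component"):
    print(
        f"{comp} component  (n={len(sub)} unit-components): "
        f"amplitude {sub['amplitude_hz'].mean():.2f} +/- {sub['amplitude_hz'].sem():.2f} spikes/s, "
        f"latency {sub['latency_ms'].median():.0f} ms (median)"
    )
print(
    "\nAmplitudes sit near the generating 25 spikes/s excursion (100-ms binning\n"
    "trims the transient peak slightly); latencies recover the generating\n"
    "0.32 s / 0.35 s peak times. ON-OFF units contribute one row per component."
)
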