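"""Pharmacological blockade: photoreceptor-driven vs intrinsic responses.

Simulates the same units across three recording blocks — pre-drug,
glutamatergic blockade (L-AP4 + DNQX + D-AP5 silences the photoreceptor ->
bipolar -> ganglion cell pathway) and washout — and classifies each block.
Cone-driven archetypes lose their light response under blockade; the slow
melanopsin-style (ipRGC) archetype keeps its response.
"""

import lightresp as lr
from lightresp import ResponseClass
from lightresp.synthetic import PopulationSpec, default_archetype

protocol = lr.StimulusProtocol()
config = lr.RunConfig()

pop = PopulationSpec(
    counts={ResponseClass.ON: 5, ResponseClass.OFF: 5, ResponseClass.SLOW_SUSTAINED: 5},
    archetypes={cls: default_archetype(cls, amplitude_hz=25.0) for cls in ResponseClass},
    seed=2,
)
spikes, truth = lr.simulate_blockade_experiment(pop)
classes = lr.classify_population(spikes, protocol, config)
merged = classes.merge(truth, on=["retina_id", "channel", "unit_id", "condition"])

print(f"{'condition':10s} {'archetype':16s} {'% responsive':>12s}")
for condition in ("pre_drug", "blockade", "washout"):
    sub = merged[merged["condition"] == condition]
    for kind, mask in (
        ("cone-driven", sub["true_class"] != "SLOW_SUSTAINED"),
        ("ipRGC-style", sub["true_class"] == "SLOW_SUSTAINED"),
    ):
        part = sub[mask]
        pct = 100.0 * (part["response_class"] != "NON_LIGHT_RESPONSIVE").mean()
        print(f"{condition:10s} {kind:16s} {pct:11.0f}%")

print(
    "\nCone-driven responsiveness collapses under blockade and returns after\n"
    "washout, while the intrinsic melanopsin-style responses persist\n"
    "throughout. Residual blockade-condition 'responses' in cone-driven\n"
    "units are false threshold crossings of baseline noise (see the methods\n"
    "note on the rule's false-positive character for ideal Poisson baselines)."
)
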