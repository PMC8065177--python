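"""Classify a synthetic retina into the 10 light-response categories.

Simulates 60 units spanning several response archetypes under the standard
protocol (1-s flash from darkness, 20 s ISI, 20 repeats), runs the
threshold-and-duration classifier on every unit, and prints the per-class
census next to the generating truth.
"""

import lightresp as lr
from lightresp import ResponseClass
from lightresp.synthetic import PopulationSpec, default_archetype

protocol = lr.StimulusProtocol()
config = lr.RunConfig()

pop = PopulationSpec(
    counts={
        ResponseClass.ON: 15,
        ResponseClass.ON_OFF: 8,
        ResponseClass.OFF: 8,
        ResponseClass.SLOW_SUSTAINED: 5,
        ResponseClass.SUPPRESSED_ON: 4,
        ResponseClass.NON_LIGHT_RESPONSIVE: 20,
    },
    archetypes={cls: default_archetype(cls, amplitude_hz=25.0) for cls in ResponseClass},
    seed=1,
)
spikes, truth = lr.simulate_retina(pop)
classes = lr.classify_population(spikes, protocol, config)
summary = lr.summarize_retina(classes)

print(f"units: {summary.n_units}   light-responsive: {summary.pct_light_responsive:.1f}%")
print(f"{'class':26s} {'assigned':>8s} {'generated':>9s}")
truth_counts = truth["true_class"].value_counts()
for cls in ResponseClass:
    print(
        f"{cls.value:26s} {summary.class_counts[cls.value]:8d} "
        f"{truth_counts.get(cls.value, 0):9d}"
    )
print(
    "\nStrong excitatory and suppressive archetypes are recovered nearly\n"
    "one-for-one. The surplus of assigned responsive classes over generated\n"
    "ones comes from quiet units whose Poisson baseline crosses a threshold\n"
    "by chance in one of the 80 analysis bins: the +3 SD / one-bin rule is a\n"
    "repeated per-bin test with no multiplicity control (see\n"
    "docs/methods.md, 'False-positive character of the crossing rules')."
)
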