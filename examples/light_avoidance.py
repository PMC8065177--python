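"""Light-avoidance assay: occupancy, first-crossing latency, heatmaps.

Simulates 10-minute arena trials for a 'sighted' group (strong dark
preference) and a 'blind' group (no preference), then quantifies avoidance
the standard way: % of trial time in the dark compartment and latency to
the first light-to-dark crossing, with an unpaired t test across groups.
"""

import numpy as np

import lightresp as lr

arena = lr.ArenaConfig()
groups = {"sighted": 0.85, "blind": 0.5}
sessions = []
for g, (group, pref) in enumerate(groups.items()):
    for k in range(8):
        s, _ = lr.simulate_track(pref, arena, seed=100 * g + k)
        s.group, s.subject_id = group, f"{group}_{k}"
        sessions.append(s)

table = lr.behavior_summary(sessions, arena)
for group, sub in table.groupby("group"):
    print(
        f"{group:8s} time in dark {sub['pct_time_in_dark'].mean():5.1f}% "
        f"+/- {sub['pct_time_in_dark'].sem():4.1f}%   "
        f"first cross {sub['latency_first_cross_min'].median():.2f} min (median)"
    )

samples = {g: sub["pct_time_in_dark"].to_numpy() for g, sub in table.groupby("group")}
test = lr.compare_groups(samples, test="t")
print(
    f"unpaired t: t={test['statistic'].iloc[0]:.2f}, "
    f"p={test['p'].iloc[0]:.2e} {test['stars'].iloc[0]}"
)

grid = lr.occupancy_heatmap(
    [s for s in sessions if s.group == "sighted"], arena, cap_s=20.0
)
dark_side = grid["raw"][grid["x_edges"][:-1] >= arena.divider_x_cm, :].sum()
print(
    f"sighted-group heatmap: {100 * dark_side / grid['raw'].sum():.0f}% of dwell "
    f"time on the dark side; render ceiling {grid['render'].max():.1f} s (cap 20 s)"
)
print(
    "\nThe dark-preferring group spends most of the trial in the dark\n"
    "compartment and crosses within seconds of release (mice start in the\n"
    "light chamber next to the aperture); the no-preference group divides\n"
    "its time roughly evenly, and the group difference is highly significant."
)
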