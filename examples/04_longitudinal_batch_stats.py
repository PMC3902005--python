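"""Longitudinal batch statistics on a synthetic study.

Generates latent developmental trajectories for 6 cultures in 2 batches
(batch-level parameter offsets, small culture jitter), tabulates per-day
mean connection lengths and runs the one-way ANOVA comparisons: across
batches (per-culture time averages) and within each batch (per-day values
by culture).
"""

import pandas as pd

import meanet as m
from meanet.synth import batch_adjusted_schedule, session_seed

emap = m.standard_mea_layout()
schedule = m.GrowthSchedule()
manifest = m.default_manifest()
seed = 2

rows = []
for ci, culture in manifest.cultures.reset_index(drop=True).iterrows():
    sched_c = batch_adjusted_schedule(schedule, manifest, ci, seed)
    traj = m.generate_latent_trajectory(emap, sched_c, session_seed(seed, ci, 0, "latent"))
    for day in culture["days"]:
        rows.append(
            {"culture_id": culture["culture_id"], "batch_id": culture["batch_id"],
             "day_in_vitro": day, "window_ms": 150.0,
             "metric_name": "mean_connection_length_um",
             "value": traj[day - 1].mean_edge_length()}
        )
metrics = pd.DataFrame(rows)

summary = m.batch_average(metrics, manifest)
tests = m.batch_variability_tests(metrics)

plateau = summary[(summary["day_in_vitro"] >= 25) & summary["recorded_flag"]]
print("plateau-phase mean connection length by batch:")
for batch, grp in plateau.groupby("batch_id"):
    print(f"  {batch}: {grp['mean'].mean():.0f} um (+- {grp['standard_error'].mean():.0f} SE)")
print()
print(f"across-batch ANOVA : F = {tests['across'].f_stat:.2f}, p = {tests['across'].p_value:.4f}")
for batch, res in tests["within"].items():
    print(f"within {batch}      : F = {res.f_stat:.2f}, p = {res.p_value:.4f}")
print()
print("Batches differ from each other (across-batch p below 0.05) while")
print("cultures within a batch are typically indistinguishable; in any")
print("single run a within-batch test can still dip below 0.05 by chance")
print("(the pattern holds in the majority of simulated studies).")
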