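"""Estimate per-protein replacement times from a simulated nutrient upshift.

Simulates a pulse-labeling experiment — 600 proteins diluting at the
post-shift growth rate 0.433/h, sampled every 15 min for 2 h with duplicate
unlabeled t0 — plus a handful of actively degraded and production-stagnated
proteins, then runs the turnover pipeline and prints the cohort summary.
"""

import numpy as np

import pulselab as pl

MU = 0.433  # post-shift specific growth rate, h^-1

rng = np.random.default_rng(1)
truths = (
    pl.make_cohort(600, rng=rng)  # bulk: diluted by growth, unchanged level
    + pl.make_cohort(5, rng=rng, k_deg=2 * MU, prefix="DEG")  # actively degraded
    + pl.make_cohort(5, rng=rng, stagnation_time=0.0, prefix="STAG")  # shut off
)
config = pl.SimulationConfig(
    n_proteins=len(truths),
    mu_post=MU,
    sampling_times=tuple(range(15, 121, 15)),
    noise_cv=0.2,
    seed=2,
)
table = pl.simulate_labeling_experiment(config, truths)
estimates, cohort = pl.run_turnover_pipeline(table)

print(f"proteins analysed:          {len(estimates)}")
print(f"replacement models:         {cohort.n_replacement_models}")
print(f"median replacement time:    {cohort.median_replacement_time:.1f} min "
      f"(doubling time ln2/mu = {np.log(2) / MU * 60:.1f} min)")
print(f"median half-life:           {cohort.half_life_median:.1f} min")
print("classification counts:")
print(estimates["classification"].value_counts().to_string())
print()
print("The median replacement time proxies the culture generation time;")
print("'faster_than_growth' marks candidate actively degraded proteins and")
print("production-stagnated proteins carry no replacement time at all")
print("(their heavy/light ratio never reaches 1).")
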