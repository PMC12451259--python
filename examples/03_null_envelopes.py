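"""Contrast observed indices with class-label permutation null models.

Simulates a small resurvey network with class-exchangeable dynamics (no
boreal colonisation advantage), recomputes BCI and BAI under 999 random
reshuffles of the species class labels within each study area, and reports
how many plots fall outside their simulated mean ± 2 SD envelope.
"""

from borealis import pipeline
from borealis.classification import class_lookup
from borealis.nullmodels import flag_fraction, null_table
from borealis.simulate import SimulationConfig, generate_dataset

dataset = generate_dataset(SimulationConfig(n_study_areas=6, seed=42))
series = pipeline.standardise(dataset.records).series
lookup = class_lookup(dataset.class_table)

nulls = null_table(series, lookup, n_resamples=999, seed=42)
fractions = flag_fraction(nulls)

print(f"{len(series)} plots, 999 label permutations per study area")
print(nulls.head(4)[["plot", "index_kind", "observed", "sim_mean",
                     "sim_sd", "outside_2sd"]].to_string(index=False))
print()
for kind in ("BCI", "BAI"):
    print(f"{kind}: {100 * fractions[kind]:.1f}% of plots outside ±2 SD")
print()
print("Because the simulated dynamics ignore species class, observed values")
print("should rarely leave the null envelope — a flag fraction near the")
print("few-percent level indicates ordinary community turnover, not a")
print("class-specific borealisation signal.")
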