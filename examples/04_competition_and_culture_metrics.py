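"""Competition and culture assay statistics.

Generates a selective two-population competition, prints the relative
fitness of the focal population over time, and shows the scalar assay
helpers: stratification ratio, barrier permeability, wound closure rate and
the punch-passaging expansion projection.
"""

from epidrift.culture import (
    expansion_projection,
    permeability_percent,
    relative_fitness,
    round_sig,
    stratification_ratio,
    wound_closure_rate,
)
from epidrift.synthetic import CompetitionConfig, gen_competition_series

series = gen_competition_series(CompetitionConfig(p0=0.5, s=0.2, seed=3))
print("competition (selection s = 0.2 /week, 1:1 start):")
for t in (0.0, 4.0, 8.0, 10.0):
    print(f"  week {t:4.0f}: relative fitness {relative_fitness(series, t):.2f}")
# fitness 1.0 = neutral; >1 means the focal population is winning.

print(f"\nstratification ratio (30 suprabasal / 10 basal): "
      f"{stratification_ratio(30, 10):.1f}")

res = permeability_percent(f_sample=35.0, f_blank=10.0, f_max=110.0)
print(f"barrier permeability: {res.percent:.0f}% of the no-cell control")

areas = {float(d): 8.0 * max(1 - d / 15, 0.0) for d in range(0, 16)}
wound = wound_closure_rate(areas)
print(f"wound closure rate: {wound.rate_per_day:.3f} of the wound per day "
      f"(closes in ~{1 / wound.rate_per_day:.0f} days)")

fold = expansion_projection(initial_fold=57.0, split_factor=16, rounds=4)
print(f"\nexpansion projection: 57-fold explant outgrowth, then 4 rounds of "
      f"16-piece punch passaging\n  -> {fold:,.0f}-fold "
      f"(~{round_sig(fold, 2):.1e}) in ~100 days")
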