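"""Triglyceride chain-length and saturation analysis.

Simulates TG species abundances (even carbons 38-60 x double bonds 0-12)
with the DR chain-length distribution shifted one category (2 carbons)
shorter, then runs the composition statistics: per-category ANOVA + Tukey,
paired signed-rank tests on the 38-52 / 54-60 carbon tails, and the
age x diet interaction ANOVA on total TG content.
"""

import drmeth
from drmeth import lipidomics

tg, sheet = drmeth.simdata.simulate_tg_table(n_samples_per_group=4, shift=1.0, seed=7)
rel = lipidomics.normalize_tg(tg)                       # percent of TG lipidome
carbon = lipidomics.aggregate_by(rel, "carbons")
groups = dict(zip(sheet["sample"], sheet["group"]))

cats = lipidomics.per_category_test(carbon, groups).set_index("category")
sig = cats[cats["tukey_p_AL_old_vs_DR_old"] < 0.05].index.tolist()
print(f"chain-length categories with Tukey p<0.05 (AL_old vs DR_old): {sig}")

tails = lipidomics.interval_test(carbon, groups, ("AL_old", "DR_old"),
                                 lipidomics.CARBON_INTERVALS)
print("\npaired signed-rank tail tests (DR_old minus AL_old):")
print(tails.round(6).to_string(index=False))
print("DR excess across all 8 short-chain categories gives the exact "
      "minimum p = 2^-8 = 0.0039; the long-chain tail moves the other way.")

totals = drmeth.simdata.simulate_tg_totals(
    {"AL_young": 4, "DR_young": 4, "AL_old": 3, "DR_old": 3},
    age_effect=5.0, interaction=15.0, noise_sd=3.0, seed=11)
anova = lipidomics.tg_content_interaction(totals)
print(f"\ntotal TG age x diet interaction: "
      f"F = {anova.loc['age:diet', 'F']:.2f}, "
      f"p = {anova.loc['age:diet', 'PR(>F)']:.4f}")
print("A significant interaction means TG accumulates with age under AL "
      "but not under DR.")
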