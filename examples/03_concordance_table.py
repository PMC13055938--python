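"""Reproduce the published death-concordance table and its percentages.

The generator's exact-count mode pins the matched cohort's 8-category
death-status distribution to the published table; the pipeline then has to
recover those counts through linkage and classification, not copy them.
"""

import mortcord as mc

TABLE = {
    "ABS": 209, "AB": 2682, "AS": 1071, "BS": 43,
    "A_only": 10697, "B_only": 1017, "S_only": 3972, "none": 884890,
}

# Scaled-down run (9,046 patients, same structure) keeps this example quick;
# scripts/acceptance.py runs the full 904,581-subject version.
scale = 100
scaled = {c: round(v / scale) for c, v in TABLE.items()}
scaled["none"] += 904581 // scale - sum(scaled.values())

config = mc.SyntheticConfig(
    n_matched=sum(scaled.values()), category_counts=scaled,
    death_rate_a=0, death_rate_b=0, death_rate_s=0, seed=11,
)
result = mc.run_pipeline(mc.RunConfig(synthetic=config, seed=11))

summary = result.summary
print(f"matched cohort: {summary.n_matched}")
print(f"union of deaths across sources: {summary.union_deaths}")
print("\ncategory counts (pct of cohort):")
for cat in mc.CATEGORIES:
    print(f"  {cat:<8} {summary.counts[cat]:>6}  ({summary.pct_of_cohort[cat]:.2f}%)")
print("\nexclusive shares of the union:",
      {c: summary.pct_of_union[c] for c in ("A_only", "B_only", "S_only")})
print("source contributions to the union:", summary.contribution_pct)
print("Venn regions:", mc.export_venn(summary))
# The full-scale table yields union 19,691 with system A alone holding
# 54.32% of all deaths — the central finding: most deaths are known to only
# one source.
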