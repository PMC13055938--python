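"""Run the three data-quality detectors on a cohort with designed defects.

The generator designates specific persons as lost-contact switchers,
cross-source death-date shifts, and post-death-encounter cases; the
detectors must find exactly those persons.
"""

import mortcord as mc

counts = {"ABS": 40, "AB": 60, "AS": 50, "BS": 30,
          "A_only": 300, "B_only": 100, "S_only": 120, "none": 4300}
config = mc.SyntheticConfig(
    n_matched=5000, category_counts=counts,
    death_rate_a=0, death_rate_b=0, death_rate_s=0,
    lost_contact_fraction=0.02,        # 100 designated switchers
    postdeath_encounter_fraction=0.1,  # 10% of eligible deceased
    date_shift_fraction=0.1,           # 10% of multi-source deaths
    seed=29,
)
cohort = mc.generate_cohort(config)
members, _ = mc.link_all(cohort.registry_a, cohort.registry_b, cohort.ssadmf,
                         cohort.crosswalk, "example-salt")
status = mc.death_status_frame(members, cohort.registry_a, cohort.registry_b,
                               cohort.ssadmf)

lc = mc.detect_lost_contact(cohort.encounters, members, window_months=12)
print(f"lost-contact flags: {len(lc)} "
      f"(designated: {(cohort.truth['lost_from'] != '').sum()})")
print(lc.head(3).to_string(index=False))

dd, dd_summary = mc.detect_date_discrepancies(status, threshold_months=1)
print(f"\ndate-discrepancy flags: {len(dd)}")
for pair, stats in dd_summary.items():
    if stats["count"]:
        print(f"  {pair}: n={stats['count']} median={stats['median']} "
              f"range {stats['min']}-{stats['max']} months")

pdf, rates = mc.detect_postdeath_encounters(status, cohort.encounters,
                                            members, threshold_days=365)
print(f"\npost-death encounter flags: {len(pdf)}")
for src, r in rates.items():
    pct = 100 * r["rate"] if r["rate"] is not None else 0.0
    print(f"  {src}: {r['flagged_deaths']}/{r['deaths']} deaths ({pct:.2f}%)")
# Every flag corresponds to a designated person: with zero identity noise
# the detectors recover the generator's defect sets exactly, which is what
# makes them trustworthy on cohorts where the truth is unknown.
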