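"""Link records across the three sources and score against ground truth.

Cross-system links use a crosswalk, exact name+gender+birth-date agreement,
or a shared MRN; death-master links use the five hash tokens (token 1 AND
token 2 jointly, or token 3, 4 or 5 alone).  Clusters are connected
components of the link graph.
"""

import mortcord as mc

config = mc.SyntheticConfig(n_matched=2000, n_only_a=500, n_only_b=500,
                            name_typo_rate=0.05, seed=42)
cohort = mc.generate_cohort(config)

members, evidence = mc.link_all(
    cohort.registry_a, cohort.registry_b, cohort.ssadmf,
    cohort.crosswalk, salt="example-salt",
)

n_clusters = members["cluster_id"].nunique()
n_matched = members.loc[members["matched"], "cluster_id"].nunique()
print(f"{n_clusters} clusters resolved; {n_matched} span both health systems")
print("\nlink rules fired:")
print(evidence["rule"].value_counts().to_string())

# Score the clustering against the generator's truth table: pairs of records
# grouped together vs pairs that belong to the same true person.
lookup = {}
for col, source in (("record_id_a", "SYSTEM_A"), ("record_id_b", "SYSTEM_B"),
                    ("record_id_s", "SSADMF")):
    sub = cohort.truth[cohort.truth[col] != ""]
    lookup.update(dict(zip(zip([source] * len(sub), sub[col]), sub["person_uid"])))
assignment = members.assign(
    person_uid=[lookup[(s, r)] for s, r in zip(members["source"],
                                               members["record_id"])]
)
metrics = mc.pairwise_linkage_metrics(assignment)
print(f"\npairwise precision {metrics['precision']:.4f}, "
      f"recall {metrics['recall']:.4f}")
# With SSNs present, name typos cost nothing: the SSN-based tokens 4 and 5
# still link every true pair, so recall stays at 1.
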