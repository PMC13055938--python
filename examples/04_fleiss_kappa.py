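"""Inter-source agreement on dead/not-dead status: Fleiss kappa and its CI.

Also demonstrates why kappa misleads under extreme class imbalance: as the
unanimous-not-dead count grows, chance agreement approaches 1 and kappa
becomes numerically unstable even though raw agreement is nearly perfect.
"""

import mortcord as mc

TABLE = {
    "ABS": 209, "AB": 2682, "AS": 1071, "BS": 43,
    "A_only": 10697, "B_only": 1017, "S_only": 3972, "none": 884890,
}

res = mc.agreement_report(TABLE, ci_method="asymptotic")
print(f"subjects: {res.n_subjects}, raters: {res.n_raters}")
print(f"observed agreement (Fleiss mean pairwise): {res.p_observed:.4f}")
print(f"observed agreement (all three concur):     {res.p_all_concur:.4f}")
print(f"expected agreement by chance:              {res.p_expected:.4f}")
print(f"Fleiss kappa: {res.kappa:.3f} "
      f"(95% CI {res.ci_low:.3f} to {res.ci_high:.3f})")

boot = mc.kappa_ci(TABLE, method="bootstrap", n_boot=1000, seed=1)
print(f"bootstrap 95% CI: {boot[0]:.3f} to {boot[1]:.3f}")

alt = mc.fleiss_kappa(TABLE, observed="all-concur")
print(f"kappa under the all-concur observed definition: {alt.kappa:.3f}")

print("\nimbalance ladder (discordance fixed, not-dead count growing):")
disc = {c: v for c, v in TABLE.items() if c != "none"}
for none in (20000, 200000, 884890, 5000000):
    r = mc.fleiss_kappa({**disc, "none": none})
    print(f"  none={none:>8}: expected={r.p_expected:.5f} kappa={r.kappa:+.3f}")
# Chance agreement climbs toward 1, so the denominator of kappa vanishes:
# with >97% of patients not dead anywhere, the category table and Venn
# regions describe the data better than any single agreement coefficient.
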