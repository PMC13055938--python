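# Methods

## Problem and model

`mortcord` analyses how consistently death is recorded across three
imperfect mortality sources covering one patient population: two health
systems (A and B) serving the same region, and a death-master-file extract
of the kind US institutions license from the Social Security
Administration. No single source is a gold standard — deaths outside a
facility are often invisible to it, and the public death-master file has
excluded protected state records since late 2011 — so the analysis treats
the three sources as three raters and asks where they agree.

The pipeline has four stages.

1. **Identity linkage.** Records are linked across the two health systems
   by any of three deterministic rules: an identifier crosswalk, exact
   agreement of normalized first name, last name, gender and birth date, or
   a shared medical record number. The merged clusters are then linked to
   the death-master extract through five keyed hash tokens of normalized
   identity fields:

   | token | material |
   |---|---|
   | 1 | last name, first initial, gender, birth date |
   | 2 | Soundex(last), Soundex(first), gender, birth date |
   | 3 | last name, first name, gender, birth date |
   | 4 | SSN, gender, birth date |
   | 5 | SSN, first name |

   Tokens 3–5 each suffice alone; tokens 1 and 2 must agree jointly (on the
   same member record of a cluster). The joint rule tolerates spelling
   variation via the phonetic code while anchoring on the exact last name
   and birth date; its cost is a higher false-link risk between similarly
   named people, which is why it is not accepted singly. Links are resolved
   into person clusters by connected components; conflicting links merge
   components (union resolution). Patients whose cluster contains records
   from both health systems form the *matched cohort*.

2. **Concordance classification.** Each matched cluster gets a death-status
   triple (did A, B, the extract record a death), using the earliest death
   date when a source holds several, and falls into one of eight mutually
   exclusive categories: all three sources, each pair, each single source,
   or none. The summary derives the union of deaths (cohort size minus the
   none count), per-source totals, and percentages on two denominators —
   the cohort and the union — under half-up rounding to two decimals
   computed in exact rational arithmetic, so printed shares recompute
   bit-for-bit from counts.

3. **Agreement.** With three raters and two categories, the per-subject
   agreement for a patient with *n* "dead" votes is
   P_i = [n(n−1) + (3−n)(2−n)]/6, the fraction of concordant rater pairs.
   Observed agreement is reported under two definitions: the Fleiss mean of
   P_i (default, and what feeds κ) and the all-concur proportion
   (ABS + none)/N, because epidemiological reports sometimes define
   "observed agreement" as unanimity. Expected agreement is
   p̄² + (1−p̄)² from the pooled dead-vote marginal, and
   κ = (P_obs − P_e)/(1 − P_e). The 95% CI is asymptotic by default
   (Fleiss–Nee–Landis large-sample variance) with a seeded percentile
   bootstrap over subjects as an alternative; degenerate bootstrap
   resamples (a single category everywhere) are dropped.

   Under extreme class imbalance — here >97.8% of matched patients are
   "not dead" in every source — P_e approaches 1 and κ's denominator
   vanishes, so tiny absolute disagreements produce large or sign-flipped
   κ values. The package therefore treats the category table and Venn
   regions as the primary description and κ as a caveated summary. On a
   ladder with the discordance counts held fixed and the unanimous-not-dead
   count growing, P_e rises monotonically toward 1 and κ climbs
   monotonically toward the finite limit 1 − N_disc/D (N_disc = discordant
   subjects, D = total dead votes); the test suite pins this behaviour.

4. **Data-quality detectors.** Three rule-based checks:
   * *Date discrepancies*: for each source pair that both dated a cluster's
     death, the whole-calendar-month difference (decremented when the final
     month is incomplete; symmetric); differences of ≥ 1 month are flagged
     and summarized per pair (count, median, min, max; the median of an
     even count is the mean of the central pair).
   * *Lost contact*: a matched cluster with encounters at facility X is
     flagged (lost_from = X) when no X encounter occurs for 12 months after
     its last X visit and the other facility sees the patient strictly
     after that window. One flag per (cluster, direction). A last visit
     within 12 months of the study end cannot satisfy the after-window
     requirement, so such clusters are implicitly censored.
   * *Post-death encounters*: any health-system encounter strictly later
     than a recorded death date + 365 days (leap years not special-cased —
     the simplest defensible reading of "more than a year"). Rates divide
     flagged deaths by each source's death total.

## Synthetic cohorts

The study setting this emulates deposits no data, so the generator is a
first-class module that defines the study conditions. It creates a matched cohort plus
single-system patients over the 2007-01-01 to 2020-07-10 observation
window, with:

* identities drawn from a packaged name-frequency list (network-free,
  seed-reproducible), gender from {F, M, U}, birth dates uniform over
  1920–2004, unique SSNs, and a shared per-person MRN emulating a regional
  enterprise identifier;
* death status either sampled independently per source (defaults are the
  matched-cohort rates of the study setting: A 1.62%, B 0.44%, extract
  0.59%) or pinned exactly by an 8-category count table — the mode the
  reproduction runs use;
* death dates uniform over the window, shared across sources except for
  designated date-shift persons, whose chosen source is moved by a whole
  number of months (day-of-month capped at 28 so the shift is exactly
  recoverable);
* per-facility encounter streams, Poisson with 0.25 visits/facility-year
  (the setting states no encounter frequency; this is our choice of a
  sparse ambulatory population) truncated at death;
* identity noise at configurable rates: single-character name typos,
  blanked SSN/MRN.

Two engineering properties make exact evaluation possible and are worth
stating because they are *departures from realism*:

* **Identity keys are unique by construction.** No two distinct persons
  share (last name, gender, birth date, first initial, first-name Soundex)
  — the strongest key any linkage rule matches on — enforced by resampling
  birth dates. Real registries contain such collisions; here they are
  excluded so that zero-noise linkage has precision = recall = 1 as an
  exact target and the 904,581-subject table reproduction cannot be
  perturbed by a chance false link.
* **Encounter streams are edited to avoid accidental QC patterns.** Each
  non-designated person's last visits at the two facilities are aligned,
  designated lost-contact persons get constructed streams (last visit at
  the lost facility 6–18 months into the window, a switch visit 12 months
  + 31 days later at the other facility), and designated post-death cases
  get one extra visit at both facilities 366–394 days after death. Flag
  sets therefore equal designated sets exactly; on real data the detectors
  would also fire on coincidental patterns.

Consequently, passing tests demonstrate that the *rules are implemented
faithfully and recover planted structure exactly*; they do not estimate the
detectors' false-positive rates on real encounter processes, nor the
linkage error under realistic name-collision rates.

## Numerical and design choices

* Hashes are keyed BLAKE2b, 256-bit; the linkage contract is only
  determinism and one-wayness, so the function and salt are configuration.
* Soundex is the American (census-style) code: initial letter + three
  digits, vowels separate consonant runs, H/W do not, adjacent equal codes
  collapse.
* "1 month or more" is the operative date-discrepancy rule (the published
  ranges start at 1 month), implemented as whole-month delta ≥ 1.
* Rounding of printed percentages is half-up at 2 decimals in `Decimal`
  rational arithmetic, never binary-float rounding.
* κ is reported to 3 decimals, agreements to 4.
* Cluster ids are assigned by the lexicographically smallest member key, so
  outputs are byte-stable across runs; report bundles contain no
  timestamps.
* The bootstrap-coverage calibration in the test suite uses a moderately
  imbalanced generating law (18% of subjects with some death record) at 500
  subjects; under the full study-scale imbalance a 500-subject draw holds
  roughly 11 death records and the percentile bootstrap undercovers — an
  instance of the same small-expected-count instability that makes κ itself
  fragile here.
* Problem sizes in the routine checks: the full 904,581-subject
  reproduction runs once; linkage recovery uses 10,000 matched + 5,000
  single-system persons; the designated-pattern QC cohort uses 5,000
  persons. These sizes make every exact target meaningful while keeping a
  complete run in minutes on one CPU.

## Known limitations

* The published κ of the motivating study (−0.312, observed 0.9771,
  expected 0.9826) is **not** derivable from its own category table under
  the standard Fleiss formulas or the all-concur variant; this
  implementation yields +0.178 (Fleiss observed) or −0.233 (all-concur)
  with observed agreement 0.9856/0.9785 and expected 0.9825. The package
  documents and reports its own internally consistent values rather than
  matching the printed ones.
* Linkage is purely deterministic: no probabilistic (Fellegi–Sunter)
  weighting, and no approximate string matching beyond Soundex.
* The generator does not model demographic correlation structure,
  geography, or survival processes; death dates are uniform, not
  hazard-driven.
* Whether the original death-master linkage operated on records or merged
  clusters is unstated in the setting this emulates; linking against
  clusters is this package's choice, with record-level linking equivalent
  under union resolution.
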