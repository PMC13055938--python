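"""Death-status assignment and 8-category concordance classification.

Every matched cluster (a resolved identity with records in both health
systems) is reduced to a boolean triple — did system A, system B, and the
death-master extract each record a death — and classified into one of eight
mutually exclusive categories: all three sources (ABS), each pair (AB, AS,
BS), each single source (A_only, B_only, S_only), or none.  The summary
derives the union of deaths, per-source totals, and every percentage the
category table supports, under half-up rounding to two decimals so printed
shares recompute exactly from the counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .linkage import SSADMF, SYSTEM_A, SYSTEM_B

CATEGORIES = ("ABS", "AB", "AS", "BS", "A_only", "B_only", "S_only", "none")

CATEGORY_FLAGS = {
    "ABS": (True, True, True),
    "AB": (True, True, False),
    "AS": (True, False, True),
    "BS": (False, True, True),
    "A_only": (True, False, False),
    "B_only": (False, True, False),
    "S_only": (False, False, True),
    "none": (False, False, False),
}

_FLAGS_TO_CATEGORY = {flags: cat for cat, flags in CATEGORY_FLAGS.items()}


class CohortError(ValueError):
    """Raised for clusters or summaries outside the matched-cohort contract."""


def percent(numerator: int, denominator: int, decimals: int = 2) -> float:
    """Exact half-up percentage, as printed in the study's tables.

    Computed rationally (no binary-float rounding surprises):
    ``percent(10697, 19691)`` is exactly ``54.32``.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    q = Decimal(100 * numerator) / Decimal(denominator)
    return float(q.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


@dataclass
class DeathStatusVector:
    """Per-cluster death booleans and dates for the three sources."""

    cluster_id: str
    dead_a: bool
    dead_b: bool
    dead_s: bool
    death_date_a: Optional[pd.Timestamp] = None
    death_date_b: Optional[pd.Timestamp] = None
    death_date_s: Optional[pd.Timestamp] = None
    multiple_dates: bool = False


def classify(v) -> str:
    """The unique category matching a death-status boolean triple."""
    if isinstance(v, DeathStatusVector):
        triple = (v.dead_a, v.dead_b, v.dead_s)
    else:
        triple = tuple(bool(x) for x in v)
    return _FLAGS_TO_CATEGORY[triple]


def death_status_frame(
    members: pd.DataFrame,
    registry_a: pd.DataFrame,
    registry_b: pd.DataFrame,
    ssadmf: pd.DataFrame,
    matched_only: bool = True,
) -> pd.DataFrame:
    """Per-cluster death status from the earliest death date any member carries.

    When a cluster holds several dated records within one source, the
    earliest date is retained and the multiplicity is flagged.  Returns one
    row per cluster with columns ``cluster_id, dead_A/B/S, death_date_A/B/S,
    multiple_dates_A/B/S, category``.
    """
    sub = members[members["matched"]] if matched_only else members
    cluster_ids = sub["cluster_id"].unique()
    out = pd.DataFrame({"cluster_id": np.sort(cluster_ids)})
    for suffix, source, registry in (
        ("A", SYSTEM_A, registry_a),
        ("B", SYSTEM_B, registry_b),
        ("S", SSADMF, ssadmf),
    ):
        side = sub[sub["source"] == source]
        if len(side) and len(registry):
            m = side.merge(
                registry[["record_id", "death_date"]], on="record_id", how="left"
            )
            dated = m.dropna(subset=["death_date"])
            agg = dated.groupby("cluster_id")["death_date"].agg(["min", "size"])
        else:
            agg = pd.DataFrame(columns=["min", "size"])
        out[f"death_date_{suffix}"] = pd.to_datetime(
            out["cluster_id"].map(agg["min"])
        )
        out[f"multiple_dates_{suffix}"] = (
            out["cluster_id"].map(agg["size"]).fillna(0).astype(int) > 1
        )
        out[f"dead_{suffix}"] = out[f"death_date_{suffix}"].notna()
    code = (
        out["dead_A"].astype(int) * 4
        + out["dead_B"].astype(int) * 2
        + out["dead_S"].astype(int)
    )
    lut = {a * 4 + b * 2 + s: cat
           for cat, (a, b, s) in CATEGORY_FLAGS.items()}
    out["category"] = code.map(lut)
    return out


def assign_death_status(
    cluster, registry_a: pd.DataFrame, registry_b: pd.DataFrame, ssadmf: pd.DataFrame
) -> DeathStatusVector:
    """Death-status vector of a single matched cluster.

    ``cluster`` is a `linkage.PersonCluster`.  Clusters without records in
    both health systems are outside the matched cohort and rejected.
    """
    if not cluster.matched:
        raise CohortError(
            f"cluster {cluster.cluster_id} lacks records in both health systems"
        )
    vals = {}
    multi = False
    for suffix, source, registry in (
        ("a", SYSTEM_A, registry_a),
        ("b", SYSTEM_B, registry_b),
        ("s", SSADMF, ssadmf),
    ):
        ids = cluster.members.get(source, [])
        dates = registry.loc[
            registry["record_id"].isin(ids), "death_date"
        ].dropna()
        vals[suffix] = dates.min() if len(dates) else None
        multi = multi or len(dates) > 1
    return DeathStatusVector(
        cluster.cluster_id,
        vals["a"] is not None,
        vals["b"] is not None,
        vals["s"] is not None,
        vals["a"], vals["b"], vals["s"],
        multiple_dates=multi,
    )


@dataclass
class ConcordanceSummary:
    """The 8-category count table plus its derived totals and percentages."""

    n_matched: int
    counts: dict  # category -> count
    union_deaths: int
    totals: dict  # source letter A/B/S -> deaths recorded by that source
    pct_of_cohort: dict  # category -> percent of n_matched
    pct_of_union: dict  # category -> percent of union_deaths
    contribution_pct: dict  # source letter -> percent of union contributed

    def venn_regions(self) -> dict:
        """Exclusive region counts for the 3-set Venn diagram."""
        c = self.counts
        return {
            "A": c["A_only"], "B": c["B_only"], "S": c["S_only"],
            "AB": c["AB"], "AS": c["AS"], "BS": c["BS"], "ABS": c["ABS"],
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "category": cat,
                "count": self.counts[cat],
                "pct_of_cohort": self.pct_of_cohort[cat],
                "pct_of_union": self.pct_of_union.get(cat),
            }
            for cat in CATEGORIES
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "n_matched": self.n_matched,
            "counts": dict(self.counts),
            "union_deaths": self.union_deaths,
            "totals": dict(self.totals),
            "pct_of_cohort": dict(self.pct_of_cohort),
            "pct_of_union": dict(self.pct_of_union),
            "contribution_pct": dict(self.contribution_pct),
            "venn_regions": self.venn_regions(),
        }


def summarize_counts(counts: Mapping[str, int]) -> ConcordanceSummary:
    """Build the full summary from an 8-category count table."""
    missing = set(CATEGORIES) - set(counts)
    if missing:
        counts = {**{c: 0 for c in missing}, **dict(counts)}
    counts = {c: int(counts[c]) for c in CATEGORIES}
    n = sum(counts.values())
    if n == 0:
        raise CohortError("empty cohort: no subjects to summarize")
    union = n - counts["none"]
    totals = {
        "A": counts["ABS"] + counts["AB"] + counts["AS"] + counts["A_only"],
        "B": counts["ABS"] + counts["AB"] + counts["BS"] + counts["B_only"],
        "S": counts["ABS"] + counts["AS"] + counts["BS"] + counts["S_only"],
    }
    pct_cohort = {c: percent(k, n) for c, k in counts.items()}
    death_cats = [c for c in CATEGORIES if c != "none"]
    pct_union = (
        {c: percent(counts[c], union) for c in death_cats} if union else {}
    )
    contrib = (
        {s: percent(totals[s], union) for s in totals} if union else {}
    )
    return ConcordanceSummary(n, counts, union, totals, pct_cohort, pct_union, contrib)


def summarize(vectors) -> ConcordanceSummary:
    """Summarize per-cluster death-status vectors (frame or iterable)."""
    if isinstance(vectors, pd.DataFrame):
        if len(vectors) == 0:
            raise CohortError("empty cohort: no subjects to summarize")
        cats = (
            vectors["category"]
            if "category" in vectors.columns
            else vectors.apply(
                lambda r: classify((r["dead_A"], r["dead_B"], r["dead_S"])), axis=1
            )
        )
        counts = cats.value_counts().to_dict()
    else:
        vectors = list(vectors)
        if not vectors:
            raise CohortError("empty cohort: no subjects to summarize")
        counts = pd.Series([classify(v) for v in vectors]).value_counts().to_dict()
    return summarize_counts(counts)


def export_venn(summary: ConcordanceSummary) -> dict:
    """Region-count mapping for the 3-set Venn diagram; sums to the union."""
    return summary.venn_regions()
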