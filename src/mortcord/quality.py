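"""Exploratory EHR data-quality detectors.

Three rule-based checks over a linked, death-classified cohort:

* cross-source death-date discrepancies of at least a whole calendar month;
* lost-contact patients — no encounters at one facility for 12 months after
  their last visit there, while the other facility sees them after that
  window;
* post-death encounters — visits at either health system more than a year
  after a source's recorded death date.

Month differences are whole elapsed calendar months: the day-of-month rule
decrements the raw month count when the final month is incomplete, so
2010-03-10 to 2010-04-09 is 0 months and to 2010-05-10 is 2.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
import pandas as pd

from .linkage import SSADMF, SYSTEM_A, SYSTEM_B

SOURCE_PAIRS = (("A-B", SYSTEM_A, SYSTEM_B), ("A-S", SYSTEM_A, SSADMF),
                ("B-S", SYSTEM_B, SSADMF))

_DateLike = Union[pd.Timestamp, np.datetime64, str]


def add_months(date: _DateLike, months: int) -> pd.Timestamp:
    """Shift a date by whole calendar months, clamping the day to month end."""
    t = pd.Timestamp(date)
    m = t.month - 1 + months
    year, month = t.year + m // 12, m % 12 + 1
    day = min(t.day, pd.Timestamp(year=year, month=month, day=1).days_in_month)
    return pd.Timestamp(year=year, month=month, day=day)


def _add_months_array(dates: pd.Series, months: int) -> pd.Series:
    d = pd.DatetimeIndex(dates)
    m = d.year * 12 + (d.month - 1) + months
    year, month = m // 12, m % 12 + 1
    firsts = pd.to_datetime(pd.DataFrame({"year": year, "month": month, "day": 1}))
    day = np.minimum(d.day, pd.DatetimeIndex(firsts).days_in_month)
    shifted = pd.to_datetime(pd.DataFrame({"year": year, "month": month, "day": day}))
    return pd.Series(shifted.to_numpy(), index=dates.index)


def month_delta(d1: _DateLike, d2: _DateLike) -> int:
    """Whole elapsed calendar months between two dates (symmetric, >= 0)."""
    a, b = sorted((pd.Timestamp(d1), pd.Timestamp(d2)))
    months = (b.year - a.year) * 12 + (b.month - a.month)
    if b.day < a.day:
        months -= 1
    return int(months)


def _month_delta_array(a: pd.Series, b: pd.Series) -> np.ndarray:
    lo = pd.DatetimeIndex(np.minimum(a.to_numpy(), b.to_numpy()))
    hi = pd.DatetimeIndex(np.maximum(a.to_numpy(), b.to_numpy()))
    months = (hi.year - lo.year) * 12 + (hi.month - lo.month)
    return (months - (hi.day < lo.day)).to_numpy()


def _summary(deltas: np.ndarray) -> dict:
    if len(deltas) == 0:
        return {"count": 0, "median": None, "min": None, "max": None}
    return {
        "count": int(len(deltas)),
        "median": float(np.median(deltas)),
        "min": int(deltas.min()),
        "max": int(deltas.max()),
    }


def detect_date_discrepancies(
    status: pd.DataFrame, threshold_months: int = 1
) -> tuple[pd.DataFrame, dict]:
    """Flag clusters whose two recorded death dates differ by >= the threshold.

    ``status`` is the per-cluster death-status frame (columns ``cluster_id``,
    ``death_date_A/B/S``).  Returns the flag table (cluster, source pair,
    whole-month delta) and a per-pair summary with count, median, min, max.
    """
    status = status.copy()
    for col in ("death_date_A", "death_date_B", "death_date_S"):
        status[col] = pd.to_datetime(status[col]) if col in status else pd.NaT
    flags = []
    summary = {}
    for label, left, right in SOURCE_PAIRS:
        col_l = {"SYSTEM_A": "death_date_A", "SYSTEM_B": "death_date_B",
                 "SSADMF": "death_date_S"}[left]
        col_r = {"SYSTEM_A": "death_date_A", "SYSTEM_B": "death_date_B",
                 "SSADMF": "death_date_S"}[right]
        both = status.dropna(subset=[col_l, col_r])
        if len(both):
            deltas = _month_delta_array(both[col_l], both[col_r])
            keep = deltas >= threshold_months
            flagged = pd.DataFrame(
                {
                    "cluster_id": both["cluster_id"].to_numpy()[keep],
                    "source_pair": label,
                    "delta_months": deltas[keep],
                }
            )
        else:
            flagged = pd.DataFrame(columns=["cluster_id", "source_pair", "delta_months"])
            deltas = np.array([], int)
            keep = np.array([], bool)
        flags.append(flagged)
        summary[label] = _summary(deltas[keep] if len(deltas) else np.array([], int))
    out = pd.concat(flags, ignore_index=True)
    return out, summary


def detect_lost_contact(
    encounters: pd.DataFrame,
    members: pd.DataFrame,
    window_months: int = 12,
    study_end: Optional[_DateLike] = None,
) -> pd.DataFrame:
    """Flag matched clusters that silently left one facility for the other.

    For each matched cluster and each health system X where it has at least
    one encounter: if no X encounter follows the last X visit for
    ``window_months`` months (trivially true of the last visit) and the other
    system records at least one encounter strictly after that window, the
    cluster is flagged once per direction (``lost_from`` = X).

    When ``study_end`` is given, clusters whose last X visit lies within the
    window of the study end are censored (insufficient follow-up) — they
    cannot be flagged, which the after-window requirement already enforces,
    and they are excluded from any denominator a caller builds from this
    table.
    """
    enc = encounters.merge(
        members[["record_id", "cluster_id", "matched"]], on="record_id", how="inner"
    )
    enc = enc[enc["matched"] & enc["source"].isin((SYSTEM_A, SYSTEM_B))]
    if enc.empty:
        return pd.DataFrame(
            columns=["cluster_id", "lost_from", "switched_to",
                     "last_visit_lost_source", "first_visit_other_after_window"]
        )
    last = (
        enc.groupby(["cluster_id", "source"])["encounter_date"].max().unstack()
    )
    flags = []
    for lost, other in ((SYSTEM_A, SYSTEM_B), (SYSTEM_B, SYSTEM_A)):
        if lost not in last.columns or other not in last.columns:
            continue
        sub = last.dropna(subset=[lost])
        cutoff = _add_months_array(sub[lost], window_months)
        # earliest other-system visit strictly after the window
        other_enc = enc[enc["source"] == other][["cluster_id", "encounter_date"]]
        joined = other_enc.merge(
            pd.DataFrame({"cluster_id": sub.index, "cutoff": cutoff.to_numpy()}),
            on="cluster_id",
        )
        joined = joined[joined["encounter_date"] > joined["cutoff"]]
        if joined.empty:
            continue
        first_after = joined.groupby("cluster_id")["encounter_date"].min()
        flags.append(
            pd.DataFrame(
                {
                    "cluster_id": first_after.index,
                    "lost_from": lost,
                    "switched_to": other,
                    "last_visit_lost_source": sub.loc[first_after.index, lost].to_numpy(),
                    "first_visit_other_after_window": first_after.to_numpy(),
                }
            )
        )
    if not flags:
        return pd.DataFrame(
            columns=["cluster_id", "lost_from", "switched_to",
                     "last_visit_lost_source", "first_visit_other_after_window"]
        )
    return pd.concat(flags, ignore_index=True).sort_values(
        ["cluster_id", "lost_from"], ignore_index=True
    )


def detect_postdeath_encounters(
    status: pd.DataFrame,
    encounters: pd.DataFrame,
    members: pd.DataFrame,
    threshold_days: int = 365,
) -> tuple[pd.DataFrame, dict]:
    """Flag encounters occurring more than a year after a recorded death.

    Each source-specific death date is compared with every health-system
    encounter of the same cluster; encounters strictly later than
    ``death date + threshold_days`` are flagged.  The per-source rate divides
    flagged deaths (clusters, not encounters) by the number of deaths that
    source recorded.
    """
    status = status.copy()
    for col in ("death_date_A", "death_date_B", "death_date_S"):
        status[col] = pd.to_datetime(status[col]) if col in status else pd.NaT
    enc = encounters.merge(
        members[["record_id", "cluster_id"]], on="record_id", how="inner"
    )
    enc = enc[enc["source"].isin((SYSTEM_A, SYSTEM_B))]
    flags = []
    rates = {}
    for src, col in ((SYSTEM_A, "death_date_A"), (SYSTEM_B, "death_date_B"),
                     (SSADMF, "death_date_S")):
        deaths = status.dropna(subset=[col])[["cluster_id", col]]
        n_deaths = len(deaths)
        joined = enc.merge(deaths, on="cluster_id")
        hit = joined[
            joined["encounter_date"] > joined[col] + pd.Timedelta(days=threshold_days)
        ]
        if len(hit):
            flags.append(
                pd.DataFrame(
                    {
                        "cluster_id": hit["cluster_id"].to_numpy(),
                        "death_source": src,
                        "death_date": hit[col].to_numpy(),
                        "encounter_source": hit["source"].to_numpy(),
                        "encounter_date": hit["encounter_date"].to_numpy(),
                    }
                )
            )
            n_flagged = hit["cluster_id"].nunique()
        else:
            n_flagged = 0
        rates[src] = {
            "flagged_deaths": int(n_flagged),
            "deaths": int(n_deaths),
            "rate": (n_flagged / n_deaths) if n_deaths else None,
        }
    if flags:
        out = pd.concat(flags, ignore_index=True).sort_values(
            ["cluster_id", "death_source", "encounter_date"], ignore_index=True
        )
    else:
        out = pd.DataFrame(
            columns=["cluster_id", "death_source", "death_date",
                     "encounter_source", "encounter_date"]
        )
    return out, rates
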