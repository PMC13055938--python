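"""Synthetic multi-source cohort generator with known ground truth.

Emulates the study setting: two health systems serving one region with a
partially overlapping patient population, and a death-master-file extract
covering everyone.  Matched patients (present in both systems) carry a
death-status combination across the three sources — either sampled from
per-source death rates or fixed exactly by an 8-category count table — plus
optional identity noise (name typos, missing SSN/MRN), cross-source
death-date shifts, and encounter streams engineered to contain designated
lost-contact and post-death-encounter patterns and, importantly, no
accidental ones, so detector output can be compared with the truth table
set-for-set.

Identity keys are unique by construction: no two distinct synthetic persons
share (last name, gender, birth date, first initial, first-name Soundex),
the strongest key any linkage rule matches on.  Zero-noise linkage therefore
has a well-defined exact answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import _names
from .concordance import CATEGORIES, CATEGORY_FLAGS
from .linkage import SYSTEM_A, SYSTEM_B, SSADMF, soundex
from .quality import add_months


class ConfigError(ValueError):
    """Inconsistent or invalid generator configuration."""


DateShiftSpec = Union[Sequence[int], tuple]


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    ``category_counts`` pins the matched cohort's death-status table exactly
    (counts over the 8 source-combination categories, summing to
    ``n_matched``); it is mutually exclusive with nonzero per-source death
    rates.  Default death rates are the matched-cohort rates the study
    setting exhibits (A 1.62%, B 0.44%, death master 0.59%); the observation
    window defaults to 2007-01-01 through 2020-07-10.
    """

    n_matched: int = 1000
    n_only_a: int = 0
    n_only_b: int = 0
    category_counts: Optional[dict] = None
    death_rate_a: float = 0.0162
    death_rate_b: float = 0.0044
    death_rate_s: float = 0.0059
    name_typo_rate: float = 0.0
    ssn_missing_rate: float = 0.0
    mrn_missing_rate: float = 0.0
    date_shift_months: DateShiftSpec = (1, 2, 3, 6, 12, 24)
    date_shift_fraction: float = 0.0
    lost_contact_fraction: float = 0.0
    postdeath_encounter_fraction: float = 0.0
    encounter_rate_per_year: float = 0.25
    crosswalk_fraction: float = 0.5
    study_start: str = "2007-01-01"
    study_end: str = "2020-07-10"
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "death_rate_a": self.death_rate_a,
            "death_rate_b": self.death_rate_b,
            "death_rate_s": self.death_rate_s,
            "name_typo_rate": self.name_typo_rate,
            "ssn_missing_rate": self.ssn_missing_rate,
            "mrn_missing_rate": self.mrn_missing_rate,
            "date_shift_fraction": self.date_shift_fraction,
            "lost_contact_fraction": self.lost_contact_fraction,
            "postdeath_encounter_fraction": self.postdeath_encounter_fraction,
            "crosswalk_fraction": self.crosswalk_fraction,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name}={p} outside [0, 1]")
        if min(self.n_matched, self.n_only_a, self.n_only_b) < 0:
            raise ConfigError("cohort sizes must be nonnegative")
        if pd.Timestamp(self.study_start) >= pd.Timestamp(self.study_end):
            raise ConfigError("study_start must precede study_end")
        if self.category_counts is not None:
            unknown = set(self.category_counts) - set(CATEGORIES)
            if unknown:
                raise ConfigError(f"unknown categories {sorted(unknown)}")
            total = sum(int(v) for v in self.category_counts.values())
            if total != self.n_matched:
                raise ConfigError(
                    f"category_counts sum to {total}, expected n_matched={self.n_matched}"
                )
            if any(v < 0 for v in self.category_counts.values()):
                raise ConfigError("category counts must be nonnegative")
            if self.death_rate_a or self.death_rate_b or self.death_rate_s:
                raise ConfigError(
                    "category_counts fixes the death table; death rates must be 0"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["date_shift_months"] is not None:
            d["date_shift_months"] = list(d["date_shift_months"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class CohortData:
    """Generator output: three registries, encounters, crosswalk, and truth."""

    registry_a: pd.DataFrame
    registry_b: pd.DataFrame
    ssadmf: pd.DataFrame
    encounters: pd.DataFrame
    truth: pd.DataFrame
    crosswalk: pd.DataFrame
    config: SyntheticConfig


def _unique_identities(n: int, rng: np.random.Generator) -> pd.DataFrame:
    gender = np.where(rng.random(n) < 0.5, "F", "M")
    sur_w = _names.rank_weights(len(_names.SURNAMES))
    last = rng.choice(np.array(_names.SURNAMES), size=n, p=sur_w)
    first = np.empty(n, dtype=object)
    for g, pool in (("F", _names.FEMALE_GIVEN), ("M", _names.MALE_GIVEN)):
        m = gender == g
        first[m] = rng.choice(np.array(pool), size=int(m.sum()), p=_names.rank_weights(len(pool)))

    d0 = np.datetime64("1920-01-01")
    span = (np.datetime64("2004-12-31") - d0).astype(int)
    dob = d0 + rng.integers(0, span + 1, n).astype("timedelta64[D]")

    sdx = {name: soundex(name) for name in set(_names.FEMALE_GIVEN) | set(_names.MALE_GIVEN)}
    key = pd.DataFrame(
        {
            "last": last,
            "gender": gender,
            "dob": dob,
            "ini": pd.Series(first).str[0].to_numpy(),
            "sdx": pd.Series(first).map(sdx).to_numpy(),
        }
    )
    # resample birth dates until the strongest linkage key is collision-free
    for _ in range(50):
        dup = key.duplicated(keep="first").to_numpy()
        if not dup.any():
            break
        k = int(dup.sum())
        key.loc[dup, "dob"] = d0 + rng.integers(0, span + 1, k).astype("timedelta64[D]")
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not deduplicate identity keys")

    ssn = rng.integers(100_000_000, 1_000_000_000, n)
    for _ in range(50):
        dup = pd.Series(ssn).duplicated(keep="first").to_numpy()
        if not dup.any():
            break
        ssn[dup] = rng.integers(100_000_000, 1_000_000_000, int(dup.sum()))

    return pd.DataFrame(
        {
            "first_name": pd.Series(first).str.title().to_numpy(),
            "last_name": pd.Series(last).str.title().to_numpy(),
            "gender": gender,
            "birth_date": key["dob"].to_numpy(),
            "ssn": np.array([f"{s:09d}" for s in ssn], dtype=object),
        }
    )


def _sample_shift_months(spec: DateShiftSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec, tuple) and len(spec) == 2 and spec[0] == "geometric":
        return rng.geometric(float(spec[1]), size)
    arr = np.asarray(list(spec), dtype=int)
    if len(arr) == 0 or (arr < 1).any():
        raise ConfigError("date_shift_months must be positive whole months")
    return rng.choice(arr, size)


def generate_cohort(config: SyntheticConfig) -> CohortData:
    """Generate registries, death-master extract, encounters and truth table.

    Deterministic given ``config`` (including its seed): two runs with the
    same configuration produce identical tables.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    r_ident, r_death, r_desig, r_enc, r_noise, r_xwalk = (
        np.random.default_rng(c) for c in ss.spawn(6)
    )

    n_m, n_a, n_b = config.n_matched, config.n_only_a, config.n_only_b
    n = n_m + n_a + n_b
    start = np.datetime64(config.study_start, "D")
    end = np.datetime64(config.study_end, "D")
    window_days = int((end - start).astype(int))

    ident = _unique_identities(n, r_ident)
    uid = np.arange(n)
    # person order: matched, then only-A, then only-B
    in_a = uid < n_m + n_a
    in_b = (uid < n_m) | (uid >= n_m + n_a)
    matched = uid < n_m

    # --- death status -----------------------------------------------------
    dead_a = np.zeros(n, bool)
    dead_b = np.zeros(n, bool)
    dead_s = np.zeros(n, bool)
    category = np.full(n, "", dtype=object)
    if config.category_counts is not None:
        labels = np.concatenate(
            [np.full(int(config.category_counts.get(c, 0)), c) for c in CATEGORIES]
        )
        labels = r_death.permutation(labels)
        category[:n_m] = labels
        flags = np.array([CATEGORY_FLAGS[c] for c in labels])
        dead_a[:n_m], dead_b[:n_m], dead_s[:n_m] = flags.T
    else:
        dead_a[in_a] = r_death.random(int(in_a.sum())) < config.death_rate_a
        dead_b[in_b] = r_death.random(int(in_b.sum())) < config.death_rate_b
        dead_s = r_death.random(n) < config.death_rate_s
        code = dead_a.astype(int) * 4 + dead_b.astype(int) * 2 + dead_s.astype(int)
        lut = {int(a) * 4 + int(b) * 2 + int(s): c
               for c, (a, b, s) in CATEGORY_FLAGS.items()}
        category[matched] = [lut[c] for c in code[matched]]
    category[n_m : n_m + n_a] = "only_A"
    category[n_m + n_a :] = "only_B"

    any_dead = dead_a | dead_b | dead_s
    true_death = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    true_death[any_dead] = start + r_death.integers(
        0, window_days + 1, int(any_dead.sum())
    ).astype("timedelta64[D]")

    date_a = np.where(dead_a, true_death, np.datetime64("NaT"))
    date_b = np.where(dead_b, true_death, np.datetime64("NaT"))
    date_s = np.where(dead_s, true_death, np.datetime64("NaT"))

    # --- designated cross-source death-date shifts ------------------------
    shift_source = np.full(n, "", dtype=object)
    shift_months = np.zeros(n, int)
    n_sources_dead = dead_a.astype(int) + dead_b.astype(int) + dead_s.astype(int)
    elig_shift = np.flatnonzero(matched & (n_sources_dead >= 2))
    k_shift = int(round(config.date_shift_fraction * len(elig_shift)))
    if k_shift:
        chosen = r_desig.choice(elig_shift, k_shift, replace=False)
        # day-of-month capped at 28 so a whole-month shift is exact
        td = pd.DatetimeIndex(true_death[chosen])
        capped = td.map(lambda t: t.replace(day=min(t.day, 28)))
        true_death[chosen] = np.array(capped, dtype="datetime64[D]")
        for arr, dead in ((date_a, dead_a), (date_b, dead_b), (date_s, dead_s)):
            sel = chosen[dead[chosen]]
            arr[sel] = true_death[sel]
        months = _sample_shift_months(config.date_shift_months, k_shift, r_desig)
        for i, p in enumerate(chosen):
            srcs = [s for s, d in zip((SYSTEM_A, SYSTEM_B, SSADMF),
                                      (dead_a[p], dead_b[p], dead_s[p])) if d]
            src = srcs[int(r_desig.integers(0, len(srcs)))]
            k = int(months[i])
            base = pd.Timestamp(true_death[p])
            shifted = add_months(base, k)
            if shifted > pd.Timestamp(end):
                shifted = add_months(base, -k)
                k = -k
                if shifted < pd.Timestamp(start):  # pragma: no cover
                    continue
            shift_source[p] = src
            shift_months[p] = k
            val = np.datetime64(shifted.date())
            if src == SYSTEM_A:
                date_a[p] = val
            elif src == SYSTEM_B:
                date_b[p] = val
            else:
                date_s[p] = val
    # refresh per-person earliest death after shifts
    stack = np.stack([date_a, date_b, date_s])
    min_death = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    has = ~np.all(np.isnat(stack), axis=0)
    if has.any():
        big = np.where(np.isnat(stack), np.datetime64("2262-01-01"), stack)
        min_death[has] = big.min(axis=0)[has]

    # --- designated lost-contact and post-death-encounter persons ---------
    lost_from = np.full(n, "", dtype=object)
    lc_horizon = start + np.timedelta64(1000, "D")
    elig_lc = np.flatnonzero(
        matched & (np.isnat(min_death) | (min_death > lc_horizon)) & (shift_months == 0)
    )
    k_lc = min(int(round(config.lost_contact_fraction * n_m)), len(elig_lc))
    lc_idx = r_desig.choice(elig_lc, k_lc, replace=False) if k_lc else np.array([], int)
    for p in lc_idx:
        if dead_a[p] and not dead_b[p]:
            lost_from[p] = SYSTEM_B
        elif dead_b[p] and not dead_a[p]:
            lost_from[p] = SYSTEM_A
        else:
            lost_from[p] = SYSTEM_A if r_desig.random() < 0.5 else SYSTEM_B

    postdeath = np.zeros(n, bool)
    elig_pd = np.flatnonzero(
        matched
        & ~np.isnat(min_death)
        & (min_death <= end - np.timedelta64(400, "D"))
        & (shift_months == 0)
        & (lost_from == "")
    )
    k_pd = int(round(config.postdeath_encounter_fraction * len(elig_pd)))
    if k_pd:
        postdeath[r_desig.choice(elig_pd, k_pd, replace=False)] = True

    # --- encounters -------------------------------------------------------
    upper = np.where(np.isnat(min_death), end, min_death)
    upper_days = (upper - start).astype(int)
    is_lc = lost_from != ""
    rows_p, rows_f, rows_d = [], [], []
    for fac, present in ((SYSTEM_A, in_a), (SYSTEM_B, in_b)):
        idx = np.flatnonzero(present & ~is_lc)
        lam = config.encounter_rate_per_year * (upper_days[idx] / 365.25)
        cnt = r_enc.poisson(lam)
        rep = np.repeat(idx, cnt)
        offs = r_enc.random(len(rep)) * (upper_days[rep] + 1)
        rows_p.append(rep)
        rows_f.append(np.full(len(rep), fac, dtype=object))
        rows_d.append(offs.astype(int))
    enc = pd.DataFrame(
        {
            "person": np.concatenate(rows_p),
            "source": np.concatenate(rows_f),
            "day": np.concatenate(rows_d),
        }
    )
    # align each facility's last visit with the person's overall last visit so
    # no undesignated person exhibits the lost-contact pattern
    if len(enc):
        last_idx = enc.groupby(["person", "source"])["day"].idxmax()
        overall = enc.groupby("person")["day"].max()
        enc.loc[last_idx, "day"] = overall.loc[
            enc.loc[last_idx, "person"]
        ].to_numpy()

    extra = []
    if len(lc_idx):
        c_off = r_desig.integers(180, 541, len(lc_idx))  # last visit 6-18 mo in
        for p, co in zip(lc_idx, c_off):
            c_day = int(co)
            c_date = start + np.timedelta64(c_day, "D")
            switch = np.datetime64(add_months(pd.Timestamp(c_date), 12).date()) + np.timedelta64(31, "D")
            other = SYSTEM_A if lost_from[p] == SYSTEM_B else SYSTEM_B
            sw_day = int((switch - start).astype(int))
            extra.append((p, lost_from[p], max(c_day - 180, 0)))
            extra.append((p, lost_from[p], c_day))
            extra.append((p, other, max(c_day - 60, 0)))
            extra.append((p, other, sw_day))
    pd_idx = np.flatnonzero(postdeath)
    if len(pd_idx):
        offs = 366 + r_desig.integers(0, 29, len(pd_idx))
        for p, o in zip(pd_idx, offs):
            d = int((min_death[p] - start).astype(int)) + int(o)
            extra.append((p, SYSTEM_A, d))
            extra.append((p, SYSTEM_B, d))
    if extra:
        enc = pd.concat(
            [enc, pd.DataFrame(extra, columns=["person", "source", "day"])],
            ignore_index=True,
        )
    enc["encounter_date"] = start + enc["day"].to_numpy().astype("timedelta64[D]")
    enc["record_id"] = np.where(
        enc["source"] == SYSTEM_A,
        pd.Series(enc["person"]).map(lambda p: f"A{p:07d}"),
        pd.Series(enc["person"]).map(lambda p: f"B{p:07d}"),
    )
    encounters = (
        enc[["record_id", "source", "encounter_date"]]
        .sort_values(["record_id", "source", "encounter_date"], ignore_index=True)
    )

    # --- registries and truth --------------------------------------------
    def registry(present: np.ndarray, prefix: str, dates: np.ndarray) -> pd.DataFrame:
        idx = np.flatnonzero(present)
        return pd.DataFrame(
            {
                "record_id": [f"{prefix}{p:07d}" for p in idx],
                "first_name": ident["first_name"].to_numpy()[idx],
                "last_name": ident["last_name"].to_numpy()[idx],
                "gender": ident["gender"].to_numpy()[idx],
                "birth_date": ident["birth_date"].to_numpy()[idx],
                "ssn": ident["ssn"].to_numpy()[idx],
                "mrn": [f"M{p:08d}" for p in idx],
                "death_date": dates[idx],
            }
        )

    registry_a = registry(in_a, "A", date_a)
    registry_b = registry(in_b, "B", date_b)
    ssadmf = registry(dead_s, "S", date_s).drop(columns=["mrn"])

    registry_a = inject_identity_noise(
        registry_a, config.name_typo_rate, config.ssn_missing_rate,
        config.mrn_missing_rate, r_noise,
    )
    registry_b = inject_identity_noise(
        registry_b, config.name_typo_rate, config.ssn_missing_rate,
        config.mrn_missing_rate, r_noise,
    )

    k_xw = int(round(config.crosswalk_fraction * n_m))
    xw_idx = np.sort(r_xwalk.choice(n_m, k_xw, replace=False)) if k_xw else np.array([], int)
    crosswalk = pd.DataFrame(
        {
            "record_id_a": [f"A{p:07d}" for p in xw_idx],
            "record_id_b": [f"B{p:07d}" for p in xw_idx],
        }
    )

    truth = pd.DataFrame(
        {
            "person_uid": uid,
            "record_id_a": np.where(in_a, [f"A{p:07d}" for p in uid], ""),
            "record_id_b": np.where(in_b, [f"B{p:07d}" for p in uid], ""),
            "record_id_s": np.where(dead_s, [f"S{p:07d}" for p in uid], ""),
            "true_category": category,
            "true_death_date": true_death,
            "death_date_a": date_a,
            "death_date_b": date_b,
            "death_date_s": date_s,
            "shift_source": shift_source,
            "shift_months": shift_months,
            "lost_from": lost_from,
            "postdeath": postdeath,
        }
    )
    return CohortData(registry_a, registry_b, ssadmf, encounters, truth, crosswalk, config)


_ALPHABET = np.array(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ"))


def inject_identity_noise(
    records: pd.DataFrame,
    name_typo_rate: float,
    ssn_missing_rate: float = 0.0,
    mrn_missing_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Perturb identity fields: one-character name typos, blanked SSN/MRN.

    With probability ``name_typo_rate`` a record's first or last name has
    exactly one character substituted (edit distance 1); SSN and MRN are
    independently blanked at their stated rates.  Truth keys (record ids)
    are untouched.  Returns a copy.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    out = records.copy()
    n = len(out)
    if n == 0:
        return out
    hit = np.flatnonzero(rng.random(n) < name_typo_rate)
    if len(hit):
        which = rng.random(len(hit)) < 0.5
        firsts = out["first_name"].to_numpy(object)
        lasts = out["last_name"].to_numpy(object)
        for i, use_first in zip(hit, which):
            name = str(firsts[i] if use_first else lasts[i])
            if not name:
                continue
            pos = int(rng.integers(0, len(name)))
            old = name[pos].upper()
            repl = old
            while repl == old:
                repl = str(rng.choice(_ALPHABET))
            if name[pos].islower():
                repl = repl.lower()
            mutated = name[:pos] + repl + name[pos + 1 :]
            if use_first:
                firsts[i] = mutated
            else:
                lasts[i] = mutated
        out["first_name"] = firsts
        out["last_name"] = lasts
    if ssn_missing_rate and "ssn" in out.columns:
        out.loc[rng.random(n) < ssn_missing_rate, "ssn"] = np.nan
    if mrn_missing_rate and "mrn" in out.columns:
        out.loc[rng.random(n) < mrn_missing_rate, "mrn"] = np.nan
    return out
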