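"""Identity normalization, hash tokens, match rules, and cluster resolution.

Links person records across two health systems and a death-master extract
without comparing raw identifiers directly: records are reduced to keyed
digests of normalized identity fields ("hash tokens"), and deterministic
match rules over those tokens produce pairwise links that are resolved into
person clusters by connected components.

Cross-system (A vs B) rules, any of which suffices:

* ``XWALK``   — the pair appears in a supplied identifier crosswalk;
* ``NAMEDOB`` — normalized first name, last name, gender and birth date all
  agree exactly;
* ``MRN``     — medical record numbers agree.

Cluster vs death-master rules over the five tokens:

* ``T12`` — token 1 (last name, first initial, gender, birth date) AND
  token 2 (Soundex last, Soundex first, gender, birth date) both agree on
  the same member record;
* ``T3``  — last name, first name, gender, birth date;
* ``T4``  — SSN, gender, birth date;
* ``T5``  — SSN, first name.

Tokens 3-5 are each individually sufficient; the token-1/token-2 pair is
required jointly, trading tolerance to name variation against a higher risk
of false linkage between similarly named individuals.
"""

from __future__ import annotations

import hashlib
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

SYSTEM_A = "SYSTEM_A"
SYSTEM_B = "SYSTEM_B"
SSADMF = "SSADMF"
HEALTH_SYSTEMS = (SYSTEM_A, SYSTEM_B)
SOURCES = (SYSTEM_A, SYSTEM_B, SSADMF)

TOKEN_KINDS = ("T1", "T2", "T3", "T4", "T5")

LINK_COLUMNS = ["source_l", "record_id_l", "source_r", "record_id_r", "rule"]

_SOUNDEX_CODES = {
    "B": "1", "F": "1", "P": "1", "V": "1",
    "C": "2", "G": "2", "J": "2", "K": "2", "Q": "2", "S": "2", "X": "2",
    "Z": "2",
    "D": "3", "T": "3",
    "L": "4",
    "M": "5", "N": "5",
    "R": "6",
}


class LinkageError(ValueError):
    """Raised for malformed linkage inputs (bad crosswalk, duplicate ids)."""


def normalize_name(raw: str) -> str:
    """Uppercase, fold diacritics to ASCII, and strip non-alphabetic characters.

    ``"O'Brien "`` becomes ``"OBRIEN"``; ``"josé"`` becomes ``"JOSE"``; the
    empty string stays empty.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return ""
    folded = unicodedata.normalize("NFKD", str(raw)).encode("ascii", "ignore")
    return "".join(ch for ch in folded.decode("ascii").upper() if "A" <= ch <= "Z")


def _normalize_series(s: pd.Series) -> pd.Series:
    # normalize via the unique values only; registries repeat names heavily
    uniques = s.dropna().unique()
    mapping = {u: normalize_name(u) for u in uniques}
    return s.map(mapping).fillna("")


def soundex(name: str) -> str:
    """American Soundex code (initial letter + three digits) of a name.

    Vowels and Y separate consonants; H and W do not, so equal-coded
    consonants straddling an H or W collapse to one digit, as do adjacent
    equal codes (including a consonant repeating the initial letter's code).
    """
    norm = normalize_name(name)
    if not norm:
        raise ValueError("cannot Soundex-encode an empty name")
    prev = _SOUNDEX_CODES.get(norm[0])
    digits: list[str] = []
    for ch in norm[1:]:
        if ch in "HW":
            continue
        code = _SOUNDEX_CODES.get(ch)
        if code is None:  # vowel or Y: resets the run
            prev = None
            continue
        if code != prev:
            digits.append(code)
            if len(digits) == 3:
                break
        prev = code
    return norm[0] + "".join(digits).ljust(3, "0")


def _soundex_series(s: pd.Series) -> pd.Series:
    uniques = s.dropna().unique()
    mapping = {u: (soundex(u) if normalize_name(u) else "") for u in uniques}
    return s.map(mapping).fillna("")


@dataclass(frozen=True)
class PersonRecord:
    """One row of a source registry."""

    record_id: str
    source: str
    first_name: str
    last_name: str
    gender: str  # F, M or U
    birth_date: Optional[pd.Timestamp]
    ssn: Optional[str] = None
    mrn: Optional[str] = None
    death_date: Optional[pd.Timestamp] = None


@dataclass(frozen=True)
class LinkToken:
    kind: str
    digest: str


def _digest(material: str, salt: str) -> str:
    return hashlib.blake2b(
        material.encode("utf-8"), key=salt.encode("utf-8")[:64], digest_size=32
    ).hexdigest()


def _gender_norm(g) -> str:
    g = str(g).strip().upper()[:1] if g is not None and not pd.isna(g) else "U"
    return g if g in ("F", "M") else "U"


def build_tokens(record: PersonRecord, salt: str) -> list[LinkToken]:
    """Emit the five linkage tokens a record supports.

    Tokens 1-3 require names and a birth date; tokens 4-5 additionally
    require an SSN (token 4 also a birth date).  Unknown gender is encoded
    as ``U`` rather than suppressing the token.  Missing fields silently
    suppress only the affected tokens.
    """
    first = normalize_name(record.first_name)
    last = normalize_name(record.last_name)
    gender = _gender_norm(record.gender)
    bdate = (
        record.birth_date.strftime("%Y-%m-%d")
        if record.birth_date is not None and not pd.isna(record.birth_date)
        else ""
    )
    ssn = "" if record.ssn is None or pd.isna(record.ssn) else str(record.ssn).strip()
    out: list[LinkToken] = []
    if first and last and bdate:
        initial = first.split()[0][0] if first.split() else first[0]
        out.append(LinkToken("T1", _digest(f"T1|{last}|{initial}|{gender}|{bdate}", salt)))
        out.append(
            LinkToken(
                "T2",
                _digest(f"T2|{soundex(last)}|{soundex(first)}|{gender}|{bdate}", salt),
            )
        )
        out.append(LinkToken("T3", _digest(f"T3|{last}|{first}|{gender}|{bdate}", salt)))
    if ssn:
        if bdate:
            out.append(LinkToken("T4", _digest(f"T4|{ssn}|{gender}|{bdate}", salt)))
        if first:
            out.append(LinkToken("T5", _digest(f"T5|{ssn}|{first}", salt)))
    return out


def token_frame(registry: pd.DataFrame, salt: str) -> pd.DataFrame:
    """Vectorized `build_tokens` over a registry.

    Returns a frame indexed like ``registry`` with columns T1..T5 holding hex
    digests, NaN where the token is suppressed by missing fields.
    """
    if len(registry) == 0:
        return pd.DataFrame(columns=["record_id", *TOKEN_KINDS])
    first = _normalize_series(registry["first_name"])
    last = _normalize_series(registry["last_name"])
    gender = registry["gender"].map(_gender_norm)
    bdate = pd.to_datetime(registry["birth_date"]).dt.strftime("%Y-%m-%d").fillna("")
    ssn = registry.get("ssn", pd.Series("", index=registry.index))
    ssn = ssn.fillna("").astype(str).str.strip()

    has_name = (first != "") & (last != "") & (bdate != "")
    has_ssn = ssn != ""
    initial = first.str[0].fillna("")
    sdx_first = _soundex_series(first.where(first != "", other=np.nan))
    sdx_last = _soundex_series(last.where(last != "", other=np.nan))

    def hash_where(mask: pd.Series, material: pd.Series, kind: str) -> pd.Series:
        vals = material[mask]
        hashed = [_digest(m, salt) for m in vals.tolist()]
        out = pd.Series(np.nan, index=registry.index, dtype=object)
        out[mask] = hashed
        return out

    t1 = hash_where(has_name, "T1|" + last + "|" + initial + "|" + gender + "|" + bdate, "T1")
    t2 = hash_where(
        has_name, "T2|" + sdx_last + "|" + sdx_first + "|" + gender + "|" + bdate, "T2"
    )
    t3 = hash_where(has_name, "T3|" + last + "|" + first + "|" + gender + "|" + bdate, "T3")
    t4 = hash_where(has_ssn & (bdate != ""), "T4|" + ssn + "|" + gender + "|" + bdate, "T4")
    t5 = hash_where(has_ssn & (first != ""), "T5|" + ssn + "|" + first, "T5")
    return pd.DataFrame(
        {"record_id": registry["record_id"].to_numpy(), "T1": t1, "T2": t2,
         "T3": t3, "T4": t4, "T5": t5},
        index=registry.index,
    )


def _check_unique_ids(registry: pd.DataFrame, source: str) -> None:
    dup = registry["record_id"].duplicated()
    if dup.any():
        ids = registry.loc[dup, "record_id"].head(5).tolist()
        raise LinkageError(f"duplicate record_id within {source}: {ids}")


def validate_crosswalk(
    crosswalk: pd.DataFrame, registry_a: pd.DataFrame, registry_b: pd.DataFrame
) -> pd.DataFrame:
    """Check a two-column A<->B crosswalk; malformed rows are rejected by index."""
    required = {"record_id_a", "record_id_b"}
    if not required.issubset(crosswalk.columns):
        raise LinkageError(f"crosswalk must have columns {sorted(required)}")
    ids_a = set(registry_a["record_id"])
    ids_b = set(registry_b["record_id"])
    bad = []
    for idx, row in enumerate(crosswalk.itertuples(index=False)):
        ra, rb = row.record_id_a, row.record_id_b
        if pd.isna(ra) or pd.isna(rb) or str(ra) == "" or str(rb) == "":
            bad.append(idx)
        elif ra not in ids_a or rb not in ids_b:
            bad.append(idx)
    if bad:
        raise LinkageError(f"malformed crosswalk rows at indices {bad[:20]}")
    return crosswalk


def link_cross_system(
    registry_a: pd.DataFrame,
    registry_b: pd.DataFrame,
    crosswalk: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Pairwise A-B links via crosswalk, exact name+gender+birth date, or MRN.

    Returns a link frame with columns ``source_l, record_id_l, source_r,
    record_id_r, rule``; the same pair may appear once per rule that fired.
    """
    _check_unique_ids(registry_a, SYSTEM_A)
    _check_unique_ids(registry_b, SYSTEM_B)
    links = []

    if crosswalk is not None and len(crosswalk):
        validate_crosswalk(crosswalk, registry_a, registry_b)
        links.append(
            pd.DataFrame(
                {
                    "record_id_l": crosswalk["record_id_a"].to_numpy(),
                    "record_id_r": crosswalk["record_id_b"].to_numpy(),
                    "rule": "XWALK",
                }
            )
        )

    def namedob_key(reg: pd.DataFrame) -> pd.Series:
        return (
            _normalize_series(reg["first_name"])
            + "|"
            + _normalize_series(reg["last_name"])
            + "|"
            + reg["gender"].map(_gender_norm)
            + "|"
            + pd.to_datetime(reg["birth_date"]).dt.strftime("%Y-%m-%d").fillna("")
        )

    ka = pd.DataFrame({"key": namedob_key(registry_a), "record_id_l": registry_a["record_id"]})
    kb = pd.DataFrame({"key": namedob_key(registry_b), "record_id_r": registry_b["record_id"]})
    complete = ~ka["key"].str.contains(r"^\||\|\||\|$", regex=True)
    m = ka[complete].merge(kb[~kb["key"].str.contains(r"^\||\|\||\|$", regex=True)], on="key")
    if len(m):
        links.append(m[["record_id_l", "record_id_r"]].assign(rule="NAMEDOB"))

    if "mrn" in registry_a.columns and "mrn" in registry_b.columns:
        ma = registry_a[["record_id", "mrn"]].dropna(subset=["mrn"])
        ma = ma[ma["mrn"].astype(str) != ""]
        mb = registry_b[["record_id", "mrn"]].dropna(subset=["mrn"])
        mb = mb[mb["mrn"].astype(str) != ""]
        mm = ma.merge(mb, on="mrn", suffixes=("_l", "_r"))
        if len(mm):
            links.append(
                mm.rename(columns={"record_id_l": "record_id_l", "record_id_r": "record_id_r"})[
                    ["record_id_l", "record_id_r"]
                ].assign(rule="MRN")
            )

    if not links:
        return pd.DataFrame(columns=LINK_COLUMNS)
    out = pd.concat(links, ignore_index=True)
    out["source_l"] = SYSTEM_A
    out["source_r"] = SYSTEM_B
    return out[LINK_COLUMNS].drop_duplicates(ignore_index=True)


def link_ssadmf(
    records: pd.DataFrame, ssadmf: pd.DataFrame, salt: str
) -> pd.DataFrame:
    """Link health-system records (hence their clusters) to a death-master extract.

    A cluster links to an extract record when any member record matches under
    (T1 AND T2) jointly, or T3, T4 or T5 individually.  The conjunction is
    evaluated on a single member record, so a cluster whose members disagree
    on which token matches does not satisfy it.

    ``records`` must carry ``record_id``, ``source`` and the identity fields;
    returns a link frame in the standard columns with rules T12/T3/T4/T5.
    """
    if len(records) == 0 or len(ssadmf) == 0:
        return pd.DataFrame(columns=LINK_COLUMNS)
    tok = token_frame(records, salt)
    tok["source"] = records["source"].to_numpy()
    stok = token_frame(ssadmf, salt).rename(columns={"record_id": "record_id_s"})

    links = []
    pair = tok.dropna(subset=["T1", "T2"]).merge(
        stok.dropna(subset=["T1", "T2"]), on=["T1", "T2"]
    )
    if len(pair):
        links.append(pair[["source", "record_id", "record_id_s"]].assign(rule="T12"))
    for kind in ("T3", "T4", "T5"):
        m = tok.dropna(subset=[kind])[["source", "record_id", kind]].merge(
            stok.dropna(subset=[kind])[["record_id_s", kind]], on=kind
        )
        if len(m):
            links.append(m[["source", "record_id", "record_id_s"]].assign(rule=kind))
    if not links:
        return pd.DataFrame(columns=LINK_COLUMNS)
    out = pd.concat(links, ignore_index=True).rename(
        columns={"source": "source_l", "record_id": "record_id_l", "record_id_s": "record_id_r"}
    )
    out["source_r"] = SSADMF
    return out[LINK_COLUMNS].drop_duplicates(ignore_index=True)


@dataclass
class PersonCluster:
    """A resolved identity spanning sources, with the evidence that formed it."""

    cluster_id: str
    members: dict = field(default_factory=dict)  # source -> list of record_ids
    evidence: list = field(default_factory=list)  # (rule, (key_l, key_r))

    @property
    def matched(self) -> bool:
        return bool(self.members.get(SYSTEM_A)) and bool(self.members.get(SYSTEM_B))


def resolve_clusters(
    records: pd.DataFrame, links: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Connected components of the link graph over all records.

    ``records`` needs columns ``source`` and ``record_id`` covering every
    record from every source; ``links`` is a concatenation of link frames.
    Conflicting links (one record reachable from two otherwise separate
    groups) merge their components — union resolution.

    Returns ``(members, evidence)``: members has columns ``cluster_id,
    source, record_id, matched`` (matched = cluster spans both health
    systems) with deterministic cluster ids; evidence is the link frame
    annotated with the cluster each link landed in.
    """
    recs = records[["source", "record_id"]].copy()
    if recs.duplicated().any():
        raise LinkageError("duplicate (source, record_id) among input records")
    key = recs["source"] + ":" + recs["record_id"].astype(str)
    code = pd.Series(np.arange(len(key)), index=key.to_numpy())

    n = len(recs)
    if len(links):
        kl = (links["source_l"] + ":" + links["record_id_l"].astype(str)).map(code)
        kr = (links["source_r"] + ":" + links["record_id_r"].astype(str)).map(code)
        if kl.isna().any() or kr.isna().any():
            raise LinkageError("link references a record not present in records")
        g = coo_matrix(
            (np.ones(len(links)), (kl.to_numpy(int), kr.to_numpy(int))), shape=(n, n)
        )
        _, labels = connected_components(g, directed=False)
    else:
        labels = np.arange(n)

    # deterministic ids: order components by their lexicographically smallest key
    comp_min = pd.Series(key.to_numpy()).groupby(labels).min().sort_values()
    width = max(6, len(str(len(comp_min))))
    remap = pd.Series(
        ["C" + str(i).zfill(width) for i in range(len(comp_min))], index=comp_min.index
    )
    cluster_id = pd.Series(labels).map(remap).to_numpy()

    members = pd.DataFrame(
        {"cluster_id": cluster_id, "source": recs["source"].to_numpy(),
         "record_id": recs["record_id"].to_numpy()}
    )
    spans = members.assign(
        is_a=members["source"] == SYSTEM_A, is_b=members["source"] == SYSTEM_B
    ).groupby("cluster_id")[["is_a", "is_b"]].any()
    matched_ids = spans.index[spans["is_a"] & spans["is_b"]]
    members["matched"] = members["cluster_id"].isin(matched_ids)
    members = members.sort_values(["cluster_id", "source", "record_id"], ignore_index=True)

    evidence = links.copy()
    if len(links):
        evidence["cluster_id"] = (
            (links["source_l"] + ":" + links["record_id_l"].astype(str))
            .map(code)
            .map(pd.Series(cluster_id))
            .to_numpy()
        )
    else:
        evidence["cluster_id"] = pd.Series(dtype=object)
    return members, evidence


def iter_clusters(members: pd.DataFrame, evidence: pd.DataFrame) -> Iterable[PersonCluster]:
    """Materialize `PersonCluster` objects (for small cohorts / inspection)."""
    ev_by_cluster: dict = {}
    for row in evidence.itertuples(index=False):
        ev_by_cluster.setdefault(row.cluster_id, []).append(
            (row.rule, (f"{row.source_l}:{row.record_id_l}", f"{row.source_r}:{row.record_id_r}"))
        )
    for cid, grp in members.groupby("cluster_id", sort=True):
        mem = {s: sorted(g["record_id"]) for s, g in grp.groupby("source")}
        yield PersonCluster(cid, mem, ev_by_cluster.get(cid, []))


def pairwise_linkage_metrics(assignment: pd.DataFrame) -> dict:
    """Pairwise precision/recall of a clustering against ground-truth identities.

    ``assignment`` has one row per record with columns ``cluster_id`` and
    ``person_uid``.  Pairs of records placed in one cluster are compared with
    pairs belonging to one true person.
    """

    def n_pairs(sizes: pd.Series) -> float:
        return float((sizes * (sizes - 1) // 2).sum())

    tp = n_pairs(assignment.groupby(["cluster_id", "person_uid"]).size())
    pred = n_pairs(assignment.groupby("cluster_id").size())
    true = n_pairs(assignment.groupby("person_uid").size())
    precision = tp / pred if pred else 1.0
    recall = tp / true if true else 1.0
    return {"precision": precision, "recall": recall, "tp_pairs": tp,
            "predicted_pairs": pred, "true_pairs": true}
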