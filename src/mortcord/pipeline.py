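"""End-to-end pipeline: generate or ingest -> link -> classify -> kappa -> QC.

`run_pipeline` drives the whole analysis from a single `RunConfig` and
returns a `PipelineResult`; with an output directory set it also writes the
report bundle — delimited tables for clusters, the concordance table and the
three flag tables, plus one JSON manifest holding the seed, a config hash,
package version, derived percentages, Venn region counts and the agreement
result.  Outputs are deterministic: the same config and seed produce
byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .agreement import AgreementResult, DegenerateAgreementError, agreement_report
from .concordance import (
    ConcordanceSummary,
    death_status_frame,
    export_venn,
    summarize,
)
from .io import IngestError, read_crosswalk, read_encounters, read_registry, write_json, write_table
from .linkage import (
    SSADMF,
    SYSTEM_A,
    SYSTEM_B,
    link_cross_system,
    link_ssadmf,
    resolve_clusters,
)
from .quality import (
    detect_date_discrepancies,
    detect_lost_contact,
    detect_postdeath_encounters,
)
from .synthetic import CohortData, SyntheticConfig, generate_cohort


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Inputs, thresholds and reporting options for one pipeline run.

    Either ``synthetic`` is set (the cohort is generated) or the four input
    paths are.  Thresholds default to the study's rules: a 12-month
    lost-contact window, post-death encounters beyond 365 days, and date
    discrepancies of at least one whole month.
    """

    synthetic: Optional[SyntheticConfig] = None
    registry_a_path: Optional[str] = None
    registry_b_path: Optional[str] = None
    ssadmf_path: Optional[str] = None
    encounters_path: Optional[str] = None
    crosswalk_path: Optional[str] = None
    salt: str = "mortcord"
    seed: int = 0
    window_months: int = 12
    postdeath_days: int = 365
    date_threshold_months: int = 1
    ci_method: str = "asymptotic"
    observed: str = "fleiss"
    n_boot: int = 1000
    use_crosswalk: bool = True
    outdir: Optional[str] = None

    def validate(self) -> None:
        if min(self.window_months, self.postdeath_days, self.date_threshold_months) <= 0:
            raise ValueError("thresholds must be positive")
        if self.synthetic is None:
            needed = [self.registry_a_path, self.registry_b_path, self.ssadmf_path]
            if any(p is None for p in needed):
                raise ValueError(
                    "either a synthetic config or registry/ssadmf paths are required"
                )
            for p in [p for p in needed + [self.encounters_path, self.crosswalk_path] if p]:
                if not Path(p).exists():
                    raise IngestError(f"input file not found: {p}")


@dataclass
class PipelineResult:
    members: pd.DataFrame
    evidence: pd.DataFrame
    status: pd.DataFrame
    summary: ConcordanceSummary
    agreement: Optional[AgreementResult]
    venn: dict
    lost_contact: pd.DataFrame
    date_discrepancies: pd.DataFrame
    date_discrepancy_summary: dict
    postdeath: pd.DataFrame
    postdeath_rates: dict
    unmatched: dict
    manifest: dict = field(default_factory=dict)
    cohort: Optional[CohortData] = None


def link_all(
    registry_a: pd.DataFrame,
    registry_b: pd.DataFrame,
    ssadmf: pd.DataFrame,
    crosswalk: Optional[pd.DataFrame],
    salt: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Both linkage stages plus final cluster resolution.

    Health systems are linked pairwise first; the death-master extract is
    then linked against the resulting clusters (any member record matching
    under the token rules links the whole cluster, which union resolution
    makes equivalent to record-level linking).
    """
    ab = pd.concat(
        [registry_a.assign(source=SYSTEM_A), registry_b.assign(source=SYSTEM_B)],
        ignore_index=True,
    )
    ab_links = link_cross_system(registry_a, registry_b, crosswalk)
    s_links = link_ssadmf(ab, ssadmf, salt)
    records = pd.concat(
        [ab[["source", "record_id"]],
         ssadmf.assign(source=SSADMF)[["source", "record_id"]]],
        ignore_index=True,
    )
    links = pd.concat([ab_links, s_links], ignore_index=True)
    return resolve_clusters(records, links)


def _config_hash(cfg: RunConfig) -> str:
    d = {k: (v.to_dict() if isinstance(v, SyntheticConfig) else v)
         for k, v in cfg.__dict__.items() if k != "outdir"}
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis; write the report bundle if an outdir is set.

    Any stage failure raises `PipelineError` naming the stage; nothing is
    written unless every stage succeeded.
    """
    config.validate()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
            raise PipelineError(name, exc) from exc

    cohort = None
    if config.synthetic is not None:
        cohort = stage("generate", generate_cohort, config.synthetic)
        registry_a, registry_b = cohort.registry_a, cohort.registry_b
        ssadmf, encounters = cohort.ssadmf, cohort.encounters
        crosswalk = cohort.crosswalk if config.use_crosswalk else None
    else:
        registry_a = stage("ingest", read_registry, config.registry_a_path)
        registry_b = stage("ingest", read_registry, config.registry_b_path)
        ssadmf = stage("ingest", read_registry, config.ssadmf_path)
        encounters = (
            stage("ingest", read_encounters, config.encounters_path)
            if config.encounters_path
            else pd.DataFrame(columns=["record_id", "source", "encounter_date"])
        )
        crosswalk = (
            stage("ingest", read_crosswalk, config.crosswalk_path)
            if (config.crosswalk_path and config.use_crosswalk)
            else None
        )
    for name, reg in (("registry_a", registry_a), ("registry_b", registry_b)):
        if len(reg) == 0:
            raise PipelineError("ingest", IngestError(f"{name} is empty"))

    members, evidence = stage(
        "link", link_all, registry_a, registry_b, ssadmf, crosswalk, config.salt
    )
    status = stage(
        "classify", death_status_frame, members, registry_a, registry_b, ssadmf
    )
    summary = stage("classify", summarize, status)
    venn = export_venn(summary)

    try:
        agreement = agreement_report(
            summary.counts,
            ci_method=config.ci_method,
            observed=config.observed,
            n_boot=config.n_boot,
            seed=config.seed,
        )
    except DegenerateAgreementError:
        agreement = None
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("kappa", exc) from exc

    dd_flags, dd_summary = stage(
        "qc", detect_date_discrepancies, status, config.date_threshold_months
    )
    lc_flags = stage(
        "qc", detect_lost_contact, encounters, members, config.window_months
    )
    pd_flags, pd_rates = stage(
        "qc", detect_postdeath_encounters, status, encounters, members,
        config.postdeath_days,
    )

    # patients outside the matched cohort, summarized separately
    per_source = members.groupby("source")["record_id"].count().to_dict()
    unmatched_members = members[~members["matched"]]
    unmatched = {
        "patients_total": {
            "A": int(per_source.get(SYSTEM_A, 0)),
            "B": int(per_source.get(SYSTEM_B, 0)),
        },
        "unmatched_records": {
            "A": int((unmatched_members["source"] == SYSTEM_A).sum()),
            "B": int((unmatched_members["source"] == SYSTEM_B).sum()),
        },
        "deaths_total": {
            "A": int(registry_a["death_date"].notna().sum()),
            "B": int(registry_b["death_date"].notna().sum()),
            "S": int(ssadmf["death_date"].notna().sum()),
        },
    }

    manifest = {
        "package": "mortcord",
        "version": __version__,
        "seed": config.seed,
        "salt": config.salt,
        "config_hash": _config_hash(config),
        "parameters": {
            "window_months": config.window_months,
            "postdeath_days": config.postdeath_days,
            "date_threshold_months": config.date_threshold_months,
            "ci_method": config.ci_method,
            "observed": config.observed,
        },
        "synthetic_config": (
            config.synthetic.to_dict() if config.synthetic is not None else None
        ),
        "n_matched": summary.n_matched,
        "concordance": summary.to_dict(),
        "venn_regions": venn,
        "agreement": agreement.__dict__ if agreement is not None else None,
        "date_discrepancy_summary": dd_summary,
        "postdeath_rates": pd_rates,
        "lost_contact_flags": int(len(lc_flags)),
        "unmatched": unmatched,
    }

    result = PipelineResult(
        members, evidence, status, summary, agreement, venn,
        lc_flags, dd_flags, dd_summary, pd_flags, pd_rates, unmatched,
        manifest, cohort,
    )
    if config.outdir:
        _write_bundle(result, Path(config.outdir))
    return result


def _write_bundle(result: PipelineResult, outdir: Path) -> None:
    written: list[Path] = []
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        written.append(write_table(result.members, outdir / "clusters.csv"))
        written.append(write_table(result.evidence, outdir / "link_evidence.csv"))
        written.append(write_table(result.summary.to_frame(), outdir / "concordance_table.csv"))
        written.append(write_table(result.status, outdir / "death_status.csv"))
        written.append(write_table(result.lost_contact, outdir / "lost_contact_flags.csv"))
        written.append(write_table(result.date_discrepancies, outdir / "date_discrepancy_flags.csv"))
        written.append(write_table(result.postdeath, outdir / "postdeath_flags.csv"))
        written.append(write_json(result.manifest, outdir / "manifest.json"))
    except Exception as exc:  # noqa: BLE001 - partial bundles are removed
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError("report", exc) from exc
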