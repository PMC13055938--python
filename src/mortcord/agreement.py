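"""Multi-rater agreement on dead / not-dead status across three sources.

The three sources (health system A, health system B, death-master extract)
act as three raters assigning each matched patient one of two categories.
From the 8-category concordance table the module computes:

* per-subject agreement P_i = [n(n-1) + (3-n)(2-n)] / 6 for n raters saying
  "dead" — the fraction of concordant rater pairs;
* observed agreement, under two definitions: the standard Fleiss mean of
  P_i, and the stricter all-concur proportion (subjects on whom all three
  sources agree).  The Fleiss mean feeds kappa by default; the all-concur
  variant is reported alongside and selectable because study reports
  sometimes define "observed agreement" as unanimity;
* expected chance agreement p_e = p_dead^2 + p_notdead^2 from the pooled
  marginals, and kappa = (P_obs - p_e) / (1 - p_e);
* a 95% CI, asymptotic (Fleiss-Nee-Landis large-sample variance) or a
  seeded percentile bootstrap over subjects.

With extreme class imbalance (nearly everyone "not dead" everywhere) p_e
approaches 1 and kappa becomes numerically unstable and hard to interpret:
tiny absolute disagreement moves it far from zero.  The concordance table
itself is then the more informative summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

# deaths recorded per category, for (A, B, S) raters
_N_DEAD = {"ABS": 3, "AB": 2, "AS": 2, "BS": 2,
           "A_only": 1, "B_only": 1, "S_only": 1, "none": 0}

N_RATERS = 3


class DegenerateAgreementError(ValueError):
    """Kappa is undefined: every rater used a single category for everyone."""


def per_subject_agreement(n_dead: int) -> float:
    """Fraction of concordant rater pairs for a subject with ``n_dead`` dead votes."""
    if not 0 <= n_dead <= N_RATERS:
        raise ValueError(f"n_dead must be in 0..{N_RATERS}, got {n_dead}")
    return (n_dead * (n_dead - 1) + (N_RATERS - n_dead) * (2 - n_dead)) / 6.0


def _by_votes(counts: Mapping[str, int]) -> np.ndarray:
    """Collapse the 8-category table to subject counts by number of dead votes."""
    out = np.zeros(N_RATERS + 1, dtype=np.int64)
    for cat, k in counts.items():
        if cat not in _N_DEAD:
            raise ValueError(f"unknown category {cat!r}")
        if k < 0:
            raise ValueError(f"negative count for {cat!r}")
        out[_N_DEAD[cat]] += int(k)
    return out


@dataclass
class AgreementResult:
    n_subjects: int
    n_raters: int
    p_observed: float
    p_expected: float
    kappa: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    ci_method: Optional[str]
    p_all_concur: float
    observed_definition: str  # which observed-agreement definition fed kappa

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.__dict__, **kwargs)


def _core(votes: np.ndarray) -> tuple[float, float, float, float]:
    n = int(votes.sum())
    if n == 0:
        raise ValueError("empty table")
    p_i = np.array([per_subject_agreement(v) for v in range(N_RATERS + 1)])
    p_obs = float(votes @ p_i) / n
    p_dead = float(votes @ np.arange(N_RATERS + 1)) / (N_RATERS * n)
    p_exp = p_dead**2 + (1.0 - p_dead) ** 2
    p_all = float(votes[0] + votes[N_RATERS]) / n
    return p_obs, p_exp, p_all, p_dead


def fleiss_kappa(
    counts: Mapping[str, int], observed: str = "fleiss"
) -> AgreementResult:
    """Fleiss kappa (3 raters, 2 categories) from the 8-category count table.

    ``observed`` selects which observed-agreement definition enters kappa:
    ``"fleiss"`` (mean pairwise per-subject agreement, the default) or
    ``"all-concur"`` (proportion of unanimously classified subjects).
    """
    if observed not in ("fleiss", "all-concur"):
        raise ValueError("observed must be 'fleiss' or 'all-concur'")
    votes = _by_votes(counts)
    n = int(votes.sum())
    p_obs, p_exp, p_all, _ = _core(votes)
    if p_exp >= 1.0:
        raise DegenerateAgreementError(
            "expected agreement is 1 (a single category everywhere); kappa undefined"
        )
    used = p_obs if observed == "fleiss" else p_all
    kappa = (used - p_exp) / (1.0 - p_exp)
    return AgreementResult(
        n_subjects=n,
        n_raters=N_RATERS,
        p_observed=p_obs,
        p_expected=p_exp,
        kappa=kappa,
        ci_low=None,
        ci_high=None,
        ci_method=None,
        p_all_concur=p_all,
        observed_definition=observed,
    )


def _asymptotic_ci(votes: np.ndarray, kappa: float, level: float) -> tuple[float, float]:
    # Fleiss-Nee-Landis large-sample variance of overall kappa
    from scipy.stats import norm

    n = int(votes.sum())
    m = N_RATERS
    p_dead = float(votes @ np.arange(m + 1)) / (m * n)
    p = np.array([p_dead, 1.0 - p_dead])
    s2 = float((p**2).sum())
    s3 = float((p**3).sum())
    var = (2.0 / (n * m * (m - 1))) * (s2 - (2 * m - 3) * s2**2 + 2 * (m - 2) * s3)
    var /= (1.0 - s2) ** 2
    z = norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return kappa - half, kappa + half


def _bootstrap_ci(
    counts: Mapping[str, int], observed: str, n_boot: int, seed: Optional[int],
    level: float,
) -> tuple[float, float]:
    votes = _by_votes(counts)
    n = int(votes.sum())
    probs = votes / n
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, probs, size=n_boot).astype(float)
    p_i = np.array([per_subject_agreement(v) for v in range(N_RATERS + 1)])
    p_obs = draws @ p_i / n
    p_dead = draws @ np.arange(N_RATERS + 1) / (N_RATERS * n)
    p_exp = p_dead**2 + (1.0 - p_dead) ** 2
    used = (draws[:, 0] + draws[:, N_RATERS]) / n if observed == "all-concur" else p_obs
    with np.errstate(divide="ignore", invalid="ignore"):
        kappas = (used - p_exp) / (1.0 - p_exp)
    kappas = kappas[np.isfinite(kappas)]  # degenerate resamples dropped
    if len(kappas) == 0:
        raise DegenerateAgreementError("all bootstrap resamples were degenerate")
    alpha = (1.0 - level) / 2
    lo, hi = np.quantile(kappas, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def kappa_ci(
    counts: Mapping[str, int],
    method: str = "asymptotic",
    n_boot: int = 1000,
    seed: Optional[int] = None,
    observed: str = "fleiss",
    level: float = 0.95,
) -> tuple[float, float]:
    """Confidence interval for kappa; bootstrap is deterministic given its seed."""
    res = fleiss_kappa(counts, observed=observed)
    if method == "asymptotic":
        return _asymptotic_ci(_by_votes(counts), res.kappa, level)
    if method == "bootstrap":
        if n_boot < 200:
            raise ValueError("n_boot must be at least 200")
        return _bootstrap_ci(counts, observed, n_boot, seed, level)
    raise ValueError("method must be 'asymptotic' or 'bootstrap'")


def agreement_report(
    counts: Mapping[str, int],
    ci_method: str = "asymptotic",
    observed: str = "fleiss",
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> AgreementResult:
    """Kappa plus its CI in one result object."""
    res = fleiss_kappa(counts, observed=observed)
    lo, hi = kappa_ci(
        counts, method=ci_method, n_boot=n_boot, seed=seed, observed=observed
    )
    res.ci_low, res.ci_high, res.ci_method = lo, hi, ci_method
    return res
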