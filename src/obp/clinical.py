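"""Clinical concordance and prognosis statistics for small organoid cohorts.

CA19-9 is the serum tumor-burden marker for pancreatic ductal adenocarcinoma:
a decrease across neoadjuvant treatment encodes a clinical responder. Records
are excluded from concordance analysis when the baseline is in the normal
range (default cutoff 35 U/mL), when no neoadjuvant therapy was given, or when
CA19-9 values are missing.

Concordance between ex vivo assay calls and clinical response uses per-regimen
match rates and the exact McNemar test on discordant pairs. Prognosis by the
stroma/tumor marker ratio (alpha-SMA / CK-19, dichotomized at 1.0) uses a
fixed-landmark Fisher exact test on alive/dead status plus the Kaplan-Meier
log-rank test on the full survival curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CA199_NORMAL_CUTOFF",
    "CLINICAL_TO_ODSA_REGIMEN",
    "encode_clinical_response",
    "ConcordanceResult",
    "match_rates",
    "mcnemar_exact",
    "fisher_exact_2x2",
    "PrognosisResult",
    "ratio_prognosis",
    "logrank",
]

#: Default upper bound of the normal CA19-9 range, U/mL.
CA199_NORMAL_CUTOFF = 35.0

#: Clinical regimen → the ex vivo regimen it is matched against.
CLINICAL_TO_ODSA_REGIMEN = {"GA": "GEM/PAC", "FFX": "FFX"}


def _pct(numerator: int, denominator: int) -> float:
    """Match rates to one decimal, truncated (clinical reporting convention:
    16/21 prints as 76.1%)."""
    if not denominator:
        return float("nan")
    return np.floor(1000.0 * numerator / denominator) / 10.0


def encode_clinical_response(
    record: pd.Series | dict,
    cutoff: float = CA199_NORMAL_CUTOFF,
    min_relative_drop: float = 0.0,
) -> tuple[str, str | None]:
    """Encode one cohort record as responder / nonresponder / excluded.

    Excluded when the baseline is normal-range (< ``cutoff``), no neoadjuvant
    therapy was received, or CA19-9 values are missing; otherwise a responder
    iff the post-treatment value decreased (strictly, or by at least
    ``min_relative_drop`` as a fraction of baseline when configured).

    Returns ``(status, exclusion_reason)`` with the reason ``None`` for
    non-excluded records.
    """
    rec = record if isinstance(record, dict) else record.to_dict()
    if not rec.get("received_neoadjuvant", True):
        return "excluded", "no_neoadjuvant_therapy"
    pre = rec.get("ca199_pre")
    post = rec.get("ca199_post")
    if pre is None or post is None or pd.isna(pre) or pd.isna(post):
        return "excluded", "missing_ca199"
    if pre < 0 or post < 0:
        raise ValueError("CA19-9 values must be nonnegative")
    if pre < cutoff:
        return "excluded", "normal_baseline"
    if post < pre * (1.0 - min_relative_drop):
        return "responder", None
    return "nonresponder", None


@dataclass
class ConcordanceResult:
    """Per-regimen match rates, overall effectiveness, and exact McNemar p."""

    per_regimen: dict[str, tuple[int, int]]  # arm -> (matched, clinical responders)
    overall_effective: tuple[int, int]  # (models effective for >=1 regimen, models)
    discordant_b: int  # clinical responder, assay not effective
    discordant_c: int  # clinical nonresponder, assay effective
    mcnemar_p: float
    exclusions: dict[str, list[str]] = field(default_factory=dict)

    def match_pct(self, arm: str) -> float:
        matched, total = self.per_regimen[arm]
        return _pct(matched, total)

    @property
    def overall_effective_pct(self) -> float:
        return _pct(*self.overall_effective)

    def to_dict(self) -> dict:
        return {
            "per_regimen": {
                arm: {"matched": m, "responders": t, "pct": self.match_pct(arm)}
                for arm, (m, t) in self.per_regimen.items()
            },
            "overall_effective": {
                "n": self.overall_effective[0],
                "total": self.overall_effective[1],
                "pct": self.overall_effective_pct,
            },
            "mcnemar": {
                "b": self.discordant_b,
                "c": self.discordant_c,
                "p": self.mcnemar_p,
            },
            "exclusions": self.exclusions,
        }


def match_rates(
    cohort: pd.DataFrame,
    effective_calls: dict[tuple[str, str], bool],
    cutoff: float = CA199_NORMAL_CUTOFF,
) -> ConcordanceResult:
    """Compare ex vivo effectiveness calls with clinical CA19-9 response.

    Parameters
    ----------
    cohort
        Cohort summary frame: ``pdo_id, regimen, ca199_pre, ca199_post,
        received_neoadjuvant, ...``. ``regimen`` may join two arms as
        ``"GA+FFX"``.
    effective_calls
        ``(pdo_id, odsa_regimen) -> effective`` at the working threshold
        (any-dose rule, τ = 30% by default upstream).

    Returns per clinical arm the fraction of clinical responders whose matched
    ex vivo regimen call is effective, the overall fraction of models
    effective for at least one regimen, and the exact McNemar test over the
    eligible (record, arm) pairs.

    Raises
    ------
    KeyError
        When an eligible record lacks an effectiveness call for its matched
        regimen.
    """
    per_regimen: dict[str, list[int]] = {arm: [0, 0] for arm in CLINICAL_TO_ODSA_REGIMEN}
    exclusions: dict[str, list[str]] = {}
    b = c = 0
    for _, rec in cohort.iterrows():
        status, reason = encode_clinical_response(rec, cutoff=cutoff)
        if status == "excluded":
            exclusions.setdefault(reason, []).append(str(rec["pdo_id"]))
            continue
        arms = [a for a in str(rec["regimen"]).split("+") if a in CLINICAL_TO_ODSA_REGIMEN]
        for arm in arms:
            odsa_reg = CLINICAL_TO_ODSA_REGIMEN[arm]
            key = (str(rec["pdo_id"]), odsa_reg)
            if key not in effective_calls:
                raise KeyError(f"eligible record {key} has no effectiveness call")
            effective = bool(effective_calls[key])
            if status == "responder":
                per_regimen[arm][1] += 1
                if effective:
                    per_regimen[arm][0] += 1
                else:
                    b += 1
            else:
                if effective:
                    c += 1

    models = sorted({m for m, _ in effective_calls})
    n_eff = sum(
        any(effective_calls.get((m, r), False) for r in CLINICAL_TO_ODSA_REGIMEN.values())
        for m in models
    )
    return ConcordanceResult(
        per_regimen={arm: tuple(v) for arm, v in per_regimen.items()},
        overall_effective=(n_eff, len(models)),
        discordant_b=b,
        discordant_c=c,
        mcnemar_p=mcnemar_exact(b, c),
        exclusions=exclusions,
    )


def mcnemar_exact(b: int, c: int, mid_p: bool = False) -> float:
    """Exact two-sided McNemar test on discordant-pair counts.

    With ``n = b + c`` discordant pairs and ``X ~ Binomial(n, 1/2)``, the
    two-sided p is the doubled smaller tail capped at 1:
    ``min(1, 2 * min(P(X <= b), P(X >= b)))``; 1 when there are no discordant
    pairs. ``mid_p`` subtracts half the point probability from each tail (the
    mid-p variant, not the default).
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    n = b + c
    if n == 0:
        return 1.0
    lower = stats.binom.cdf(b, n, 0.5)
    upper = stats.binom.sf(b - 1, n, 0.5)
    if mid_p:
        point = stats.binom.pmf(b, n, 0.5)
        lower -= 0.5 * point
        upper -= 0.5 * point
    return float(min(1.0, 2.0 * min(lower, upper)))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2×2 table of nonnegative integers.

    Two-sidedness by probability ordering: the sum over all tables with the
    observed margins whose hypergeometric probability does not exceed that of
    the observed table. An all-zero table gives p = 1 by convention.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with nonnegative integer entries")
    if t.sum() == 0:
        return 1.0
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(p)


@dataclass
class PrognosisResult:
    """Landmark 2×2 and survival comparison for ratio > 1.0 vs < 1.0 groups."""

    landmark_months: float
    table: np.ndarray  # rows: (ratio>1, ratio<1); cols: (alive, dead) at landmark
    fisher_p: float
    logrank_statistic: float
    logrank_p: float
    n_censored_before_landmark: int
    group_sizes: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "landmark_months": self.landmark_months,
            "alive_dead_table": self.table.tolist(),
            "fisher_p": self.fisher_p,
            "logrank_statistic": self.logrank_statistic,
            "logrank_p": self.logrank_p,
            "n_censored_before_landmark": self.n_censored_before_landmark,
            "group_sizes": self.group_sizes,
        }


def ratio_prognosis(cohort: pd.DataFrame, landmark_months: float = 32.0) -> PrognosisResult:
    """Prognosis by the alpha-SMA/CK-19 ratio dichotomized at 1.0.

    Every record needs ``sma_ck19_ratio``, ``survival_months`` and ``event``.
    A patient is alive at the landmark when followed (with or without a later
    event) to at least ``landmark_months``; patients censored before the
    landmark are excluded from the 2×2 and reported separately. Ratios exactly
    1.0 join the > 1.0 group with a warning. The log-rank test runs on the
    full survival curves.
    """
    required = {"sma_ck19_ratio", "survival_months", "event"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort lacks columns {sorted(missing)}")
    df = cohort.dropna(subset=["sma_ck19_ratio", "survival_months"])
    if (df["sma_ck19_ratio"] == 1.0).any():
        warnings.warn(
            "ratio exactly 1.0 assigned to the > 1.0 group", stacklevel=2
        )
    high = df["sma_ck19_ratio"] >= 1.0
    t = df["survival_months"].to_numpy(dtype=float)
    e = df["event"].to_numpy(dtype=bool)

    alive = t >= landmark_months
    dead = e & (t < landmark_months)
    censored_early = ~e & (t < landmark_months)
    table = np.array(
        [
            [int((alive & high).sum()), int((dead & high).sum())],
            [int((alive & ~high).sum()), int((dead & ~high).sum())],
        ]
    )
    fisher_p = fisher_exact_2x2(table)
    stat, p = logrank(t, e, np.where(high, "high", "low"))
    return PrognosisResult(
        landmark_months=landmark_months,
        table=table,
        fisher_p=fisher_p,
        logrank_statistic=stat,
        logrank_p=p,
        n_censored_before_landmark=int(censored_early.sum()),
        group_sizes={"high": int(high.sum()), "low": int((~high).sum())},
    )


def logrank(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test (chi-square with 1 df).

    Returns ``(statistic, p)``; with no events the statistic is 0 and p = 1 by
    convention. Requires exactly two group labels.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(labels)}")
    if not events.any():
        return 0.0, 1.0
    from lifelines.statistics import logrank_test

    a = groups == labels[0]
    res = logrank_test(times[a], times[~a], events[a], events[~a])
    return float(res.test_statistic), float(res.p_value)
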