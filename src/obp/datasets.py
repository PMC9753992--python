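"""Packaged cohort fixtures.

The three CSVs under ``obp/data`` are *synthetic reconstructions* of a
21-model neoadjuvant-treated PDO cohort: raw per-patient values are not
available, so the fixtures were built to realize the cohort's count-level
structure (21 models; 5 normal-baseline and 5 no-neoadjuvant exclusions;
GA-arm match 3/4, FFX-arm match 7/8; overall effectiveness 16/21 at the 30%
any-dose rule; landmark survival 5/5 vs 0/3 alive). The numeric CA19-9,
survival and per-dose reduction values are invented; only count-level
results are meaningful on these files.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .odsa import ReductionProfile, classify_response

__all__ = [
    "load_table1",
    "load_odsa_reductions",
    "load_prognosis_cohort",
    "reduction_profiles_from_frame",
    "effective_calls",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("obp.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_table1() -> pd.DataFrame:
    """The 21-model clinical cohort fixture (synthetic reconstruction)."""
    df = _read("table1_synthetic.csv")
    df["received_neoadjuvant"] = df["received_neoadjuvant"].astype(bool)
    return df


def load_odsa_reductions() -> pd.DataFrame:
    """Per model × regimen viability reductions at low/medium/high dose."""
    return _read("odsa_reductions_synthetic.csv")


def load_prognosis_cohort() -> pd.DataFrame:
    """The 8-model ratio-prognosis fixture (synthetic reconstruction)."""
    df = _read("prognosis8_synthetic.csv")
    df["event"] = df["event"].astype(bool)
    return df


def reduction_profiles_from_frame(df: pd.DataFrame) -> list[ReductionProfile]:
    """Wide reduction frame → list of :class:`ReductionProfile`."""
    return [
        ReductionProfile(
            model_id=str(r["model"]),
            regimen=str(r["regimen"]),
            reductions_pct=(
                float(r["reduction_low"]),
                float(r["reduction_medium"]),
                float(r["reduction_high"]),
            ),
            doses=(float(r["dose_low"]), float(r["dose_medium"]), float(r["dose_high"])),
        )
        for _, r in df.iterrows()
    ]


def effective_calls(
    profiles: list[ReductionProfile], threshold_pct: float = 30.0
) -> dict[tuple[str, str], bool]:
    """Any-dose effectiveness calls keyed by (model, regimen)."""
    return {
        (p.model_id, p.regimen): classify_response(p, threshold_pct).effective
        for p in profiles
    }
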