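"""Ex vivo organoid drug sensitivity assay (ODSA) analysis.

Covers the plate-side arm of the platform: organoid growth curves,
four-parameter-logistic (4PL) dose-response fitting for IC50, vehicle-
normalized viability reductions, per-dose binary response classification at a
viability-reduction threshold τ, the models × thresholds matrix over
τ ∈ {10, 20, 30, 40}%, and inflection-based threshold selection.

Classification rule: at threshold τ, each of the three treatment doses (low,
medium, high) is scored 1 when its viability reduction is at least τ percent.
A model is a *responder* when all three doses score 1, a *nonresponder* when
none do, and *intermediate* otherwise; the regimen is *effective* when any
dose scores 1 (the any-dose rule, default τ = 30%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .synthetic import four_param_logistic

__all__ = [
    "GrowthSummary",
    "estimate_growth",
    "DoseResponseModel",
    "DoseResponseResults",
    "FitFailure",
    "fit_ic50",
    "viability_reduction",
    "reduction_profiles",
    "ReductionProfile",
    "ResponseCall",
    "classify_response",
    "ThresholdMatrix",
    "threshold_matrix",
    "InflectionReport",
    "detect_inflection",
    "THRESHOLDS",
    "CATEGORIES",
]

THRESHOLDS = (10, 20, 30, 40)
CATEGORIES = ("responder", "intermediate", "nonresponder")


# ---------------------------------------------------------------------------
# growth curves


@dataclass
class GrowthSummary:
    """Log-linear growth estimate: per-day rate and doubling time (days)."""

    rate_per_day: float
    doubling_time_days: float
    r_squared: float


def estimate_growth(days: np.ndarray, signal: np.ndarray) -> GrowthSummary:
    """Least-squares slope of ln(signal) against day.

    Doubling time is ``ln 2 / slope`` (infinite for nonpositive slopes).
    Requires at least three time points and strictly positive signals.
    """
    days = np.asarray(days, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if len(days) < 3:
        raise ValueError("need at least 3 time points")
    if np.any(signal <= 0):
        raise ValueError("growth signals must be positive")
    y = np.log(signal)
    slope, intercept = np.polyfit(days, y, 1)
    pred = slope * days + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    doubling = float(np.log(2) / slope) if slope > 0 else float("inf")
    return GrowthSummary(rate_per_day=float(slope), doubling_time_days=doubling, r_squared=r2)


# ---------------------------------------------------------------------------
# dose-response fitting


class FitFailure(RuntimeError):
    """Raised when the 4PL fit cannot be performed or does not converge."""


@dataclass
class DoseResponseResults:
    """Results of a 4PL dose-response fit.

    Carries the parameter estimates (``ic50, hill, bottom, top``), their
    standard errors from the fit covariance, and residual diagnostics.
    """

    ic50: float
    hill: float
    bottom: float
    top: float
    bse: dict[str, float]
    rss: float
    n_obs: int
    doses: np.ndarray = field(repr=False)
    viabilities: np.ndarray = field(repr=False)

    @property
    def params(self) -> dict[str, float]:
        return {"ic50": self.ic50, "hill": self.hill, "bottom": self.bottom, "top": self.top}

    def predict(self, doses: np.ndarray) -> np.ndarray:
        return four_param_logistic(np.asarray(doses, float), self.ic50, self.hill, self.bottom, self.top)

    def summary(self) -> str:
        lines = [
            "4PL dose-response fit",
            "=" * 38,
            f"{'parameter':<10}{'estimate':>12}{'std err':>12}",
            "-" * 38,
        ]
        for name, val in self.params.items():
            se = self.bse.get(name, float("nan"))
            lines.append(f"{name:<10}{val:>12.4g}{se:>12.3g}")
        lines.append("-" * 38)
        lines.append(f"n = {self.n_obs}, RSS = {self.rss:.4g}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Dose-response scatter with the fitted curve (log-dose axis)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pos = self.doses[self.doses > 0]
        grid = np.geomspace(pos.min() / 5, pos.max() * 5, 200)
        ax.semilogx(self.doses[self.doses > 0], self.viabilities[self.doses > 0], "o")
        ax.semilogx(grid, self.predict(grid), "-")
        ax.axvline(self.ic50, ls="--", color="grey")
        ax.set_xlabel("dose")
        ax.set_ylabel("viability (fraction of vehicle)")
        return ax


class DoseResponseModel:
    """Four-parameter logistic dose-response model.

    ``viability = bottom + (top - bottom) / (1 + (dose / ic50) ** hill)`` —
    descending with dose, midpoint at the IC50. Fit by nonlinear least squares.

    Parameters
    ----------
    doses, viabilities
        Paired observations; viabilities normalized to vehicle (vehicle ≈ 1).
        At least four distinct dose levels are required, spanning a transition.
    """

    def __init__(self, doses, viabilities):
        self.doses = np.asarray(doses, dtype=float)
        self.viabilities = np.asarray(viabilities, dtype=float)
        if self.doses.shape != self.viabilities.shape:
            raise ValueError("doses and viabilities must align")
        if len(np.unique(self.doses)) < 4:
            raise FitFailure("need at least 4 distinct dose levels")

    @classmethod
    def from_plate(cls, plate: pd.DataFrame, model: str, regimen: str) -> "DoseResponseModel":
        """Build from a long-format plate table, normalizing to vehicle-well mean."""
        sub = plate[(plate["model"] == model) & (plate["regimen"] == regimen)]
        vehicle = sub[sub["is_vehicle"]]
        treated = sub[~sub["is_vehicle"]]
        if len(vehicle) == 0 or vehicle["signal"].mean() <= 0:
            raise FitFailure("no usable vehicle wells to normalize against")
        v0 = vehicle["signal"].mean()
        doses = np.concatenate([vehicle["dose"].to_numpy(), treated["dose"].to_numpy()])
        via = np.concatenate(
            [vehicle["signal"].to_numpy() / v0, treated["signal"].to_numpy() / v0]
        )
        return cls(doses, via)

    def fit(self) -> DoseResponseResults:
        """Nonlinear least-squares fit; raises :class:`FitFailure` when the data
        show no transition or the optimizer does not converge."""
        d, v = self.doses, self.viabilities
        if v.max() - v.min() < 0.05:
            raise FitFailure("viabilities are flat: no dose-response transition to fit")
        pos = d[d > 0]
        if pos.size == 0:
            raise FitFailure("all doses are zero")
        # start near the dose whose observed viability is closest to the midpoint
        mid = (v.max() + v.min()) / 2.0
        ic50_0 = float(pos[np.argmin(np.abs(v[d > 0] - mid))])
        p0 = [ic50_0, 1.0, max(v.min(), 0.0), min(v.max(), 1.5)]
        bounds = (
            [pos.min() / 1e3, 0.1, -0.5, 0.1],
            [pos.max() * 1e3, 10.0, 0.9, 2.0],
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = optimize.curve_fit(
                    four_param_logistic, d, v, p0=p0, bounds=bounds, maxfev=20_000
                )
        except (RuntimeError, ValueError) as exc:
            raise FitFailure(f"4PL fit did not converge: {exc}") from exc
        resid = v - four_param_logistic(d, *popt)
        se = np.sqrt(np.clip(np.diag(pcov), 0, None))
        names = ("ic50", "hill", "bottom", "top")
        return DoseResponseResults(
            ic50=float(popt[0]),
            hill=float(popt[1]),
            bottom=float(popt[2]),
            top=float(popt[3]),
            bse=dict(zip(names, se.tolist())),
            rss=float(resid @ resid),
            n_obs=len(v),
            doses=d,
            viabilities=v,
        )


def fit_ic50(doses, viabilities) -> tuple[float, float, float, float]:
    """Convenience wrapper: fitted ``(ic50, hill, bottom, top)``.

    Raises :class:`FitFailure` on degenerate input or non-convergence.
    """
    res = DoseResponseModel(doses, viabilities).fit()
    return res.ic50, res.hill, res.bottom, res.top


# ---------------------------------------------------------------------------
# viability reductions and classification


def viability_reduction(treated_wells, vehicle_wells) -> float:
    """Percent viability reduction of treated wells relative to vehicle.

    ``100 * (1 - mean(treated) / mean(vehicle))``; negative values (stimulated
    growth) are permitted here and floored at 0 only during classification.
    """
    treated = np.asarray(treated_wells, dtype=float)
    vehicle = np.asarray(vehicle_wells, dtype=float)
    if treated.size == 0 or vehicle.size == 0:
        raise ValueError("need at least one treated and one vehicle well")
    v0 = vehicle.mean()
    if v0 <= 0:
        raise ValueError("vehicle mean must be positive")
    return float(100.0 * (1.0 - treated.mean() / v0))


@dataclass(frozen=True)
class ReductionProfile:
    """Per model × regimen viability reductions at the (low, medium, high) doses."""

    model_id: str
    regimen: str
    reductions_pct: tuple[float, float, float]
    doses: tuple[float, float, float] | None = None

    def __post_init__(self):
        if len(self.reductions_pct) != 3:
            raise ValueError("exactly three dose levels (low, medium, high) required")
        if self.doses is not None and any(
            b <= a for a, b in zip(self.doses, self.doses[1:])
        ):
            raise ValueError("doses must be strictly increasing")


def reduction_profiles(plate: pd.DataFrame) -> list[ReductionProfile]:
    """Mean-of-replicates reduction profiles from a long-format plate table.

    Vehicle normalization is per model × regimen using the vehicle-well mean.
    Each regimen must have exactly three nonzero dose levels.
    """
    profiles = []
    for (model, regimen), sub in plate.groupby(["model", "regimen"], sort=True):
        vehicle = sub[sub["is_vehicle"]]["signal"].to_numpy()
        doses = sorted(sub.loc[~sub["is_vehicle"], "dose"].unique())
        if len(doses) != 3:
            raise ValueError(
                f"{model}/{regimen}: expected 3 treatment doses, got {len(doses)}"
            )
        reds = tuple(
            viability_reduction(
                sub[(sub["dose"] == d) & (~sub["is_vehicle"])]["signal"].to_numpy(),
                vehicle,
            )
            for d in doses
        )
        profiles.append(
            ReductionProfile(
                model_id=str(model), regimen=str(regimen),
                reductions_pct=reds, doses=tuple(doses),
            )
        )
    return profiles


@dataclass(frozen=True)
class ResponseCall:
    """Categorical call plus the any-dose effectiveness flag at threshold τ."""

    model_id: str
    regimen: str
    category: str
    effective: bool
    threshold_pct: float
    dose_binaries: tuple[int, int, int]


def classify_response(profile: ReductionProfile, threshold_pct: float = 30.0) -> ResponseCall:
    """Classify one reduction profile at viability-reduction threshold τ.

    Negative reductions floor to 0 before comparison. Per-dose binaries
    ``b_d = [reduction_d >= τ]``; responder when all three are 1, nonresponder
    when all are 0, intermediate otherwise; effective when any is 1.
    Thresholds outside {10, 20, 30, 40} are allowed with a warning.
    """
    if threshold_pct not in THRESHOLDS:
        warnings.warn(
            f"nonstandard threshold {threshold_pct}%; the assay grid is {THRESHOLDS}",
            stacklevel=2,
        )
    floored = [max(r, 0.0) for r in profile.reductions_pct]
    binaries = tuple(int(r >= threshold_pct) for r in floored)
    total = sum(binaries)
    category = "responder" if total == 3 else "nonresponder" if total == 0 else "intermediate"
    return ResponseCall(
        model_id=profile.model_id,
        regimen=profile.regimen,
        category=category,
        effective=total > 0,
        threshold_pct=threshold_pct,
        dose_binaries=binaries,
    )


@dataclass
class ThresholdMatrix:
    """Models × thresholds categorical matrix plus its binary collapse.

    ``categories`` is indexed by (model, regimen) with one column per
    threshold; ``binary`` maps intermediate → responder. ``counts`` gives the
    (responder, intermediate, nonresponder) count vector per threshold.
    """

    categories: pd.DataFrame
    binary: pd.DataFrame
    counts: pd.DataFrame

    def to_color_table(self) -> pd.DataFrame:
        """Red/yellow/green rendering of the categorical matrix."""
        colors = {"responder": "red", "intermediate": "yellow", "nonresponder": "green"}
        return self.categories.map(colors.get)


def threshold_matrix(
    profiles: list[ReductionProfile], thresholds: tuple[int, ...] = THRESHOLDS
) -> ThresholdMatrix:
    """Classify every profile at every threshold.

    Category counts per threshold feed :func:`detect_inflection`; the binary
    collapse converts intermediate responders to responders.
    """
    if not profiles:
        raise ValueError("need at least one reduction profile")
    index = pd.MultiIndex.from_tuples(
        [(p.model_id, p.regimen) for p in profiles], names=["model", "regimen"]
    )
    cats = pd.DataFrame(
        {
            t: [classify_response(p, float(t)).category for p in profiles]
            for t in thresholds
        },
        index=index,
    )
    binary = cats.replace({"intermediate": "responder"})
    counts = pd.DataFrame(
        {
            t: [int((cats[t] == c).sum()) for c in CATEGORIES]
            for t in thresholds
        },
        index=list(CATEGORIES),
    )
    return ThresholdMatrix(categories=cats, binary=binary, counts=counts)


@dataclass
class InflectionReport:
    """Adjacent-threshold category shifts and the selected working threshold."""

    selected_threshold_pct: int
    l1_changes: dict[tuple[int, int], int]
    has_inflection: bool


def detect_inflection(matrix: ThresholdMatrix, default: int = 30) -> InflectionReport:
    """Select the working threshold from category-count shifts.

    For each adjacent threshold pair the L1 change of the (responder,
    intermediate, nonresponder) count vector is computed. The selected τ is
    the upper threshold of the pair with maximal change — the bar at which the
    category mass has just shifted — with ties broken toward ``default``
    (30%). When counts are identical across all thresholds there is no
    inflection and the default is returned.
    """
    thresholds = list(matrix.counts.columns)
    if len(thresholds) < 2:
        return InflectionReport(default, {}, False)
    changes: dict[tuple[int, int], int] = {}
    for lo, hi in zip(thresholds, thresholds[1:]):
        changes[(lo, hi)] = int(
            np.abs(matrix.counts[hi].to_numpy() - matrix.counts[lo].to_numpy()).sum()
        )
    max_change = max(changes.values())
    if max_change == 0:
        return InflectionReport(default, changes, False)
    best_pairs = [pair for pair, c in changes.items() if c == max_change]
    selected = min(best_pairs, key=lambda pair: (abs(pair[1] - default), pair[1]))[1]
    return InflectionReport(int(selected), changes, True)
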