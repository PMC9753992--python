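"""Synthetic organoid volumes, viability plates and clinical cohorts.

Every downstream stage of the platform (segmentation, per-cell intensity
quantification, dose-response fitting, threshold classification, cohort
statistics) is exercised against data generated here with known ground truth,
so the whole pipeline is testable without any imaging or clinical download.

The volume generator emulates a single organoid: quasi-spherical nuclei placed
inside a spherical shell, each wrapped in a cytoplasmic corona. Tumor cells
carry CK-19-dominant cytoplasm, activated fibroblasts alpha-SMA-dominant
cytoplasm, and apoptotic cells elevated annexin A5; DAPI marks every nucleus
and Ki-67 is a nuclear channel. Depth attenuation is exponential,
``exp(-attenuation_per_um * z)``; the default attenuation is 0 so that
segmentation oracles are clean, and nonzero values are used only for
antibody-penetration profiles.

The plate generator draws CellTiter-Glo-style luminescence from a
four-parameter logistic of dose with multiplicative log-normal noise; the
cohort generator draws clinical summary records (regimen, CA19-9 before/after
neoadjuvant treatment, exclusion flags, exponential survival by latent
stroma/tumor ratio group).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume import ANNEXIN, ASMA, CK19, CYTOPLASMIC_CHANNELS, DAPI, KI67, OrganoidVolume

__all__ = [
    "VolumeParams",
    "GroundTruth",
    "PlateParams",
    "CohortParams",
    "PackingError",
    "generate_volume",
    "generate_plate",
    "generate_cohort",
    "four_param_logistic",
]


class PackingError(RuntimeError):
    """Raised when nuclei cannot be packed into the shell within the retry budget."""


def _default_channel_params() -> dict[str, tuple[float, float]]:
    # log-normal (location of the median, sigma) per channel, arbitrary units
    return {
        DAPI: (3000.0, 0.15),
        ASMA: (1800.0, 0.25),
        CK19: (2000.0, 0.25),
        ANNEXIN: (600.0, 0.25),
        KI67: (1500.0, 0.25),
    }


@dataclass
class VolumeParams:
    """Parameters for one simulated organoid volume.

    All lengths are micrometres. ``depth_um`` defaults into the 40–120 μm range
    of thick organoid sections; the z-step defaults to 5 μm.
    """

    n_cells: int = 12
    fibroblast_fraction: float = 0.3
    apoptotic_fraction: float = 0.0
    shell_radius_um: float = 40.0
    nucleus_radius_um: float = 4.0
    nucleus_radius_dispersion: float = 0.1
    voxel_size_um: tuple[float, float, float] = (0.5, 0.5, 5.0)
    depth_um: float = 60.0
    channel_intensity_params: dict[str, tuple[float, float]] = field(
        default_factory=_default_channel_params
    )
    attenuation_per_um: float = 0.0
    cytoplasm_radius_factor: float = 1.8
    min_center_distance_um: float | None = None  # default: 2 x mean nucleus radius
    max_placement_retries: int = 10_000
    background: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be nonnegative")
        for name in ("fibroblast_fraction", "apoptotic_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("shell_radius_um", "nucleus_radius_um", "depth_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if self.attenuation_per_um < 0:
            raise ValueError("attenuation_per_um must be nonnegative")

    @property
    def min_distance_um(self) -> float:
        if self.min_center_distance_um is not None:
            return self.min_center_distance_um
        return 2.0 * self.nucleus_radius_um


@dataclass
class GroundTruth:
    """Per-cell ground truth recorded at generation time.

    ``true_channel_max`` holds, for every cell and cytoplasmic channel, the
    maximum rendered voxel value over the voxels that cell owns — the oracle
    for per-cell maximum-intensity quantification. ``true_ki67_mean`` is the
    mean rendered Ki-67 over the cell's nuclear voxels.
    """

    nucleus_centers_um: np.ndarray  # (n, 3) as (z, y, x)
    cell_type: np.ndarray  # {"tumor", "fibroblast"}
    apoptotic: np.ndarray  # bool
    nucleus_radius_um: np.ndarray
    true_channel_max: pd.DataFrame  # one row per cell, one column per channel
    true_ki67_mean: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.nucleus_centers_um)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cell": np.arange(1, self.n_cells + 1),
                "z_um": self.nucleus_centers_um[:, 0] if self.n_cells else [],
                "y_um": self.nucleus_centers_um[:, 1] if self.n_cells else [],
                "x_um": self.nucleus_centers_um[:, 2] if self.n_cells else [],
                "cell_type": self.cell_type,
                "apoptotic": self.apoptotic,
                "nucleus_radius_um": self.nucleus_radius_um,
                "ki67_nuclear_mean": self.true_ki67_mean,
            }
        )
        for ch in self.true_channel_max.columns:
            df[f"max_{ch}"] = self.true_channel_max[ch].to_numpy()
        return df


def _place_centers(params: VolumeParams, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample nucleus centers inside the shell with a minimum spacing."""
    margin = params.cytoplasm_radius_factor * params.nucleus_radius_um * 1.5
    r_eff_z = min(params.shell_radius_um, params.depth_um / 2.0 - margin)
    if r_eff_z <= 0:
        raise ValueError("depth_um too small for the requested nucleus/cytoplasm size")
    r_xy = params.shell_radius_um
    centers: list[np.ndarray] = []
    min_d2 = params.min_distance_um**2
    tries = 0
    while len(centers) < params.n_cells:
        if tries >= params.max_placement_retries:
            raise PackingError(
                f"placed {len(centers)}/{params.n_cells} nuclei after "
                f"{params.max_placement_retries} retries; shell too crowded"
            )
        tries += 1
        # uniform in the unit ball, then scale anisotropically (flattened in z
        # when the section is thinner than the shell diameter)
        while True:
            p = rng.uniform(-1.0, 1.0, size=3)
            if p @ p <= 1.0:
                break
        cand = np.array([p[0] * r_eff_z, p[1] * r_xy, p[2] * r_xy])
        if all(((cand - c) @ (cand - c)) >= min_d2 for c in centers):
            centers.append(cand)
    return np.array(centers) if centers else np.empty((0, 3))


def generate_volume(params: VolumeParams) -> tuple[OrganoidVolume, GroundTruth]:
    """Simulate one organoid stack with per-cell ground truth.

    Returns an integer-intensity (uint16) multichannel volume and the matching
    :class:`GroundTruth`. With ``n_cells=0`` both are empty. Raises
    :class:`PackingError` when the shell cannot hold ``n_cells`` nuclei at the
    minimum spacing within the retry budget.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    sx, sy, sz = params.voxel_size_um
    half_xy = params.shell_radius_um + params.cytoplasm_radius_factor * params.nucleus_radius_um * 2
    n_x = max(int(np.ceil(2 * half_xy / sx)), 4)
    n_y = max(int(np.ceil(2 * half_xy / sy)), 4)
    n_z = max(int(round(params.depth_um / sz)), 1)
    channels = tuple(params.channel_intensity_params.keys())
    data = np.full((len(channels), n_z, n_y, n_x), params.background, dtype=np.float64)

    if params.n_cells == 0:
        gt = GroundTruth(
            nucleus_centers_um=np.empty((0, 3)),
            cell_type=np.array([], dtype=object),
            apoptotic=np.array([], dtype=bool),
            nucleus_radius_um=np.array([]),
            true_channel_max=pd.DataFrame(columns=list(channels)),
            true_ki67_mean=np.array([]),
        )
        vol = OrganoidVolume(
            data=np.round(data).astype(np.uint16),
            channels=channels,
            voxel_size_um=params.voxel_size_um,
        )
        return vol, gt

    centers = _place_centers(params, rng)  # centered coordinates (z, y, x)
    # shift to array coordinates (μm from the stack origin)
    origin = np.array([n_z * sz / 2.0, n_y * sy / 2.0, n_x * sx / 2.0])
    centers_um = centers + origin

    radii = params.nucleus_radius_um * np.exp(
        params.nucleus_radius_dispersion * rng.standard_normal(params.n_cells)
    )
    radii = np.clip(radii, 0.5 * params.nucleus_radius_um, 1.5 * params.nucleus_radius_um)
    cell_type = np.where(
        rng.random(params.n_cells) < params.fibroblast_fraction, "fibroblast", "tumor"
    ).astype(object)
    apoptotic = rng.random(params.n_cells) < params.apoptotic_fraction

    # per-cell per-channel amplitude draws (log-normal around the channel median)
    amp: dict[str, np.ndarray] = {}
    for ch, (median, sigma) in params.channel_intensity_params.items():
        amp[ch] = median * np.exp(sigma * rng.standard_normal(params.n_cells))
    # cell-type dominance of the cytoplasmic markers; apoptosis elevates annexin A5
    if CK19 in amp:
        amp[CK19] = np.where(cell_type == "tumor", amp[CK19], 0.05 * amp[CK19])
    if ASMA in amp:
        amp[ASMA] = np.where(cell_type == "fibroblast", amp[ASMA], 0.05 * amp[ASMA])
    if ANNEXIN in amp:
        amp[ANNEXIN] = np.where(apoptotic, 6.0 * amp[ANNEXIN], amp[ANNEXIN])

    # voxel ownership: nearest center (distance normalized by cytoplasm radius)
    # among cells whose cytoplasm sphere contains the voxel. Deterministic
    # partition, so ground-truth per-cell maxima are exact even when coronas
    # would overlap.
    owner = np.zeros((n_z, n_y, n_x), dtype=np.int32)
    best = np.full((n_z, n_y, n_x), np.inf)
    in_nucleus = np.zeros((n_z, n_y, n_x), dtype=bool)
    zc = (np.arange(n_z) + 0.5) * sz
    yc = (np.arange(n_y) + 0.5) * sy
    xc = (np.arange(n_x) + 0.5) * sx

    boxes = []
    for i in range(params.n_cells):
        r_cyto = params.cytoplasm_radius_factor * radii[i]
        c = centers_um[i]
        z0, z1 = np.searchsorted(zc, [c[0] - r_cyto, c[0] + r_cyto])
        y0, y1 = np.searchsorted(yc, [c[1] - r_cyto, c[1] + r_cyto])
        x0, x1 = np.searchsorted(xc, [c[2] - r_cyto, c[2] + r_cyto])
        z1, y1, x1 = min(z1 + 1, n_z), min(y1 + 1, n_y), min(x1 + 1, n_x)
        dz = zc[z0:z1] - c[0]
        dy = yc[y0:y1] - c[1]
        dx = xc[x0:x1] - c[2]
        d = np.sqrt(
            dz[:, None, None] ** 2 + dy[None, :, None] ** 2 + dx[None, None, :] ** 2
        )
        boxes.append((z0, z1, y0, y1, x0, x1, d, r_cyto))
        inside = d <= r_cyto
        metric = d / r_cyto
        sl = (slice(z0, z1), slice(y0, y1), slice(x0, x1))
        take = inside & (metric < best[sl])
        owner[sl][take] = i + 1
        best[sl][take] = metric[take]

    attenuation = np.exp(-params.attenuation_per_um * zc)[:, None, None]
    ch_index = {ch: k for k, ch in enumerate(channels)}
    for i in range(params.n_cells):
        z0, z1, y0, y1, x0, x1, d, r_cyto = boxes[i]
        sl = (slice(z0, z1), slice(y0, y1), slice(x0, x1))
        owned = owner[sl] == i + 1
        nuc = owned & (d <= radii[i])
        cyto = owned & ~nuc
        in_nucleus[sl] |= nuc
        att = attenuation[z0:z1]
        for ch in channels:
            k = ch_index[ch]
            if ch in (DAPI, KI67):
                mask = nuc
            else:
                mask = cyto
            patch = data[k][sl]
            patch[mask] = np.maximum(patch[mask], (amp[ch][i] * att * np.ones_like(d))[mask])
            data[k][sl] = patch

    data = np.round(np.clip(data, 0, np.iinfo(np.uint16).max)).astype(np.uint16)
    vol = OrganoidVolume(data=data, channels=channels, voxel_size_um=params.voxel_size_um)

    # ground truth from the rendered arrays, restricted to owned voxels
    max_rows = np.zeros((params.n_cells, len(channels)))
    ki67_mean = np.zeros(params.n_cells)
    for i in range(params.n_cells):
        z0, z1, y0, y1, x0, x1, d, r_cyto = boxes[i]
        sl = (slice(z0, z1), slice(y0, y1), slice(x0, x1))
        owned = owner[sl] == i + 1
        nuc = owned & (d <= radii[i])
        cyto = owned & ~nuc
        for ch in channels:
            k = ch_index[ch]
            region = nuc if ch in (DAPI, KI67) else cyto
            vals = data[k][sl][region]
            max_rows[i, k] = vals.max() if vals.size else 0.0
        if KI67 in ch_index:
            nv = data[ch_index[KI67]][sl][nuc]
            ki67_mean[i] = nv.mean() if nv.size else 0.0

    gt = GroundTruth(
        nucleus_centers_um=centers_um,
        cell_type=cell_type,
        apoptotic=apoptotic,
        nucleus_radius_um=radii,
        true_channel_max=pd.DataFrame(max_rows, columns=list(channels)),
        true_ki67_mean=ki67_mean,
    )
    return vol, gt


# ---------------------------------------------------------------------------
# viability plates


def four_param_logistic(
    dose: np.ndarray | float,
    ic50: float,
    hill: float = 1.0,
    bottom: float = 0.0,
    top: float = 1.0,
) -> np.ndarray | float:
    """Descending 4-parameter logistic: ``top`` at dose 0, ``bottom`` at high dose.

    Viability at ``dose == ic50`` is the midpoint ``(top + bottom) / 2``.
    """
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        v = bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)
    return np.where(dose == 0, top, v) if np.ndim(dose) else (top if dose == 0 else float(v))


#: Treatment dose grids (low, medium, high) per regimen, in assay units.
DEFAULT_DOSE_GRIDS: dict[str, tuple[float, ...]] = {
    "GEM": (0.16, 0.8, 4.0),        # μM single-agent gemcitabine
    "GEM/PAC": (0.02, 0.1, 0.5),    # μM; combination doses reduced to 0.5 μM top
    "GEM/CIS": (0.02, 0.1, 0.5),
    "FFX": (0.02, 0.1, 0.5),
    "AUR": (0.76, 7.6, 10.0),       # μg/mL auranofin positive control
}


@dataclass
class PlateParams:
    """Parameters for a simulated 96-well viability plate (triplicate wells)."""

    model_ids: tuple[str, ...] = ("PATXO066",)
    regimens: tuple[str, ...] = ("GEM",)
    dose_grids: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_DOSE_GRIDS)
    )
    true_ic50: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("PATXO066", "GEM"): 1.4}
    )
    hill_slope: float = 1.0
    bottom: float = 0.0
    top: float = 1.0
    baseline_signal: float = 10_000.0
    cv_noise: float = 0.0
    n_replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_replicates < 3:
            raise ValueError("n_replicates must be >= 3")
        if self.cv_noise < 0:
            raise ValueError("cv_noise must be nonnegative")
        for reg, grid in self.dose_grids.items():
            if any(b <= a for a, b in zip(grid, grid[1:])):
                raise ValueError(f"doses for {reg} must be strictly increasing")


def generate_plate(params: PlateParams) -> pd.DataFrame:
    """Simulate a long-format viability table.

    One row per well, columns ``model, regimen, dose, replicate, signal,
    viability, is_vehicle``. Vehicle wells are dose 0. With ``cv_noise=0`` the
    ``viability`` column equals the 4PL closed form exactly.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    sigma = np.sqrt(np.log1p(params.cv_noise**2))
    rows = []
    for model in params.model_ids:
        for reg in params.regimens:
            key = (model, reg)
            if key not in params.true_ic50:
                raise ValueError(f"no true_ic50 for {key}")
            ic50 = params.true_ic50[key]
            doses = (0.0,) + tuple(params.dose_grids[reg])
            for dose in doses:
                v = four_param_logistic(
                    dose, ic50, params.hill_slope, params.bottom, params.top
                )
                for rep in range(1, params.n_replicates + 1):
                    noise = (
                        np.exp(sigma * rng.standard_normal() - sigma**2 / 2.0)
                        if sigma > 0
                        else 1.0
                    )
                    rows.append(
                        {
                            "model": model,
                            "regimen": reg,
                            "dose": dose,
                            "replicate": rep,
                            "viability": float(v) * noise,
                            "signal": params.baseline_signal * float(v) * noise,
                            "is_vehicle": dose == 0.0,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clinical cohorts


@dataclass
class CohortParams:
    """Parameters for a simulated clinical cohort summary table."""

    n_patients: int = 21
    regimen_mix: dict[str, float] = field(
        default_factory=lambda: {"GA": 0.35, "FFX": 0.45, "other": 0.2}
    )
    baseline_ca199_median: float = 400.0
    baseline_ca199_sigma: float = 1.0
    true_responder_fraction: float = 0.6
    normal_baseline_fraction: float = 0.0
    no_neoadjuvant_fraction: float = 0.0
    normal_cutoff: float = 35.0
    #: exponential survival scale (months) per latent ratio group
    median_survival_months: dict[str, float] = field(
        default_factory=lambda: {"high": 40.0, "low": 10.0}
    )
    high_ratio_fraction: float = 0.5
    censor_horizon_months: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in (
            "true_responder_fraction",
            "normal_baseline_fraction",
            "no_neoadjuvant_fraction",
            "high_ratio_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Simulate a cohort table with known responder and survival structure.

    Columns mirror the clinical schema: ``pdo_id, regimen, ca199_pre,
    ca199_post, ca199_followup, received_neoadjuvant, survival_months, event,
    sma_ck19_ratio`` plus the latent ``ratio_group`` and ``true_responder``
    flags used by simulation oracles.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    regs = list(params.regimen_mix)
    probs = np.array([params.regimen_mix[r] for r in regs], dtype=float)
    probs /= probs.sum()
    regimen = rng.choice(regs, size=n, p=probs).astype(object)
    no_neo = rng.random(n) < params.no_neoadjuvant_fraction
    regimen[no_neo] = "none"
    normal_base = rng.random(n) < params.normal_baseline_fraction
    pre = params.baseline_ca199_median * np.exp(
        params.baseline_ca199_sigma * rng.standard_normal(n)
    )
    pre = np.where(normal_base, rng.uniform(2.0, params.normal_cutoff * 0.9, n), np.maximum(pre, params.normal_cutoff * 1.2))
    responder = rng.random(n) < params.true_responder_fraction
    drop = rng.uniform(0.3, 0.9, n)
    rise = rng.uniform(1.1, 2.5, n)
    post = np.where(responder, pre * drop, pre * rise)
    post = np.where(no_neo, np.nan, post)
    followup = post * rng.uniform(0.8, 1.4, n)

    high = rng.random(n) < params.high_ratio_fraction
    ratio = np.where(high, rng.uniform(1.05, 3.0, n), rng.uniform(0.2, 0.95, n))
    scale_high = params.median_survival_months["high"] / np.log(2)
    scale_low = params.median_survival_months["low"] / np.log(2)
    t = rng.exponential(np.where(high, scale_high, scale_low))
    event = t <= params.censor_horizon_months
    t = np.minimum(t, params.censor_horizon_months)

    return pd.DataFrame(
        {
            "pdo_id": [f"SIM{i:03d}" for i in range(1, n + 1)],
            "regimen": regimen,
            "ca199_pre": pre,
            "ca199_post": post,
            "ca199_followup": followup,
            "received_neoadjuvant": ~no_neo,
            "survival_months": t,
            "event": event,
            "sma_ck19_ratio": ratio,
            "ratio_group": np.where(high, "high", "low"),
            "true_responder": responder & ~no_neo & ~normal_base,
        }
    )
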