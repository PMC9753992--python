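"""End-to-end pipeline: simulate → segment → quantify → assay → clinical.

A :class:`PipelineConfig` (flat YAML/JSON document, CLI flags override)
drives the stages; :func:`run_pipeline` writes per-stage CSV/JSON outputs, a
run log echoing the seed and parameters, and a deterministic ``summary.json``
(floating-point values written at fixed precision, so reruns with the same
seed are byte-identical).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import CA199_NORMAL_CUTOFF, match_rates, ratio_prognosis
from .datasets import (
    effective_calls,
    load_odsa_reductions,
    load_prognosis_cohort,
    load_table1,
    reduction_profiles_from_frame,
)
from .odsa import THRESHOLDS, detect_inflection, threshold_matrix
from .quantify import build_cell_table, organoid_summary
from .segmentation import segment_cells, segment_nuclei
from .synthetic import VolumeParams, generate_volume
from .volume import load_volume, save_labels, save_volume

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]

log = logging.getLogger("obp")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run.

    Paths left as ``None`` fall back to simulation (volume) or the packaged
    synthetic fixtures (cohort, reductions, prognosis).
    """

    seed: int = 0
    out_dir: str = "obp_out"
    # volume source: either a TIFF path or simulation parameters
    volume_path: str | None = None
    n_cells: int = 12
    fibroblast_fraction: float = 0.3
    apoptotic_fraction: float = 0.0
    shell_radius_um: float = 30.0
    separation_um: float = 16.0
    # segmentation
    min_nucleus_volume_um3: float = 65.0
    # assay
    thresholds: tuple[int, ...] = THRESHOLDS
    default_threshold_pct: float = 30.0
    reductions_path: str | None = None
    # clinical
    cohort_path: str | None = None
    prognosis_path: str | None = None
    ca199_cutoff: float = CA199_NORMAL_CUTOFF
    landmark_months: float = 32.0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "thresholds" in doc:
            doc["thresholds"] = tuple(doc["thresholds"])
        return cls(**doc)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (the output location is excluded)."""
        doc = asdict(self)
        doc.pop("out_dir")
        payload = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the summary dict.

    Outputs land under ``config.out_dir``: the (possibly simulated) volume,
    nucleus/cell label TIFFs, the per-cell table, the threshold matrix, the
    concordance and prognosis reports, a run log, and ``summary.json``.
    Stage failures raise :class:`StageError`; outputs of completed stages are
    retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }
    logpath = out / "run.log"
    handler = logging.FileHandler(logpath, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("obp %s seed=%d config=%s", __version__, config.seed, config.config_hash())

    try:
        # --- imaging arm -------------------------------------------------
        stage = "simulate/load"
        try:
            if config.volume_path:
                volume = load_volume(config.volume_path)
                truth = None
            else:
                params = VolumeParams(
                    n_cells=config.n_cells,
                    fibroblast_fraction=config.fibroblast_fraction,
                    apoptotic_fraction=config.apoptotic_fraction,
                    shell_radius_um=config.shell_radius_um,
                    min_center_distance_um=config.separation_um,
                    seed=config.seed,
                )
                volume, truth = generate_volume(params)
                save_volume(volume, out / "volume.ome.tif")
                truth.to_frame().to_csv(out / "ground_truth.csv", index=False)
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

        stage = "segment"
        try:
            nuclei = segment_nuclei(volume, min_volume_um3=config.min_nucleus_volume_um3)
            cells = segment_cells(volume, nuclei)
            save_labels(nuclei, out / "nuclei_labels.tif")
            save_labels(cells, out / "cell_labels.tif")
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

        stage = "quantify"
        try:
            table = build_cell_table(volume, nuclei, cells)
            table.to_csv(out / "cell_table.csv", index=False)
            osum = organoid_summary(table, nuclei, cells)
            summary["organoid"] = osum.to_dict()
            if truth is not None:
                summary["organoid"]["true_n_cells"] = truth.n_cells
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

        # --- assay arm ---------------------------------------------------
        stage = "odsa"
        try:
            red_df = (
                load_odsa_reductions()
                if config.reductions_path is None
                else pd.read_csv(config.reductions_path)
            )
            profiles = reduction_profiles_from_frame(red_df)
            matrix = threshold_matrix(profiles, config.thresholds)
            matrix.categories.to_csv(out / "threshold_matrix.csv")
            matrix.binary.to_csv(out / "threshold_matrix_binary.csv")
            inflection = detect_inflection(matrix, default=int(config.default_threshold_pct))
            summary["odsa"] = {
                "n_profiles": len(profiles),
                "category_counts": {
                    str(t): matrix.counts[t].tolist() for t in matrix.counts.columns
                },
                "selected_threshold_pct": inflection.selected_threshold_pct,
                "has_inflection": inflection.has_inflection,
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

        # --- clinical arm ------------------------------------------------
        stage = "concordance"
        try:
            cohort = (
                load_table1()
                if config.cohort_path is None
                else pd.read_csv(config.cohort_path)
            )
            calls = effective_calls(profiles, config.default_threshold_pct)
            conc = match_rates(cohort, calls, cutoff=config.ca199_cutoff)
            summary["concordance"] = conc.to_dict()
            (out / "concordance.json").write_text(
                json.dumps(_round_floats(conc.to_dict()), indent=2, sort_keys=True)
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

        stage = "prognosis"
        try:
            prog_cohort = (
                load_prognosis_cohort()
                if config.prognosis_path is None
                else pd.read_csv(config.prognosis_path)
            )
            prog = ratio_prognosis(prog_cohort, landmark_months=config.landmark_months)
            summary["prognosis"] = prog.to_dict()
            (out / "prognosis.json").write_text(
                json.dumps(_round_floats(prog.to_dict()), indent=2, sort_keys=True)
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

        summary["elapsed_s"] = round(time.time() - t0, 1)
        clean = _round_floats(summary)
        clean["elapsed_s"] = None  # keep summary.json reproducible across reruns
        (out / "summary.json").write_text(json.dumps(clean, indent=2, sort_keys=True))
        log.info("pipeline complete in %.1fs", time.time() - t0)
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()
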