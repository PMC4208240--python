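"""Placement design study: source-angle sweep, metric maps and rankings.

Orchestrates the full study grid -- source angles 0..180 deg in 15 deg steps,
48 detectors, two wavelengths, two cardiac phases, both finger models,
single- and three-element multi-detector modes -- and reduces the transport
tallies to a metrics table with one row per (model, source, detector, mode).

Phase pairs are run with common random numbers by default: the diastolic and
systolic geometries differ only inside the artery cylinders, so sharing the
per-photon random streams cancels most counting noise in the AC difference.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .finger_model import CardiacPhase, build_finger_model
from .metrics import (
    IR_NM,
    RED_NM,
    filter_R,
    pi_ratio,
    ppg_components,
    r_flags,
    ratio_R,
)
from .transport import SimResult, SourceSpec, run_simulation

__all__ = [
    "SweepConfig",
    "SweepTable",
    "run_sweep",
    "rank_placements",
    "write_report",
    "read_metrics",
]

logger = logging.getLogger(__name__)

DEFAULT_SOURCE_ANGLES = tuple(range(0, 181, 15))

METRIC_COLUMNS = [
    "model",
    "source_deg",
    "detector_bin",
    "detector_deg",
    "mode",
    "pi_656_pct",
    "pi_943_pct",
    "R_raw",
    "R_filtered",
    "flags",
]

_MODE_WIDTH = {"single": 1, "multi3": 3}


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of one design-study sweep."""

    models: tuple[int, ...] = (1, 2)
    source_angles: tuple[float, ...] = DEFAULT_SOURCE_ANGLES
    wavelengths: tuple[int, ...] = (RED_NM, IR_NM)
    photons: int = 1_000_000
    seed: int = 0
    pairing: str = "crn"  # or "independent"
    modes: tuple[str, ...] = ("single", "multi3")
    dc_mode: str = "mean"
    half_angle_deg: float = 60.0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.photons < 1_000:
            raise ValueError("photon budget must be >= 1000")
        for a in self.source_angles:
            if not (0.0 <= a < 360.0):
                raise ValueError(f"source angle {a} outside [0, 360)")
        if self.pairing not in ("crn", "independent"):
            raise ValueError("pairing must be 'crn' or 'independent'")
        for m in self.modes:
            if m not in _MODE_WIDTH:
                raise ValueError(f"unknown detector mode {m!r}")
        if sorted(self.wavelengths) != sorted((RED_NM, IR_NM)):
            raise ValueError("the design study needs both 656 and 943 nm")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["models"] = list(self.models)
        d["source_angles"] = list(self.source_angles)
        d["wavelengths"] = list(self.wavelengths)
        d["modes"] = list(self.modes)
        return d

    @classmethod
    def from_yaml(cls, source) -> "SweepConfig":
        if hasattr(source, "read"):
            raw = yaml.safe_load(source.read())
        else:
            with open(source, "r") as fh:
                raw = yaml.safe_load(fh)
        for key in ("models", "source_angles", "wavelengths", "modes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SweepTable:
    """Metrics table plus the manifest needed to reproduce it."""

    df: pd.DataFrame
    config: SweepConfig
    manifest: dict


def _run_seed(master: int, model: int, theta: float, wavelength: int,
              phase: CardiacPhase, pairing: str) -> int:
    phase_key = 0 if pairing == "crn" else (1 if phase is CardiacPhase.DIASTOLE else 2)
    ss = np.random.SeedSequence(
        int(master), spawn_key=(int(model), int(round(theta * 8)), int(wavelength), phase_key)
    )
    return int(ss.generate_state(1, np.uint64)[0])


def run_sweep(config: SweepConfig) -> SweepTable:
    """Run the full placement study described by ``config``.

    Per (model, source angle, wavelength, phase) one seeded transport run is
    performed; metrics are then computed per detector bin for every detector
    mode.  The result is complete (|models| x |sources| x 48 x |modes| rows)
    and reproducible from (config, seed); a run manifest with all seeds and
    conservation tallies is attached.
    """
    rows = []
    run_records = []
    for model in config.models:
        geoms = {
            phase: build_finger_model(model, phase)
            for phase in (CardiacPhase.DIASTOLE, CardiacPhase.SYSTOLE)
        }
        for theta in config.source_angles:
            results: dict[tuple[int, CardiacPhase], SimResult] = {}
            for wl in (RED_NM, IR_NM):
                for phase in (CardiacPhase.DIASTOLE, CardiacPhase.SYSTOLE):
                    seed = _run_seed(config.seed, model, theta, wl, phase, config.pairing)
                    src = SourceSpec(
                        theta_deg=float(theta),
                        wavelength=wl,
                        n_photons=config.photons,
                        seed=seed,
                        half_angle_deg=config.half_angle_deg,
                    )
                    res = run_simulation(geoms[phase], src)
                    results[(wl, phase)] = res
                    rec = res.meta_dict()
                    rec["mean_events"] = round(rec["mean_events"], 3)
                    run_records.append(rec)
            dia_r = results[(RED_NM, CardiacPhase.DIASTOLE)]
            sys_r = results[(RED_NM, CardiacPhase.SYSTOLE)]
            dia_i = results[(IR_NM, CardiacPhase.DIASTOLE)]
            sys_i = results[(IR_NM, CardiacPhase.SYSTOLE)]
            launched = config.photons
            for mode in config.modes:
                width = _MODE_WIDTH[mode]
                for b in range(dia_r.n_bins):
                    ppg = ppg_components(
                        dia_r, sys_r, dia_i, sys_i, b, width=width, dc_mode=config.dc_mode
                    )
                    r_raw = ratio_R(ppg)
                    # AC is already the diastole-minus-systole difference
                    pi_r = pi_ratio(ppg.ac_red, 0.0, launched)
                    pi_i = pi_ratio(ppg.ac_ir, 0.0, launched)
                    flags = r_flags(ppg, r_raw)
                    rows.append(
                        (
                            model,
                            float(theta),
                            b,
                            b * 360.0 / dia_r.n_bins,
                            mode,
                            pi_r,
                            pi_i,
                            r_raw,
                            filter_R(r_raw),
                            flags,
                        )
                    )
    df = pd.DataFrame(rows, columns=METRIC_COLUMNS)
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "runs": run_records,
        "versions": {"ringoxsim": __version__, "numpy": np.__version__},
    }
    return SweepTable(df=df, config=config, manifest=manifest)


def rank_placements(table: SweepTable, stability_weight: float = 1.0) -> pd.DataFrame:
    """Rank placements by pulsatile signal strength and cross-model stability.

    Only placements whose screened R is positive in every model are eligible
    (an unreasonable R in either model disqualifies the placement).  The
    score is the worst-case (minimum over models) near-infrared P-I ratio,
    divided by ``1 + stability_weight * relative cross-model P-I spread``;
    ties break on smaller source angle, then smaller detector angle.  This
    scalarisation of "strong and structurally stable" is this package's own
    formalisation of the design goal.
    """
    df = table.df
    n_models = df["model"].nunique()
    key = ["mode", "source_deg", "detector_bin", "detector_deg"]
    if n_models < 2:
        warnings.warn(
            "single-model table: cross-model stability undefined, ranking by P-I only",
            stacklevel=2,
        )
        out = df[df["R_filtered"] > 0].copy()
        g = out.groupby(key, as_index=False).agg(pi943_min=("pi_943_pct", "min"))
        g["rel_spread"] = 0.0
        g["score"] = g["pi943_min"]
    else:
        valid = df.groupby(key)["R_filtered"].transform("min") > 0
        sub = df[valid]
        g = sub.groupby(key, as_index=False).agg(
            pi943_min=("pi_943_pct", "min"),
            pi943_max=("pi_943_pct", "max"),
            n_models=("model", "nunique"),
        )
        g = g[g["n_models"] == n_models].drop(columns="n_models")
        denom = np.maximum(np.abs(g["pi943_max"]), np.abs(g["pi943_min"]))
        denom = np.where(denom > 0, denom, 1.0)
        g["rel_spread"] = (g["pi943_max"] - g["pi943_min"]) / denom
        g["score"] = g["pi943_min"] / (1.0 + stability_weight * g["rel_spread"])
        g = g.drop(columns="pi943_max")
    g = g.sort_values(
        by=["score", "source_deg", "detector_deg"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    g.insert(0, "rank", np.arange(1, len(g) + 1))
    return g


def _heatmap(df: pd.DataFrame, model: int, mode: str, column: str) -> pd.DataFrame:
    sub = df[(df["model"] == model) & (df["mode"] == mode)]
    mat = sub.pivot(index="source_deg", columns="detector_deg", values=column)
    return mat.sort_index()


def write_report(table: SweepTable, path) -> dict[str, Path]:
    """Write metrics/ranking CSVs, heat-map matrices and the JSON manifest.

    Outputs are byte-stable for identical inputs.  Raises on an empty table
    before creating any file.
    """
    if table.df.empty:
        raise ValueError("refusing to write a report for an empty sweep table")
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    metrics_path = out / "metrics.csv"
    table.df.to_csv(metrics_path, index=False, float_format="%.10g", lineterminator="\n")
    files["metrics"] = metrics_path

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ranking = rank_placements(table)
    ranking_path = out / "ranking.csv"
    ranking.to_csv(ranking_path, index=False, float_format="%.10g", lineterminator="\n")
    files["ranking"] = ranking_path

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(table.manifest, indent=2, sort_keys=True) + "\n")
    files["manifest"] = manifest_path

    for model in sorted(table.df["model"].unique()):
        for mode in sorted(table.df["mode"].unique()):
            for column, tag in (("pi_943_pct", "pi943"), ("R_filtered", "Rf")):
                mat = _heatmap(table.df, model, mode, column)
                p = out / f"heatmap_{tag}_model{model}_{mode}.csv"
                mat.to_csv(p, float_format="%.10g", lineterminator="\n")
                files[f"heatmap_{tag}_m{model}_{mode}"] = p
    logger.info("report written to %s (%d files)", out, len(files))
    return files


def read_metrics(path) -> pd.DataFrame:
    """Read back a metrics CSV written by :func:`write_report`."""
    df = pd.read_csv(path, dtype={"flags": "string"})
    df["flags"] = df["flags"].fillna("").astype(str)
    return df
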