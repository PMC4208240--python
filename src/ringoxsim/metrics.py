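"""PPG-derived pulse-oximetry metrics from paired-phase detector tallies.

A simulated PPG record is built from two static transport runs that differ
only in the cardiac phase of the geometry.  Per detector selection and per
wavelength the pulsatile (AC) component is the diastolic-minus-systolic
detected intensity and the baseline (DC) component is, by default, the mean
of the two phases.  From these:

* P-I ratio  = (I_dia - I_sys) / I_incident * 100  (percent), the
  penetrated-to-incident pulsatile intensity, a proxy for PPG signal
  strength;
* ratio R    = (AC_red / DC_red) / (AC_ir / DC_ir), the ratio of ratios a
  pulse oximeter calibrates against SpO2;
* the screening rule maps unreasonable R (undefined, negative, or > 2.5)
  to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transport import SimResult

__all__ = [
    "PPGComponents",
    "PlacementMetrics",
    "R_FILTER_THRESHOLD",
    "pi_ratio",
    "aggregate_multi",
    "ppg_components",
    "ratio_R",
    "filter_R",
]

#: R values above this (or negative / undefined) are screened to zero.
R_FILTER_THRESHOLD = 2.5

RED_NM = 656
IR_NM = 943


@dataclass(frozen=True)
class PPGComponents:
    """AC/DC components of a simulated PPG record at both wavelengths."""

    ac_red: float
    dc_red: float
    ac_ir: float
    dc_ir: float


@dataclass(frozen=True)
class PlacementMetrics:
    """Metrics of one (model, source, detector, mode) placement."""

    model_id: int
    source_deg: float
    detector_bin: int
    detector_deg: float
    mode: str
    pi_656_pct: float
    pi_943_pct: float
    r_raw: float
    r_filtered: float
    flags: str


def pi_ratio(i_dia, i_sys, i_incident):
    """P-I ratio in percent: (I_dia - I_sys) / I_incident * 100.

    Negative values (systolic detection exceeding diastolic) are returned
    as-is; callers flag them.  Accepts scalars or arrays.
    """
    inc = np.asarray(i_incident, dtype=float)
    if np.any(inc <= 0):
        raise ValueError("incident intensity must be positive")
    out = (np.asarray(i_dia, dtype=float) - np.asarray(i_sys, dtype=float)) / inc * 100.0
    return float(out) if out.ndim == 0 else out


def aggregate_multi(result: SimResult, center_bin: int, width: int = 3):
    """Summed detected weight over an odd-width window of adjacent bins.

    Bins wrap modulo the detector count; ``width=1`` is the single-detector
    tally, ``width=3`` the three-element multi-detector of the design study.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError("window width must be odd and >= 1")
    n = result.n_bins
    half = width // 2
    idx = (np.arange(center_bin - half, center_bin + half + 1)) % n
    return int(result.bin_counts[idx].sum())


def _check_pair(dia: SimResult, sys: SimResult, wavelength: int) -> None:
    if dia.phase != "diastole" or sys.phase != "systole":
        raise ValueError("expected a (diastole, systole) result pair")
    same = (
        dia.model_id == sys.model_id
        and dia.wavelength == sys.wavelength == wavelength
        and dia.source_theta_deg == sys.source_theta_deg
        and dia.n_launched == sys.n_launched
        and dia.n_bins == sys.n_bins
    )
    if not same:
        raise ValueError("phase pair metadata mismatch (model/wavelength/source/budget)")


def ppg_components(
    dia_red: SimResult,
    sys_red: SimResult,
    dia_ir: SimResult,
    sys_ir: SimResult,
    detector_bin: int,
    width: int = 1,
    dc_mode: str = "mean",
) -> PPGComponents:
    """Assemble AC/DC components from the four phase/wavelength runs.

    AC = I_dia - I_sys and DC = (I_dia + I_sys)/2 (or DC = I_dia with
    ``dc_mode="diastole"``), per wavelength, over the selected detector
    window.
    """
    _check_pair(dia_red, sys_red, RED_NM)
    _check_pair(dia_ir, sys_ir, IR_NM)
    if dc_mode not in ("mean", "diastole"):
        raise ValueError("dc_mode must be 'mean' or 'diastole'")

    def _acdc(dia: SimResult, sys: SimResult) -> tuple[float, float]:
        i_d = aggregate_multi(dia, detector_bin, width)
        i_s = aggregate_multi(sys, detector_bin, width)
        dc = (i_d + i_s) / 2.0 if dc_mode == "mean" else float(i_d)
        return float(i_d - i_s), dc

    ac_r, dc_r = _acdc(dia_red, sys_red)
    ac_ir, dc_ir = _acdc(dia_ir, sys_ir)
    return PPGComponents(ac_red=ac_r, dc_red=dc_r, ac_ir=ac_ir, dc_ir=dc_ir)


def ratio_R(ppg: PPGComponents) -> float:
    """Ratio of ratios (AC_red/DC_red)/(AC_ir/DC_ir); NaN when undefined.

    Undefined cases -- non-positive DC in either band or zero AC_ir -- are
    returned as NaN and are mapped to zero by :func:`filter_R`, matching the
    screening of unreasonable values.
    """
    if ppg.dc_red <= 0 or ppg.dc_ir <= 0 or ppg.ac_ir == 0:
        return float("nan")
    return (ppg.ac_red / ppg.dc_red) / (ppg.ac_ir / ppg.dc_ir)


def filter_R(r):
    """Screen unreasonable R: keep values in [0, 2.5], map all else to 0.

    NaN (undefined), negative and > 2.5 values all become 0; the threshold
    itself is kept.  Idempotent; accepts scalars or arrays.
    """
    arr = np.asarray(r, dtype=float)
    out = np.where(np.isfinite(arr) & (arr >= 0.0) & (arr <= R_FILTER_THRESHOLD), arr, 0.0)
    return float(out) if out.ndim == 0 else out


def r_flags(ppg: PPGComponents, r_raw: float) -> str:
    """Diagnostic flags for a metrics record (semicolon-joined)."""
    flags = []
    if ppg.dc_red <= 0 or ppg.dc_ir <= 0:
        flags.append("zero_dc")
    elif ppg.ac_ir == 0:
        flags.append("undefined_R")
    elif r_raw < 0:
        flags.append("negative_R")
    elif r_raw > R_FILTER_THRESHOLD:
        flags.append("R_above_threshold")
    if ppg.ac_ir < 0 or ppg.ac_red < 0:
        flags.append("negative_AC")
    return ";".join(flags)
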