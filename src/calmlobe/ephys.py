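"""Calcium-dependent inactivation (CDI) metrics from whole-cell currents.

Calmodulin bound to the Ca_V1.2 channel closes it in response to incoming
calcium (CDI).  Barium permeates the channel but is not sensed by
calmodulin, so a barium trace from the same cell isolates the
voltage-dependent component of inactivation.  The standard quantification:

* ``r300`` — fraction of the peak current remaining 300 ms after the peak
  of the depolarizing step (computed on current magnitudes, so it is
  invariant to the inward-negative sign convention and to uniform scaling);
* ``f300`` — Ba r300 minus Ca r300; the barium-normalized form
  ``f300 / Ba r300`` is the default reported statistic.

Traces are assumed leak-subtracted (P/8 at acquisition time).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import medfilt

__all__ = ["CurrentTrace", "CDIMetrics", "r300", "f300", "cdi_voltage_profile"]


@dataclass(frozen=True)
class CurrentTrace:
    time_ms: np.ndarray
    current_pa: np.ndarray
    carrier: str = "Ca"      # "Ca" or "Ba"
    voltage_mv: float = 30.0
    cell_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_ms, dtype=float)
        i = np.asarray(self.current_pa, dtype=float)
        object.__setattr__(self, "time_ms", t)
        object.__setattr__(self, "current_pa", i)
        if t.shape != i.shape:
            raise ValueError("time and current shapes differ")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.carrier not in ("Ca", "Ba"):
            raise ValueError("carrier must be 'Ca' or 'Ba'")


@dataclass(frozen=True)
class CDIMetrics:
    r300_ca: float
    r300_ba: float
    f300_raw: float
    f300_norm: float
    voltage_mv: float
    cell_id: str = ""


class FlatTraceError(ValueError):
    """No discernible peak above the noise floor."""


def r300(
    trace: CurrentTrace,
    step_onset_ms: float = 0.0,
    window_ms: float = 300.0,
    smooth_samples: int = 5,
    noise_floor_sd: float = 3.0,
) -> float:
    """|I(peak + 300 ms)| / |I_peak| within the depolarizing step.

    The peak is located on a median-smoothed copy of the trace (resistant
    to single-sample noise); the current 300 ms later is read off with
    linear interpolation between samples.
    """
    t, i = trace.time_ms, trace.current_pa
    if t[-1] < step_onset_ms + window_ms:
        raise ValueError("trace does not cover onset + 300 ms")
    in_step = t >= step_onset_ms
    smoothed = medfilt(i, kernel_size=smooth_samples)
    seg_t, seg_i = t[in_step], smoothed[in_step]
    mag = np.abs(seg_i)
    pre = i[~in_step]
    noise_sd = pre.std() if pre.size >= 4 else 0.0
    if mag.max() <= noise_floor_sd * noise_sd or mag.max() == 0.0:
        raise FlatTraceError("no discernible peak above noise floor")
    k = int(np.argmax(mag))
    peak_t, peak_i = seg_t[k], mag[k]
    end_val = abs(float(np.interp(peak_t + window_ms, t, smoothed)))
    return end_val / peak_i


def f300(
    ca: CurrentTrace,
    ba: CurrentTrace,
    step_onset_ms: float = 0.0,
    window_ms: float = 300.0,
) -> CDIMetrics:
    """Pairwise CDI metrics from a calcium and a barium trace.

    Both the raw difference (Ba r300 - Ca r300) and the barium-normalized
    variant are reported; the normalized form is the headline statistic.
    """
    if ca.carrier != "Ca" or ba.carrier != "Ba":
        raise ValueError("expected a Ca trace and a Ba trace, in that order")
    if ca.voltage_mv != ba.voltage_mv:
        raise ValueError("Ca and Ba traces recorded at different voltages")
    r_ca = r300(ca, step_onset_ms, window_ms)
    r_ba = r300(ba, step_onset_ms, window_ms)
    raw = r_ba - r_ca
    norm = raw / r_ba if r_ba > 0 else math.nan
    return CDIMetrics(
        r300_ca=r_ca, r300_ba=r_ba, f300_raw=raw, f300_norm=norm,
        voltage_mv=ca.voltage_mv,
        cell_id=ca.cell_id or ba.cell_id,
    )


def cdi_voltage_profile(
    traces: list[CurrentTrace], step_onset_ms: float = 0.0
) -> pd.DataFrame:
    """Per-voltage mean +/- SEM of r300/f300 across paired traces.

    Ca and Ba traces are paired per (cell, voltage); voltages where a cell
    lacks one carrier are excluded with a warning.
    """
    index: dict[tuple, dict[str, CurrentTrace]] = {}
    for tr in traces:
        index.setdefault((tr.cell_id, tr.voltage_mv), {})[tr.carrier] = tr
    metrics = []
    for (cell, volt), pair in sorted(index.items()):
        if "Ca" not in pair or "Ba" not in pair:
            warnings.warn(
                f"cell {cell!r} at {volt} mV lacks a paired carrier; excluded"
            )
            continue
        metrics.append(f300(pair["Ca"], pair["Ba"], step_onset_ms))
    if not metrics:
        raise ValueError("no complete Ca/Ba pairs")
    df = pd.DataFrame(
        {
            "voltage_mv": [m.voltage_mv for m in metrics],
            "r300_ca": [m.r300_ca for m in metrics],
            "r300_ba": [m.r300_ba for m in metrics],
            "f300_raw": [m.f300_raw for m in metrics],
            "f300_norm": [m.f300_norm for m in metrics],
        }
    )
    g = df.groupby("voltage_mv")
    out = g.mean()
    out.columns = [f"{c}_mean" for c in out.columns]
    sem = g.sem(ddof=1)
    for c in sem.columns:
        out[f"{c}_sem"] = sem[c]
    out["n"] = g.size()
    return out.reset_index()
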