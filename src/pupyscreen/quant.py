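"""Peak detection/integration, internal-standard calibration and
concentration read-out for MRM traces."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .panel import PanelRegistry
from .simulate import ChromatogramTrace, QUALIFIER_ION_RATIO

__all__ = [
    "PeakResult",
    "CalibrationFit",
    "QuantReadout",
    "InjectionError",
    "integrate_peak",
    "fit_calibration",
    "quantify",
    "carryover_check",
    "calibrate_from_series",
    "quantify_sample",
]

SNR_DETECTION = 3.0  # a peak below S/N 3 counts as not found
ION_RATIO_TOLERANCE = 0.30  # relative window on qualifier/quantifier ratio


class InjectionError(RuntimeError):
    """The internal-standard peak is missing: the injection failed."""


@dataclass(frozen=True)
class PeakResult:
    analyte: str
    channel_role: str
    retention_time: float
    height: float
    area: float
    width_at_half_height: float
    noise_sd: float
    snr: float
    found: bool


@dataclass(frozen=True)
class CalibrationFit:
    analyte: str
    slope: float
    intercept: float
    r_squared: float
    weighting: str  # "none" | "1/x"
    level_range_used: tuple[float, float]


@dataclass(frozen=True)
class QuantReadout:
    value_um: float  # pre-preparation calibrator scale
    below_lod: bool


def _interp_crossing(t0, y0, t1, y1, target):
    if y1 == y0:
        return t0
    return t0 + (target - y0) * (t1 - t0) / (y1 - y0)


def integrate_peak(
    trace: ChromatogramTrace,
    expected_rt: float,
    window_halfwidth: float = 1.5,
    margin_fraction: float = 0.15,
    descent_fraction: float = 0.05,
) -> PeakResult:
    """Locate and integrate the peak nearest ``expected_rt``.

    Baseline and noise SD come from the window margins (median, and the
    median-to-84th-percentile spread); the apex is the maximum of the
    baseline-subtracted window; integration bounds extend from the apex
    until the signal has dropped below ``descent_fraction`` of the apex
    *and* stopped descending.  A peak below S/N 3 is reported as not
    found.
    """
    t = np.asarray(trace.times, dtype=float)
    y = np.asarray(trace.intensities, dtype=float)
    if t.size == 0:
        raise ValueError(f"{trace.analyte}: empty trace")
    mask = (t >= expected_rt - window_halfwidth) & (t <= expected_rt + window_halfwidth)
    if not mask.any():
        raise ValueError(
            f"{trace.analyte}: window {expected_rt}+/-{window_halfwidth} min "
            "outside trace time range"
        )
    tw, yw = t[mask], y[mask]
    k = max(3, int(round(margin_fraction * tw.size / 2)))
    margins = np.concatenate([yw[:k], yw[-k:]])
    baseline = float(np.median(margins))
    # robust spread: median-to-84th-percentile distance equals sigma for
    # Gaussian noise and, unlike the MAD, survives zero-truncated noise
    # (where half the samples sit exactly at zero)
    noise_sd = float(np.quantile(margins, 0.8413) - baseline)
    ys = yw - baseline

    # apex detection on a lightly smoothed window so single noise samples
    # cannot fake a peak; height/area/width are taken from the raw signal
    win = 5
    ys_smooth = np.convolve(ys, np.ones(win) / win, mode="same")
    apex_s = int(np.argmax(ys_smooth))
    lo_a = max(apex_s - win, 0)
    apex = lo_a + int(np.argmax(ys[lo_a : apex_s + win + 1]))
    height = float(ys[apex])
    detect_height = float(ys_smooth[apex_s])
    found = height > 0 and (
        noise_sd == 0 or detect_height >= SNR_DETECTION * noise_sd
    )
    if noise_sd > 0:
        snr = max(height, 0.0) / noise_sd
    else:
        snr = math.inf if height > 0 else 0.0

    if not found:
        return PeakResult(
            analyte=trace.analyte,
            channel_role=trace.channel_role,
            retention_time=float(tw[apex]),
            height=max(height, 0.0),
            area=0.0,
            width_at_half_height=float("nan"),
            noise_sd=noise_sd,
            snr=snr,
            found=False,
        )

    # sub-grid apex position by parabolic interpolation
    rt = float(tw[apex])
    if 0 < apex < ys.size - 1:
        y0, y1, y2 = ys[apex - 1], ys[apex], ys[apex + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            rt += 0.5 * (y0 - y2) / denom * (tw[1] - tw[0])

    half = height / 2.0
    left_t = tw[0]
    for i in range(apex, 0, -1):
        if ys[i - 1] < half <= ys[i]:
            left_t = _interp_crossing(tw[i - 1], ys[i - 1], tw[i], ys[i], half)
            break
    right_t = tw[-1]
    for i in range(apex, ys.size - 1):
        if ys[i + 1] < half <= ys[i]:
            right_t = _interp_crossing(tw[i], ys[i], tw[i + 1], ys[i + 1], half)
            break
    width = float(right_t - left_t)

    thr = descent_fraction * height
    lo = apex
    while lo > 0 and not (ys[lo] <= thr and ys[lo - 1] >= ys[lo]):
        lo -= 1
    hi = apex
    while hi < ys.size - 1 and not (ys[hi] <= thr and ys[hi + 1] >= ys[hi]):
        hi += 1
    area = float(max(np.trapezoid(ys[lo : hi + 1], tw[lo : hi + 1]), 0.0))

    return PeakResult(
        analyte=trace.analyte,
        channel_role=trace.channel_role,
        retention_time=rt,
        height=height,
        area=area,
        width_at_half_height=width,
        noise_sd=noise_sd,
        snr=snr,
        found=True,
    )


def fit_calibration(
    levels: list[tuple[float, float]],
    weighting: str = "none",
    analyte: str = "",
) -> CalibrationFit:
    """Least-squares line of response ratio on nominal concentration.

    The blank level (0 uM) is excluded: with the log-spaced design it
    would otherwise dominate leverage, and it serves the carryover/LOD
    logic instead.  ``weighting='1/x'`` down-weights high levels.
    """
    if weighting not in {"none", "1/x"}:
        raise ValueError(f"unknown weighting {weighting!r}")
    pts = [(float(c), float(r)) for c, r in levels if c > 0]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 non-zero calibration levels, got {len(pts)}")
    x = np.array([p[0] for p in pts])
    r = np.array([p[1] for p in pts])
    if np.ptp(r) == 0:
        raise ValueError("all calibration responses identical; cannot fit")
    w = 1.0 / x if weighting == "1/x" else np.ones_like(x)
    W = np.sum(w)
    xbar = np.sum(w * x) / W
    rbar = np.sum(w * r) / W
    sxx = np.sum(w * (x - xbar) ** 2)
    slope = float(np.sum(w * (x - xbar) * (r - rbar)) / sxx)
    intercept = float(rbar - slope * xbar)
    pred = slope * x + intercept
    ss_res = float(np.sum((r - pred) ** 2))
    ss_tot = float(np.sum((r - np.mean(r)) ** 2))
    r_squared = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return CalibrationFit(
        analyte=analyte,
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        weighting=weighting,
        level_range_used=(float(x.min()), float(x.max())),
    )


def quantify(
    analyte_peak: PeakResult, is_peak: PeakResult, fit: CalibrationFit
) -> QuantReadout:
    """Invert the calibration line for one analyte/IS peak pair."""
    if not is_peak.found:
        raise InjectionError(
            f"{analyte_peak.analyte}: internal-standard peak missing; injection failed"
        )
    if not analyte_peak.found:
        return QuantReadout(value_um=0.0, below_lod=True)
    ratio = analyte_peak.area / is_peak.area
    return QuantReadout(
        value_um=max((ratio - fit.intercept) / fit.slope, 0.0), below_lod=False
    )


def carryover_check(
    blank_traces: list[ChromatogramTrace], registry: PanelRegistry
) -> dict[str, bool]:
    """Pass per analyte iff no peak (S/N >= 3) appears in a blank."""
    by_analyte = {
        tr.analyte: tr for tr in blank_traces if tr.channel_role == "quantifier"
    }
    out: dict[str, bool] = {}
    for analyte, trace in by_analyte.items():
        rt = registry.analytes[analyte].retention_time
        out[analyte] = not integrate_peak(trace, rt).found
    return out


# -- run-level conveniences ---------------------------------------------------


def _trace_index(traces: list[ChromatogramTrace]) -> dict[tuple[str, str, str], ChromatogramTrace]:
    return {(tr.analyte, tr.channel_role, tr.esi_mode): tr for tr in traces}


def calibrate_from_series(
    series: list[tuple[object, list[ChromatogramTrace]]],
    registry: PanelRegistry,
    weighting: str = "none",
) -> dict[str, CalibrationFit]:
    """Integrate a generated calibrator series and fit every analyte."""
    ratios: dict[str, list[tuple[float, float]]] = {}
    for design, traces in series:
        idx = _trace_index(traces)
        for analyte in registry.measured_analytes:
            if analyte not in design.concentrations:
                continue
            nominal = design.concentrations[analyte]
            if nominal <= 0:
                continue
            adef = registry.analytes[analyte]
            quant_t = adef.quantifier()
            a_tr = idx[(analyte, "quantifier", quant_t.esi_mode)]
            is_def = registry.analytes[adef.internal_standard]
            is_tr = idx[(is_def.name, "IS-quantifier", quant_t.esi_mode)]
            a_peak = integrate_peak(a_tr, adef.retention_time)
            is_peak = integrate_peak(is_tr, is_def.retention_time)
            if not (a_peak.found and is_peak.found):
                continue
            ratios.setdefault(analyte, []).append((nominal, a_peak.area / is_peak.area))
    return {
        analyte: fit_calibration(levels, weighting=weighting, analyte=analyte)
        for analyte, levels in ratios.items()
        if len([l for l in levels if l[0] > 0]) >= 3
    }


def quantify_sample(
    traces: list[ChromatogramTrace],
    registry: PanelRegistry,
    fits: dict[str, CalibrationFit],
) -> list[dict]:
    """Quantify every fitted analyte in one sample's traces.

    Returns one record per analyte with the readout (pre-preparation
    scale), S/N and QC flags (below-LOD, qualifier ion-ratio failures).
    """
    idx = _trace_index(traces)
    records: list[dict] = []
    for analyte, fit in sorted(fits.items()):
        adef = registry.analytes[analyte]
        quant_t = adef.quantifier()
        key = (analyte, "quantifier", quant_t.esi_mode)
        if key not in idx:
            continue
        a_peak = integrate_peak(idx[key], adef.retention_time)
        is_def = registry.analytes[adef.internal_standard]
        is_peak = integrate_peak(
            idx[(is_def.name, "IS-quantifier", quant_t.esi_mode)],
            is_def.retention_time,
        )
        readout = quantify(a_peak, is_peak, fit)
        flags = []
        if readout.below_lod:
            flags.append("below_lod")
        qual_key = (analyte, "qualifier", quant_t.esi_mode)
        if a_peak.found and qual_key in idx:
            q_peak = integrate_peak(idx[qual_key], adef.retention_time)
            if q_peak.found and a_peak.area > 0:
                ion_ratio = q_peak.area / a_peak.area
                if abs(ion_ratio / QUALIFIER_ION_RATIO - 1.0) > ION_RATIO_TOLERANCE:
                    flags.append("ion_ratio_out")
        records.append(
            {
                "sample": traces[0].sample_label if traces else "",
                "analyte": analyte,
                "readout_uM": readout.value_um,
                "snr": a_peak.snr,
                "flags": ";".join(flags),
            }
        )
    return records
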