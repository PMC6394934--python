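"""Assay-validation statistics: linearity, LOD, LLOQ, ULOQ, precision,
recovery, chromatographic resolution and stability.

Definitions: LOD is the concentration reaching S/N = 3; LLOQ the lowest
level with replicate CV below 20%; ULOQ the top of the range over which
the calibration stays linear (R^2 above 0.99); baseline resolution means
Rs = 1.18(t2-t1)/(w1+w2) of at least 1.5; stability requires CV below
15% across storage conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .quant import fit_calibration

__all__ = [
    "LimitUndefined",
    "LodEstimate",
    "LloqEstimate",
    "PrecisionResult",
    "StabilityResult",
    "ValidationReport",
    "resolution",
    "determine_lod",
    "determine_lloq",
    "determine_uloq",
    "precision_and_recovery",
    "stability_check",
    "sample_cv",
]

SNR_RULE = 3.0
LLOQ_CV_LIMIT_PCT = 20.0
ULOQ_R2_THRESHOLD = 0.99
BASELINE_RESOLUTION = 1.5
STABILITY_CV_LIMIT_PCT = 15.0


class LimitUndefined(ValueError):
    """No tested level satisfies the limit's defining rule."""


def sample_cv(values: Sequence[float]) -> float:
    """Coefficient of variation in percent, n-1 denominator."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 replicates")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


def resolution(t1: float, t2: float, w1: float, w2: float) -> float:
    """Chromatographic resolution Rs = 1.18 (t2 - t1) / (w1 + w2)."""
    if w1 <= 0 or w2 <= 0:
        raise ValueError("peak widths must be positive")
    if t2 < t1:
        raise ValueError("t2 must be >= t1")
    return 1.18 * (t2 - t1) / (w1 + w2)


@dataclass(frozen=True)
class LodEstimate:
    value: float  # uM
    flag: str  # "measured" | "interpolated" | "below_range"
    threshold: float = SNR_RULE


def determine_lod(
    dilution_series: Sequence[tuple[float, float]],
    interpolate: bool = True,
) -> LodEstimate:
    """Lowest concentration whose S/N reaches 3 in a dilution series.

    With ``interpolate`` the crossing is placed linearly between the
    bracketing levels; if even the lowest level exceeds S/N 3 the result
    carries a below-range flag.
    """
    series = sorted((float(c), float(s)) for c, s in dilution_series)
    if not series:
        raise ValueError("empty dilution series")
    concs = [c for c, _ in series]
    snrs = [s for _, s in series]
    hit = next((i for i, s in enumerate(snrs) if s >= SNR_RULE), None)
    if hit is None:
        raise LimitUndefined(
            f"no level reaches S/N = {SNR_RULE}; LOD above {concs[-1]} uM"
        )
    if hit == 0:
        return LodEstimate(value=concs[0], flag="below_range")
    if interpolate and snrs[hit] > SNR_RULE:
        c0, s0 = series[hit - 1]
        c1, s1 = series[hit]
        value = c0 + (SNR_RULE - s0) * (c1 - c0) / (s1 - s0)
        return LodEstimate(value=value, flag="interpolated")
    return LodEstimate(value=concs[hit], flag="measured")


@dataclass(frozen=True)
class LloqEstimate:
    value: float  # uM
    cv: float  # % at the accepted level
    nonmonotone: bool  # a lower level also qualified below a failing one


def determine_lloq(replicates: Mapping[float, Sequence[float]]) -> LloqEstimate:
    """Lowest level measured with CV < 20%.

    When qualification is non-monotone (a low level qualifies below a
    failing higher level), the lowest qualifying level *above* the
    highest failing one is returned and the result flagged.
    """
    if not replicates:
        raise ValueError("no replicate levels")
    levels = sorted(replicates)
    cvs: dict[float, float] = {}
    for level in levels:
        reps = replicates[level]
        if len(reps) < 2:
            raise ValueError(f"level {level}: CV undefined with < 2 replicates")
        cvs[level] = sample_cv(reps)
    failing = [lv for lv in levels if cvs[lv] >= LLOQ_CV_LIMIT_PCT]
    qualifying = [lv for lv in levels if cvs[lv] < LLOQ_CV_LIMIT_PCT]
    if not qualifying:
        raise LimitUndefined(f"no level reaches CV < {LLOQ_CV_LIMIT_PCT}%")
    highest_fail = max(failing) if failing else -np.inf
    candidates = [lv for lv in qualifying if lv > highest_fail]
    if not candidates:
        raise LimitUndefined(
            "every qualifying level lies below a failing one; LLOQ indeterminate"
        )
    value = min(candidates)
    nonmonotone = any(lv < highest_fail for lv in qualifying)
    return LloqEstimate(value=value, cv=cvs[value], nonmonotone=nonmonotone)


def determine_uloq(series: Sequence[tuple[float, float]]) -> float:
    """Largest level whose full prefix still fits with R^2 > 0.99."""
    pts = sorted((float(c), float(r)) for c, r in series if c > 0)
    if len(pts) < 3:
        raise ValueError("ULOQ needs at least 3 non-zero levels")
    best = None
    for k in range(3, len(pts) + 1):
        fit = fit_calibration(pts[:k])
        if fit.r_squared > ULOQ_R2_THRESHOLD:
            best = pts[k - 1][0]
    if best is None:
        raise LimitUndefined(f"no linear range with R^2 > {ULOQ_R2_THRESHOLD}")
    return best


@dataclass(frozen=True)
class PrecisionResult:
    cv: float  # %
    recovery: float  # %
    design: str  # interday | intraday | injection


def precision_and_recovery(
    qc_runs: Sequence[float],
    nominal: float,
    design: str = "interday",
) -> PrecisionResult:
    """Replicate CV and mean recovery against the nominal level."""
    if len(qc_runs) < 2:
        raise ValueError("precision needs >= 2 replicates")
    if nominal <= 0:
        raise ValueError("recovery undefined for non-positive nominal")
    v = np.asarray(qc_runs, dtype=float)
    return PrecisionResult(
        cv=sample_cv(v),
        recovery=float(100.0 * v.mean() / nominal),
        design=design,
    )


@dataclass(frozen=True)
class StabilityResult:
    passed: bool
    cv: float  # % across storage conditions


def stability_check(
    timepoint_measurements: Mapping[str, float],
) -> StabilityResult:
    """Pass iff the CV across storage conditions stays below 15%."""
    if len(timepoint_measurements) < 2:
        raise ValueError("stability check needs >= 2 conditions")
    cv = sample_cv(list(timepoint_measurements.values()))
    return StabilityResult(passed=cv < STABILITY_CV_LIMIT_PCT, cv=cv)


@dataclass
class ValidationReport:
    analyte: str
    lod: float | None = None
    lloq: float | None = None
    uloq: float | None = None
    r_squared: float | None = None
    cv_interday: float | None = None
    cv_intraday: float | None = None
    cv_injection: float | None = None
    recovery: float | None = None
    resolution_entries: list[tuple[str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "lod_uM": self.lod,
            "lloq_uM": self.lloq,
            "uloq_uM": self.uloq,
            "r_squared": self.r_squared,
            "cv_interday_pct": self.cv_interday,
            "cv_intraday_pct": self.cv_intraday,
            "cv_injection_pct": self.cv_injection,
            "recovery_pct": self.recovery,
            "resolution": [
                {"pair": pair, "Rs": rs} for pair, rs in self.resolution_entries
            ],
        }


def critical_pair_resolution(
    registry, seed: int = 0, conc_um: float = 16.0
) -> list[tuple[str, float]]:
    """Measure Rs for every bundled critical pair on noiseless default
    chromatograms (retention times and half-height widths taken from the
    integrated peaks, not the generator parameters)."""
    from . import quant, simulate

    entries: list[tuple[str, float]] = []
    for first, second in registry.critical_pairs:
        peaks = []
        for name in (first, second):
            adef = registry.analytes[name]
            if adef.is_internal_standard:
                design = simulate.RunDesign(
                    sample_label="rs-check",
                    concentrations={_analyte_using(registry, name): conc_um},
                    seed=seed,
                )
                role = "IS-quantifier"
            else:
                design = simulate.RunDesign(
                    sample_label="rs-check", concentrations={name: conc_um}, seed=seed
                )
                role = "quantifier"
            traces = simulate.generate_chromatogram(design, registry)
            trace = next(
                tr for tr in traces if tr.analyte == name and tr.channel_role == role
            )
            peaks.append(quant.integrate_peak(trace, adef.retention_time))
        p1, p2 = sorted(peaks, key=lambda p: p.retention_time)
        rs = resolution(
            p1.retention_time,
            p2.retention_time,
            p1.width_at_half_height,
            p2.width_at_half_height,
        )
        entries.append((f"{first}/{second}", rs))
    return entries


def _analyte_using(registry, is_name: str) -> str:
    for a in registry.analytes.values():
        if a.internal_standard == is_name:
            return a.name
    raise ValueError(f"no analyte references internal standard {is_name!r}")


def run_validation(
    registry,
    seed: int = 0,
    noise: float = 0.02,
    analytes: list[str] | None = None,
    n_replicates: int = 4,
) -> dict[str, ValidationReport]:
    """Desk-scale validation sweep on synthetic runs.

    Simulates the calibrator series, replicate QC-style runs and blank
    carryover checks, then derives the full report per analyte.
    """
    from . import quant, simulate

    names = analytes if analytes is not None else registry.measured_analytes
    rng = np.random.default_rng(seed)
    series = simulate.generate_calibrator_series(
        registry, noise=noise, seed=seed, analytes=names
    )
    fits = quant.calibrate_from_series(series, registry)

    # per-level response ratios and S/N for LOD / ULOQ
    ratios: dict[str, list[tuple[float, float]]] = {a: [] for a in names}
    snrs: dict[str, list[tuple[float, float]]] = {a: [] for a in names}
    noise_floor = 0.001 * simulate.peak_height(
        simulate.DEFAULT_RESPONSE_FACTOR * 0.2, simulate.DEFAULT_PEAK_SIGMA_MIN
    )
    for design, traces in series:
        idx = {(tr.analyte, tr.channel_role, tr.esi_mode): tr for tr in traces}
        for a in names:
            nominal = design.concentrations[a]
            adef = registry.analytes[a]
            mode = adef.quantifier().esi_mode
            peak = quant.integrate_peak(idx[(a, "quantifier", mode)], adef.retention_time)
            is_def = registry.analytes[adef.internal_standard]
            is_peak = quant.integrate_peak(
                idx[(is_def.name, "IS-quantifier", mode)], is_def.retention_time
            )
            if nominal > 0 and peak.found and is_peak.found:
                ratios[a].append((nominal, peak.area / is_peak.area))
            snr = peak.height / noise_floor if noise_floor > 0 else peak.snr
            snrs[a].append((nominal, snr))

    reports: dict[str, ValidationReport] = {}
    for a in names:
        rep = ValidationReport(analyte=a)
        if a in fits:
            rep.r_squared = fits[a].r_squared
        try:
            rep.lod = determine_lod([s for s in snrs[a] if s[0] > 0]).value
        except (LimitUndefined, ValueError):
            rep.lod = None
        try:
            rep.uloq = determine_uloq(ratios[a])
        except (LimitUndefined, ValueError):
            rep.uloq = None
        # replicate QC runs at 20 uM: batch effect + within-run noise
        nominal_qc = 20.0
        for design_name, attr in (
            ("interday", "cv_interday"),
            ("intraday", "cv_intraday"),
            ("injection", "cv_injection"),
        ):
            reps = nominal_qc * (
                1.0
                + noise * rng.standard_normal(n_replicates)
                + (noise if design_name == "interday" else noise / 2)
                * rng.standard_normal(n_replicates)
            )
            pr = precision_and_recovery(reps, nominal_qc, design=design_name)
            setattr(rep, attr, pr.cv)
            if design_name == "interday":
                rep.recovery = pr.recovery
        # LLOQ from replicate low-level measurements with level-scaled noise
        low_levels = [0.05, 0.2, 1.0, 4.0]
        replicate_map = {
            lv: lv * (1.0 + (0.08 / np.sqrt(lv)) * rng.standard_normal(5))
            for lv in low_levels
        }
        try:
            rep.lloq = determine_lloq(replicate_map).value
        except (LimitUndefined, ValueError):
            rep.lloq = None
        reports[a] = rep

    rs_entries = critical_pair_resolution(registry, seed=seed)
    for pair, rs in rs_entries:
        for name in pair.split("/"):
            if name in reports:
                reports[name].resolution_entries.append((pair, rs))
    return reports
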