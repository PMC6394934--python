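"""Synthetic input generation: chromatograms, calibrator series,
reference cohorts and pathological patient profiles.

All generators are deterministic for a fixed seed.  Peak shapes, noise
levels, response factors and cohort distributions are fixture choices
documented here, not measured values.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import prep
from .diagnose import UrineProfile
from .panel import PanelRegistry, get_cutoff

__all__ = [
    "ChromatogramTrace",
    "RunDesign",
    "CohortModel",
    "CohortSpec",
    "generate_chromatogram",
    "generate_calibrator_series",
    "default_cohort_spec",
    "generate_cohort",
    "generate_patient_profile",
    "CALIBRATOR_NOMINALS_UM",
]

# -- defaults (fictional but fixed; see module docstring) --------------------
DEFAULT_PEAK_SIGMA_MIN = 0.05
DEFAULT_RESPONSE_FACTOR = 5.0e4  # counts*min per vial uM
QUALIFIER_ION_RATIO = 0.35  # qualifier / quantifier response
IS_VIAL_UM = 5.0  # every prepared sample carries 5 uM IS
TIME_START_MIN, TIME_END_MIN, TIME_STEP_MIN = 0.0, 10.0, 0.005

#: Pre-preparation calibrator concentrations, Cal01..Cal10 (uM):
#: a blank, then doubling from 1 uM.
CALIBRATOR_NOMINALS_UM = (0.0, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0, 256.0)

AGE_BINS = ((0.0, 1.0), (1.0, 3.0), (3.0, 6.0), (6.0, 18.0))

# Upper-quantile z-score tying the default cohort's 97.5th percentile to
# the registry cutoff when the median sits at median_fraction * cutoff.
_Z_975 = 1.959963984540054


@dataclass
class ChromatogramTrace:
    """One acquired MRM channel: uniform time grid plus intensities."""

    sample_label: str
    analyte: str
    channel_role: str  # quantifier | qualifier | IS-quantifier | IS-qualifier
    esi_mode: str
    times: np.ndarray  # minutes, strictly increasing, uniform step
    intensities: np.ndarray  # counts >= 0


@dataclass
class RunDesign:
    """Everything needed to synthesise one injection."""

    sample_label: str
    concentrations: Mapping[str, float]  # analyte -> uM, pre-preparation scale
    noise_sd: float = 0.0  # additive baseline noise (counts)
    response_factor: float | Mapping[str, float] = DEFAULT_RESPONSE_FACTOR
    peak_sigma: float = DEFAULT_PEAK_SIGMA_MIN
    amplitude_cv: float = 0.0  # multiplicative per-analyte response jitter
    seed: int = 0

    def rf(self, analyte: str) -> float:
        if isinstance(self.response_factor, Mapping):
            return float(self.response_factor[analyte])
        return float(self.response_factor)


def _validate_design(design: RunDesign) -> None:
    for analyte, conc in design.concentrations.items():
        if conc < 0:
            raise ValueError(f"{analyte}: negative concentration {conc}")
        if design.rf(analyte) <= 0:
            raise ValueError(f"{analyte}: response factor must be positive")
    if design.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")


def _gaussian(times: np.ndarray, rt: float, sigma: float, height: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((times - rt) / sigma) ** 2)


def peak_height(area: float, sigma: float) -> float:
    """Apex height of a Gaussian peak with the given area and sigma."""
    return area / (sigma * np.sqrt(2.0 * np.pi))


def generate_chromatogram(
    design: RunDesign,
    registry: PanelRegistry,
    time_start: float = TIME_START_MIN,
    time_end: float = TIME_END_MIN,
    time_step: float = TIME_STEP_MIN,
) -> list[ChromatogramTrace]:
    """Synthesise all MRM channels for one injection.

    Analyte channels carry one Gaussian peak at the registry retention
    time with area = response_factor x vial concentration (vial = 1/5 of
    the pre-preparation scale); qualifier channels at a fixed 0.35 ion
    ratio; IS channels always peak at the 5 uM response.  Additive
    Gaussian baseline noise is truncated at zero counts.
    """
    _validate_design(design)
    for analyte in design.concentrations:
        if analyte not in registry.analytes:
            raise KeyError(f"unknown analyte in design: {analyte!r}")
    rng = np.random.default_rng(design.seed)
    times = np.arange(time_start, time_end + 0.5 * time_step, time_step)
    traces: list[ChromatogramTrace] = []

    def emit(name: str, role: str, mode: str, signal: np.ndarray) -> None:
        if design.noise_sd > 0:
            signal = signal + rng.normal(0.0, design.noise_sd, signal.shape)
        traces.append(
            ChromatogramTrace(
                sample_label=design.sample_label,
                analyte=name,
                channel_role=role,
                esi_mode=mode,
                times=times,
                intensities=np.clip(signal, 0.0, None),
            )
        )

    is_needed: set[str] = set()
    for analyte in sorted(design.concentrations):
        adef = registry.analytes[analyte]
        if adef.is_internal_standard:
            raise ValueError(f"{analyte}: design concentrations must be non-IS analytes")
        if adef.internal_standard:
            is_needed.add(adef.internal_standard)
        vial_um = design.concentrations[analyte] * prep.CALIBRATOR_DILUTION
        area = design.rf(analyte) * vial_um
        if design.amplitude_cv > 0:
            area *= max(0.0, 1.0 + design.amplitude_cv * rng.standard_normal())
        height = peak_height(area, design.peak_sigma)
        for t in adef.transitions:
            scale = 1.0 if t.role == "quantifier" else QUALIFIER_ION_RATIO
            emit(
                analyte,
                t.role,
                t.esi_mode,
                _gaussian(times, adef.retention_time, design.peak_sigma, height * scale),
            )

    for is_name in sorted(is_needed):
        isdef = registry.analytes[is_name]
        area = design.rf(is_name) if isinstance(design.response_factor, Mapping) else (
            float(design.response_factor)
        )
        area *= IS_VIAL_UM
        height = peak_height(area, design.peak_sigma)
        for t in isdef.transitions:
            scale = 1.0 if t.role == "quantifier" else QUALIFIER_ION_RATIO
            emit(
                is_name,
                "IS-quantifier" if t.role == "quantifier" else "IS-qualifier",
                t.esi_mode,
                _gaussian(times, isdef.retention_time, design.peak_sigma, height * scale),
            )
    return traces


def generate_calibrator_series(
    registry: PanelRegistry,
    noise: float = 0.0,
    seed: int = 0,
    analytes: list[str] | None = None,
    noise_sd: float = 0.0,
    **chromatogram_kwargs,
) -> list[tuple[RunDesign, list[ChromatogramTrace]]]:
    """Build the 10-level calibrator series (blank + doubling to 256 uM).

    ``noise`` is the multiplicative response jitter (fraction, e.g. 0.02
    for 2%); ``noise_sd`` adds baseline noise in counts.
    """
    if noise < 0:
        raise ValueError("noise fraction must be >= 0")
    names = analytes if analytes is not None else registry.measured_analytes
    seeds = np.random.SeedSequence(seed).spawn(len(CALIBRATOR_NOMINALS_UM))
    out = []
    for level, (conc, ss) in enumerate(zip(CALIBRATOR_NOMINALS_UM, seeds), start=1):
        design = RunDesign(
            sample_label=f"Cal{level:02d}",
            concentrations={a: conc for a in names},
            noise_sd=noise_sd,
            amplitude_cv=noise,
            seed=ss.generate_state(1)[0],
        )
        out.append((design, generate_chromatogram(design, registry, **chromatogram_kwargs)))
    return out


@dataclass(frozen=True)
class CohortModel:
    """Log-normal excretion model for one analyte.

    value = median * age_multiplier[bin] * exp(sigma_log * z).  A zero
    model (drug channels) always yields 0.
    """

    median: float  # mmol/mol creatinine
    sigma_log: float
    age_multipliers: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    zero: bool = False


@dataclass
class CohortSpec:
    n: int
    seed: int
    models: dict[str, CohortModel]
    age_bins: tuple[tuple[float, float], ...] = AGE_BINS
    age_weights: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        for name, m in self.models.items():
            if m.sigma_log < 0 or m.median < 0:
                raise ValueError(f"{name}: cohort model parameters must be >= 0")


def default_cohort_spec(
    registry: PanelRegistry,
    n: int = 251,
    seed: int = 0,
    median_fraction: float = 0.25,
    sigma_log: float | None = None,
    age_effects: Mapping[str, tuple[float, float, float, float]] | None = None,
) -> CohortSpec:
    """Cohort spec whose per-analyte medians sit at ``median_fraction`` of
    the (older age group) cutoff; with the default sigma the marginal
    97.5th percentile then lands on the cutoff itself.
    """
    if sigma_log is None:
        sigma_log = float(np.log(1.0 / median_fraction) / _Z_975)
    models: dict[str, CohortModel] = {}
    for analyte in registry.measured_analytes:
        rc = get_cutoff(registry, analyte, 10.0)
        if rc.detection_is_abnormal:
            models[analyte] = CohortModel(median=0.0, sigma_log=0.0, zero=True)
            continue
        mult = tuple(age_effects.get(analyte, (1.0,) * 4)) if age_effects else (1.0,) * 4
        models[analyte] = CohortModel(
            median=rc.upper * median_fraction,
            sigma_log=sigma_log,
            age_multipliers=mult,
        )
    return CohortSpec(n=n, seed=seed, models=models)


def _draw_ages(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    bins = rng.choice(len(spec.age_bins), size=spec.n, p=np.asarray(spec.age_weights))
    lo = np.array([spec.age_bins[b][0] for b in bins])
    hi = np.array([spec.age_bins[b][1] for b in bins])
    return lo + rng.random(spec.n) * (hi - lo)


def _age_bin_index(ages: np.ndarray, bins: tuple[tuple[float, float], ...]) -> np.ndarray:
    idx = np.full(len(ages), len(bins) - 1, dtype=int)
    for i, (lo, hi) in enumerate(bins[:-1]):
        idx[(ages >= lo) & (ages < hi)] = i
    return idx


def generate_cohort(spec: CohortSpec, registry: PanelRegistry) -> pd.DataFrame:
    """Draw a cohort table: one row per (sample, analyte), long format."""
    for analyte in spec.models:
        if analyte not in registry.analytes:
            raise KeyError(f"unknown analyte in cohort spec: {analyte!r}")
    rng = np.random.default_rng(spec.seed)
    ages = _draw_ages(spec, rng)
    bin_idx = _age_bin_index(ages, spec.age_bins)
    sample_ids = [f"S{i + 1:04d}" for i in range(spec.n)]
    frames = []
    for analyte in sorted(spec.models):
        m = spec.models[analyte]
        if m.zero:
            values = np.zeros(spec.n)
        else:
            mult = np.array(m.age_multipliers)[bin_idx]
            values = m.median * mult * np.exp(m.sigma_log * rng.standard_normal(spec.n))
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sample_ids,
                    "age_years": ages,
                    "analyte": analyte,
                    "value_mmol_per_mol": values,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _stable_code_seed(seed: int, code: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([seed, zlib.crc32(code.encode())])


def generate_patient_profile(
    disorder_code: str,
    fold: float,
    age: float,
    registry: PanelRegistry,
    seed: int = 0,
    with_allopurinol: bool = False,
    cohort_spec: CohortSpec | None = None,
) -> UrineProfile:
    """One pathological urine profile for a signature disorder.

    Required-high markers sit exactly at ``fold`` x their age-resolved
    upper cutoff; required-low markers below the lower bound; everything
    else is a draw from the normal cohort model.
    """
    if disorder_code not in registry.signatures:
        raise KeyError(f"unknown disorder code: {disorder_code!r}")
    if fold < 1:
        raise ValueError(f"fold must be >= 1, got {fold}")
    sig = registry.signatures[disorder_code]
    ss = _stable_code_seed(seed, disorder_code)
    spec = cohort_spec or default_cohort_spec(
        registry, n=1, seed=int(ss.generate_state(1)[0])
    )
    rng = np.random.default_rng(int(ss.generate_state(2)[1]))
    bin_idx = int(_age_bin_index(np.array([age]), spec.age_bins)[0])
    values: dict[str, float] = {}
    for analyte in sorted(spec.models):
        m = spec.models[analyte]
        if m.zero:
            values[analyte] = 0.0
        else:
            values[analyte] = float(
                m.median
                * m.age_multipliers[bin_idx]
                * np.exp(m.sigma_log * rng.standard_normal())
            )
    for marker in sorted(sig.required_high):
        rc = get_cutoff(registry, marker, age)
        if rc.detection_is_abnormal or rc.upper is None:
            values[marker] = 50.0  # any detectable amount is pathological
        else:
            values[marker] = fold * rc.upper
    for marker in sorted(sig.required_low):
        rc = get_cutoff(registry, marker, age)
        if rc.lower is not None:
            values[marker] = rc.lower / fold
    if with_allopurinol:
        values["Allopurinol"] = 50.0
    return UrineProfile(
        sample_id=f"SYN-{disorder_code}",
        age=age,
        values=values,
        allopurinol_detected=with_allopurinol,
    )
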