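"""Fold-over-cutoff computation and rule-based disorder screening.

A urine profile (analyte -> mmol/mol creatinine) is compared against the
age-resolved cutoffs; disorder signatures then match on the pattern of
elevations.  Calls are ranked, and drug confounds (allopurinol elevating
orotidine/orotic acid) are annotated before reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .panel import PanelRegistry, get_cutoff, AGE_MAX

__all__ = [
    "UrineProfile",
    "FoldResult",
    "DisorderCall",
    "fold_over_cutoff",
    "classify",
    "flag_confounds",
    "screen",
]

#: Analytes whose elevation is explained by allopurinol treatment.
ALLOPURINOL_CONFOUNDED = frozenset({"Orotidine", "Orotic acid"})


@dataclass(frozen=True)
class UrineProfile:
    sample_id: str
    age: float  # years
    values: dict[str, float]  # analyte -> mmol/mol creatinine
    allopurinol_detected: bool = False


@dataclass(frozen=True)
class FoldResult:
    analyte: str
    value: float
    fold: float | None  # value / upper cutoff; None for detection-is-abnormal analytes
    direction: str  # "high" | "low" | "normal" | "detected" | "not_detected"


@dataclass(frozen=True)
class DisorderCall:
    code: str
    matched_required: frozenset[str]
    matched_optional: frozenset[str]
    max_fold: float
    confounds: tuple[str, ...] = ()
    rank: int = 0

    def to_dict(self) -> dict:
        return {
            "code": self.code,
            "matched_required": sorted(self.matched_required),
            "matched_optional": sorted(self.matched_optional),
            "max_fold": self.max_fold,
            "confounds": list(self.confounds),
            "rank": self.rank,
        }


def _effective_age(profile: UrineProfile) -> float:
    if profile.age < 0:
        raise ValueError(f"{profile.sample_id}: negative age {profile.age}")
    if profile.age > AGE_MAX:
        warnings.warn(
            f"{profile.sample_id}: age {profile.age} y above the pediatric "
            f"reference range; applying the oldest age group's cutoffs",
            stacklevel=3,
        )
        return AGE_MAX
    return profile.age


def fold_over_cutoff(
    profile: UrineProfile, registry: PanelRegistry
) -> dict[str, FoldResult]:
    """How many times each analyte exceeds its age-resolved cutoff.

    Detection-is-abnormal analytes (no numeric cutoff) are flagged
    ``detected`` whenever any amount is present.  Analytes missing from
    the profile are omitted with a warning.
    """
    age = _effective_age(profile)
    out: dict[str, FoldResult] = {}
    for analyte in registry.cutoffs:
        if analyte not in profile.values:
            warnings.warn(
                f"{profile.sample_id}: analyte {analyte!r} missing from profile",
                stacklevel=2,
            )
            continue
        value = profile.values[analyte]
        rc = get_cutoff(registry, analyte, age)
        if rc.detection_is_abnormal:
            out[analyte] = FoldResult(
                analyte, value, None, "detected" if value > 0 else "not_detected"
            )
            continue
        fold = value / rc.upper
        if fold > 1.0:
            direction = "high"
        elif rc.lower is not None and value < rc.lower:
            direction = "low"
        else:
            direction = "normal"
        out[analyte] = FoldResult(analyte, value, fold, direction)
    return out


def classify(profile: UrineProfile, registry: PanelRegistry) -> list[DisorderCall]:
    """Match disorder signatures against the fold map and rank the calls.

    A signature matches when every required-high marker exceeds its
    cutoff (fold > 1) and every required-low marker is below its lower
    bound.  Ranking: more matched required markers first, then larger
    maximum fold, then signature code (deterministic tie-break).
    """
    folds = fold_over_cutoff(profile, registry)
    high = {a for a, f in folds.items() if f.direction == "high"}
    low = {a for a, f in folds.items() if f.direction == "low"}
    calls: list[DisorderCall] = []
    for sig in registry.signatures.values():
        if not sig.required_high or not sig.required_high <= high:
            continue
        if not sig.required_low <= low:
            continue
        matched_optional = sig.optional_high & high
        marker_folds = [
            folds[a].fold for a in (sig.required_high | matched_optional) if folds[a].fold
        ]
        calls.append(
            DisorderCall(
                code=sig.code,
                matched_required=frozenset(sig.required_high),
                matched_optional=frozenset(matched_optional),
                max_fold=max(marker_folds),
            )
        )
    return _rank(calls)


def _rank(calls: list[DisorderCall]) -> list[DisorderCall]:
    ordered = sorted(
        calls, key=lambda c: (-len(c.matched_required), -c.max_fold, c.code)
    )
    return [replace(c, rank=i + 1) for i, c in enumerate(ordered)]


def flag_confounds(
    profile: UrineProfile,
    calls: list[DisorderCall],
    registry: PanelRegistry,
) -> list[DisorderCall]:
    """Annotate treatment-related elevations and drop calls they fully explain.

    Under allopurinol, orotidine and orotic acid accumulate as a drug
    effect; a call supported exclusively by those markers is withdrawn,
    and other calls matching them are annotated.
    """
    folds = fold_over_cutoff(profile, registry)
    allopurinol = profile.allopurinol_detected or (
        folds.get("Allopurinol") is not None
        and folds["Allopurinol"].direction == "detected"
    )
    if not allopurinol:
        return calls
    elevated = sorted(
        a
        for a in ALLOPURINOL_CONFOUNDED
        if a in folds and folds[a].direction == "high"
    )
    notes = tuple(
        f"{a} elevation may be allopurinol treatment-related" for a in elevated
    )
    kept: list[DisorderCall] = []
    for call in calls:
        if call.matched_required <= ALLOPURINOL_CONFOUNDED:
            continue  # elevation explained by treatment alone
        kept.append(replace(call, confounds=call.confounds + notes))
    return _rank(kept)


def screen(profile: UrineProfile, registry: PanelRegistry) -> list[DisorderCall]:
    """Classify then apply confound handling; the standard reporting path."""
    return flag_confounds(profile, classify(profile, registry), registry)
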