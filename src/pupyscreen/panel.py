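"""Machine-readable assay panel: analytes, MRM transitions, internal
standards, age-conditional cutoffs and disorder signatures.

The bundled panel ships as plain tab-separated text under
:mod:`pupyscreen.data` and is loaded with :func:`load_panel`.  All panel
semantics (who is an internal standard, which transition quantifies,
which cutoff applies at a given age) live here; downstream modules only
consume the resolved objects.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "TransitionDef",
    "AnalyteDef",
    "CutoffRule",
    "ResolvedCutoff",
    "DisorderSignature",
    "PanelRegistry",
    "PanelError",
    "CutoffLookupError",
    "load_panel",
    "write_panel",
    "validate_panel",
    "get_cutoff",
    "find_critical_pairs",
]

#: Half-width (min) of the acquisition window around each retention time;
#: the acquisition method records each channel over retention time +/- 1.5 min.
ACQUISITION_WINDOW_HALFWIDTH = 1.5

AGE_MIN, AGE_MAX = 0.0, 18.0


class PanelError(ValueError):
    """Fatal panel parse/validation problem."""


class CutoffLookupError(KeyError):
    """Unknown analyte or out-of-range age in a cutoff lookup."""


@dataclass(frozen=True)
class TransitionDef:
    """One MRM channel (parent -> daughter) with its source settings."""

    parent_mass: float
    daughter_mass: float
    esi_mode: str  # "positive" | "negative"
    role: str  # "quantifier" | "qualifier"
    cone_voltage: float
    collision_voltage: float


@dataclass(frozen=True)
class AnalyteDef:
    name: str
    compound_class: str  # "purine" | "pyrimidine"
    transitions: tuple[TransitionDef, ...]
    internal_standard: str | None
    is_internal_standard: bool
    retention_time: float
    acquisition_window_halfwidth: float = ACQUISITION_WINDOW_HALFWIDTH

    def quantifier(self, esi_mode: str | None = None) -> TransitionDef:
        cands = [
            t
            for t in self.transitions
            if t.role == "quantifier" and (esi_mode is None or t.esi_mode == esi_mode)
        ]
        if not cands:
            raise PanelError(f"{self.name}: no quantifier transition for mode {esi_mode!r}")
        return cands[0]

    @property
    def esi_modes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for t in self.transitions:
            if t.esi_mode not in seen:
                seen.append(t.esi_mode)
        return tuple(seen)


@dataclass(frozen=True)
class CutoffRule:
    """Decision limits for one analyte over [age_min, age_max).

    ``upper is None`` encodes a detection-is-abnormal analyte ("n.d.":
    any measurable amount is pathological, e.g. drug channels).
    """

    analyte: str
    age_min: float
    age_max: float
    upper: float | None
    lower: float | None = None

    @property
    def detection_is_abnormal(self) -> bool:
        return self.upper is None


@dataclass(frozen=True)
class ResolvedCutoff:
    analyte: str
    age: float
    upper: float | None
    lower: float | None
    detection_is_abnormal: bool


@dataclass(frozen=True)
class DisorderSignature:
    code: str
    name: str
    required_high: frozenset[str]
    optional_high: frozenset[str] = frozenset()
    required_low: frozenset[str] = frozenset()
    confound_notes: str = ""


@dataclass
class PanelRegistry:
    """In-memory registry of the whole assay panel."""

    analytes: dict[str, AnalyteDef]
    cutoffs: dict[str, tuple[CutoffRule, ...]] = field(default_factory=dict)
    signatures: dict[str, DisorderSignature] = field(default_factory=dict)
    critical_pairs: tuple[tuple[str, str], ...] = ()

    @property
    def measured_analytes(self) -> list[str]:
        return [a.name for a in self.analytes.values() if not a.is_internal_standard]

    @property
    def internal_standards(self) -> list[str]:
        return [a.name for a in self.analytes.values() if a.is_internal_standard]

    def analyte(self, name: str) -> AnalyteDef:
        try:
            return self.analytes[name]
        except KeyError:
            raise CutoffLookupError(f"unknown analyte: {name!r}") from None


def _bundled(name: str) -> Path:
    return Path(str(resources.files("pupyscreen.data").joinpath(name)))


def _parse_bool(s: str) -> bool:
    return str(s).strip().lower() in {"true", "1", "yes"}


def _read_tsv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise PanelError(f"{path}: empty panel file") from None
    if df.empty:
        raise PanelError(f"{path}: empty panel file")
    return df


def load_panel(
    path: str | Path = "bundled",
    cutoffs_path: str | Path | None = None,
    signatures_path: str | Path | None = None,
    critical_pairs_path: str | Path | None = None,
) -> PanelRegistry:
    """Load a panel from tab-separated text (or the bundled one).

    Raises :class:`PanelError` on any invariant violation, naming the
    offending analyte.
    """
    if path == "bundled":
        path = _bundled("panel.tsv")
        cutoffs_path = cutoffs_path or _bundled("cutoffs.tsv")
        signatures_path = signatures_path or _bundled("signatures.json")
        critical_pairs_path = critical_pairs_path or _bundled("critical_pairs.tsv")
    df = _read_tsv(Path(path))

    required_cols = {
        "analyte", "class", "is_internal_standard", "internal_standard",
        "esi_mode", "role", "parent_mz", "daughter_mz", "cone_v",
        "collision_v", "retention_time_min",
    }
    missing = required_cols - set(df.columns)
    if missing:
        raise PanelError(f"{path}: missing columns {sorted(missing)}")

    analytes: dict[str, AnalyteDef] = {}
    for name, grp in df.groupby("analyte", sort=False):
        transitions = tuple(
            TransitionDef(
                parent_mass=float(r.parent_mz),
                daughter_mass=float(r.daughter_mz),
                esi_mode=r.esi_mode,
                role=r.role,
                cone_voltage=float(r.cone_v),
                collision_voltage=float(r.collision_v),
            )
            for r in grp.itertuples()
        )
        is_is = _parse_bool(grp["is_internal_standard"].iloc[0])
        is_name = grp["internal_standard"].iloc[0].strip() or None
        analytes[str(name)] = AnalyteDef(
            name=str(name),
            compound_class=grp["class"].iloc[0],
            transitions=transitions,
            internal_standard=None if is_is else is_name,
            is_internal_standard=is_is,
            retention_time=float(grp["retention_time_min"].iloc[0]),
        )

    registry = PanelRegistry(analytes=analytes)

    if cutoffs_path is not None:
        registry.cutoffs = _load_cutoff_table(Path(cutoffs_path))
    if signatures_path is not None:
        registry.signatures = _load_signatures(Path(signatures_path))
    if critical_pairs_path is not None:
        cp = _read_tsv(Path(critical_pairs_path))
        registry.critical_pairs = tuple(
            (r.first, r.second) for r in cp.itertuples()
        )

    violations = validate_panel(registry)
    if violations:
        raise PanelError("; ".join(violations))
    return registry


def _load_cutoff_table(path: Path) -> dict[str, tuple[CutoffRule, ...]]:
    df = _read_tsv(path)
    rules: dict[str, list[CutoffRule]] = {}
    for r in df.itertuples():
        upper_raw = str(r.upper).strip()
        upper = None if upper_raw in {"n.d.", "nd", ""} else float(upper_raw)
        lower_raw = str(r.lower).strip()
        lower = float(lower_raw) if lower_raw else None
        rules.setdefault(r.analyte, []).append(
            CutoffRule(
                analyte=r.analyte,
                age_min=float(r.age_min),
                age_max=float(r.age_max),
                upper=upper,
                lower=lower,
            )
        )
    return {k: tuple(sorted(v, key=lambda c: c.age_min)) for k, v in rules.items()}


def _load_signatures(path: Path) -> dict[str, DisorderSignature]:
    raw = json.loads(Path(path).read_text())
    return {
        code: DisorderSignature(
            code=code,
            name=entry.get("name", code),
            required_high=frozenset(entry.get("required_high", [])),
            optional_high=frozenset(entry.get("optional_high", [])),
            required_low=frozenset(entry.get("required_low", [])),
            confound_notes=entry.get("confound_notes", ""),
        )
        for code, entry in raw.items()
    }


def write_panel(registry: PanelRegistry, directory: str | Path) -> dict[str, Path]:
    """Write a registry back to the documented delimited dialect.

    Returns the paths written; ``load_panel`` on them reproduces an
    equal registry (round-trip invariant).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    panel_rows = []
    for a in registry.analytes.values():
        for t in a.transitions:
            panel_rows.append(
                {
                    "analyte": a.name,
                    "class": a.compound_class,
                    "is_internal_standard": "true" if a.is_internal_standard else "false",
                    "internal_standard": a.internal_standard or "",
                    "esi_mode": t.esi_mode,
                    "role": t.role,
                    "parent_mz": f"{t.parent_mass:g}",
                    "daughter_mz": f"{t.daughter_mass:g}",
                    "cone_v": f"{t.cone_voltage:g}",
                    "collision_v": f"{t.collision_voltage:g}",
                    "retention_time_min": f"{a.retention_time:.3f}",
                }
            )
    paths = {"panel": directory / "panel.tsv"}
    pd.DataFrame(panel_rows).to_csv(paths["panel"], sep="\t", index=False)

    cutoff_rows = [
        {
            "analyte": rule.analyte,
            "age_min": f"{rule.age_min:g}",
            "age_max": f"{rule.age_max:g}",
            "lower": "" if rule.lower is None else f"{rule.lower:g}",
            "upper": "n.d." if rule.upper is None else f"{rule.upper:g}",
        }
        for rules in registry.cutoffs.values()
        for rule in rules
    ]
    paths["cutoffs"] = directory / "cutoffs.tsv"
    pd.DataFrame(
        cutoff_rows, columns=["analyte", "age_min", "age_max", "lower", "upper"]
    ).to_csv(paths["cutoffs"], sep="\t", index=False)

    sig_payload = {
        s.code: {
            "name": s.name,
            "required_high": sorted(s.required_high),
            "optional_high": sorted(s.optional_high),
            "required_low": sorted(s.required_low),
            "confound_notes": s.confound_notes,
        }
        for s in registry.signatures.values()
    }
    paths["signatures"] = directory / "signatures.json"
    paths["signatures"].write_text(json.dumps(sig_payload, indent=2) + "\n")

    paths["critical_pairs"] = directory / "critical_pairs.tsv"
    pd.DataFrame(
        [{"first": a, "second": b, "note": ""} for a, b in registry.critical_pairs],
        columns=["first", "second", "note"],
    ).to_csv(paths["critical_pairs"], sep="\t", index=False)
    return paths


def validate_panel(registry: PanelRegistry) -> list[str]:
    """Check every panel invariant; violations are returned, not raised."""
    out: list[str] = []
    for a in registry.analytes.values():
        for t in a.transitions:
            if not (t.parent_mass > t.daughter_mass > 0):
                out.append(f"{a.name}: parent mass must exceed daughter mass (> 0)")
            if t.cone_voltage <= 0 or t.collision_voltage <= 0:
                out.append(f"{a.name}: voltages must be positive")
            if t.esi_mode not in {"positive", "negative"}:
                out.append(f"{a.name}: unknown ESI mode {t.esi_mode!r}")
        for mode in a.esi_modes:
            n_quant = sum(
                1 for t in a.transitions if t.role == "quantifier" and t.esi_mode == mode
            )
            if n_quant != 1:
                out.append(
                    f"{a.name}: expected exactly one quantifier in ESI {mode}, found {n_quant}"
                )
        if a.is_internal_standard:
            if a.internal_standard is not None:
                out.append(f"{a.name}: internal standard must not reference another IS")
        else:
            if a.internal_standard is None:
                out.append(f"{a.name}: missing internal standard assignment")
            elif a.internal_standard not in registry.analytes:
                out.append(
                    f"{a.name}: internal standard {a.internal_standard!r} not in registry"
                )
            elif not registry.analytes[a.internal_standard].is_internal_standard:
                out.append(
                    f"{a.name}: assigned internal standard {a.internal_standard!r} "
                    "is not flagged as one"
                )
        if a.acquisition_window_halfwidth != ACQUISITION_WINDOW_HALFWIDTH:
            out.append(
                f"{a.name}: acquisition window halfwidth must be "
                f"{ACQUISITION_WINDOW_HALFWIDTH} min"
            )

    for analyte, rules in registry.cutoffs.items():
        if analyte not in registry.analytes:
            out.append(f"cutoff table references unknown analyte {analyte!r}")
        ordered = sorted(rules, key=lambda r: r.age_min)
        if not ordered:
            continue
        if not math.isclose(ordered[0].age_min, AGE_MIN):
            out.append(f"{analyte}: cutoff rules must start at age {AGE_MIN}")
        if not math.isclose(ordered[-1].age_max, AGE_MAX):
            out.append(f"{analyte}: cutoff rules must end at age {AGE_MAX}")
        for prev, nxt in zip(ordered, ordered[1:]):
            if not math.isclose(prev.age_max, nxt.age_min):
                out.append(f"{analyte}: cutoff age intervals must tile [0, 18]")
        for rule in ordered:
            if rule.lower is not None and rule.upper is not None and rule.lower >= rule.upper:
                out.append(f"{analyte}: lower cutoff must be below upper cutoff")
            if rule.lower is not None and analyte != "Pseudouridine":
                out.append(f"{analyte}: only pseudouridine carries a lower cutoff")

    for sig in registry.signatures.values():
        if not sig.required_high and not sig.required_low:
            out.append(f"signature {sig.code}: no required markers")
        for marker in sig.required_high | sig.optional_high | sig.required_low:
            if marker not in registry.analytes:
                out.append(f"signature {sig.code}: unknown analyte {marker!r}")
    return out


def get_cutoff(registry: PanelRegistry, analyte: str, age: float) -> ResolvedCutoff:
    """Resolve the unique age-matching decision limits for one analyte.

    Intervals are [age_min, age_max) except the last, closed at 18.
    """
    if analyte not in registry.cutoffs:
        raise CutoffLookupError(f"no cutoff rules for analyte {analyte!r}")
    if not (AGE_MIN <= age <= AGE_MAX):
        raise ValueError(f"age {age} outside [{AGE_MIN}, {AGE_MAX}] years")
    rules = registry.cutoffs[analyte]
    for i, rule in enumerate(rules):
        last = i == len(rules) - 1
        if rule.age_min <= age < rule.age_max or (last and age == rule.age_max):
            return ResolvedCutoff(
                analyte=analyte,
                age=age,
                upper=rule.upper,
                lower=rule.lower,
                detection_is_abnormal=rule.detection_is_abnormal,
            )
    raise CutoffLookupError(f"no cutoff rule covers age {age} for {analyte!r}")


def find_critical_pairs(
    registry: PanelRegistry,
    parent_tol: float = 0.2,
    daughter_tol: float = 2.0,
) -> list[tuple[str, str]]:
    """Find compound pairs whose MRM channels can interfere.

    Two compounds are critical when, in the same ESI mode, any pair of
    their transitions has parent masses within ``parent_tol`` Da and
    daughter masses within ``daughter_tol`` Da (the latter generous
    enough to catch isotope crosstalk between labeled standards and
    neighbouring analytes).
    """
    names = list(registry.analytes)
    pairs: list[tuple[str, str]] = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ta, tb = registry.analytes[a].transitions, registry.analytes[b].transitions
            hit = any(
                x.esi_mode == y.esi_mode
                and abs(x.parent_mass - y.parent_mass) <= parent_tol
                and abs(x.daughter_mass - y.daughter_mass) <= daughter_tol
                for x in ta
                for y in tb
            )
            if hit:
                pairs.append((a, b))
    return pairs


def with_renamed_internal_standard(
    registry: PanelRegistry, analyte: str, new_is: str
) -> PanelRegistry:
    """Copy of the registry with one analyte's IS reassigned (test helper)."""
    analytes = dict(registry.analytes)
    analytes[analyte] = replace(analytes[analyte], internal_standard=new_is)
    return PanelRegistry(
        analytes=analytes,
        cutoffs=registry.cutoffs,
        signatures=registry.signatures,
        critical_pairs=registry.critical_pairs,
    )
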