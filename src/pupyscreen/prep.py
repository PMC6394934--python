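"""Volumetric sample-preparation planning and back-calculation.

Every sample is brought to a common creatinine level before measurement:
urine is diluted with water to 400 ul targeting 0.25 mM creatinine,
calibrators/QCs are mixed 100 ul + 300 ul synthetic urine (0.333 mM
creatinine), and 100 ul of 25 uM internal-standard working solution is
added to all, giving 500 ul at nominally 0.20 mM creatinine and 5 uM IS.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

FIRST_STAGE_VOLUME_UL = 400.0
FIRST_STAGE_CREATININE_MM = 0.25
IS_VOLUME_UL = 100.0
IS_WORKING_UM = 25.0
TOTAL_VOLUME_UL = 500.0
CALIBRATOR_ALIQUOT_UL = 100.0
SYNTHETIC_URINE_VOLUME_UL = 300.0
SYNTHETIC_URINE_CREATININE_MM = 0.333

#: vial concentration / pre-preparation calibrator concentration
CALIBRATOR_DILUTION = CALIBRATOR_ALIQUOT_UL / TOTAL_VOLUME_UL


@dataclass(frozen=True)
class PrepRecord:
    """Volumetric record of one prepared sample."""

    sample_kind: str  # "urine" | "calibrator" | "qc"
    urine_creatinine: float | None  # mM, urine only
    urine_volume: float  # ul
    water_volume: float  # ul
    synthetic_urine_volume: float  # ul
    is_volume: float  # ul of 25 uM IS working solution
    total_volume: float  # ul
    first_stage_creatinine: float  # mM at 400 ul
    final_creatinine: float  # mM at 500 ul
    final_is: float  # uM at 500 ul
    capped: bool  # urine aliquot hit the 400 ul ceiling

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PrepRecord":
        return cls(**d)


def plan_urine_prep(urine_creatinine: float) -> PrepRecord:
    """Plan the dilution of one urine sample from its creatinine level.

    The urine aliquot is chosen so the first 400 ul stage holds 0.25 mM
    creatinine; very dilute urines are capped at 400 ul (no water) and
    flagged, with the shortfall corrected downstream in
    :func:`back_calculate`.
    """
    if urine_creatinine <= 0:
        raise ValueError(f"urine creatinine must be positive, got {urine_creatinine}")
    ideal = FIRST_STAGE_CREATININE_MM * FIRST_STAGE_VOLUME_UL / urine_creatinine
    capped = ideal > FIRST_STAGE_VOLUME_UL
    urine_volume = min(ideal, FIRST_STAGE_VOLUME_UL)
    water_volume = FIRST_STAGE_VOLUME_UL - urine_volume
    first_stage = urine_creatinine * urine_volume / FIRST_STAGE_VOLUME_UL
    return PrepRecord(
        sample_kind="urine",
        urine_creatinine=urine_creatinine,
        urine_volume=urine_volume,
        water_volume=water_volume,
        synthetic_urine_volume=0.0,
        is_volume=IS_VOLUME_UL,
        total_volume=TOTAL_VOLUME_UL,
        first_stage_creatinine=first_stage,
        final_creatinine=first_stage * FIRST_STAGE_VOLUME_UL / TOTAL_VOLUME_UL,
        final_is=IS_WORKING_UM * IS_VOLUME_UL / TOTAL_VOLUME_UL,
        capped=capped,
    )


def plan_calibrator_prep(sample_kind: str = "calibrator") -> PrepRecord:
    """Plan a calibrator/QC preparation (fixed-volume recipe)."""
    if sample_kind not in {"calibrator", "qc"}:
        raise ValueError(f"sample_kind must be calibrator or qc, got {sample_kind!r}")
    first_stage = (
        SYNTHETIC_URINE_CREATININE_MM * SYNTHETIC_URINE_VOLUME_UL / FIRST_STAGE_VOLUME_UL
    )
    return PrepRecord(
        sample_kind=sample_kind,
        urine_creatinine=None,
        urine_volume=0.0,
        water_volume=0.0,
        synthetic_urine_volume=SYNTHETIC_URINE_VOLUME_UL,
        is_volume=IS_VOLUME_UL,
        total_volume=TOTAL_VOLUME_UL,
        first_stage_creatinine=first_stage,
        final_creatinine=first_stage * FIRST_STAGE_VOLUME_UL / TOTAL_VOLUME_UL,
        final_is=IS_WORKING_UM * IS_VOLUME_UL / TOTAL_VOLUME_UL,
        capped=False,
    )


def back_calculate(readout_um: float, prep: PrepRecord) -> float:
    """Convert a readout on the pre-preparation calibrator scale (uM) to
    mmol analyte per mol creatinine for the originating urine.

    The calibration curve reports concentrations on the calibrator
    pre-preparation scale, i.e. vial concentration x 5.  For a urine
    prepared exactly to target (uncapped) the creatinine normalisation
    cancels the dilution and the result equals the readout.
    """
    if prep.sample_kind != "urine":
        raise ValueError("back_calculate requires a urine prep record")
    if prep.urine_creatinine is None or prep.urine_volume <= 0:
        raise ValueError("prep record lacks urine volume/creatinine")
    urine_um = readout_um * CALIBRATOR_ALIQUOT_UL / prep.urine_volume
    return urine_um / prep.urine_creatinine
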