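"""Voluntary dry-matter-intake prediction and ME intake.

Voluntary DMI blends a physical (rumen-fill) and a physiological
(energy-demand) regulation term:

    DMI_raw = (NDF_capacity / diet_NDF  +  ME_requirement / diet_ME) / 2

The NDF intake capacity of lactating (sub-)tropical cattle is 0.0135 kg NDF
per kg body weight and day.  The ME requirement entering the blend is the
*potential* total requirement, so the raw prediction is scaled once by the
body-weight condition index to avoid over-estimating intake in animals that
are below their potential weight-for-age; the feed actually on offer then
caps the result.  ME intake is simply DMI times the diet ME concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import Ration

__all__ = ["IntakeResult", "ndf_intake_capacity", "voluntary_dmi"]

NDF_CAPACITY_PER_KG_BW = 0.0135  # kg NDF/kg BW/day


@dataclass(frozen=True)
class IntakeResult:
    """All intermediate and final terms of one intake prediction."""

    ndf_capacity: float  # kg NDF/day
    physical_dmi: float  # kg DM/day, rumen-fill-limited term
    physiological_dmi: float  # kg DM/day, energy-demand term
    raw_dmi: float  # kg DM/day, blended prediction
    scaled_dmi: float  # kg DM/day, after condition scaling and offer cap
    mei: float  # MJ/day


def ndf_intake_capacity(bw: float) -> float:
    """Maximum daily NDF intake (kg/day) of a lactating animal."""
    if bw <= 0:
        raise ValueError(f"body weight must be > 0, got {bw}")
    return NDF_CAPACITY_PER_KG_BW * bw


def voluntary_dmi(
    bw: float, total_me_req: float, ration: Ration, index: float
) -> IntakeResult:
    """Predict voluntary DMI (kg/day) and the resulting ME intake (MJ/day).

    ``total_me_req`` is the potential total ME requirement (MJ/day);
    ``index`` the body-weight condition index in [0, 1].
    """
    if ration.ndf <= 0 or ration.me <= 0:
        raise ValueError("diet NDF and ME concentrations must be > 0")
    if not 0 <= index <= 1:
        raise ValueError(f"condition index out of [0, 1]: {index}")
    if total_me_req < 0:
        raise ValueError(f"total_me_req must be >= 0, got {total_me_req}")

    capacity = ndf_intake_capacity(bw)
    physical = capacity / ration.ndf
    physiological = total_me_req / ration.me
    raw = (physical + physiological) / 2.0
    scaled = min(raw * index, ration.offered_dm)
    return IntakeResult(
        ndf_capacity=capacity,
        physical_dmi=physical,
        physiological_dmi=physiological,
        raw_dmi=raw,
        scaled_dmi=scaled,
        mei=scaled * ration.me,
    )
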