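"""Potential growth, potential lactation and the body-weight condition index.

Potential growth follows a Gompertz curve: the daily gain is proportional
to the current weight times the log-distance to the mature weight,

    dBW/dt = mu0 * BW * ln(BWf / BW) / ln(BWf / BW0),

capped at a breed ceiling (1.2 kg/day by default) to avoid unrealistic
rates.  BWf is the mature weight reached under (sub-)tropical feeding,
taken as 90% of the genetic maximum.

The potential lactation curve is an incomplete-gamma (Wood-type) form
parameterised directly by the peak yield and the month of peak:

    y(n) = n / (a * exp(k * n)),   a = 1 / (peak * (1/T) * e),   k = 1/T,

which attains its maximum, equal to ``peak``, exactly at month n = T.

The condition index locates the animal's weight inside a breed- and
age-specific envelope [BW_min(t), BW_max(t)], clamped to [0, 1].  The
envelope bounds are themselves Gompertz trajectories from the birth weight
toward the breed's minimum mature weight and toward 90% of its genetic
maximum, so the envelope stays internally consistent with the growth model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from .core import BreedParameters

__all__ = [
    "potential_growth_rate",
    "gompertz_weight",
    "GrowthEnvelope",
    "growth_envelope",
    "potential_milk_yield",
    "condition_index",
    "DegenerateEnvelopeError",
]

DAYS_PER_YEAR = 365.25


class DegenerateEnvelopeError(ValueError):
    """The weight envelope has zero width at the requested age."""


def potential_growth_rate(bw: float, breed: BreedParameters) -> float:
    """Potential daily body-weight gain (kg/day) at the current weight.

    Weights above the mature weight are clamped (rate 0); weights below the
    birth weight are rejected.
    """
    if bw <= 0:
        raise ValueError(f"body weight must be > 0, got {bw}")
    if bw < breed.birth_weight:
        raise ValueError(
            f"body weight {bw} below the breed birth weight {breed.birth_weight}"
        )
    bwf = breed.final_weight
    bw = min(bw, bwf)
    rate = breed.gompertz_mu0 * bw * math.log(bwf / bw) / math.log(bwf / breed.birth_weight)
    return min(max(rate, 0.0), breed.max_daily_gain)


def gompertz_weight(age_years: float, bw0: float, bwf: float, mu0: float) -> float:
    """Closed-form Gompertz weight-for-age trajectory (kg).

    Solves dBW/dt = mu0*BW*ln(bwf/BW)/ln(bwf/bw0) with BW(0) = bw0; the
    log-distance to maturity decays exponentially at rate mu0/ln(bwf/bw0).
    """
    if age_years < 0:
        raise ValueError(f"age must be >= 0, got {age_years}")
    u0 = math.log(bwf / bw0)
    u = u0 * math.exp(-mu0 * age_years * DAYS_PER_YEAR / u0)
    return bwf * math.exp(-u)


@dataclass(frozen=True)
class GrowthEnvelope:
    """Age-indexed lower/upper body-weight bounds for one breed."""

    bw_min_at_age: Callable[[float], float]
    bw_max_at_age: Callable[[float], float]
    final_weight: float  # kg, upper asymptote (0.9 x genetic maximum)


def growth_envelope(breed: BreedParameters) -> GrowthEnvelope:
    """Build the breed's weight envelope from its mature-weight bounds."""
    bw0, mu0 = breed.birth_weight, breed.gompertz_mu0
    lo, hi = breed.min_mature_weight, breed.final_weight
    return GrowthEnvelope(
        bw_min_at_age=lambda age: gompertz_weight(age, bw0, lo, mu0),
        bw_max_at_age=lambda age: gompertz_weight(age, bw0, hi, mu0),
        final_weight=hi,
    )


def potential_milk_yield(n: float, breed: BreedParameters) -> float:
    """Potential milk yield (kg/animal/day) in month ``n`` of lactation.

    Months outside (0, lactation_length] yield 0 (dry animal), not an error.
    """
    if n <= 0 or n > breed.lactation_length:
        return 0.0
    t = breed.peak_month
    a = 1.0 / (breed.peak_milk_yield * (1.0 / t) * math.e)
    k = 1.0 / t
    return n / (a * math.exp(k * n))


def condition_index(bw: float, age: float, envelope: GrowthEnvelope) -> float:
    """Body-weight condition index in [0, 1].

    (BW - BW_min(age)) / (BW_max(age) - BW_min(age)), clamped to [0, 1].
    """
    lo = envelope.bw_min_at_age(age)
    hi = envelope.bw_max_at_age(age)
    width = hi - lo
    if width <= 1e-9:
        raise DegenerateEnvelopeError(
            f"envelope has width {width} at age {age}; bounds [{lo}, {hi}]"
        )
    return min(max((bw - lo) / width, 0.0), 1.0)
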