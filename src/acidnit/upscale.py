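"""Global upscaling of the acidification response of nitrification-derived N2O.

Scenario arithmetic: a fractional increase of nitrification-derived N2O
production at the globally averaged pH decline (about 0.21 units over recent
decades) is applied to the nitrifier share of the global estuarine + coastal
N2O emission, and the resulting increase is expressed as a share of total
anthropogenic N2O emissions (6.9 Tg N2O-N yr-1).

The baseline estuarine + coastal emission is a required configuration input.
:data:`RECONSTRUCTED_BASELINE_TG` is a documented placeholder obtained by
inverting the published increase range (0.05-0.15 Tg N2O-N yr-1) against a
nitrifier share of 0.5 and a response range of 9.5-27.5%; it is flagged as
reconstructed, not sourced.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .errors import UndefinedInputError

__all__ = [
    "UpscaleScenario",
    "RECONSTRUCTED_BASELINE_TG",
    "ANTHROPOGENIC_TOTAL_TG",
    "emission_increase",
    "share_of_anthropogenic",
    "implied_baseline",
]

#: Total anthropogenic N2O emission, Tg N2O-N yr-1.
ANTHROPOGENIC_TOTAL_TG = 6.9

#: Placeholder baseline global estuarine + coastal N2O emission
#: (Tg N2O-N yr-1), RECONSTRUCTED by inverting the published increase range
#: (0.05 and 0.15 Tg at responses 9.5% and 27.5%, share 0.5, which imply
#: baselines of ~1.05 and ~1.09 Tg); replace with a sourced value for any
#: real assessment.
RECONSTRUCTED_BASELINE_TG = 1.08


@dataclass(frozen=True)
class UpscaleScenario:
    """Inputs of the emission-increase calculation.

    ``response_low``/``response_high`` are fractional increases of the
    nitrification-derived N2O production rate at the reference pH decline
    (e.g. 0.095 and 0.275 for +9.5% to +27.5%).
    """

    baseline_emission: float  # Tg N2O-N yr-1, estuarine + coastal
    response_low: float
    response_high: float
    nitrifier_share: float = 0.5
    anthropogenic_total: float = ANTHROPOGENIC_TOTAL_TG

    def __post_init__(self) -> None:
        for name in (
            "baseline_emission",
            "response_low",
            "response_high",
            "nitrifier_share",
            "anthropogenic_total",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.response_low > self.response_high:
            raise ValueError("response_low must be <= response_high")
        if self.nitrifier_share > 1.0:
            raise ValueError("nitrifier_share must be <= 1")


def emission_increase(scenario: UpscaleScenario) -> tuple[float, float]:
    """Absolute emission increase range, Tg N2O-N yr-1.

    ``baseline * nitrifier_share * response`` for the low and high ends of
    the response range; linear in every factor, and order-preserving
    (low <= high).
    """
    base = scenario.baseline_emission * scenario.nitrifier_share
    return (base * scenario.response_low, base * scenario.response_high)


def share_of_anthropogenic(
    increase_low: float,
    increase_high: float,
    anthropogenic_total: float = ANTHROPOGENIC_TOTAL_TG,
) -> tuple[float, float]:
    """Emission increase as a percentage of total anthropogenic emissions.

    Each bound is ``100 * increase / total`` rounded half-up to one decimal
    place, the convention of published emission-share figures.
    """
    if anthropogenic_total <= 0:
        raise UndefinedInputError("anthropogenic total must be > 0")
    return (
        _round1(100.0 * increase_low / anthropogenic_total),
        _round1(100.0 * increase_high / anthropogenic_total),
    )


def implied_baseline(
    increase: float, response: float, nitrifier_share: float = 0.5
) -> float:
    """Invert the emission increase for the baseline it implies.

    Consistency diagnostic: a published increase divided by
    ``share * response`` recovers the baseline emission that scenario used.
    """
    if response <= 0 or nitrifier_share <= 0:
        raise UndefinedInputError("response and nitrifier_share must be > 0")
    return increase / (nitrifier_share * response)


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
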