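"""Strict-clock dating of haplogroup splits from uncorrected p-distances.

A calibration is a *pairwise* rate r — percent uncorrected pairwise
distance accumulated per million years between two diverging lineages — so
a divergence time is simply t = p / r (no factor of 2, no multiple-hit
correction). Two standard arthropod COI/mitogenome calibrations bracket the
estimate: 1.5 %/Myr (slow, COI, various invertebrates) and 2.3 %/Myr (fast,
whole mitogenome, various arthropods). The faster rate yields the lower
bound of the time interval, the slower rate the upper bound.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .io import InputError

#: Standard calibration pair: slow COI rate and fast mitogenome rate, in
#: percent uncorrected pairwise distance per million years.
DEFAULT_RATES = (1.5, 2.3)


@dataclass(frozen=True)
class ClockCalibration:
    """A pairwise divergence rate in % uncorrected distance per Myr."""

    rate: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise InputError(f"calibration rate must be positive, got {self.rate}")


@dataclass(frozen=True)
class TimeInterval:
    """Divergence-time interval in Myr, one endpoint per calibration.

    ``t_low`` comes from the fastest rate, ``t_high`` from the slowest;
    ``estimates`` maps each calibration to its point estimate.
    """

    t_low: float
    t_high: float
    estimates: tuple[tuple[ClockCalibration, float], ...]

    def render(self) -> str:
        """One-decimal rendering, round-half-up — e.g. ``'1.0–1.6 Myr'``."""
        return f"{_round1(self.t_low)}–{_round1(self.t_high)} Myr"


def _round1(x: float) -> Decimal:
    return Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)


def as_fraction(p: float, unit: str) -> float:
    """Normalize a distance stated in ``'percent'`` or ``'fraction'``."""
    if unit not in ("percent", "fraction"):
        raise InputError(f"unknown distance unit {unit!r}")
    value = p / 100.0 if unit == "percent" else p
    if value < 0:
        raise InputError(f"negative distance {p!r}")
    return value


def divergence_time(
    p: float, calibration: ClockCalibration, unit: str = "percent"
) -> float:
    """Divergence time t = p / r in Myr.

    *p* is an uncorrected pairwise distance, by default in percent (the
    scale calibrations are quoted on); pass ``unit='fraction'`` for a raw
    proportion.
    """
    fraction = as_fraction(p, unit)
    return 100.0 * fraction / calibration.rate


def divergence_interval(
    p: float,
    calibrations: tuple[ClockCalibration, ClockCalibration],
    unit: str = "percent",
) -> TimeInterval:
    """Time interval spanned by two point estimates, one per calibration.

    Invariant under the order the calibrations are supplied; identical
    rates yield a degenerate interval.
    """
    if len(calibrations) != 2:
        raise InputError("exactly two calibrations are required")
    estimates = tuple(
        (cal, divergence_time(p, cal, unit)) for cal in calibrations
    )
    times = sorted(t for _, t in estimates)
    return TimeInterval(t_low=times[0], t_high=times[1], estimates=estimates)
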