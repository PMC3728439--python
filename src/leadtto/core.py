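"""Domain types and the deterministic value algebra of lead-time TTO.

In a lead-time time trade-off task the respondent compares Life A — ``LT``
years in full health (the *lead time*) followed by ``UT`` years in the health
state being valued (the *unhealthy time*) — against Life B, ``x`` years in
full health.  The duration ``T`` of Life B at which the respondent judges the
two lives "about the same" maps to a health-state value

    U = (T - LT) / UT

so that ``T = LT`` gives value 0 (equivalent to dead) and ``T = LT + UT``
gives value 1 (full health).  The attainable range is ``[-LT/UT, 1]``:
``[-2, 1]`` for a 10-year lead time over 5 unhealthy years, ``[-1, 1]`` when
lead time and unhealthy time are both 5 years.

All durations are multiples of a quarter year (3 months, the finest iteration
step) and are stored internally as integer quarter-year counts, so that the
value algebra is exact and round-trips without floating-point drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Tuple

#: Length of the finest duration grid step, in years (3 months).
QUARTER_YEAR = 0.25

FULL_HEALTH_CODE = "11111"


class DomainError(ValueError):
    """A quantity lies outside the domain its operation is defined on."""


class ConfigError(ValueError):
    """An invalid task or study configuration."""


class ProtocolError(RuntimeError):
    """An elicitation trace violates the iteration protocol."""


class VisualVariant(str, Enum):
    """How the Life-A bars are drawn on screen.

    ``aligned``: lead-time and unhealthy-time bars lie on one line.
    ``raised_bar``: the unhealthy-time bar is slightly raised to highlight
    the point where the lead time ends (the time point equivalent to dead).
    """

    ALIGNED = "aligned"
    RAISED_BAR = "raised_bar"


class Arm(str, Enum):
    STANDARD = "standard"
    EXPERIMENTAL = "experimental"


class Response(str, Enum):
    """A respondent's answer to one offer."""

    PREFER_A = "A"
    PREFER_B = "B"
    INDIFFERENT = "same"


def to_quarters(years: float, what: str = "duration") -> int:
    """Convert a year duration to an exact integer quarter-year count."""
    q = years / QUARTER_YEAR
    qi = round(q)
    if abs(q - qi) > 1e-9:
        raise DomainError(
            f"{what} {years!r} years is not a multiple of {QUARTER_YEAR} years"
        )
    return int(qi)


def from_quarters(q: int) -> float:
    return q * QUARTER_YEAR


@dataclass(frozen=True)
class HealthState:
    """An EQ-5D-5L health state.

    The five digits describe mobility, self-care, usual activities,
    pain/discomfort and anxiety/depression, each on levels 1 (no problems)
    to 5 (extreme problems).  ``11111`` is full health.
    """

    code: str

    def __post_init__(self) -> None:
        if len(self.code) != 5 or not all(c in "12345" for c in self.code):
            raise DomainError(
                f"health-state code {self.code!r} must be 5 digits, each 1-5"
            )

    @property
    def is_full_health(self) -> bool:
        return self.code == FULL_HEALTH_CODE

    def __str__(self) -> str:
        return self.code


FULL_HEALTH = HealthState(FULL_HEALTH_CODE)


@dataclass(frozen=True)
class TaskConfig:
    """One arm's task design.

    Parameters
    ----------
    lead_time : float
        LT, years of full health preceding the unhealthy period in Life A.
    unhealthy_time : float
        UT, years spent in the state being valued.
    min_step : float
        Finest iteration step of the offer grid, years (default 3 months).
    visual_variant : VisualVariant
        How the Life-A bars are displayed.
    """

    lead_time: float
    unhealthy_time: float
    min_step: float = QUARTER_YEAR
    visual_variant: VisualVariant = VisualVariant.ALIGNED

    def __post_init__(self) -> None:
        for name in ("lead_time", "unhealthy_time", "min_step"):
            v = getattr(self, name)
            if not v > 0:
                raise ConfigError(f"{name} must be > 0, got {v!r}")
        # frozen dataclass: validate the quarter representation eagerly
        to_quarters(self.lead_time, "lead_time")
        to_quarters(self.unhealthy_time, "unhealthy_time")
        sq = to_quarters(self.min_step, "min_step")
        if sq < 1:
            raise ConfigError("min_step must be at least one quarter year")
        object.__setattr__(
            self, "visual_variant", VisualVariant(self.visual_variant)
        )

    # -- integer quarter views -------------------------------------------
    @property
    def lt_q(self) -> int:
        return to_quarters(self.lead_time)

    @property
    def ut_q(self) -> int:
        return to_quarters(self.unhealthy_time)

    @property
    def step_q(self) -> int:
        return to_quarters(self.min_step)

    @property
    def max_offer(self) -> float:
        """Longest Life B on offer: LT + UT years."""
        return from_quarters(self.lt_q + self.ut_q)

    @property
    def max_q(self) -> int:
        return self.lt_q + self.ut_q

    @property
    def value_range(self) -> Tuple[float, float]:
        """Attainable values ``[-LT/UT, 1]``."""
        return (-self.lt_q / self.ut_q, 1.0)


@dataclass(frozen=True)
class Offer:
    """One Life-B proposal: live ``duration`` years in full health, then die."""

    duration: float
    ordinal: int

    def __post_init__(self) -> None:
        if self.ordinal < 1:
            raise DomainError(f"offer ordinal must be >= 1, got {self.ordinal}")
        to_quarters(self.duration, "offer duration")

    def validate(self, config: TaskConfig) -> None:
        q = to_quarters(self.duration, "offer duration")
        if not 0 <= q <= config.max_q:
            raise DomainError(
                f"offer duration {self.duration} outside [0, {config.max_offer}]"
            )
        if q % config.step_q != 0:
            raise DomainError(
                f"offer duration {self.duration} not on the {config.min_step}-year grid"
            )


def compute_value(T: float, config: TaskConfig) -> float:
    """TTO value ``U = (T - LT)/UT`` of an indifference time ``T`` (years).

    ``T`` must lie in ``[0, LT + UT]``.  On the quarter-year grid the result
    is computed from integer quarter counts, so equal times give bitwise-equal
    values.
    """
    if not 0 <= T:
        raise DomainError(f"indifference time {T} below lower bound 0")
    if not T <= config.max_offer:
        raise DomainError(
            f"indifference time {T} above upper bound {config.max_offer}"
        )
    try:
        tq = to_quarters(T, "indifference time")
    except DomainError:
        return (T - config.lead_time) / config.unhealthy_time
    return (tq - config.lt_q) / config.ut_q


def invert_value(U: float, config: TaskConfig) -> float:
    """Indifference time ``T = LT + U*UT`` (years) for a value ``U``.

    Inverse of :func:`compute_value`; exact on grid-representable values.
    """
    lo, hi = config.value_range
    if not lo - 1e-12 <= U <= hi + 1e-12:
        raise DomainError(f"value {U} outside attainable range [{lo}, {hi}]")
    r = U * config.ut_q
    k = round(r)
    if abs(r - k) < 1e-9:  # grid value: exact integer-quarter path
        return from_quarters(config.lt_q + int(k))
    return config.lead_time + U * config.unhealthy_time


def detectable_resolution(config: TaskConfig) -> float:
    """Smallest detectable value difference, ``min_step / UT``.

    A 3-month step over 10 unhealthy years resolves value differences of
    0.025 (3/120); over 5 unhealthy years, 0.05.
    """
    return config.min_step / config.unhealthy_time


def grid_values(config: TaskConfig) -> "list[float]":
    """All values attainable on the quarter-year offer grid, ascending."""
    return [
        (tq - config.lt_q) / config.ut_q for tq in range(0, config.max_q + 1)
    ]


@dataclass
class ValuationRecord:
    """One completed valuation task in long format."""

    respondent_id: str
    arm: Arm
    block: int
    state: HealthState
    indifference_time: float
    value: float
    n_questions: int
    duration_s: float
    censored: bool

    def __post_init__(self) -> None:
        self.arm = Arm(self.arm)
        if isinstance(self.state, str):
            self.state = HealthState(self.state)

    def validate(self, config: TaskConfig) -> None:
        expected = compute_value(self.indifference_time, config)
        if not math.isclose(self.value, expected, abs_tol=1e-9):
            raise DomainError(
                f"value {self.value} inconsistent with T={self.indifference_time} "
                f"(expected {expected})"
            )
        lo, hi = config.value_range
        if not lo - 1e-9 <= self.value <= hi + 1e-9:
            raise DomainError(f"value {self.value} outside range [{lo}, {hi}]")
        if self.n_questions < 1:
            raise DomainError("n_questions must be >= 1")
        if self.duration_s < 0:
            raise DomainError("duration_s must be >= 0")


# Task designs used in the two randomized comparisons: a lead-time contrast
# (10 vs 5 years over 5 unhealthy years) and a visual-aid contrast
# (aligned vs raised unhealthy-time bar, both with LT=10/UT=5).
CHINA_STANDARD = TaskConfig(lead_time=10, unhealthy_time=5)
CHINA_EXPERIMENTAL = TaskConfig(lead_time=5, unhealthy_time=5)
SINGAPORE_STANDARD = TaskConfig(lead_time=10, unhealthy_time=5)
SINGAPORE_EXPERIMENTAL = TaskConfig(
    lead_time=10, unhealthy_time=5, visual_variant=VisualVariant.RAISED_BAR
)
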