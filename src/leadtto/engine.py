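"""Iterative lead-time TTO search.

The engine poses Life-B durations (offers), consumes responses
(Life A / Life B / about the same) and terminates at indifference or when
the offer grid is exhausted.  The schedule is anchored by the instrument's
printed opening sequence — the first offer is ``LT + UT`` years, the second
``LT`` years, the third the exact midpoint of the bracket established by the
second answer (12.5 or 5 years for LT=10/UT=5; 7.5 or 2.5 for LT=5/UT=5) —
and thereafter bisects the current preference bracket with offers snapped to
1-year, then half-year, then quarter-year grids as the bracket narrows.
The exact step sequence of the original computerized instrument beyond the
third offer is not public; the snapped bisection here is this package's
documented stand-in, chosen to reproduce the printed anchor offers and to
reach quarter-year resolution within a dozen questions.

A respondent who still prefers Life B when the grid reaches its lower bound
(or Life A at its upper bound) has exhausted the tradable time: the task is
censored at that bound, mirroring the instruction to indicate indifference at
the offer closest to one's indifference point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .core import (
    Arm,
    HealthState,
    Offer,
    ProtocolError,
    Response,
    TaskConfig,
    ValuationRecord,
    compute_value,
    from_quarters,
)

#: Defensive bound on offers per task; the schedule's tree depth is ~12.
HARD_CAP = 64

# Snap grids for bisection offers, coarse to fine, in quarter-year units.
_SNAP_LEVELS = (4, 2, 1)  # 1 year, 6 months, 3 months


@dataclass
class ElicitationTrace:
    """Ordered offers, responses and timing for one valuation task."""

    state: HealthState
    offers: List[Offer] = field(default_factory=list)
    responses: List[Response] = field(default_factory=list)
    terminal_T: float = float("nan")
    censored: bool = False
    elapsed_s: float = 0.0

    def validate(self, config: TaskConfig) -> None:
        if len(self.offers) != len(self.responses):
            raise ProtocolError(
                f"{len(self.offers)} offers vs {len(self.responses)} responses"
            )
        if not self.offers:
            raise ProtocolError("empty trace")
        for off in self.offers:
            off.validate(config)
        if self.responses[-1] is not Response.INDIFFERENT:
            if not self.censored or self.terminal_T not in (0.0, config.max_offer):
                raise ProtocolError(
                    "trace must end in indifference or be censored at a grid bound"
                )
        if self.offers[0].duration != config.max_offer:
            raise ProtocolError("first offer must be LT + UT")
        if len(self.offers) >= 2 and self.responses[0] is Response.PREFER_B:
            if self.offers[1].duration != config.lead_time:
                raise ProtocolError("second offer must be LT")


def _history(trace: ElicitationTrace, config: TaskConfig) -> List[Tuple[int, Response]]:
    if len(trace.offers) != len(trace.responses):
        raise ProtocolError(
            f"{len(trace.offers)} offers vs {len(trace.responses)} responses"
        )
    return [
        (round(o.duration / 0.25), r)
        for o, r in zip(trace.offers, trace.responses)
    ]


def _bracket(
    history: Sequence[Tuple[int, Response]], config: TaskConfig
) -> Tuple[int, int, bool]:
    """Current preference bracket (lo, hi) in quarters, plus whether 0 was posed."""
    lo, hi = 0, config.max_q
    zero_offered = False
    for xq, r in history:
        if r is Response.INDIFFERENT:
            raise ProtocolError("task already terminated at indifference")
        if xq == 0:
            zero_offered = True
        if r is Response.PREFER_A:
            lo = xq
        else:
            hi = xq
    return lo, hi, zero_offered


def _next_offer_q(
    history: Sequence[Tuple[int, Response]], config: TaskConfig
) -> Optional[int]:
    """Next Life-B duration in quarters, or None when the grid is exhausted."""
    if not history:
        return config.max_q
    lo, hi, zero_offered = _bracket(history, config)
    w = hi - lo
    if len(history) == 1 and history[0][1] is Response.PREFER_B:
        return config.lt_q
    if w <= config.step_q:
        if lo == 0 and not zero_offered and w > 0:
            return 0
        return None
    if (
        len(history) == 2
        and history[0][1] is Response.PREFER_B
        and history[1][0] == config.lt_q
    ):
        # third offer: exact midpoint of the established bracket
        m = (lo + hi) // 2
        if lo < m < hi:
            return m
    mid = (lo + hi) / 2.0
    levels = [
        s for s in _SNAP_LEVELS if s >= config.step_q and s % config.step_q == 0
    ] or [config.step_q]
    for i, s in enumerate(levels):
        if w <= 2 * s and i < len(levels) - 1:
            continue  # bracket too narrow for this snap grid
        first = (lo // s + 1) * s
        cands = range(first, hi, s)
        if len(cands):
            return min(cands, key=lambda m: (abs(m - mid), m))
    return None


def next_offer(trace: ElicitationTrace, config: TaskConfig) -> Optional[Offer]:
    """The offer following ``trace``, or None when the grid is exhausted."""
    hist = _history(trace, config)
    xq = _next_offer_q(hist, config)
    if xq is None:
        return None
    return Offer(duration=from_quarters(xq), ordinal=len(trace.offers) + 1)


def run_task(
    agent,
    state: HealthState,
    config: TaskConfig,
    rng: Union[int, np.random.Generator, None] = None,
    *,
    respondent_id: str = "r0",
    arm: Arm = Arm.STANDARD,
    block: int = 1,
) -> Tuple[ValuationRecord, ElicitationTrace]:
    """Run one valuation task to completion.

    ``agent`` supplies ``decide(offer, state, config, rng)``,
    ``response_time(offer, state, config, rng)`` and
    ``forced_indifference(lo_T, hi_T, state, config)`` (the choice between the
    two bracket endpoints when the grid resolution is exhausted without an
    expressed indifference).

    Returns the completed :class:`ValuationRecord` and its trace.  The record
    is censored when the task terminated at a grid bound (0 or LT+UT years)
    without the agent ever reporting indifference.
    """
    if isinstance(state, str):
        state = HealthState(state)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    trace = ElicitationTrace(state=state)
    history: List[Tuple[int, Response]] = []
    terminal_q: Optional[int] = None
    censored = False
    while True:
        if len(trace.offers) >= HARD_CAP:
            raise ProtocolError(
                f"agent did not terminate within {HARD_CAP} offers"
            )
        xq = _next_offer_q(history, config)
        if xq is None:
            lo, hi, _ = _bracket(history, config)
            if lo >= hi:
                # still prefers A at the top offer, or B at the bottom one
                terminal_q = lo
                censored = True
                break
            # grid resolution exhausted strictly inside the range: the
            # respondent indicates indifference at the closer endpoint
            chosen = agent.forced_indifference(
                from_quarters(lo), from_quarters(hi), state, config
            )
            off = Offer(duration=chosen, ordinal=len(trace.offers) + 1)
            trace.offers.append(off)
            trace.responses.append(Response.INDIFFERENT)
            trace.elapsed_s += float(
                agent.response_time(off, state, config, rng)
            )
            terminal_q = round(chosen / 0.25)
            censored = terminal_q in (0, config.max_q)
            break
        off = Offer(duration=from_quarters(xq), ordinal=len(trace.offers) + 1)
        trace.elapsed_s += float(agent.response_time(off, state, config, rng))
        resp = Response(agent.decide(off, state, config, rng))
        trace.offers.append(off)
        trace.responses.append(resp)
        history.append((xq, resp))
        if resp is Response.INDIFFERENT:
            terminal_q = xq
            censored = False
            break
    trace.terminal_T = from_quarters(terminal_q)
    trace.censored = censored
    record = ValuationRecord(
        respondent_id=respondent_id,
        arm=arm,
        block=block,
        state=state,
        indifference_time=trace.terminal_T,
        value=compute_value(trace.terminal_T, config),
        n_questions=len(trace.offers),
        duration_s=trace.elapsed_s,
        censored=censored,
    )
    return record, trace


# ---------------------------------------------------------------------------
# Offer schedule as an explicit decision tree (for testing and documentation)
# ---------------------------------------------------------------------------


@dataclass
class Terminal:
    """Leaf of the schedule: the grid is exhausted for this response path."""

    lo: float
    hi: float

    @property
    def at_bound(self) -> bool:
        return self.lo == self.hi


@dataclass
class OfferNode:
    duration: float
    on_prefer_A: Union["OfferNode", Terminal]
    on_prefer_B: Union["OfferNode", Terminal]


def offer_schedule(config: TaskConfig) -> OfferNode:
    """Materialize the full search tree of offers for ``config``.

    Each node is an offered Life-B duration; children follow the Life-A and
    Life-B answers ("about the same" ends the task at the node itself).
    Leaves mark response paths on which the grid is exhausted.
    """

    def build(history: List[Tuple[int, Response]]) -> Union[OfferNode, Terminal]:
        xq = _next_offer_q(history, config)
        if xq is None:
            lo, hi, _ = _bracket(history, config)
            return Terminal(lo=from_quarters(lo), hi=from_quarters(hi))
        return OfferNode(
            duration=from_quarters(xq),
            on_prefer_A=build(history + [(xq, Response.PREFER_A)]),
            on_prefer_B=build(history + [(xq, Response.PREFER_B)]),
        )

    root = build([])
    assert isinstance(root, OfferNode)
    return root


def schedule_offers(node: Union[OfferNode, Terminal]) -> List[float]:
    """All distinct durations posed anywhere in a schedule tree, sorted."""
    out = set()

    def walk(n):
        if isinstance(n, OfferNode):
            out.add(n.duration)
            walk(n.on_prefer_A)
            walk(n.on_prefer_B)

    walk(node)
    return sorted(out)
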