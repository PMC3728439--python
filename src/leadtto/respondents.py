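"""Synthetic respondents: agents with true utilities, decision noise and the
bias mechanisms hypothesized for lead-time TTO, plus the randomized study
design (two arms, two five-state blocks).

Each agent holds a true utility ``u*`` per health state.  When deciding on an
offer with value ``v`` the agent perceives the difference ``v - u_eff + eps``
with decision noise ``eps ~ N(0, sigma)`` and reports "about the same" when
that difference is within the indifference tolerance ``delta``.  The
*effective* utility bends ``u*`` by the two lead-time bias mechanisms:

    u_eff = u* - kappa * (LT/UT - 1) - nu * (LT + UT - 10) / 10

``kappa`` (framing): people trade more time simply because more lead time is
available; ``nu`` (visual contrast): with longer total bars a given value
difference looks smaller, so respondents trade extra years to *see* the bar
difference.  Both terms vanish at the 5-year-lead-time arm (1:1 ratio,
10-year bar), so the biases are identified as between-arm contrasts.

The raised-bar visual variant is modelled as an engagement effect ``gamma``:
near the time point equivalent to dead (offer values within ±0.5) the agent
deliberates — its indifference tolerance shrinks to ``delta/(1+gamma)`` and
its per-offer response time inflates by ``(1+gamma)``.  Time inflation
applies when the agent's own indifference region lies near dead
(``|u_eff| <= 0.5``) and the offer probes it (offer value within 0.25 of
``u_eff``): the raised bar alerts respondents whose deliberation happens in
the proximity of the dead point, which confines the extra time to tasks
that end with values near 0 — the localization seen in the source data's
behavior table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    Arm,
    ConfigError,
    HealthState,
    Offer,
    Response,
    TaskConfig,
    compute_value,
)
from .engine import run_task
from . import tables

#: Half-width (in value units) of the engagement/deliberation band around 0.
ENGAGEMENT_BAND = 0.5
#: An offer is "deliberated over" when its value is this close to u_eff.
DELIBERATION_BAND = 0.25


@dataclass
class RespondentProfile:
    """A simulated survey respondent.

    Parameters
    ----------
    true_utilities : mapping state code -> u* in [-2, 1]
    decision_sd : sigma, SD of the per-offer perception noise (value units).
    indifference_tol : delta, half-width within which "about the same"
        is reported.
    framing_coeff : kappa >= 0, extra value traded per unit excess of the
        LT/UT ratio over 1.
    visual_error_coeff : nu >= 0, downward bias per unit excess of the total
        bar length over 10 years (in 10-year units).
    engagement_gain : gamma >= 0, raised-bar variant only: tolerance shrink
        and response-time inflation near value 0.
    base_log_time, time_sd : per-offer response times are
        lognormal(base_log_time, time_sd), in log-seconds.
    """

    respondent_id: str
    true_utilities: Mapping[str, float]
    age_group: str = "18-34"
    gender: str = "female"
    education: str = "tertiary"
    decision_sd: float = 0.0
    indifference_tol: float = 0.0
    framing_coeff: float = 0.0
    visual_error_coeff: float = 0.0
    engagement_gain: float = 0.0
    base_log_time: float = math.log(6.0)
    time_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "decision_sd",
            "indifference_tol",
            "framing_coeff",
            "visual_error_coeff",
            "engagement_gain",
            "time_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for s, u in self.true_utilities.items():
            if not -2.0 - 1e-9 <= u <= 1.0 + 1e-9:
                raise ConfigError(
                    f"true utility {u} for state {s} outside [-2, 1]"
                )

    # ------------------------------------------------------------------
    def effective_utility(self, state: HealthState, config: TaskConfig) -> float:
        """True utility bent by the framing and visual-contrast biases."""
        u = self.true_utilities[str(state)]
        ratio_excess = config.lead_time / config.unhealthy_time - 1.0
        bar_excess = (config.lead_time + config.unhealthy_time - 10.0) / 10.0
        return u - self.framing_coeff * ratio_excess - self.visual_error_coeff * bar_excess

    def _tolerance(self, v: float, config: TaskConfig) -> float:
        from .core import VisualVariant

        delta = self.indifference_tol
        if (
            config.visual_variant is VisualVariant.RAISED_BAR
            and abs(v) <= ENGAGEMENT_BAND
        ):
            delta = delta / (1.0 + self.engagement_gain)
        return delta

    def decide(
        self,
        offer: Offer,
        state: HealthState,
        config: TaskConfig,
        rng: np.random.Generator,
    ) -> Response:
        """Preference between Life A and the offered Life B."""
        v = compute_value(offer.duration, config)
        u_eff = self.effective_utility(state, config)
        eps = rng.normal(0.0, self.decision_sd) if self.decision_sd > 0 else 0.0
        d = v - u_eff + eps
        if abs(d) <= self._tolerance(v, config):
            return Response.INDIFFERENT
        return Response.PREFER_B if d > 0 else Response.PREFER_A

    def response_time(
        self,
        offer: Offer,
        state: HealthState,
        config: TaskConfig,
        rng: np.random.Generator,
    ) -> float:
        """Seconds spent on one offer (lognormal, inflated on deliberated
        raised-bar offers near the dead point)."""
        from .core import VisualVariant

        if self.time_sd > 0:
            t = math.exp(rng.normal(self.base_log_time, self.time_sd))
        else:
            t = math.exp(self.base_log_time)
        v = compute_value(offer.duration, config)
        u_eff = self.effective_utility(state, config)
        if (
            config.visual_variant is VisualVariant.RAISED_BAR
            and abs(u_eff) <= ENGAGEMENT_BAND
            and abs(v - u_eff) <= DELIBERATION_BAND
        ):
            t *= 1.0 + self.engagement_gain
        return t

    def forced_indifference(
        self, lo_T: float, hi_T: float, state: HealthState, config: TaskConfig
    ) -> float:
        """Endpoint closest to the agent's indifference point, when the grid
        is exhausted between two offers."""
        u_eff = self.effective_utility(state, config)
        v_lo = compute_value(lo_T, config)
        v_hi = compute_value(hi_T, config)
        return lo_T if abs(v_lo - u_eff) <= abs(v_hi - u_eff) else hi_T


def decide(agent, offer, state, config, rng):
    return agent.decide(offer, state, config, rng)


def response_time(agent, offer, state, config, rng):
    return agent.response_time(offer, state, config, rng)


# ---------------------------------------------------------------------------
# Study design and population sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyDesign:
    """Randomized two-arm, two-block design.

    ``n_per_arm`` may be a single count (equal arms) or a mapping
    ``{"standard": n1, "experimental": n2}``.
    """

    n_per_arm: Union[int, Mapping[str, int]] = 200
    blocks: Tuple[Tuple[str, ...], Tuple[str, ...]] = (
        tables.BLOCK_1,
        tables.BLOCK_2,
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for b in self.blocks:
            if len(b) == 0:
                raise ConfigError("empty block")
            for s in b:
                HealthState(s)
        if self.arm_sizes["standard"] < 1 or self.arm_sizes["experimental"] < 1:
            raise ConfigError("n_per_arm must be >= 1 in both arms")

    @property
    def arm_sizes(self) -> Dict[str, int]:
        if isinstance(self.n_per_arm, Mapping):
            return {
                "standard": int(self.n_per_arm["standard"]),
                "experimental": int(self.n_per_arm["experimental"]),
            }
        return {"standard": int(self.n_per_arm), "experimental": int(self.n_per_arm)}

    @property
    def n_total(self) -> int:
        sizes = self.arm_sizes
        return sizes["standard"] + sizes["experimental"]

    @property
    def all_states(self) -> Tuple[str, ...]:
        return tuple(s for b in self.blocks for s in b)


@dataclass
class ProfileParams:
    """Population-level generating parameters for :func:`sample_population`.

    True utilities are generated hierarchically: each respondent carries a
    normal shift ``b_r ~ N(0, respondent_sd)`` (some people systematically
    trade more than others — this is the respondent-level clustering the
    mixed models adjust for), and the utility for state ``s`` is drawn from
    a normal centered at ``state_means[s] + b_r`` with SD ``state_sd``,
    truncated to the attainable support [-2, 1].  The remaining fields are
    copied into every profile; demographic categories are drawn from the
    given frequency tables.
    """

    state_means: Mapping[str, float] = field(
        default_factory=lambda: tables.state_means("china", "experimental")
    )
    state_sd: Union[float, Mapping[str, float]] = 0.45
    respondent_sd: float = 0.3
    decision_sd: float = 0.15
    indifference_tol: float = 0.05
    framing_coeff: float = 0.04
    visual_error_coeff: float = 0.02
    engagement_gain: float = 0.4
    base_log_time: float = math.log(6.0)
    time_sd: float = 0.5
    age_groups: Mapping[str, float] = field(
        default_factory=lambda: {"18-34": 0.45, "35-54": 0.40, "55+": 0.15}
    )
    genders: Mapping[str, float] = field(
        default_factory=lambda: {"female": 0.53, "male": 0.47}
    )
    educations: Mapping[str, float] = field(
        default_factory=lambda: {"tertiary": 0.84, "secondary_or_lower": 0.16}
    )

    def sd_for(self, state: str) -> float:
        if isinstance(self.state_sd, Mapping):
            return float(self.state_sd[state])
        return float(self.state_sd)


def _categorical(rng: np.random.Generator, freqs: Mapping[str, float]) -> str:
    cats = list(freqs)
    p = np.asarray([freqs[c] for c in cats], dtype=float)
    return cats[rng.choice(len(cats), p=p / p.sum())]


def _truncnorm_u(
    rng: np.random.Generator, mean: float, sd: float, lo: float = -2.0, hi: float = 1.0
) -> float:
    if sd == 0:
        return float(min(max(mean, lo), hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def truncated_mean(mean: float, sd: float, lo: float = -2.0, hi: float = 1.0) -> float:
    """Theoretical mean of the truncated-normal utility distribution."""
    if sd == 0:
        return float(min(max(mean, lo), hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.mean(a, b, loc=mean, scale=sd))


def sample_population(
    design: StudyDesign,
    params: ProfileParams,
    seed: Optional[int] = None,
) -> "list[RespondentProfile]":
    """Draw the full study population (both arms), reproducibly under seed."""
    rng = np.random.default_rng(design.seed if seed is None else seed)
    profiles = []
    for i in range(design.n_total):
        b_r = (
            rng.normal(0.0, params.respondent_sd)
            if params.respondent_sd > 0
            else 0.0
        )
        utilities = {
            s: _truncnorm_u(rng, params.state_means[s] + b_r, params.sd_for(s))
            for s in design.all_states
        }
        profiles.append(
            RespondentProfile(
                respondent_id=f"r{i:04d}",
                true_utilities=utilities,
                age_group=_categorical(rng, params.age_groups),
                gender=_categorical(rng, params.genders),
                education=_categorical(rng, params.educations),
                decision_sd=params.decision_sd,
                indifference_tol=params.indifference_tol,
                framing_coeff=params.framing_coeff,
                visual_error_coeff=params.visual_error_coeff,
                engagement_gain=params.engagement_gain,
                base_log_time=params.base_log_time,
                time_sd=params.time_sd,
            )
        )
    return profiles


RECORD_COLUMNS = [
    "respondent_id",
    "arm",
    "block",
    "state",
    "T",
    "U",
    "n_questions",
    "duration_s",
    "censored",
    "age_group",
    "gender",
    "education",
]


def simulate_study(
    design: StudyDesign,
    params: ProfileParams,
    configs: Mapping[str, TaskConfig],
    seed: Optional[int] = None,
    return_profiles: bool = False,
):
    """Run the whole study: sample agents, randomize arms and blocks, run
    every valuation task.  Returns a long-format DataFrame (one row per
    respondent x state) with :data:`RECORD_COLUMNS`.
    """
    for arm in ("standard", "experimental"):
        if arm not in configs:
            raise ConfigError(f"missing TaskConfig for arm {arm!r}")
    base = design.seed if seed is None else seed
    ss = np.random.SeedSequence(base)
    pop_seed, assign_seed, task_seed = ss.spawn(3)
    profiles = sample_population(
        design, params, seed=int(pop_seed.generate_state(1)[0] % 2**31)
    )
    rng = np.random.default_rng(assign_seed)
    sizes = design.arm_sizes
    arms = np.array(
        ["standard"] * sizes["standard"] + ["experimental"] * sizes["experimental"]
    )
    rng.shuffle(arms)
    blocks = rng.integers(1, len(design.blocks) + 1, size=design.n_total)
    task_rng = np.random.default_rng(task_seed)
    rows = []
    for prof, arm, block in zip(profiles, arms, blocks):
        config = configs[arm]
        for s in design.blocks[block - 1]:
            rec, _ = run_task(
                prof,
                HealthState(s),
                config,
                task_rng,
                respondent_id=prof.respondent_id,
                arm=Arm(arm),
                block=int(block),
            )
            rows.append(
                {
                    "respondent_id": rec.respondent_id,
                    "arm": rec.arm.value,
                    "block": rec.block,
                    "state": str(rec.state),
                    "T": rec.indifference_time,
                    "U": rec.value,
                    "n_questions": rec.n_questions,
                    "duration_s": rec.duration_s,
                    "censored": rec.censored,
                    "age_group": prof.age_group,
                    "gender": prof.gender,
                    "education": prof.education,
                }
            )
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    if return_profiles:
        return df, profiles
    return df
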