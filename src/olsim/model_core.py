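"""Core agent and unit state for the opinion-leadership simulation.

A *unit* is a closed group of nurse agents (staff nurses, educators and a
manager).  Each discrete time step ("tick") one agent announces a piece of
evidence; every other agent assesses the evidence and the announcer's
credibility against its own state, possibly seeks advice from an available
colleague, and decides whether to revise its belief.  Between ticks the unit
commits revised beliefs and recomputes visibility and credibility.

All belief-like quantities live on a 1-100 probability-score scale.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "SCORE_MIN",
    "SCORE_MAX",
    "Role",
    "Motive",
    "UNEARNED_AUTHORITY",
    "ConfigurationError",
    "StateError",
    "AgentState",
    "UnitConfig",
    "GlobalState",
    "AdviceLink",
    "TickRecord",
    "Unit",
    "sample_attribute",
    "classify_motive",
    "visibility_threshold",
    "update_visibility",
    "compute_credibility",
    "announce_evidence",
    "assess_evidence",
    "assess_announcer_credibility",
    "credibility_doubt",
    "determine_uncertainty",
    "find_available_advisors",
    "seek_advice",
    "adoption_decision",
    "revise_belief",
    "tick",
    "commit_and_reset",
]

SCORE_MIN = 1.0
SCORE_MAX = 100.0


class ConfigurationError(ValueError):
    """A model parameter is missing, unknown, or out of its allowed range."""


class StateError(RuntimeError):
    """An operation was called on a unit in the wrong lifecycle state."""


class Role(str, enum.Enum):
    """Job position of an agent; fixes the unearned-authority component."""

    STAFF_NURSE = "staff_nurse"
    EDUCATOR = "educator"
    MANAGER = "manager"


class Motive(str, enum.Enum):
    """Motivational orientation derived from the motives score."""

    PRAGMATIC = "pragmatic"
    EPISTEMIC = "epistemic"


#: Authority assigned purely by job position, on the 1-100 scale.
UNEARNED_AUTHORITY: Mapping[Role, float] = {
    Role.STAFF_NURSE: 50.0,
    Role.EDUCATOR: 80.0,
    Role.MANAGER: 90.0,
}

#: Motives score at and above which an agent is classified epistemic.
EPISTEMIC_MOTIVE_BOUNDARY = 50.0


def _clip_score(value: float) -> float:
    return min(max(float(value), SCORE_MIN), SCORE_MAX)


@dataclass
class UnitConfig:
    """All user-settable parameters of one unit.

    Distribution means are on the 1-100 score scale.  Draws outside the
    scale are clipped, not resampled.  ``sd_attributes``/``sd_evidence`` of
    exactly 0 are allowed and produce degenerate (constant) draws, which is
    useful for limit checks.
    """

    n_staff: int = 100
    n_educators: int = 5
    n_managers: int = 1
    mean_prior_belief: float = 50.0
    mean_earned_authority: float = 50.0
    mean_motives: float = 50.0
    mean_evidence: float = 60.0
    sd_attributes: float = 10.0
    sd_evidence: float = 10.0
    credibility_threshold: float = 65.0
    evidence_tolerance: float = 20.0
    credibility_tolerance: float = 20.0
    epistemic_visibility_threshold: float = 70.0
    pragmatic_visibility_threshold: float = 30.0
    visible_earned_weight: float = 0.8
    hidden_earned_weight: float = 0.2
    #: "all": any agent may announce; "available": only currently available
    #: agents may (falls back to all agents when nobody is available).
    announcer_pool: str = "all"
    #: Whether the announcer applies the adoption/revision rule to its own
    #: announcement.  Off by default; switching it on makes every agent
    #: contract toward the evidence each tick, which the convergence checks
    #: rely on.
    announcer_updates_self: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_staff < 1:
            raise ConfigurationError(
                f"n_staff={self.n_staff}: need at least one staff nurse"
            )
        if self.n_educators < 0 or self.n_managers < 0:
            raise ConfigurationError("agent counts must be non-negative")
        for key in (
            "mean_prior_belief",
            "mean_earned_authority",
            "mean_motives",
            "mean_evidence",
            "credibility_threshold",
        ):
            value = getattr(self, key)
            if not SCORE_MIN <= value <= SCORE_MAX:
                raise ConfigurationError(
                    f"{key}={value}: must be within [{SCORE_MIN:g}, {SCORE_MAX:g}]"
                )
        for key in ("sd_attributes", "sd_evidence"):
            value = getattr(self, key)
            if value < 0:
                raise ConfigurationError(f"{key}={value}: must be >= 0")
        for key in ("evidence_tolerance", "credibility_tolerance"):
            if getattr(self, key) <= 0:
                raise ConfigurationError(f"{key} must be > 0")
        for key in ("visible_earned_weight", "hidden_earned_weight"):
            value = getattr(self, key)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{key}={value}: must be within [0, 1]")
        if not (
            self.pragmatic_visibility_threshold
            < self.epistemic_visibility_threshold
        ):
            raise ConfigurationError(
                "pragmatic_visibility_threshold must be below "
                "epistemic_visibility_threshold"
            )
        if self.announcer_pool not in ("all", "available"):
            raise ConfigurationError(
                f"announcer_pool={self.announcer_pool!r}: must be 'all' or 'available'"
            )

    @property
    def n_agents(self) -> int:
        return self.n_staff + self.n_educators + self.n_managers

    def replace(self, **changes) -> "UnitConfig":
        return replace(self, **changes)


@dataclass(slots=True)
class AgentState:
    """One agent: static attributes plus evolving per-tick state."""

    agent_id: int
    role: Role
    prior_belief: float
    earned_authority: float
    motives: float
    unearned_authority: float = 0.0
    visible: bool = False
    credibility: float = 0.0
    assessed_evidence: float = 0.0
    assessed_announcer_credibility: float = 0.0
    credibility_doubt: float = 0.0
    uncertain: bool = False
    available: bool = False
    sought_advice: bool = False
    gave_advice_count: int = 0
    out_link_count: int = 0
    revised_evidence_assessment: bool = False
    revised_credibility_assessment: bool = False
    new_belief: float = 0.0
    revised_belief: bool = False

    def __post_init__(self) -> None:
        self.unearned_authority = UNEARNED_AUTHORITY[self.role]
        self.new_belief = self.prior_belief


@dataclass(frozen=True)
class GlobalState:
    """The announcement visible to every agent at one tick."""

    announced_evidence: float
    announcer_id: int
    announcer_credibility: float
    tick_index: int


@dataclass(frozen=True)
class AdviceLink:
    """A directed seeker -> advisor edge recorded at one tick."""

    tick_index: int
    seeker_id: int
    advisor_id: int


@dataclass(frozen=True)
class TickRecord:
    """Aggregate agent counts for one tick."""

    tick_index: int
    not_visible: int
    visible: int
    available: int
    gave_advice: int
    need_advice: int
    sought_advice: int
    revised_evidence_assessment: int
    revised_credibility_assessment: int
    revised_beliefs: int
    #: split of revised_beliefs by pathway: straight from the announcement
    #: vs. after a reassessment prompted by advice
    revised_via_evidence: int = 0
    revised_via_advice: int = 0

    #: Column order used by every writer; the nine output counts.
    COUNT_FIELDS = (
        "not_visible",
        "visible",
        "available",
        "gave_advice",
        "need_advice",
        "sought_advice",
        "revised_evidence_assessment",
        "revised_credibility_assessment",
        "revised_beliefs",
    )


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------


def sample_attribute(
    mean: float, sd: float, rng: np.random.Generator
) -> float:
    """Draw Normal(mean, sd) and clip to the 1-100 score scale.

    ``sd == 0`` yields the (clipped) mean exactly.
    """
    if not SCORE_MIN <= mean <= SCORE_MAX:
        raise ConfigurationError(
            f"mean={mean}: must be within [{SCORE_MIN:g}, {SCORE_MAX:g}]"
        )
    if sd < 0:
        raise ConfigurationError(f"sd={sd}: must be >= 0")
    draw = mean if sd == 0 else rng.normal(mean, sd)
    return _clip_score(draw)


def classify_motive(motives: float) -> Motive:
    """Scores below 50 are pragmatic; 50 and above are epistemic."""
    return Motive.PRAGMATIC if motives < EPISTEMIC_MOTIVE_BOUNDARY else Motive.EPISTEMIC


def visibility_threshold(motives: float, config: UnitConfig) -> float:
    """Prior-belief level above which an agent acts on (exposes) its belief.

    Epistemic agents demand stronger belief before acting than pragmatic
    ones, so they carry the higher threshold.
    """
    if classify_motive(motives) is Motive.EPISTEMIC:
        return config.epistemic_visibility_threshold
    return config.pragmatic_visibility_threshold


def update_visibility(agent: AgentState, config: UnitConfig) -> bool:
    """Set and return whether the agent acts on its current prior belief."""
    agent.visible = agent.prior_belief > visibility_threshold(agent.motives, config)
    return agent.visible


def compute_credibility(agent: AgentState, config: UnitConfig) -> float:
    """Weighted blend of earned and unearned authority.

    Visible agents are judged mostly on earned authority (performance);
    hidden agents mostly on the unearned authority of their position.
    """
    w = config.visible_earned_weight if agent.visible else config.hidden_earned_weight
    value = w * agent.earned_authority + (1.0 - w) * agent.unearned_authority
    agent.credibility = _clip_score(value)
    return agent.credibility


def assess_evidence(prior_belief: float, announced_evidence: float) -> float:
    """Distance between an agent's prior belief and the announcement."""
    return abs(prior_belief - announced_evidence)


def assess_announcer_credibility(
    own_credibility: float, announcer_credibility: float
) -> float:
    """Distance between the agent's credibility and the announcer's."""
    return abs(own_credibility - announcer_credibility)


def credibility_doubt(
    own_credibility: float,
    announcer_credibility: float,
    credibility_threshold: float,
) -> float:
    """How far a source's credibility falls short of the assessor's bar.

    An agent holds an information source to the unit's credibility
    threshold — the same bar applied to advice givers — or to its own
    credibility standing, whichever is higher.  The doubt gap is zero when
    the source meets that bar: sources are judged credible *relative to*
    the assessor, so only a deficit raises doubt.  This one-sided gap (not
    the symmetric assessed difference, which is recorded separately) is
    what the uncertainty and adoption rules compare against the
    credibility tolerance.
    """
    bar = max(own_credibility, credibility_threshold)
    return max(bar - announcer_credibility, 0.0)


def determine_uncertainty(
    assessed_evidence: float,
    assessed_credibility: float,
    config: UnitConfig,
) -> bool:
    """Uncertain when either assessment exceeds its tolerance."""
    return (
        assessed_evidence > config.evidence_tolerance
        or assessed_credibility > config.credibility_tolerance
    )


def adoption_decision(
    assessed_evidence: float,
    assessed_credibility: float,
    config: UnitConfig,
) -> bool:
    """Adopt the evidence when both assessments sit within tolerance."""
    return (
        assessed_evidence <= config.evidence_tolerance
        and assessed_credibility <= config.credibility_tolerance
    )


def revise_belief(
    prior_belief: float,
    announced_evidence: float,
    announcer_credibility: float,
) -> float:
    """Move the belief toward the evidence, weighted by announcer credibility.

    With a fully credible announcer (100) the belief jumps to the evidence;
    with low credibility it barely moves.
    """
    step = (announcer_credibility / 100.0) * (announced_evidence - prior_belief)
    return _clip_score(prior_belief + step)


# ---------------------------------------------------------------------------
# unit-level operations
# ---------------------------------------------------------------------------


class Unit:
    """A patient-care unit: the agent population plus per-tick bookkeeping.

    ``links`` holds the advice links of the current (uncommitted) tick only;
    callers that need the full history collect them before
    :meth:`commit_and_reset`.
    """

    def __init__(
        self, config: UnitConfig, rng: Optional[np.random.Generator] = None
    ) -> None:
        self.config = config
        if rng is None:
            rng = np.random.default_rng(config.seed)
        self.agents: list[AgentState] = []
        self.links: list[AdviceLink] = []
        self.global_state: Optional[GlobalState] = None
        self.tick_index = 0
        self._tick_pending_commit = False

        roles = (
            [Role.STAFF_NURSE] * config.n_staff
            + [Role.EDUCATOR] * config.n_educators
            + [Role.MANAGER] * config.n_managers
        )
        n = len(roles)
        priors = [sample_attribute(config.mean_prior_belief, config.sd_attributes, rng) for _ in range(n)]
        earned = [sample_attribute(config.mean_earned_authority, config.sd_attributes, rng) for _ in range(n)]
        motives = [sample_attribute(config.mean_motives, config.sd_attributes, rng) for _ in range(n)]
        for i, role in enumerate(roles):
            agent = AgentState(
                agent_id=i,
                role=role,
                prior_belief=priors[i],
                earned_authority=earned[i],
                motives=motives[i],
            )
            update_visibility(agent, config)
            compute_credibility(agent, config)
            self.agents.append(agent)

    @property
    def n_agents(self) -> int:
        return len(self.agents)

    def agent(self, agent_id: int) -> AgentState:
        return self.agents[agent_id]

    def tick(self, rng: np.random.Generator) -> TickRecord:
        return tick(self, rng)

    def commit_and_reset(self) -> None:
        commit_and_reset(self, self.config)


def announce_evidence(unit: Unit, rng: np.random.Generator) -> GlobalState:
    """Pick an announcer and broadcast a fresh evidence draw.

    The announcer pool is all agents by default; with
    ``announcer_pool="available"`` only currently available agents announce,
    falling back to the whole unit when none is available.
    """
    if not unit.agents:
        raise ConfigurationError("cannot announce evidence in an empty unit")
    config = unit.config
    pool: Sequence[AgentState] = unit.agents
    if config.announcer_pool == "available":
        available = [
            a
            for a in unit.agents
            if a.visible and a.credibility >= config.credibility_threshold
        ]
        if available:
            pool = available
    announcer = pool[int(rng.integers(len(pool)))]
    evidence = sample_attribute(config.mean_evidence, config.sd_evidence, rng)
    state = GlobalState(
        announced_evidence=evidence,
        announcer_id=announcer.agent_id,
        announcer_credibility=announcer.credibility,
        tick_index=unit.tick_index,
    )
    unit.global_state = state
    return state


def find_available_advisors(unit: Unit, config: Optional[UnitConfig] = None) -> set:
    """Agents credible and visible enough to serve as opinion resources."""
    config = config or unit.config
    return {
        a.agent_id
        for a in unit.agents
        if a.visible and a.credibility >= config.credibility_threshold
    }


def seek_advice(
    seeker: AgentState,
    advisors: Iterable[int],
    unit: Unit,
    announced: GlobalState,
    rng: np.random.Generator,
) -> Optional[AdviceLink]:
    """Link an uncertain seeker to one available advisor and reassess.

    The seeker re-evaluates, from the advisor's belief and credibility,
    whichever assessment(s) drove its uncertainty: an out-of-tolerance
    evidence assessment is replaced by the advisor's distance to the
    evidence, an out-of-tolerance credibility doubt by the advisor's
    credibility standing relative to the announcer.  An in-tolerance
    assessment is left alone.  An empty advisor pool (after excluding the
    seeker) is a legitimate outcome and leaves the seeker untouched.
    """
    config = unit.config
    pool = sorted(set(advisors) - {seeker.agent_id})
    if not pool:
        return None
    advisor = unit.agent(pool[int(rng.integers(len(pool)))])
    seeker.out_link_count += 1
    seeker.sought_advice = True
    advisor.gave_advice_count += 1

    if seeker.assessed_evidence > config.evidence_tolerance:
        new_assessment = assess_evidence(
            advisor.prior_belief, announced.announced_evidence
        )
        if new_assessment != seeker.assessed_evidence:
            seeker.revised_evidence_assessment = True
        seeker.assessed_evidence = new_assessment
    if seeker.credibility_doubt > config.credibility_tolerance:
        new_assessment = assess_announcer_credibility(
            advisor.credibility, announced.announcer_credibility
        )
        new_doubt = credibility_doubt(
            seeker.credibility, advisor.credibility, config.credibility_threshold
        )
        if new_doubt != seeker.credibility_doubt:
            seeker.revised_credibility_assessment = True
        seeker.assessed_announcer_credibility = new_assessment
        seeker.credibility_doubt = new_doubt

    link = AdviceLink(
        tick_index=announced.tick_index,
        seeker_id=seeker.agent_id,
        advisor_id=advisor.agent_id,
    )
    unit.links.append(link)
    return link


def tick(unit: Unit, rng: np.random.Generator) -> TickRecord:
    """Run one full announcement/assessment/advice/revision sequence.

    The announcer neither assesses nor seeks advice about its own
    announcement; whether it applies the adoption rule to itself is
    controlled by ``announcer_updates_self``.
    """
    config = unit.config
    state = announce_evidence(unit, rng)
    announcer_id = state.announcer_id

    for agent in unit.agents:
        if agent.agent_id == announcer_id:
            continue
        agent.assessed_evidence = assess_evidence(
            agent.prior_belief, state.announced_evidence
        )
        agent.assessed_announcer_credibility = assess_announcer_credibility(
            agent.credibility, state.announcer_credibility
        )
        agent.credibility_doubt = credibility_doubt(
            agent.credibility,
            state.announcer_credibility,
            config.credibility_threshold,
        )
        agent.uncertain = determine_uncertainty(
            agent.assessed_evidence, agent.credibility_doubt, config
        )

    advisors = find_available_advisors(unit, config)
    for agent in unit.agents:
        agent.available = agent.agent_id in advisors

    for agent in unit.agents:
        if agent.uncertain and agent.agent_id != announcer_id:
            seek_advice(agent, advisors, unit, state, rng)

    for agent in unit.agents:
        if agent.agent_id == announcer_id and not config.announcer_updates_self:
            agent.new_belief = agent.prior_belief
            agent.revised_belief = False
            continue
        if adoption_decision(
            agent.assessed_evidence, agent.credibility_doubt, config
        ):
            agent.new_belief = revise_belief(
                agent.prior_belief,
                state.announced_evidence,
                state.announcer_credibility,
            )
            agent.revised_belief = True
        else:
            agent.new_belief = agent.prior_belief
            agent.revised_belief = False

    record = TickRecord(
        tick_index=unit.tick_index,
        not_visible=sum(not a.visible for a in unit.agents),
        visible=sum(a.visible for a in unit.agents),
        available=len(advisors),
        gave_advice=sum(a.gave_advice_count > 0 for a in unit.agents),
        need_advice=sum(a.uncertain for a in unit.agents),
        sought_advice=sum(a.sought_advice for a in unit.agents),
        revised_evidence_assessment=sum(
            a.revised_evidence_assessment for a in unit.agents
        ),
        revised_credibility_assessment=sum(
            a.revised_credibility_assessment for a in unit.agents
        ),
        revised_beliefs=sum(a.revised_belief for a in unit.agents),
        revised_via_evidence=sum(
            a.revised_belief and not a.sought_advice for a in unit.agents
        ),
        revised_via_advice=sum(
            a.revised_belief and a.sought_advice for a in unit.agents
        ),
    )
    unit.tick_index += 1
    unit._tick_pending_commit = True
    return record


def commit_and_reset(unit: Unit, config: Optional[UnitConfig] = None) -> Unit:
    """Carry revised beliefs into the next tick and clear per-tick state.

    Only agents that actually revised replace their prior belief; everyone
    else keeps the previous value bit-for-bit.  Visibility is then refreshed
    from the new beliefs and credibility from the new visibility.
    """
    config = config or unit.config
    if not unit._tick_pending_commit:
        raise StateError("commit_and_reset called before any tick completed")
    for agent in unit.agents:
        if agent.revised_belief:
            agent.prior_belief = agent.new_belief
        agent.assessed_evidence = 0.0
        agent.assessed_announcer_credibility = 0.0
        agent.credibility_doubt = 0.0
        agent.uncertain = False
        agent.available = False
        agent.sought_advice = False
        agent.gave_advice_count = 0
        agent.out_link_count = 0
        agent.revised_evidence_assessment = False
        agent.revised_credibility_assessment = False
        agent.revised_belief = False
        agent.new_belief = agent.prior_belief
        update_visibility(agent, config)
        compute_credibility(agent, config)
    unit.links = []
    unit.global_state = None
    unit._tick_pending_commit = False
    return unit
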