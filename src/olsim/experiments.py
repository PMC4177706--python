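"""Verification experiments: factorial parameter sweep and agent time series.

The sweep runs every cell of a full-factorial design for a number of
independent single-tick replicates; the time series runs one fixed unit for
20 chained ticks and exports per-agent trajectories plus the advice-network
edge list.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_cli.rngs import derive_rng, stream_seed
from .model_core import (
    ConfigurationError,
    TickRecord,
    Unit,
    UnitConfig,
)

__all__ = [
    "SWEEP_FACTORS",
    "TimeSeriesConfig",
    "TimeSeriesResult",
    "build_sweep_design",
    "run_sweep",
    "run_time_series",
    "identify_persistent_advisors",
    "AGENT_COLUMNS",
    "EDGE_COLUMNS",
    "SWEEP_EXTRA_COLUMNS",
]

#: Factor levels of the full-factorial sweep, in design order.
#: 3 * 2 * 2 * 2 * 2 * 2 * 3 = 288 cells.
SWEEP_FACTORS: Mapping[str, Sequence[float]] = {
    "n_staff": (50, 100, 200),
    "n_educators": (3, 7),
    "mean_prior_belief": (35.0, 65.0),
    "mean_earned_authority": (35.0, 65.0),
    "mean_motives": (35.0, 65.0),
    "mean_evidence": (40.0, 70.0),
    "credibility_threshold": (60.0, 70.0, 80.0),
}

#: Non-count observables recorded per sweep row; needed by the
#: verification regressions.
SWEEP_EXTRA_COLUMNS = (
    "revised_via_evidence",
    "revised_via_advice",
    "announcer_credibility",
    "obs_mean_prior_belief",
    "obs_mean_credibility",
    "obs_mean_new_belief",
)

AGENT_COLUMNS = (
    "tick",
    "agent_id",
    "role",
    "prior_belief",
    "motives",
    "earned_authority",
    "visible",
    "credibility",
    "assessed_evidence",
    "assessed_credibility",
    "uncertain",
    "available",
    "in_links",
    "out_links",
    "revised_belief",
    "new_belief",
)

EDGE_COLUMNS = ("tick", "seeker_id", "advisor_id")


def build_sweep_design(
    levels: Optional[Mapping[str, Sequence]] = None,
) -> list[dict]:
    """Enumerate the full factorial design in lexicographic factor order.

    Returns one dict per cell, keyed by factor name.  Cell order is the
    Cartesian product iterated with the last-listed factor fastest, which is
    deterministic for a given level mapping.
    """
    levels = dict(SWEEP_FACTORS if levels is None else levels)
    for name, values in levels.items():
        if len(tuple(values)) < 1:
            raise ConfigurationError(f"factor {name!r} has no levels")
    names = list(levels)
    return [
        dict(zip(names, combo))
        for combo in itertools.product(*(levels[name] for name in names))
    ]


def _cell_stream_seed(master_seed: int, cell: Mapping, replicate: int) -> int:
    # Keyed by unit composition only (credibility_threshold excluded): cells
    # that differ solely in the threshold then share agent draws and the
    # announcement, making availability comparisons exact.
    return stream_seed(
        master_seed,
        "sweep",
        cell["n_staff"],
        cell["n_educators"],
        cell["mean_prior_belief"],
        cell["mean_earned_authority"],
        cell["mean_motives"],
        cell["mean_evidence"],
        replicate,
    )


def run_sweep(
    design: Optional[Sequence[Mapping]] = None,
    replicates: int = 50,
    master_seed: int = 0,
    base_config: Optional[UnitConfig] = None,
) -> pd.DataFrame:
    """Run every design cell for ``replicates`` independent single ticks.

    Each (cell, replicate) initializes a fresh unit from its own substream
    and runs exactly one tick.  The returned frame has one row per run:
    factor values, replicate index, substream seed, the nine tick counts and
    the extra observables in :data:`SWEEP_EXTRA_COLUMNS`.
    """
    if design is None:
        design = build_sweep_design()
    if not design:
        raise ConfigurationError("sweep design is empty")
    if replicates < 1:
        raise ConfigurationError(f"replicates={replicates}: must be >= 1")
    base = base_config or UnitConfig()

    rows = []
    for cell_index, cell in enumerate(design):
        for rep in range(replicates):
            sub_seed = _cell_stream_seed(master_seed, cell, rep)
            config = base.replace(seed=sub_seed, **{
                "n_staff": int(cell["n_staff"]),
                "n_educators": int(cell["n_educators"]),
                "mean_prior_belief": float(cell["mean_prior_belief"]),
                "mean_earned_authority": float(cell["mean_earned_authority"]),
                "mean_motives": float(cell["mean_motives"]),
                "mean_evidence": float(cell["mean_evidence"]),
                "credibility_threshold": float(cell["credibility_threshold"]),
            })
            rng = np.random.default_rng(sub_seed)
            unit = Unit(config, rng)
            record = unit.tick(rng)
            row = {**cell, "cell_index": cell_index, "replicate": rep, "seed": sub_seed}
            for name in TickRecord.COUNT_FIELDS:
                row[name] = getattr(record, name)
            row["revised_via_evidence"] = record.revised_via_evidence
            row["revised_via_advice"] = record.revised_via_advice
            row["announcer_credibility"] = unit.global_state.announcer_credibility
            row["obs_mean_prior_belief"] = float(
                np.mean([a.prior_belief for a in unit.agents])
            )
            row["obs_mean_credibility"] = float(
                np.mean([a.credibility for a in unit.agents])
            )
            row["obs_mean_new_belief"] = float(
                np.mean([a.new_belief for a in unit.agents])
            )
            rows.append(row)
    columns = (
        list(SWEEP_FACTORS)
        + ["cell_index", "replicate", "seed"]
        + list(TickRecord.COUNT_FIELDS)
        + list(SWEEP_EXTRA_COLUMNS)
    )
    return pd.DataFrame(rows, columns=columns)


@dataclass
class TimeSeriesConfig:
    """Fixed-unit configuration for the 20-tick individual-agent series."""

    n_staff: int = 100
    n_educators: int = 5
    n_managers: int = 1
    mean_prior_belief: float = 50.0
    mean_earned_authority: float = 50.0
    mean_motives: float = 50.0
    mean_evidence: float = 60.0
    credibility_threshold: float = 65.0
    n_ticks: int = 20

    def __post_init__(self) -> None:
        if self.n_ticks < 1:
            raise ConfigurationError(f"n_ticks={self.n_ticks}: must be >= 1")

    @property
    def n_agents(self) -> int:
        return self.n_staff + self.n_educators + self.n_managers

    def to_unit_config(self, seed: int = 0, **overrides) -> UnitConfig:
        return UnitConfig(
            n_staff=self.n_staff,
            n_educators=self.n_educators,
            n_managers=self.n_managers,
            mean_prior_belief=self.mean_prior_belief,
            mean_earned_authority=self.mean_earned_authority,
            mean_motives=self.mean_motives,
            mean_evidence=self.mean_evidence,
            credibility_threshold=self.credibility_threshold,
            seed=seed,
            **overrides,
        )


@dataclass
class TimeSeriesResult:
    """Per-agent trajectories, advice edges and tick aggregates."""

    agents: pd.DataFrame
    edges: pd.DataFrame
    ticks: pd.DataFrame
    config: TimeSeriesConfig
    master_seed: int


def run_time_series(
    config: Optional[TimeSeriesConfig] = None,
    master_seed: int = 0,
    unit_config: Optional[UnitConfig] = None,
) -> TimeSeriesResult:
    """Run one unit through ``config.n_ticks`` chained ticks.

    Earned authority and motives are drawn once at initialization and never
    touched; beliefs carry over between ticks via commit.  Agent rows record
    the state as of the tick: the prior belief the agent entered with and
    the new belief it left with.
    """
    config = config or TimeSeriesConfig()
    if unit_config is None:
        unit_config = config.to_unit_config(seed=stream_seed(master_seed, "ts-init"))
    init_rng = derive_rng(master_seed, "ts-init")
    unit = Unit(unit_config, init_rng)

    agent_rows = []
    edge_rows = []
    tick_rows = []
    for t in range(config.n_ticks):
        rng = derive_rng(master_seed, "ts-tick", t)
        record = unit.tick(rng)
        tick_rows.append(
            {"tick_index": t, **{
                name: getattr(record, name) for name in TickRecord.COUNT_FIELDS
            }}
        )
        for a in unit.agents:
            agent_rows.append(
                {
                    "tick": t,
                    "agent_id": a.agent_id,
                    "role": a.role.value,
                    "prior_belief": a.prior_belief,
                    "motives": a.motives,
                    "earned_authority": a.earned_authority,
                    "visible": a.visible,
                    "credibility": a.credibility,
                    "assessed_evidence": a.assessed_evidence,
                    "assessed_credibility": a.assessed_announcer_credibility,
                    "uncertain": a.uncertain,
                    "available": a.available,
                    "in_links": a.gave_advice_count,
                    "out_links": a.out_link_count,
                    "revised_belief": a.revised_belief,
                    "new_belief": a.new_belief,
                }
            )
        for link in unit.links:
            edge_rows.append(
                {
                    "tick": link.tick_index,
                    "seeker_id": link.seeker_id,
                    "advisor_id": link.advisor_id,
                }
            )
        unit.commit_and_reset()

    agents = pd.DataFrame(agent_rows, columns=AGENT_COLUMNS)
    edges = pd.DataFrame(edge_rows, columns=EDGE_COLUMNS)
    ticks = pd.DataFrame(
        tick_rows, columns=["tick_index", *TickRecord.COUNT_FIELDS]
    )
    return TimeSeriesResult(
        agents=agents, edges=edges, ticks=ticks, config=config,
        master_seed=master_seed,
    )


def identify_persistent_advisors(
    edges: pd.DataFrame, min_ticks: int = 2
) -> set:
    """Agents that received advice links at ``min_ticks`` or more distinct ticks."""
    if min_ticks < 1:
        raise ConfigurationError(f"min_ticks={min_ticks}: must be >= 1")
    if edges.empty:
        return set()
    per_advisor = edges.groupby("advisor_id")["tick"].nunique()
    return set(per_advisor.index[per_advisor >= min_ticks])
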