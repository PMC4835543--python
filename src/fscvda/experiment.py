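"""Cohort-level orchestration of the four-session devaluation design.

Each animal performs two baseline sessions (A and B), each preceding a
devaluation session (devalue-food and devalue-sucrose, order
counterbalanced across animals).  Devaluation sessions start from the
animal's baseline value state passed through selective satiation; learned
predictions then update with experience inside the session, which is what
produces the within-session dynamics the analyses measure.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import alignment, stats
from .task import (BehaviorParams, SessionSchedule, SimulatedSession,
                   TaskConfig, ValueState, apply_satiation, generate_schedule,
                   simulate_behavior)
from .voltammetry import (ConcentrationTrace, KineticsParams,
                          simulate_concentration)

SESSION_ORDER_FOOD_FIRST = ["baseline_A", "devalue_food",
                            "baseline_B", "devalue_sucrose"]
SESSION_ORDER_SUCROSE_FIRST = ["baseline_A", "devalue_sucrose",
                               "baseline_B", "devalue_food"]


@dataclass(frozen=True)
class SatiationParams:
    devaluation_factor: float = 0.3
    gain_factor: float = 0.7
    valued_boost: float = 1.4
    boost_valued_sucrose: bool = True


@dataclass(frozen=True)
class CohortParams:
    """Cohort composition and between-animal heterogeneity.

    Per-animal learning rates, gains and satiation factors are jittered
    around the population values (truncated normal) so group-level tests
    see realistic between-subject variance.
    """

    n_animals: int = 8
    alpha: float = 0.1
    alpha_sd: float = 0.03
    beta: float = 0.5
    beta_sd: float = 0.1
    gain_sd: float = 0.05
    devaluation_sd: float = 0.05
    boost_sd: float = 0.1


@dataclass
class ExperimentConfig:
    task: TaskConfig = field(default_factory=TaskConfig)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    satiation: SatiationParams = field(default_factory=SatiationParams)
    cohort: CohortParams = field(default_factory=CohortParams)
    seed: int = 0

    def to_json(self, path=None) -> str:
        payload = dataclasses.asdict(self)
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text

    @classmethod
    def from_json(cls, path_or_text) -> "ExperimentConfig":
        if isinstance(path_or_text, str) and path_or_text.lstrip().startswith("{"):
            payload = json.loads(path_or_text)
        else:
            with open(path_or_text) as f:
                payload = json.load(f)
        return cls(task=TaskConfig(**payload["task"]),
                   behavior=BehaviorParams(**payload["behavior"]),
                   kinetics=KineticsParams(**payload["kinetics"]),
                   satiation=SatiationParams(**payload["satiation"]),
                   cohort=CohortParams(**payload["cohort"]),
                   seed=int(payload.get("seed", 0)))


@dataclass
class SessionData:
    """Everything one recorded session yields before statistics."""

    animal: str
    session_kind: str
    session: SimulatedSession
    trace: ConcentrationTrace
    devalued: str  # "food" | "sucrose" | "none"

    @property
    def schedule(self) -> SessionSchedule:
        return self.session.schedule

    def aligned(self, event: str, **kw) -> alignment.AlignedTraces:
        events = alignment.events_from_schedule(
            self.schedule, event=event,
            extra={"animal": self.animal, "devalued": self.devalued}, **kw)
        al = alignment.align(self.trace.times, self.trace.da, events,
                             event=event)
        al.labels = alignment.encode_labels(al.labels)
        return al


def _truncnorm(rng, mean, sd, lo, hi):
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def animal_state(cfg: ExperimentConfig, rng) -> ValueState:
    c = cfg.cohort
    return ValueState(alpha=_truncnorm(rng, c.alpha, c.alpha_sd, 0.01, 0.99),
                      beta=max(0.01, rng.normal(c.beta, c.beta_sd)))


def run_session(cfg: ExperimentConfig, baseline_state: ValueState,
                kind: str, seed: int, animal: str = "r0",
                satiation: Optional[SatiationParams] = None,
                with_trace: bool = True) -> SessionData:
    """Simulate one session end to end (schedule, behavior, dopamine)."""
    sat = satiation or cfg.satiation
    rng = np.random.default_rng(seed)
    state = baseline_state
    devalued = "none"
    if kind == "devalue_food":
        state = apply_satiation(state, "food", sat.devaluation_factor,
                                sat.gain_factor, sat.valued_boost,
                                sat.boost_valued_sucrose)
        devalued = "food"
    elif kind == "devalue_sucrose":
        state = apply_satiation(state, "sucrose", sat.devaluation_factor,
                                sat.gain_factor, sat.valued_boost,
                                sat.boost_valued_sucrose)
        devalued = "sucrose"
    sched = generate_schedule(cfg.task, kind, int(rng.integers(2 ** 31)))
    sim = simulate_behavior(sched, state, int(rng.integers(2 ** 31)),
                            cfg.behavior)
    trace = simulate_concentration(sim, cfg.kinetics,
                                   int(rng.integers(2 ** 31))) if with_trace \
        else ConcentrationTrace(times=np.array([0.0, 0.1]),
                                da=np.zeros(2), ph_shift=np.zeros(2),
                                truth_labels=pd.DataFrame())
    return SessionData(animal=animal, session_kind=kind, session=sim,
                       trace=trace, devalued=devalued)


def jittered_satiation(cfg: ExperimentConfig, rng) -> SatiationParams:
    c, s = cfg.cohort, cfg.satiation
    return SatiationParams(
        devaluation_factor=_truncnorm(rng, s.devaluation_factor,
                                      c.devaluation_sd, 0.05, 0.9),
        gain_factor=_truncnorm(rng, s.gain_factor, c.gain_sd, 0.3, 1.0),
        valued_boost=_truncnorm(rng, s.valued_boost, c.boost_sd, 1.0, 2.0),
        boost_valued_sucrose=s.boost_valued_sucrose)


def run_experiment(cfg: ExperimentConfig,
                   seed: Optional[int] = None,
                   with_traces: bool = True) -> list[SessionData]:
    """Simulate the full cohort: n_animals x four counterbalanced sessions."""
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    out: list[SessionData] = []
    for i in range(cfg.cohort.n_animals):
        animal = f"r{i:02d}"
        base = animal_state(cfg, rng)
        sat = jittered_satiation(cfg, rng)
        order = SESSION_ORDER_FOOD_FIRST if i % 2 == 0 \
            else SESSION_ORDER_SUCROSE_FIRST
        for kind in order:
            out.append(run_session(cfg, base, kind,
                                   int(rng.integers(2 ** 31)),
                                   animal=animal, satiation=sat,
                                   with_trace=with_traces))
    return out


def reward_window_table(sessions: list[SessionData],
                        window: str = "reward_3s") -> pd.DataFrame:
    """Tidy per-trial reward-window dopamine across sessions."""
    frames = []
    for s in sessions:
        al = s.aligned("reward")
        if al.n_trials == 0:
            continue
        df = al.labels.copy()
        df["window_mean"] = alignment.window_mean(al, window)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
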