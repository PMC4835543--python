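"""Two-option operant task: session schedules, simulated choice behavior,
and the latent subjective-value state.

The task is a blocked forced/choice design: each block presents eight forced
trials (four per lever, pseudorandom order) followed by four free-choice
trials.  One lever earns a food pellet, the other a bolus of sucrose
solution.  A fixed fraction of trials are "surprise" trials — SWITCH (the
other reinforcer is delivered at standard magnitude) or MORE (the expected
reinforcer at several times the standard magnitude).  Surprise counts are
enforced exactly per session and their positions shuffled under the seed, so
design counts are deterministic while placement is pseudorandom.

Value state separates two quantities that selective satiation dissociates:

* ``v_food`` / ``v_sucrose`` — learned reward predictions.  They drive
  cue-evoked dopamine and choice, and update by a delta rule with experience.
* ``u_food`` / ``u_sucrose`` — current intrinsic unit values of consuming one
  standard reward.  Satiation rescales these immediately; predictions only
  catch up through within-session learning.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

FOOD = "food"
SUCROSE = "sucrose"
IDENTITIES = (FOOD, SUCROSE)

TRIAL_CLASSES = ("forced_food", "forced_sucrose", "choice")
OUTCOME_CLASSES = ("standard", "MORE", "SWITCH", "omitted")
SESSION_KINDS = ("baseline_A", "baseline_B", "devalue_food", "devalue_sucrose")

#: column order of the tab-separated session event log
TRIAL_COLUMNS = [
    "index", "block", "trial_class",
    "cue_onset", "lever_extension", "response_time", "reward_delivery",
    "chosen_option", "outcome_identity", "outcome_class",
    "wrong_lever", "missed", "latency",
]
_TIME_COLUMNS = ["cue_onset", "lever_extension", "response_time",
                 "reward_delivery", "latency"]


class DegenerateScheduleError(ValueError):
    """A requested surprise rate rounds to zero trials of that type."""


def other_identity(identity: str) -> str:
    return SUCROSE if identity == FOOD else FOOD


@dataclass(frozen=True)
class TaskConfig:
    """Design parameters of one session.

    Defaults give 10 blocks x (8 forced + 4 choice) = 120 trials, with
    SWITCH on 10% of forced and 5% of choice trials, MORE on 5% of forced
    trials at four times the standard magnitude.  Rewards are a 45-mg food
    pellet or 95 ul of 20% (w/v) sucrose solution.
    """

    n_blocks: int = 10
    forced_per_block: int = 8
    choice_per_block: int = 4
    forced_per_lever: int = 4
    p_switch_forced: float = 0.10
    p_switch_choice: float = 0.05
    p_more_forced: float = 0.05
    more_multiplier: float = 4.0
    pellet_mass_mg: float = 45.0
    sucrose_volume_ul: float = 95.0
    sucrose_concentration_pct: float = 20.0
    cue_to_lever_s: float = 5.0      # cue onset -> lever extension
    lever_to_reward_s: float = 2.0   # lever extension -> reward delivery
    iti_s: float = 8.0               # reward delivery -> next cue
    session_start_s: float = 5.0     # pre-roll before the first cue

    def __post_init__(self) -> None:
        if self.forced_per_block != 2 * self.forced_per_lever:
            raise ValueError("forced_per_block must equal 2 * forced_per_lever")
        if self.forced_per_block % 2:
            raise ValueError("forced_per_block must be even")
        for name in ("p_switch_forced", "p_switch_choice", "p_more_forced"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.more_multiplier <= 1.0:
            raise ValueError("more_multiplier must exceed 1")
        if min(self.cue_to_lever_s, self.lever_to_reward_s, self.iti_s) <= 0:
            raise ValueError("event timing intervals must be positive")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * (self.forced_per_block + self.choice_per_block)

    @property
    def n_forced(self) -> int:
        return self.n_blocks * self.forced_per_block

    @property
    def n_choice(self) -> int:
        return self.n_blocks * self.choice_per_block

    @property
    def trial_period_s(self) -> float:
        return self.cue_to_lever_s + self.lever_to_reward_s + self.iti_s

    def surprise_counts(self) -> dict:
        """Exact per-session surprise counts, round(rate x trial count)."""
        return {
            "switch_forced": int(round(self.p_switch_forced * self.n_forced)),
            "more_forced": int(round(self.p_more_forced * self.n_forced)),
            "switch_choice": int(round(self.p_switch_choice * self.n_choice)),
        }


@dataclass
class TrialRecord:
    """One trial: timestamps (s from session start), type, choice, outcome."""

    index: int
    block: int
    trial_class: str
    cue_onset: float
    lever_extension: float
    response_time: float = math.nan
    reward_delivery: float = math.nan
    chosen_option: str = "none"          # food_lever | sucrose_lever | none
    outcome_identity: str = "none"       # food | sucrose | none
    outcome_class: str = "standard"      # standard | MORE | SWITCH | omitted
    wrong_lever: bool = False
    missed: bool = False
    latency: float = math.nan

    @property
    def forced_identity(self) -> Optional[str]:
        if self.trial_class == "forced_food":
            return FOOD
        if self.trial_class == "forced_sucrose":
            return SUCROSE
        return None

    @property
    def rewarded(self) -> bool:
        return self.outcome_identity in IDENTITIES


def outcome_magnitude(record: TrialRecord, config: TaskConfig) -> float:
    """Delivered magnitude in units of the standard reward amount."""
    if not record.rewarded:
        return 0.0
    return config.more_multiplier if record.outcome_class == "MORE" else 1.0


@dataclass
class SessionSchedule:
    """Ordered trials of one session plus the seed that generated them."""

    session_kind: str
    trials: list[TrialRecord]
    rng_seed: int
    config: TaskConfig = field(default_factory=TaskConfig)

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(t) for t in self.trials]
        return pd.DataFrame(rows, columns=TRIAL_COLUMNS)

    def to_tsv(self, path) -> None:
        df = self.to_frame().copy()
        for c in _TIME_COLUMNS:
            df[c] = df[c].map(lambda x: "" if pd.isna(x) else f"{x:.3f}")
        df["wrong_lever"] = df["wrong_lever"].astype(int)
        df["missed"] = df["missed"].astype(int)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, session_kind: str = "baseline_A",
                 rng_seed: int = 0, config: Optional[TaskConfig] = None
                 ) -> "SessionSchedule":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"event log missing columns: {missing}")
        trials = []
        for _, row in df.iterrows():
            kw = {c: row[c] for c in TRIAL_COLUMNS}
            for c in _TIME_COLUMNS:
                kw[c] = float(kw[c]) if pd.notna(kw[c]) and kw[c] != "" else math.nan
            kw["index"] = int(kw["index"])
            kw["block"] = int(kw["block"])
            kw["wrong_lever"] = bool(int(kw["wrong_lever"]))
            kw["missed"] = bool(int(kw["missed"]))
            trials.append(TrialRecord(**kw))
        return cls(session_kind=session_kind, trials=trials,
                   rng_seed=rng_seed, config=config or TaskConfig())

    def counts(self) -> dict:
        df = self.to_frame()
        forced = df.trial_class.str.startswith("forced")
        return {
            "n_trials": len(df),
            "n_forced": int(forced.sum()),
            "n_choice": int((~forced).sum()),
            "switch_forced": int((forced & (df.outcome_class == "SWITCH")).sum()),
            "more_forced": int((forced & (df.outcome_class == "MORE")).sum()),
            "switch_choice": int((~forced & (df.outcome_class == "SWITCH")).sum()),
        }


def generate_schedule(config: TaskConfig, kind: str, seed: int) -> SessionSchedule:
    """Build a pseudorandom session schedule with exact surprise counts.

    Each block places ``forced_per_lever`` forced trials of each identity in
    a shuffled order, then the free-choice trials.  SWITCH and MORE
    assignments are drawn without replacement over the forced (respectively
    choice) trial positions, so every session realises exactly
    ``round(rate * count)`` surprise trials of each type.

    Choice-trial outcome identity is left unresolved ("none") until
    :func:`simulate_behavior` resolves the animal's choice; the surprise
    class of each trial is fixed here.
    """
    if kind not in SESSION_KINDS:
        raise ValueError(f"unknown session kind {kind!r}; expected one of {SESSION_KINDS}")
    counts = config.surprise_counts()
    for name, rate in (("switch_forced", config.p_switch_forced),
                       ("more_forced", config.p_more_forced),
                       ("switch_choice", config.p_switch_choice)):
        if rate > 0 and counts[name] == 0:
            raise DegenerateScheduleError(
                f"{name} rate {rate} rounds to zero trials — degenerate schedule")
    if counts["switch_forced"] + counts["more_forced"] > config.n_forced:
        raise ValueError("surprise counts exceed forced trial count")

    rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []
    forced_positions: list[int] = []
    choice_positions: list[int] = []
    t_index = 0
    for b in range(config.n_blocks):
        identities = [FOOD] * config.forced_per_lever + [SUCROSE] * config.forced_per_lever
        rng.shuffle(identities)
        for ident in identities:
            forced_positions.append(t_index)
            trials.append(_blank_trial(t_index, b, f"forced_{ident}", config))
            t_index += 1
        for _ in range(config.choice_per_block):
            choice_positions.append(t_index)
            trials.append(_blank_trial(t_index, b, "choice", config))
            t_index += 1

    surprise_forced = rng.choice(len(forced_positions),
                                 counts["switch_forced"] + counts["more_forced"],
                                 replace=False)
    for j in surprise_forced[:counts["switch_forced"]]:
        trials[forced_positions[j]].outcome_class = "SWITCH"
    for j in surprise_forced[counts["switch_forced"]:]:
        trials[forced_positions[j]].outcome_class = "MORE"
    for j in rng.choice(len(choice_positions), counts["switch_choice"], replace=False):
        trials[choice_positions[j]].outcome_class = "SWITCH"

    return SessionSchedule(session_kind=kind, trials=trials,
                           rng_seed=int(seed), config=config)


def _blank_trial(index: int, block: int, trial_class: str, config: TaskConfig) -> TrialRecord:
    cue = config.session_start_s + index * config.trial_period_s
    return TrialRecord(index=index, block=block, trial_class=trial_class,
                       cue_onset=cue, lever_extension=cue + config.cue_to_lever_s)


# ---------------------------------------------------------------------------
# value state and learning


@dataclass(frozen=True)
class ValueState:
    """Subjective-value state of one animal.

    ``v_*`` are learned predictions (arbitrary units, 1.0 = asymptotic
    baseline value of one standard reward); ``u_*`` are the intrinsic unit
    values of consuming one standard reward in the current physiological
    state.  ``general_gain`` multiplicatively scales anticipatory
    (cue/lever) dopamine drive; satiation lowers it below 1.
    """

    v_food: float = 1.0
    v_sucrose: float = 1.0
    alpha: float = 0.1
    beta: float = 0.5            # softmax choice temperature
    general_gain: float = 1.0
    u_food: float = 1.0
    u_sucrose: float = 1.0
    devalued: Optional[str] = None

    def __post_init__(self) -> None:
        vals = (self.v_food, self.v_sucrose, self.u_food, self.u_sucrose,
                self.beta, self.general_gain)
        if not all(math.isfinite(x) for x in vals):
            raise ValueError("non-finite value state")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha={self.alpha} outside [0, 1]")
        if not 0.0 < self.general_gain <= 1.0:
            raise ValueError("general_gain must lie in (0, 1]")

    def v(self, identity: str) -> float:
        return self.v_food if identity == FOOD else self.v_sucrose

    def u(self, identity: str) -> float:
        return self.u_food if identity == FOOD else self.u_sucrose

    def p_food(self) -> float:
        """Softmax probability of choosing the food lever."""
        dv = self.v_food - self.v_sucrose
        if self.beta <= 0:
            return 0.5 if dv == 0 else (1.0 if dv > 0 else 0.0)
        return float(1.0 / (1.0 + math.exp(-dv / self.beta)))


def update_values(state: ValueState, outcome_identity: str,
                  outcome_magnitude: float) -> ValueState:
    """Delta-rule update of the consumed identity's prediction.

    v_x <- v_x + alpha * (magnitude * u_x - v_x); the other prediction is
    untouched.
    """
    if outcome_magnitude < 0:
        raise ValueError("outcome magnitude must be non-negative")
    if outcome_identity not in IDENTITIES:
        return state
    target = outcome_magnitude * state.u(outcome_identity)
    if outcome_identity == FOOD:
        return replace(state, v_food=state.v_food + state.alpha * (target - state.v_food))
    return replace(state, v_sucrose=state.v_sucrose + state.alpha * (target - state.v_sucrose))


def apply_satiation(state: ValueState, reinforcer: str,
                    devaluation_factor: float = 0.3,
                    gain_factor: float = 0.7,
                    valued_boost: float = 1.4,
                    boost_valued_sucrose: bool = True) -> ValueState:
    """Selective satiation on one reinforcer.

    Scales the devalued reinforcer's intrinsic unit value by
    ``devaluation_factor`` (< 1), reduces ``general_gain`` by
    ``gain_factor`` (the immediate, non-selective attenuation of
    anticipatory dopamine), and — by default only when food is the sated
    reinforcer — boosts the valued sucrose unit value by ``valued_boost``
    (the asymmetric contrast effect on the sweet liquid).  Learned
    predictions ``v_*`` are deliberately untouched: they update only with
    experience of the reinforcers in the new state.
    """
    if reinforcer not in IDENTITIES:
        raise ValueError(f"unknown reinforcer {reinforcer!r}")
    u_food, u_sucrose = state.u_food, state.u_sucrose
    if reinforcer == FOOD:
        u_food *= devaluation_factor
        if boost_valued_sucrose:
            u_sucrose *= valued_boost
    else:
        u_sucrose *= devaluation_factor
    return replace(state, u_food=u_food, u_sucrose=u_sucrose,
                   general_gain=state.general_gain * gain_factor,
                   devalued=reinforcer)


# ---------------------------------------------------------------------------
# behavior simulation


@dataclass(frozen=True)
class BehaviorParams:
    """Response-generation parameters.

    Latencies are lognormal (median ``latency_median_s``, log-sd
    ``latency_sigma``) clipped to fit before reward delivery.  Miss and
    wrong-lever probabilities on forced trials are multiplied by
    ``devalued_inflation`` when the extended lever's reinforcer is devalued.
    """

    p_missed: float = 0.02
    p_wrong: float = 0.02
    devalued_inflation: float = 4.0
    latency_median_s: float = 0.5
    latency_sigma: float = 0.4
    devalued_latency_factor: float = 1.5


@dataclass
class SimulatedSession:
    schedule: SessionSchedule
    trajectory: pd.DataFrame
    final_state: ValueState


def simulate_behavior(schedule: SessionSchedule, state: ValueState, seed: int,
                      behavior: BehaviorParams = BehaviorParams()
                      ) -> SimulatedSession:
    """Resolve choices, latencies, errors, rewards, and the value trajectory.

    Trials are processed in order: choice trials are resolved by softmax on
    the current predictions, outcomes delivered per the scheduled surprise
    class, and predictions updated by the delta rule after every rewarded
    trial.  Returns a completed copy of the schedule plus a per-trial record
    of the pre-trial value state (used downstream to generate dopamine).
    """
    cfg = schedule.config
    rng = np.random.default_rng(seed)
    trials = [replace(t) for t in schedule.trials]
    rows = []
    for t in trials:
        pre = state
        forced_id = t.forced_identity
        devalued_trial = forced_id is not None and forced_id == state.devalued

        p_miss = behavior.p_missed
        p_wrong = behavior.p_wrong if forced_id is not None else 0.0
        lat_median = behavior.latency_median_s
        if devalued_trial:
            p_miss = min(0.9, p_miss * behavior.devalued_inflation)
            p_wrong = min(0.9, p_wrong * behavior.devalued_inflation)
            lat_median *= behavior.devalued_latency_factor

        p_food_choice = state.p_food() if t.trial_class == "choice" else math.nan
        missed = rng.random() < p_miss
        wrong = (not missed) and rng.random() < p_wrong

        if missed:
            t.missed = True
            t.chosen_option = "none"
            t.outcome_identity = "none"
            t.outcome_class = "omitted"
        else:
            lat = float(np.exp(np.log(lat_median)
                               + behavior.latency_sigma * rng.standard_normal()))
            lat = min(max(lat, 0.05), cfg.lever_to_reward_s - 0.05)
            t.latency = lat
            t.response_time = t.lever_extension + lat
            if t.trial_class == "choice":
                chosen = FOOD if rng.random() < p_food_choice else SUCROSE
            else:
                chosen = other_identity(forced_id) if wrong else forced_id
            t.chosen_option = f"{chosen}_lever"
            if wrong:
                t.wrong_lever = True
                t.outcome_identity = "none"
                t.outcome_class = "omitted"
            else:
                if t.outcome_class == "SWITCH":
                    t.outcome_identity = other_identity(chosen)
                else:
                    t.outcome_identity = chosen
                t.reward_delivery = t.lever_extension + cfg.lever_to_reward_s

        rows.append({
            "index": t.index, "v_food_pre": pre.v_food, "v_sucrose_pre": pre.v_sucrose,
            "u_food": pre.u_food, "u_sucrose": pre.u_sucrose,
            "general_gain": pre.general_gain, "p_food": p_food_choice,
            "devalued": pre.devalued or "none",
        })
        if t.rewarded:
            state = update_values(state, t.outcome_identity,
                                  outcome_magnitude(t, cfg))

    done = SessionSchedule(session_kind=schedule.session_kind, trials=trials,
                           rng_seed=schedule.rng_seed, config=cfg)
    return SimulatedSession(schedule=done,
                            trajectory=pd.DataFrame(rows),
                            final_state=state)
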