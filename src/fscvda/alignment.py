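"""Peri-event alignment of dopamine traces and windowed trial summaries.

Every analysis downstream works on :class:`AlignedTraces`: a rectangular
trials-by-timepoints array locked to a task event (cue onset, lever
extension, or reward delivery), baseline-subtracted per trial, with the
trial labels carried alongside.  The default window spans 2 s before to 5 s
after the event and the default baseline is the 2 s preceding it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .task import SessionSchedule, outcome_magnitude

logger = logging.getLogger(__name__)

#: named analysis windows, in seconds relative to the aligned event
WINDOWS = {
    "reward_5s": (0.0, 5.0),   # post reward delivery
    "reward_3s": (0.0, 3.0),   # post reward delivery
    "cue_5s": (0.0, 5.0),      # cue onset -> lever extension
    "lever_2s": (0.0, 2.0),    # lever extension -> reward delivery
}

EVENT_COLUMNS = {"cue": "cue_onset", "lever": "lever_extension",
                 "reward": "reward_delivery"}


@dataclass
class AlignedTraces:
    """Trials x timepoints dopamine locked to one event.

    ``data[i, j]`` is baseline-subtracted dopamine (nM) of trial ``i`` at
    ``time[j]`` seconds from the event.  ``labels`` has one row per retained
    trial; ``excluded`` lists trial indices dropped because the window fell
    outside the recording.
    """

    data: np.ndarray
    time: np.ndarray
    labels: pd.DataFrame
    event: str = "reward"
    excluded: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.shape != (len(self.labels), len(self.time)):
            raise ValueError("data shape must be (n_trials, n_timepoints)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, mask) -> "AlignedTraces":
        mask = np.asarray(mask)
        return AlignedTraces(data=self.data[mask], time=self.time,
                             labels=self.labels.loc[mask].reset_index(drop=True),
                             event=self.event, excluded=list(self.excluded))

    def to_tsv(self, path) -> None:
        df = pd.concat(
            [self.labels.reset_index(drop=True),
             pd.DataFrame(self.data, columns=[f"t{t:+.1f}" for t in self.time])],
            axis=1)
        df.to_csv(path, sep="\t", index=False)

    def plot(self, by: Optional[str] = None, ax=None):
        """Quick diagnostic plot of the mean aligned trace (optionally by label)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        if by is None:
            ax.plot(self.time, self.data.mean(axis=0))
        else:
            for val, grp in self.labels.groupby(by).groups.items():
                ax.plot(self.time, self.data[np.asarray(grp)].mean(axis=0),
                        label=f"{by}={val}")
            ax.legend()
        ax.axvline(0.0, color="k", lw=0.5)
        ax.set_xlabel(f"time from {self.event} (s)")
        ax.set_ylabel("dopamine (nM)")
        return ax


def align(times: np.ndarray, da: np.ndarray, events: pd.DataFrame,
          event_time_col: str = "event_time",
          window: tuple = (-2.0, 5.0),
          baseline_window: Optional[tuple] = (-2.0, 0.0),
          event: str = "reward") -> AlignedTraces:
    """Cut one peri-event row per event and baseline-subtract it.

    Parameters
    ----------
    times, da : ndarray
        Uniformly sampled recording (seconds, nM).
    events : DataFrame
        One row per event; ``event_time_col`` holds the event time, all
        other columns are carried into ``labels``.
    window : (start, stop)
        Seconds relative to the event.
    baseline_window : (start, stop) or None
        Per-trial mean over this pre-event span is subtracted; None skips
        baseline subtraction.

    Events whose window extends past the recording edge are excluded, logged,
    and listed in ``excluded``.
    """
    times = np.asarray(times, float)
    da = np.asarray(da, float)
    if len(times) < 2:
        raise ValueError("recording too short to align")
    dt = times[1] - times[0]
    if not np.allclose(np.diff(times), dt, rtol=1e-6, atol=1e-9):
        raise ValueError("alignment requires uniform sampling")
    lo = int(np.floor(window[0] / dt + 1e-9))
    hi = int(np.floor(window[1] / dt + 1e-9))
    offsets = np.arange(lo, hi + 1)
    rel_time = offsets * dt

    rows, kept, excluded = [], [], []
    for _, ev in events.iterrows():
        t_ev = float(ev[event_time_col])
        if not np.isfinite(t_ev):
            excluded.append(ev.get("index", None))
            continue
        center = int(round((t_ev - times[0]) / dt))
        i0, i1 = center + lo, center + hi
        if i0 < 0 or i1 >= len(da):
            excluded.append(ev.get("index", None))
            logger.info("event at %.3f s too close to recording edge; excluded",
                        t_ev)
            continue
        row = da[i0:i1 + 1].copy()
        if baseline_window is not None:
            bmask = (rel_time >= baseline_window[0] - 1e-9) \
                & (rel_time <= baseline_window[1] + 1e-9)
            if not bmask.any():
                raise ValueError("baseline window outside the aligned window")
            row = row - row[bmask].mean()
        rows.append(row)
        kept.append(ev)

    labels = pd.DataFrame(kept).reset_index(drop=True) if kept else \
        events.iloc[:0].copy()
    data = np.array(rows) if rows else np.empty((0, len(rel_time)))
    return AlignedTraces(data=data, time=rel_time, labels=labels,
                         event=event, excluded=excluded)


def events_from_schedule(schedule: SessionSchedule, event: str = "reward",
                         rewarded_only: bool = True,
                         extra: Optional[dict] = None) -> pd.DataFrame:
    """Tabulate event times + trial labels from a completed schedule.

    Missed and wrong-lever trials are excluded when ``rewarded_only`` (the
    dopamine analyses consider rewarded outcomes); exclusion counts are
    logged.
    """
    if event not in EVENT_COLUMNS:
        raise ValueError(f"unknown event {event!r}; expected {list(EVENT_COLUMNS)}")
    df = schedule.to_frame()
    df["event_time"] = df[EVENT_COLUMNS[event]]
    df["session_kind"] = schedule.session_kind
    df["magnitude"] = [outcome_magnitude(t, schedule.config)
                       for t in schedule.trials]
    if extra:
        for k, v in extra.items():
            df[k] = v
    if rewarded_only:
        bad = df["missed"] | df["wrong_lever"] \
            | ~df["outcome_identity"].isin(("food", "sucrose"))
        n_bad = int(bad.sum())
        if n_bad:
            logger.info("excluding %d missed/wrong/unrewarded trials", n_bad)
        df = df.loc[~bad]
    df = df[np.isfinite(df["event_time"])]
    return df.reset_index(drop=True)


def encode_labels(labels: pd.DataFrame) -> pd.DataFrame:
    """Add the canonical {0,1} regressor codings to a label table.

    is_more    : outcome_class == MORE
    is_switch  : outcome_class == SWITCH
    is_food    : outcome_identity == food  (reward-type indicator, food=1)
    cue_food   : trial_class == forced_food (available option at the cue)
    """
    out = labels.copy()
    out["is_more"] = (labels["outcome_class"] == "MORE").astype(float)
    out["is_switch"] = (labels["outcome_class"] == "SWITCH").astype(float)
    out["is_food"] = (labels["outcome_identity"] == "food").astype(float)
    if "trial_class" in labels:
        out["cue_food"] = (labels["trial_class"] == "forced_food").astype(float)
    return out


def window_mean(aligned: AlignedTraces,
                window: Union[str, tuple]) -> np.ndarray:
    """Per-trial arithmetic mean of the aligned trace over a named window."""
    if isinstance(window, str):
        if window not in WINDOWS:
            raise KeyError(f"unknown window {window!r}; registered: "
                           f"{sorted(WINDOWS)}")
        lo, hi = WINDOWS[window]
    else:
        lo, hi = window
    mask = (aligned.time >= lo - 1e-9) & (aligned.time <= hi + 1e-9)
    if not mask.any():
        raise ValueError(f"window ({lo}, {hi}) outside aligned time axis")
    return aligned.data[:, mask].mean(axis=1)


def bin_blocks(values: np.ndarray, blocks: np.ndarray,
               n_bins: int = 5) -> pd.DataFrame:
    """Average per-trial scalars into session bins of consecutive blocks.

    With the default 10-block session and ``n_bins=5``, each bin spans two
    blocks of trials.  Returns one row per bin with the bin mean and trial
    count.
    """
    values = np.asarray(values, float)
    blocks = np.asarray(blocks, int)
    n_blocks = int(blocks.max()) + 1
    if n_blocks % n_bins:
        raise ValueError(f"{n_blocks} blocks not divisible into {n_bins} bins")
    per_bin = n_blocks // n_bins
    bin_idx = blocks // per_bin
    df = pd.DataFrame({"bin": bin_idx, "value": values})
    out = df.groupby("bin")["value"].agg(["mean", "count"]).reset_index()
    out.columns = ["bin", "mean", "n_trials"]
    return out


def first_trial_contrast(sessions: Sequence[dict],
                         cue_aligned_key: str = "cue",
                         lever_aligned_key: str = "lever",
                         reference_devalued: Optional[dict] = None
                         ) -> pd.DataFrame:
    """First-presentation window means per animal x session kind x valuation.

    Each element of ``sessions`` is a dict with keys ``animal``,
    ``session_kind``, ``devalued`` ("food" / "sucrose" / "none") and aligned
    traces for the cue and lever events.  For each session the first forced
    trial of each reinforcer (the earliest responded one if the first was
    missed, logged) contributes its ``cue_5s`` and ``lever_2s`` window
    means, labelled "valued" or "devalued" relative to ``devalued``.  For
    baseline sessions (``devalued == "none"``) the valuation tag is taken
    from ``reference_devalued[animal]`` when provided — the reinforcer sated
    in that animal's paired devaluation session — otherwise both identities
    are tagged "valued".
    """
    rows = []
    for sess in sessions:
        devalued = sess.get("devalued", "none")
        if devalued == "none" and reference_devalued is not None:
            devalued = reference_devalued.get(sess.get("animal"), "none")
        for identity in ("food", "sucrose"):
            cue_al: AlignedTraces = sess[cue_aligned_key]
            lev_al: AlignedTraces = sess[lever_aligned_key]
            cmask = (cue_al.labels["trial_class"] == f"forced_{identity}").to_numpy()
            if not cmask.any():
                logger.warning("no responded forced %s trial in %s/%s",
                               identity, sess.get("animal"), sess.get("session_kind"))
                continue
            ci = int(np.flatnonzero(cmask)[0])
            first_idx = cue_al.labels["index"].iloc[ci]
            if first_idx != cue_al.labels["index"].min():
                logger.info("first %s presentation missed; using trial %s",
                            identity, first_idx)
            cue_mean = float(window_mean(cue_al.select(cmask), "cue_5s")[0])
            lmask = (lev_al.labels["index"] == first_idx).to_numpy()
            lever_mean = float(window_mean(lev_al.select(lmask), "lever_2s")[0]) \
                if lmask.any() else np.nan
            valuation = "devalued" if identity == devalued else "valued"
            rows.append({"animal": sess["animal"],
                         "session_kind": sess["session_kind"],
                         "identity": identity, "valuation": valuation,
                         "trial_index": int(first_idx),
                         "cue_5s": cue_mean, "lever_2s": lever_mean})
    return pd.DataFrame(rows)
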