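"""Forward model: value/prediction-error signals -> dopamine concentration
traces -> background-subtracted voltammetric current matrices.

This module provides ground truth for testing the chemometric extraction
stage.  Concentration dynamics are phenomenological: each task event injects
an impulse of dopamine whose amplitude follows the value model, and impulses
decay exponentially (first-order clearance).  Current synthesis is an exact
linear mixture of analyte voltammogram templates plus low-frequency drift and
i.i.d. Gaussian noise; the templates are synthetic Gaussian-peak stand-ins
whose only job is to play the linear-algebraic role of measured
electrochemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .task import (FOOD, SUCROSE, SessionSchedule, SimulatedSession,
                   outcome_magnitude, other_identity)


@dataclass(frozen=True)
class KineticsParams:
    """Event-to-dopamine transduction parameters.

    Amplitude gains are nM of peak release per unit of subjective value.
    ``decay_tau_s`` is the exponential clearance time constant.  Negative
    prediction errors are read out at ``neg_rpe_scale`` times the positive
    gain (voltammetric under-reporting of pauses/dips).
    """

    amp_cue: float = 50.0
    amp_lever: float = 30.0
    amp_reward: float = 50.0
    decay_tau_s: float = 1.0
    neg_rpe_scale: float = 0.25
    scan_hz: float = 10.0
    noise_sd_nm: float = 2.0
    ph_drift_sd: float = 0.02
    rectify: bool = False

    def __post_init__(self) -> None:
        if self.decay_tau_s <= 0:
            raise ValueError("decay constant must be positive")
        if self.scan_hz <= 0:
            raise ValueError("scan rate must be positive")


@dataclass
class ConcentrationTrace:
    """Uniformly sampled dopamine (nM) and pH-shift traces with ground truth.

    ``truth_labels`` has one row per task event (cue / lever / reward) with
    the injected impulse amplitude before convolution — the quantity the
    analysis stages try to recover.
    """

    times: np.ndarray
    da: np.ndarray
    ph_shift: np.ndarray
    truth_labels: pd.DataFrame

    def __len__(self) -> int:
        return len(self.times)

    @property
    def scan_hz(self) -> float:
        return 1.0 / float(self.times[1] - self.times[0])


def simulate_concentration(session: SimulatedSession,
                           kinetics: KineticsParams = KineticsParams(),
                           seed: int = 0) -> ConcentrationTrace:
    """Generate the dopamine trace implied by a completed session.

    Impulse amplitudes (in value units, scaled by the amplitude gains):

    * cue onset:        general_gain * prediction of the available option
                        (forced: that lever's v; choice: max of the two);
    * lever extension:  general_gain * intrinsic unit value u of the same
                        option — the quantity satiation changes immediately;
    * reward delivery:  rectified prediction error
                        max(rpe, 0) + neg_rpe_scale * min(rpe, 0), with
                        rpe = magnitude * u(delivered) - v(expected).

    Missed trials produce only the cue impulse; wrong-lever trials produce
    cue and lever impulses but no reward.
    """
    sched = session.schedule
    traj = session.trajectory.set_index("index")
    cfg = sched.config
    dt = 1.0 / kinetics.scan_hz
    t_end = sched.trials[-1].cue_onset + cfg.trial_period_s
    n = int(np.ceil(t_end / dt)) + 1
    times = np.arange(n) * dt
    impulses = np.zeros(n)
    rng = np.random.default_rng(seed)

    rows = []

    def inject(time_s: float, amp_value: float, gain_nm: float,
               trial_index: int, event: str) -> None:
        amp_nm = gain_nm * amp_value
        idx = int(round(time_s / dt))
        if 0 <= idx < n:
            impulses[idx] += amp_nm
        rows.append({"trial": trial_index, "event": event,
                     "time": time_s, "amplitude": amp_nm,
                     "amplitude_value": amp_value})

    for t in sched.trials:
        st = traj.loc[t.index]
        gain = float(st["general_gain"])
        v = {FOOD: float(st["v_food_pre"]), SUCROSE: float(st["v_sucrose_pre"])}
        u = {FOOD: float(st["u_food"]), SUCROSE: float(st["u_sucrose"])}

        forced_id = t.forced_identity
        if forced_id is not None:
            v_avail, u_avail = v[forced_id], u[forced_id]
        else:
            v_avail = max(v.values())
            u_avail = u[FOOD] if v[FOOD] >= v[SUCROSE] else u[SUCROSE]

        inject(t.cue_onset, gain * v_avail, kinetics.amp_cue, t.index, "cue")
        if not t.missed:
            inject(t.lever_extension, gain * u_avail, kinetics.amp_lever,
                   t.index, "lever")
        if t.rewarded:
            expected = forced_id if forced_id is not None \
                else t.chosen_option.replace("_lever", "")
            rpe = outcome_magnitude(t, cfg) * u[t.outcome_identity] - v[expected]
            readout = max(rpe, 0.0) + kinetics.neg_rpe_scale * min(rpe, 0.0)
            inject(t.reward_delivery, readout, kinetics.amp_reward,
                   t.index, "reward")

    # first-order clearance: y[k] = x[k] + exp(-dt/tau) * y[k-1]
    decay = np.exp(-dt / kinetics.decay_tau_s)
    da = lfilter([1.0], [1.0, -decay], impulses)
    if kinetics.noise_sd_nm > 0:
        da = da + kinetics.noise_sd_nm * rng.standard_normal(n)
    if kinetics.rectify:
        da = np.maximum(da, 0.0)

    if kinetics.ph_drift_sd > 0:
        # slow pH wander: heavily smoothed random walk
        walk = np.cumsum(rng.standard_normal(n))
        kernel = np.ones(int(10 * kinetics.scan_hz)) if n > 10 * kinetics.scan_hz \
            else np.ones(max(1, n // 4))
        kernel /= kernel.sum()
        smooth = np.convolve(walk, kernel, mode="same")
        sd = smooth.std()
        ph = kinetics.ph_drift_sd * (smooth - smooth.mean()) / (sd if sd > 0 else 1.0)
    else:
        ph = np.zeros(n)

    return ConcentrationTrace(times=times, da=np.asarray(da),
                              ph_shift=ph, truth_labels=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# voltammogram templates and current synthesis


@dataclass(frozen=True)
class VoltammogramTemplate:
    """Unit-concentration cyclic voltammogram of one analyte."""

    voltages: np.ndarray
    current_per_unit: np.ndarray   # nA per nM (dopamine) or nA per pH unit
    analyte: str

    def __post_init__(self) -> None:
        if self.voltages.shape != self.current_per_unit.shape:
            raise ValueError("voltage grid and current template differ in length")


def default_voltage_grid(n_samples: int = 1000,
                         v_min: float = -0.4, v_max: float = 1.3) -> np.ndarray:
    """Triangular scan waveform v_min -> v_max -> v_min."""
    half = n_samples // 2
    up = np.linspace(v_min, v_max, half, endpoint=False)
    down = np.linspace(v_max, v_min, n_samples - half)
    return np.concatenate([up, down])


def _gauss(v: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((v - center) / width) ** 2)


def make_templates(voltages: Optional[np.ndarray] = None) -> dict:
    """Synthetic analyte templates on a shared voltage grid.

    The dopamine template has a single dominant oxidation peak on the anodic
    sweep (~+0.6 V) and a smaller reduction feature on the cathodic sweep;
    pH and drift templates are broader shapes that overlap it only partially.
    Scales: 0.01 nA/nM dopamine sensitivity at the peak; 5 nA per pH unit.
    """
    v = default_voltage_grid() if voltages is None else np.asarray(voltages, float)
    n = len(v)
    anodic = np.zeros(n, bool)
    anodic[:np.argmax(v) + 1] = True
    da = 0.01 * (_gauss(v, 0.6, 0.12) * anodic
                 - 0.35 * _gauss(v, -0.2, 0.10) * ~anodic)
    ph = 5.0 * (_gauss(v, 0.25, 0.30) * anodic
                - 0.6 * _gauss(v, 0.9, 0.35) * ~anodic)
    drift = 0.05 * (0.4 + _gauss(v, 1.0, 0.50))
    return {
        "dopamine": VoltammogramTemplate(v, da, "dopamine"),
        "ph": VoltammogramTemplate(v, ph, "ph"),
        "drift": VoltammogramTemplate(v, drift, "drift"),
    }


@dataclass
class CurrentMatrix:
    """Background-subtracted FSCV currents: scans x voltage samples (nA)."""

    currents: np.ndarray
    scan_times: np.ndarray
    voltages: np.ndarray
    animal: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        if self.currents.shape != (len(self.scan_times), len(self.voltages)):
            raise ValueError("currents shape must be (n_scans, n_voltage_samples)")

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("currents", data=self.currents.astype(np.float32),
                             compression="gzip")
            f.create_dataset("scan_times", data=self.scan_times)
            f.create_dataset("voltages", data=self.voltages)
            f.attrs["animal"] = self.animal
            f.attrs["session"] = self.session

    @classmethod
    def from_hdf5(cls, path) -> "CurrentMatrix":
        with h5py.File(path, "r") as f:
            return cls(currents=f["currents"][...].astype(float),
                       scan_times=f["scan_times"][...],
                       voltages=f["voltages"][...],
                       animal=str(f.attrs.get("animal", "")),
                       session=str(f.attrs.get("session", "")))

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.currents, index=self.scan_times,
                          columns=[f"{v:.4f}" for v in self.voltages])
        df.index.name = "scan_time"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "CurrentMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(currents=df.to_numpy(float),
                   scan_times=df.index.to_numpy(float),
                   voltages=np.array([float(c) for c in df.columns]))


@dataclass(frozen=True)
class DriftParams:
    amplitude_na: float = 0.0     # off by default
    timescale_s: float = 60.0


def synthesize_current(trace: ConcentrationTrace, templates: dict,
                       noise_sd: float = 0.02,
                       drift: DriftParams = DriftParams(),
                       seed: int = 0,
                       animal: str = "", session: str = "") -> CurrentMatrix:
    """Linear forward mixture: currents = da x T_da + ph x T_ph + drift + noise."""
    t_da, t_ph = templates["dopamine"], templates["ph"]
    if not np.array_equal(t_da.voltages, t_ph.voltages):
        raise ValueError("templates do not share a voltage grid")
    v = t_da.voltages
    n = len(trace)
    rng = np.random.default_rng(seed)
    currents = (np.outer(trace.da, t_da.current_per_unit)
                + np.outer(trace.ph_shift, t_ph.current_per_unit))
    if drift.amplitude_na > 0 and "drift" in templates:
        t_dr = templates["drift"]
        if not np.array_equal(t_dr.voltages, v):
            raise ValueError("drift template grid mismatch")
        dt = trace.times[1] - trace.times[0] if n > 1 else 1.0
        coeff = np.sin(2 * np.pi * trace.times / drift.timescale_s
                       + rng.uniform(0, 2 * np.pi))
        currents += drift.amplitude_na * np.outer(coeff, t_dr.current_per_unit)
        del dt
    if noise_sd > 0:
        currents = currents + noise_sd * rng.standard_normal(currents.shape)
    return CurrentMatrix(currents=currents, scan_times=np.asarray(trace.times),
                         voltages=v, animal=animal, session=session)


def templates_to_csv(templates: dict, path) -> None:
    cols = {"voltage": next(iter(templates.values())).voltages}
    for name, t in templates.items():
        cols[name] = t.current_per_unit
    pd.DataFrame(cols).to_csv(path, index=False)


def templates_from_csv(path) -> dict:
    df = pd.read_csv(path)
    v = df["voltage"].to_numpy(float)
    return {name: VoltammogramTemplate(v, df[name].to_numpy(float), name)
            for name in df.columns if name != "voltage"}
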