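"""Principal-component regression (PCR) extraction of analyte concentrations
from background-subtracted voltammograms, with Q-residual validation.

The chemometric model is standard for fast-scan cyclic voltammetry: principal
components of a calibration set of voltammograms with known analyte
concentrations define a low-dimensional subspace; measured scans are
projected onto it and component scores mapped to concentrations by least
squares.  The per-scan Q statistic — the sum of squared reconstruction
residuals outside the retained subspace — flags scans whose shape is not
explained by the calibrated analytes (electrical artifacts, uncalibrated
interferents).  The Q threshold uses the Jackson–Mudholkar approximation at a
configurable significance level.

Calibration voltammograms are *not* mean-centered by default, so an exact
linear mixture of calibration components is recovered exactly; centering is
available as an option.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .voltammetry import CurrentMatrix


@dataclass
class CalibrationSet:
    """Voltammogram standards with known concentrations.

    Parameters
    ----------
    voltammograms : ndarray, (n_standards, n_voltage_samples)
        Background-subtracted calibration scans in nA.
    concentrations : ndarray, (n_standards, n_analytes)
        Known analyte levels of each standard (nM dopamine, pH units).
    analytes : sequence of str
        Analyte names, one per concentration column.
    voltages : ndarray, optional
        Applied-potential grid; checked against data at prediction time.
    """

    voltammograms: np.ndarray
    concentrations: np.ndarray
    analytes: Sequence[str] = ("dopamine", "ph")
    voltages: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.voltammograms = np.atleast_2d(np.asarray(self.voltammograms, float))
        self.concentrations = np.atleast_2d(np.asarray(self.concentrations, float))
        k, a = self.concentrations.shape
        if self.voltammograms.shape[0] != k:
            raise ValueError("standards count mismatch between voltammograms "
                             "and concentrations")
        if len(self.analytes) != a:
            raise ValueError("analyte names do not match concentration columns")
        if k < 2 * a:
            raise ValueError(f"need >= 2 standards per analyte ({k} standards, "
                             f"{a} analytes)")

    def sha256(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.voltammograms).tobytes())
        h.update(np.ascontiguousarray(self.concentrations).tobytes())
        return h.hexdigest()

    def to_csv(self, path) -> None:
        n_v = self.voltammograms.shape[1]
        df = pd.DataFrame(self.voltammograms,
                          columns=[f"i_{j}" for j in range(n_v)])
        for j, name in enumerate(self.analytes):
            df.insert(j, f"conc_{name}", self.concentrations[:, j])
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, voltages: Optional[np.ndarray] = None
                 ) -> "CalibrationSet":
        df = pd.read_csv(path)
        conc_cols = [c for c in df.columns if c.startswith("conc_")]
        curr_cols = [c for c in df.columns if c.startswith("i_")]
        return cls(voltammograms=df[curr_cols].to_numpy(float),
                   concentrations=df[conc_cols].to_numpy(float),
                   analytes=[c[len("conc_"):] for c in conc_cols],
                   voltages=voltages)


def make_calibration(templates: dict, da_levels: Sequence[float] = (0, 100, 250, 500, 750, 1000),
                     ph_levels: Sequence[float] = (-0.1, 0.0, 0.1),
                     noise_sd: float = 0.02, seed: int = 0) -> CalibrationSet:
    """Build a factorial calibration set from analyte templates."""
    rng = np.random.default_rng(seed)
    t_da, t_ph = templates["dopamine"], templates["ph"]
    rows, conc = [], []
    for da in da_levels:
        for ph in ph_levels:
            scan = da * t_da.current_per_unit + ph * t_ph.current_per_unit
            if noise_sd > 0:
                scan = scan + noise_sd * rng.standard_normal(len(scan))
            rows.append(scan)
            conc.append([da, ph])
    return CalibrationSet(voltammograms=np.array(rows),
                          concentrations=np.array(conc),
                          analytes=("dopamine", "ph"),
                          voltages=t_da.voltages)


class PrincipalComponentRegression:
    """PCR model of a voltammetric calibration set.

    Parameters
    ----------
    calibration : CalibrationSet
    variance_floor : float
        Principal components are retained in order of variance until their
        cumulative fraction reaches this floor (default 0.995).
    q_alpha : float
        Significance level of the Jackson–Mudholkar Q-residual threshold.
    center : bool
        Mean-center calibration scans before the SVD (default False; see
        module docstring).

    Examples
    --------
    >>> model = PrincipalComponentRegression(calibration)
    >>> res = model.fit()
    >>> extraction = res.predict(current_matrix)
    """

    def __init__(self, calibration: CalibrationSet,
                 variance_floor: float = 0.995,
                 q_alpha: float = 0.05,
                 center: bool = False) -> None:
        if not 0.0 < variance_floor <= 1.0:
            raise ValueError("variance_floor must lie in (0, 1]")
        if not 0.0 < q_alpha < 1.0:
            raise ValueError("q_alpha must lie in (0, 1)")
        self.calibration = calibration
        self.variance_floor = float(variance_floor)
        self.q_alpha = float(q_alpha)
        self.center = bool(center)

    def fit(self) -> "PCRResults":
        X = self.calibration.voltammograms
        C = self.calibration.concentrations
        mean = X.mean(axis=0) if self.center else np.zeros(X.shape[1])
        Xc = X - mean
        # SVD of the calibration block; eigenvalues of X'X scaled to covariance
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        lam = s ** 2 / max(X.shape[0] - 1, 1)
        total = lam.sum()
        if total <= 0:
            raise ValueError("calibration has zero variance")
        cum = np.cumsum(lam) / total
        n_keep = int(np.searchsorted(cum, self.variance_floor - 1e-12) + 1)
        # never retain fewer components than analytes (when the data allow)
        rank = int(np.linalg.matrix_rank(Xc))
        n_keep = min(max(n_keep, min(C.shape[1], rank)), len(lam))
        loadings = Vt[:n_keep]                       # (r, n_samples)
        scores = Xc @ loadings.T                     # (k, r)
        if np.linalg.matrix_rank(scores) < C.shape[1]:
            raise ValueError("rank-deficient calibration: fewer independent "
                             "standards than analytes")
        coefs, *_ = np.linalg.lstsq(scores, C, rcond=None)  # (r, n_analytes)
        q_cal = np.sum((Xc - scores @ loadings) ** 2, axis=1)
        q_threshold = _jackson_mudholkar(lam[n_keep:], self.q_alpha,
                                         fallback=float(max(q_cal.max(), 1e-12)))
        return PCRResults(model=self, mean=mean, loadings=loadings,
                          coefs=coefs, eigenvalues=lam,
                          variance_retained=float(cum[n_keep - 1]),
                          q_threshold=q_threshold,
                          calibration_hash=self.calibration.sha256())


def _jackson_mudholkar(discarded: np.ndarray, alpha: float,
                       fallback: float) -> float:
    """Q-statistic upper control limit from the discarded eigenvalues.

    Returns ``fallback`` (scaled up for safety) when no residual variance is
    left to model — e.g. a noiseless calibration spanned by the retained
    components — so the threshold stays positive.
    """
    th1 = float(discarded.sum())
    th2 = float((discarded ** 2).sum())
    th3 = float((discarded ** 3).sum())
    if th1 <= 0 or th2 <= 0:
        return max(2.0 * fallback, 1e-12)
    h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2 ** 2)
    if h0 <= 0:
        h0 = 1e-3
    z = stats.norm.ppf(1.0 - alpha)
    inner = (z * np.sqrt(2.0 * th2 * h0 ** 2) / th1
             + 1.0 + th2 * h0 * (h0 - 1.0) / th1 ** 2)
    if inner <= 0:
        return max(2.0 * fallback, 1e-12)
    return float(th1 * inner ** (1.0 / h0))


@dataclass
class Extraction:
    """Per-scan concentration estimates plus Q-residual diagnostics."""

    times: np.ndarray
    concentrations: pd.DataFrame   # one column per analyte
    q: np.ndarray
    q_threshold: float
    flagged: np.ndarray            # bool, q > threshold

    @property
    def da(self) -> np.ndarray:
        return self.concentrations["dopamine"].to_numpy()

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())


class PCRResults:
    """Fitted PCR model: retained loadings, regression matrix, Q threshold."""

    def __init__(self, model: PrincipalComponentRegression, mean: np.ndarray,
                 loadings: np.ndarray, coefs: np.ndarray,
                 eigenvalues: np.ndarray, variance_retained: float,
                 q_threshold: float, calibration_hash: str) -> None:
        self.model = model
        self.mean = mean
        self.loadings = loadings
        self.coefs = coefs
        self.eigenvalues = eigenvalues
        self.variance_retained = variance_retained
        self.q_threshold = q_threshold
        self.calibration_hash = calibration_hash
        self.analytes = list(model.calibration.analytes) if model else \
            ["dopamine", "ph"]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def predict(self, matrix, flag_policy: str = "interpolate") -> Extraction:
        """Extract concentrations from a current matrix.

        Parameters
        ----------
        matrix : CurrentMatrix or ndarray (n_scans, n_voltage_samples)
        flag_policy : {"interpolate", "keep", "nan"}
            What to do with scans whose Q exceeds the threshold: linearly
            interpolate their concentrations from neighbours (default, keeps
            the trace grid rectangular), keep the raw estimate, or set NaN.
            Flags are always reported, never silently dropped.
        """
        if isinstance(matrix, CurrentMatrix):
            X = matrix.currents
            times = matrix.scan_times
            cal_v = self.model.calibration.voltages if self.model else None
            if cal_v is not None and (len(cal_v) != len(matrix.voltages)
                                      or not np.allclose(cal_v, matrix.voltages)):
                raise ValueError("voltage grid of data does not match calibration")
        else:
            X = np.atleast_2d(np.asarray(matrix, float))
            times = np.arange(X.shape[0], dtype=float)
        if X.shape[1] != self.loadings.shape[1]:
            raise ValueError(f"scan length {X.shape[1]} does not match model "
                             f"grid {self.loadings.shape[1]}")
        Xc = X - self.mean
        scores = Xc @ self.loadings.T
        conc = scores @ self.coefs
        q = np.sum((Xc - scores @ self.loadings) ** 2, axis=1)
        flagged = q > self.q_threshold
        if flag_policy not in ("interpolate", "keep", "nan"):
            raise ValueError(f"unknown flag_policy {flag_policy!r}")
        if flag_policy != "keep" and flagged.any():
            conc = conc.copy()
            good = ~flagged
            if flag_policy == "interpolate" and not good.any():
                import warnings
                warnings.warn("every scan exceeds the Q threshold; keeping "
                              "raw estimates", stacklevel=2)
            else:
                for j in range(conc.shape[1]):
                    if flag_policy == "nan":
                        conc[flagged, j] = np.nan
                    else:
                        conc[flagged, j] = np.interp(times[flagged],
                                                     times[good],
                                                     conc[good, j])
        df = pd.DataFrame(conc, columns=self.analytes)
        return Extraction(times=np.asarray(times), concentrations=df, q=q,
                          q_threshold=self.q_threshold, flagged=flagged)

    def summary(self) -> str:
        lines = [
            "Principal Component Regression",
            "==============================",
            f"analytes            : {', '.join(self.analytes)}",
            f"retained components : {self.n_components}",
            f"variance retained   : {self.variance_retained:.6f}",
            f"Q threshold (nA^2)  : {self.q_threshold:.4g}",
            f"calibration sha256  : {self.calibration_hash[:16]}…",
        ]
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "analytes": self.analytes,
            "mean": self.mean.tolist(),
            "loadings": self.loadings.tolist(),
            "coefs": self.coefs.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_retained": self.variance_retained,
            "q_threshold": self.q_threshold,
            "calibration_sha256": self.calibration_hash,
        }
        with open(path, "w") as f:
            json.dump(payload, f)

    @classmethod
    def from_json(cls, path) -> "PCRResults":
        with open(path) as f:
            p = json.load(f)
        res = cls(model=None, mean=np.array(p["mean"]),
                  loadings=np.array(p["loadings"]), coefs=np.array(p["coefs"]),
                  eigenvalues=np.array(p["eigenvalues"]),
                  variance_retained=p["variance_retained"],
                  q_threshold=p["q_threshold"],
                  calibration_hash=p["calibration_sha256"])
        res.analytes = list(p["analytes"])
        return res

    def predict_from_arrays(self, X: np.ndarray, **kw) -> Extraction:
        return self.predict(X, **kw)


def fit_pcr(calibration: CalibrationSet, variance_floor: float = 0.995,
            q_alpha: float = 0.05, **kw) -> PCRResults:
    """Convenience wrapper: fit the PCR model in one call."""
    return PrincipalComponentRegression(calibration, variance_floor,
                                        q_alpha, **kw).fit()


def apply_pcr(results: PCRResults, matrix, **kw) -> Extraction:
    """Convenience wrapper mirroring :meth:`PCRResults.predict`."""
    return results.predict(matrix, **kw)
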