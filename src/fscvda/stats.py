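"""Time-resolved statistics on aligned dopamine traces.

Three pieces of machinery drive the analyses:

* :class:`TimepointGLM` — ordinary least squares of the aligned dopamine at
  each peri-event timepoint on trial regressors (with a constant term),
  fitted per animal; group-level inference by sign-flip permutation of the
  per-animal coefficient traces.
* :func:`auroc` / :func:`auroc_series` — rank-based area under the ROC curve
  as a per-timepoint discriminability measure between two trial types, ties
  counted one half; a scalar "discrimination index" is the auROC of window
  means.
* permutation tests — within-animal label shuffles or group-level sign
  flips, with a fixed corrected pointwise alpha (default 0.001, the
  multiple-comparison-corrected criterion) rather than cluster statistics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .alignment import AlignedTraces, window_mean

DEFAULT_CORRECTED_ALPHA = 0.001
MAX_EXHAUSTIVE_SUBJECTS = 12

# canonical regressor designs
REWARD_DESIGN = ["is_more", "is_food", "is_more:is_food"]
CUE_DESIGN = ["cue_food"]


# ---------------------------------------------------------------------------
# auROC


def auroc(a: np.ndarray, b: np.ndarray) -> float:
    """P(B > A) + 0.5 P(B = A): probability a draw from ``b`` exceeds one
    from ``a``, ties counted half.  0.5 = indiscriminable, 1.0 = b fully
    above a."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = rankdata(np.concatenate([a, b]))
    r_b = ranks[a.size:].sum()
    return float((r_b - b.size * (b.size + 1) / 2.0) / (a.size * b.size))


def _auroc_matrix(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Columnwise auROC for (n_a, T) vs (n_b, T) arrays."""
    n_a, n_b = xa.shape[0], xb.shape[0]
    ranks = rankdata(np.vstack([xa, xb]), axis=0)
    r_b = ranks[n_a:].sum(axis=0)
    return (r_b - n_b * (n_b + 1) / 2.0) / (n_a * n_b)


@dataclass
class ROCSeries:
    """Per-timepoint discriminability of two trial types.

    ``window_index`` is the scalar auROC of the window means (the dopamine
    discrimination index); ``low_n`` flags indices computed from a group
    with fewer than 2 trials.
    """

    time: np.ndarray
    auroc: np.ndarray
    window_index: float
    window: str
    n_a: int
    n_b: int
    low_n: bool = False
    p: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.time, "auroc": self.auroc})
        if self.p is not None:
            df["p"] = self.p
        return df


def auroc_series(aligned: AlignedTraces, mask_a, mask_b,
                 window: str = "reward_5s") -> ROCSeries:
    """auROC(t) of trials in ``mask_b`` versus trials in ``mask_a``."""
    mask_a = np.asarray(mask_a, bool)
    mask_b = np.asarray(mask_b, bool)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both trial groups must be non-empty")
    xa, xb = aligned.data[mask_a], aligned.data[mask_b]
    curve = _auroc_matrix(xa, xb)
    wm = window_mean(aligned, window)
    index = auroc(wm[mask_a], wm[mask_b])
    return ROCSeries(time=aligned.time, auroc=curve, window_index=index,
                     window=window, n_a=int(mask_a.sum()), n_b=int(mask_b.sum()),
                     low_n=bool(min(mask_a.sum(), mask_b.sum()) < 2))


def discrimination_index(aligned: AlignedTraces, mask_a, mask_b,
                         window: str = "reward_5s") -> float:
    """Scalar dopamine discrimination index: auROC of window means."""
    return auroc_series(aligned, mask_a, mask_b, window=window).window_index


# ---------------------------------------------------------------------------
# permutation inference


@dataclass
class PermutationResult:
    p: np.ndarray                  # pointwise p(t), possibly (n_series, T)
    flags: np.ndarray              # p < corrected_alpha
    corrected_alpha: float
    n_perm: int
    exhaustive: bool
    min_p: float

    @property
    def flagged_fraction(self) -> float:
        return float(np.mean(self.flags))


def _check_guard(n_perm: int, corrected_alpha: float, guard: str) -> None:
    if guard == "strict":
        need = int(np.ceil(10.0 / corrected_alpha))
        if n_perm < need:
            raise ValueError(
                f"n_perm={n_perm} too small to resolve corrected alpha "
                f"{corrected_alpha}; need >= {need} (or guard='resolve')")
    elif guard == "resolve":
        if 1.0 / (n_perm + 1) > corrected_alpha:
            raise ValueError(
                f"n_perm={n_perm} cannot reach p <= {corrected_alpha}")
    else:
        raise ValueError(f"unknown guard {guard!r}")


def sign_flip_test(series: np.ndarray,
                   corrected_alpha: float = DEFAULT_CORRECTED_ALPHA,
                   n_perm: Optional[int] = None,
                   seed: Optional[int] = None) -> PermutationResult:
    """Group-level permutation test of per-animal coefficient traces.

    ``series`` is (n_subjects, T); the statistic is the group mean at each
    timepoint and the null is built by flipping the sign of whole subjects
    (exchangeability of the effect's sign under the null).  With up to
    12 subjects all 2^n flips are enumerated exactly; the smallest
    achievable p is then 2^-n, which is reported so callers can tell when a
    corrected alpha is unreachable.
    """
    series = np.atleast_2d(np.asarray(series, float))
    n, T = series.shape
    if n < 2:
        raise ValueError("group-level sign-flip test needs >= 2 subjects")
    obs = np.abs(series.mean(axis=0))
    if n <= MAX_EXHAUSTIVE_SUBJECTS and n_perm is None:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        null = np.abs(signs @ series) / n          # (2^n, T)
        p = np.mean(null >= obs[None, :] - 1e-12, axis=0)
        return PermutationResult(p=p, flags=p < corrected_alpha,
                                 corrected_alpha=corrected_alpha,
                                 n_perm=signs.shape[0], exhaustive=True,
                                 min_p=2.0 / signs.shape[0])
    n_perm = int(n_perm or 5000)
    rng = np.random.default_rng(seed)
    signs = rng.choice((1.0, -1.0), size=(n_perm, n))
    null = np.abs(signs @ series) / n
    b = np.sum(null >= obs[None, :] - 1e-12, axis=0)
    p = (1.0 + b) / (1.0 + n_perm)
    return PermutationResult(p=p, flags=p < corrected_alpha,
                             corrected_alpha=corrected_alpha,
                             n_perm=n_perm, exhaustive=False,
                             min_p=1.0 / (1.0 + n_perm))


def label_shuffle_test(data: np.ndarray, labels: np.ndarray,
                       stat: Union[str, Callable] = "meandiff",
                       n_perm: int = 10000,
                       corrected_alpha: float = DEFAULT_CORRECTED_ALPHA,
                       seed: Optional[int] = None,
                       guard: str = "strict") -> PermutationResult:
    """Within-animal permutation test by trial-label shuffling.

    ``data`` is (n_trials, T) and ``labels`` a binary trial grouping.  The
    default statistic is the group mean difference at each timepoint
    (vectorised over permutations); ``stat="auroc"`` uses the rank-based
    auROC, whose permutation p-values are invariant to monotone transforms
    of the data.  Two-sided p-values use the add-one convention
    p = (1 + #{|null| >= |obs|}) / (1 + n_perm).
    """
    data = np.atleast_2d(np.asarray(data, float))
    labels = np.asarray(labels)
    if data.shape[0] != labels.shape[0]:
        raise ValueError("labels must have one entry per trial")
    if data.shape[0] < 10:
        raise ValueError("within-animal label shuffles need >= 10 trials")
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("labels must define exactly two groups")
    _check_guard(n_perm, corrected_alpha, guard)
    g = (labels == uniq[1])
    n1, n0 = int(g.sum()), int((~g).sum())
    rng = np.random.default_rng(seed)

    if stat == "meandiff":
        def statfun(mask_mat: np.ndarray) -> np.ndarray:
            # mask_mat: (m, n_trials) in {0,1}; returns (m, T)
            s1 = mask_mat @ data
            tot = data.sum(axis=0)[None, :]
            return s1 / n1 - (tot - s1) / n0
        obs = np.abs(statfun(g[None, :].astype(float)))[0]
        perms = np.empty((n_perm, data.shape[0]))
        base = g.astype(float)
        for i in range(n_perm):
            perms[i] = rng.permutation(base)
        null = np.abs(statfun(perms))
    elif stat == "auroc":
        obs = np.abs(_auroc_matrix(data[~g], data[g]) - 0.5)
        null = np.empty((n_perm, data.shape[1]))
        for i in range(n_perm):
            pg = rng.permutation(g)
            null[i] = np.abs(_auroc_matrix(data[~pg], data[pg]) - 0.5)
    else:
        obs = np.abs(stat(data[~g], data[g]))
        null = np.empty((n_perm,) + np.shape(obs))
        for i in range(n_perm):
            pg = rng.permutation(g)
            null[i] = np.abs(stat(data[~pg], data[pg]))

    b = np.sum(null >= obs[None, ...] - 1e-12, axis=0)
    p = (1.0 + b) / (1.0 + n_perm)
    return PermutationResult(p=p, flags=p < corrected_alpha,
                             corrected_alpha=corrected_alpha,
                             n_perm=n_perm, exhaustive=False,
                             min_p=1.0 / (1.0 + n_perm))


def permutation_test(series_or_data, labels=None, **kw) -> PermutationResult:
    """Dispatch: per-animal series -> sign flips; (data, labels) -> shuffles."""
    if labels is None:
        return sign_flip_test(series_or_data, **kw)
    return label_shuffle_test(series_or_data, labels, **kw)


# ---------------------------------------------------------------------------
# time-point GLM


def build_design(labels: pd.DataFrame, terms: Sequence[str],
                 add_constant: bool = True) -> tuple:
    """Design matrix from label columns; "a:b" denotes a product term."""
    cols, names = [], []
    if add_constant:
        cols.append(np.ones(len(labels)))
        names.append("const")
    for term in terms:
        parts = term.split(":")
        x = np.ones(len(labels))
        for p in parts:
            if p not in labels.columns:
                raise KeyError(f"regressor column {p!r} not in labels "
                               f"(run alignment.encode_labels first?)")
            x = x * labels[p].to_numpy(float)
        cols.append(x)
        names.append(term)
    return np.column_stack(cols), names


class TimepointGLM:
    """OLS of aligned dopamine on trial regressors, per animal and timepoint.

    Parameters
    ----------
    aligned : AlignedTraces
        Trials x timepoints data; ``labels`` must contain the regressor
        columns and (for multi-animal fits) an ``animal`` column.
    design : sequence of str
        Regressor terms naming numeric label columns; ``"a:b"`` is the
        product (interaction).  A constant is always included.  Coding
        convention: indicators in {0, 1}, reward type food=1 / sucrose=0.

    ``fit`` solves the normal equations per animal, sweeping all timepoints
    at once, and returns a :class:`TimepointGLMResults`.
    """

    def __init__(self, aligned: AlignedTraces, design: Sequence[str],
                 group_col: str = "animal") -> None:
        self.aligned = aligned
        self.design = list(design)
        self.group_col = group_col

    def fit(self) -> "TimepointGLMResults":
        labels = self.aligned.labels
        if self.group_col in labels.columns:
            animals = list(pd.unique(labels[self.group_col]))
        else:
            animals = [None]
        T = len(self.aligned.time)
        betas, bses, kept, skipped = [], [], [], []
        names = None
        for an in animals:
            if an is None:
                mask = np.ones(len(labels), bool)
            else:
                mask = (labels[self.group_col] == an).to_numpy()
            X, names = build_design(labels.loc[mask], self.design)
            Y = self.aligned.data[mask]
            n, p = X.shape
            if n < p or np.linalg.matrix_rank(X) < p:
                skipped.append({"animal": an, "reason": "rank-deficient design"})
                continue
            xtx_inv = np.linalg.inv(X.T @ X)
            B = xtx_inv @ X.T @ Y                      # (p, T)
            resid = Y - X @ B
            dof = max(n - p, 1)
            sigma2 = (resid ** 2).sum(axis=0) / dof    # (T,)
            se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
            betas.append(B)
            bses.append(se)
            kept.append(an)
        if not betas:
            raise ValueError("no animal had a full-rank design: "
                             + "; ".join(str(s) for s in skipped))
        return TimepointGLMResults(
            time=self.aligned.time, names=names,
            animal_params=np.array(betas), animal_bse=np.array(bses),
            animals=kept, skipped=skipped, dof=dof, model=self)


class TimepointGLMResults:
    """Per-animal and group-level effect-size traces from a time-point GLM."""

    def __init__(self, time, names, animal_params, animal_bse, animals,
                 skipped, dof, model=None) -> None:
        self.time = time
        self.names = list(names)
        self.animal_params = animal_params   # (n_animals, p, T)
        self.animal_bse = animal_bse
        self.animals = animals
        self.skipped = skipped
        self.dof = dof
        self.model = model
        self._perm: Optional[dict] = None

    @property
    def params(self) -> np.ndarray:
        """Group-mean beta(t), shape (p, T)."""
        return self.animal_params.mean(axis=0)

    def beta(self, name: str, animal: Optional[object] = None) -> np.ndarray:
        j = self.names.index(name)
        if animal is None:
            return self.params[j]
        return self.animal_params[self.animals.index(animal), j]

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Per-animal (lower, upper) OLS confidence bands, t approximation.

        Shape (n_animals, p, T, 2)."""
        from scipy.stats import t as tdist
        crit = tdist.ppf(1.0 - alpha / 2.0, self.dof)
        lo = self.animal_params - crit * self.animal_bse
        hi = self.animal_params + crit * self.animal_bse
        return np.stack([lo, hi], axis=-1)

    def permutation_pvalues(self, corrected_alpha: float = DEFAULT_CORRECTED_ALPHA,
                            n_perm: Optional[int] = None,
                            seed: Optional[int] = None) -> dict:
        """Group-level sign-flip p(t) per regressor (exhaustive for small n)."""
        out = {}
        for j, name in enumerate(self.names):
            out[name] = sign_flip_test(self.animal_params[:, j, :],
                                       corrected_alpha=corrected_alpha,
                                       n_perm=n_perm, seed=seed)
        self._perm = out
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tidy effect-size table: time x regressor x animal + group mean."""
        rows = []
        for i, an in enumerate(self.animals):
            for j, name in enumerate(self.names):
                rows.append(pd.DataFrame({
                    "time": self.time, "regressor": name, "animal": an,
                    "beta": self.animal_params[i, j],
                    "bse": self.animal_bse[i, j]}))
        df = pd.concat(rows, ignore_index=True)
        if self._perm is not None:
            pmap = {name: res.p for name, res in self._perm.items()}
            gp = pd.concat([pd.DataFrame({"time": self.time, "regressor": n,
                                          "animal": "group",
                                          "beta": self.params[j],
                                          "p": pmap.get(n)})
                            for j, n in enumerate(self.names)],
                           ignore_index=True)
            df = pd.concat([df, gp], ignore_index=True)
        return df

    def summary(self) -> str:
        lines = ["Time-point GLM", "==============",
                 f"animals: {len(self.animals)}   regressors: {self.names}",
                 f"timepoints: {len(self.time)}   residual dof (last fit): {self.dof}"]
        if self.skipped:
            lines.append(f"skipped (rank-deficient): {self.skipped}")
        for j, name in enumerate(self.names):
            tr = self.params[j]
            k = int(np.argmax(np.abs(tr)))
            line = (f"  {name:<18s} peak beta {tr[k]:+8.3f} nM "
                    f"at t = {self.time[k]:+5.2f} s")
            if self._perm is not None:
                nsig = int(self._perm[name].flags.sum())
                line += (f"   significant timepoints "
                         f"(p < {self._perm[name].corrected_alpha}): {nsig}")
            lines.append(line)
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for j, name in enumerate(self.names):
            if name == "const":
                continue
            ax.plot(self.time, self.params[j], label=name)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.axvline(0.0, color="k", lw=0.5)
        ax.set_xlabel("time from event (s)")
        ax.set_ylabel("effect size (nM)")
        ax.legend()
        return ax


def fit_glm_timepoint(aligned: AlignedTraces, design: Sequence[str],
                      **kw) -> TimepointGLMResults:
    """Convenience wrapper: build and fit a :class:`TimepointGLM`."""
    return TimepointGLM(aligned, design, **kw).fit()
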