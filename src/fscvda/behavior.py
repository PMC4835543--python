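"""Behavioral summaries and group-level statistics.

Covers choice preference (t test of per-animal food-choice fractions against
50%), response latencies, wrong-lever / missed-trial repeated-measures
ANOVAs, ordered-bin linear trend contrasts, and the correlation between the
dopamine discrimination index and choice behavior.  All t tests are
two-tailed at alpha 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class StatResult:
    """One inferential test: statistic, degrees of freedom, p, direction."""

    test: str
    statistic: float
    df1: float
    df2: Optional[float] = None
    p: float = math.nan
    direction: str = ""
    note: str = ""

    def __str__(self) -> str:
        df = f"({self.df1:g})" if self.df2 is None else f"({self.df1:g}, {self.df2:g})"
        extra = f"  [{self.note}]" if self.note else ""
        return (f"{self.test}: stat{df} = {self.statistic:.3f}, "
                f"p = {self.p:.4g} {self.direction}{extra}")

    def to_dict(self) -> dict:
        return {"test": self.test, "statistic": self.statistic,
                "df1": self.df1, "df2": self.df2, "p": self.p,
                "direction": self.direction, "note": self.note}


def stats_to_tsv(results: Sequence[StatResult], path) -> None:
    pd.DataFrame([r.to_dict() for r in results]).to_csv(path, sep="\t",
                                                        index=False)


def preference_score(food_fraction: float) -> float:
    """(2 x proportion of food choices) - 1: affine [0,1] -> [-1,1]."""
    return 2.0 * food_fraction - 1.0


def summarize_behavior(schedule_frames: dict) -> pd.DataFrame:
    """Per animal x session behavioral summary.

    ``schedule_frames`` maps (animal, session_kind) -> completed trial
    DataFrame.  Food-choice fractions are computed over responded choice
    trials only; latencies (lever extension to response) over responded
    forced trials per lever; wrong/missed counts per trial class.
    """
    rows = []
    for (animal, kind), df in schedule_frames.items():
        choice = df[df.trial_class == "choice"]
        responded = choice[~choice.missed]
        if len(choice) == 0:
            raise ValueError(f"session {animal}/{kind} has zero choice trials")
        n_resp = len(responded)
        food_frac = float((responded.chosen_option == "food_lever").mean()) \
            if n_resp else math.nan
        row = {
            "animal": animal, "session_kind": kind,
            "n_choice_responded": n_resp,
            "food_choice_fraction": food_frac,
            "preference_score": preference_score(food_frac) if n_resp else math.nan,
        }
        forced = df[df.trial_class.str.startswith("forced")]
        for ident in ("food", "sucrose"):
            sel = forced[(forced.trial_class == f"forced_{ident}")]
            ok = sel[~sel.missed & ~sel.wrong_lever]
            row[f"latency_{ident}"] = float(ok.latency.mean()) if len(ok) else math.nan
            row[f"wrong_{ident}"] = int(sel.wrong_lever.sum())
            row[f"missed_{ident}"] = int(sel.missed.sum())
        row["wrong_choice_trials"] = int(choice.wrong_lever.sum())
        row["missed_choice_trials"] = int(choice.missed.sum())
        rows.append(row)
    return pd.DataFrame(rows)


def t_vs_half(fractions: Sequence[float]) -> StatResult:
    """One-sample two-tailed t of per-animal choice fractions against 0.5."""
    x = np.asarray(fractions, float)
    if len(x) < 2:
        raise ValueError("need >= 2 animals")
    if np.allclose(x.std(ddof=1), 0.0):
        direction = "above 0.5" if x[0] > 0.5 else \
            ("below 0.5" if x[0] < 0.5 else "at 0.5")
        return StatResult(test="t vs 50% food choices",
                          statistic=math.inf if x[0] != 0.5 else 0.0,
                          df1=len(x) - 1, p=math.nan, direction=direction,
                          note="zero variance (exact tie across animals)")
    t, p = sps.ttest_1samp(x, 0.5)
    direction = "food-preferring" if t > 0 else "sucrose-preferring"
    return StatResult(test="t vs 50% food choices", statistic=float(t),
                      df1=len(x) - 1, p=float(p), direction=direction)


def paired_t(a: Sequence[float], b: Sequence[float], name: str = "paired t"
             ) -> StatResult:
    a, b = np.asarray(a, float), np.asarray(b, float)
    t, p = sps.ttest_rel(a, b)
    return StatResult(test=name, statistic=float(t), df1=len(a) - 1,
                      p=float(p), direction="a>b" if t > 0 else "a<b")


def rm_anova(table: pd.DataFrame, dv: str, subject: str,
             within: Sequence[str],
             between: Optional[str] = None) -> list[StatResult]:
    """Repeated-measures ANOVA (within factors; optionally one between).

    Pure within-subject designs use statsmodels' AnovaRM; a mixed design
    (one within x one between) uses pingouin.  Subjects with incomplete
    cells are excluded listwise.  Sphericity correction is not applied for
    two-level factors (unnecessary).
    """
    cells = table.groupby([subject] + list(within))[dv].mean().reset_index()
    counts = cells.groupby(subject).size()
    full = counts.max()
    complete = counts[counts == full].index
    dropped = sorted(set(counts.index) - set(complete))
    if dropped:
        cells = cells[cells[subject].isin(complete)]
    note = f"excluded incomplete subjects: {dropped}" if dropped else ""

    results: list[StatResult] = []
    if np.allclose(cells[dv].to_numpy(float).std(), 0.0):
        # degenerate: identical values in every cell -> no effect variance
        n_sub = cells[subject].nunique()
        levels = {w: cells[w].nunique() for w in within}
        effects = {w: levels[w] - 1 for w in within}
        if len(within) == 2:
            effects[f"{within[0]} x {within[1]}"] = \
                (levels[within[0]] - 1) * (levels[within[1]] - 1)
        for effect, df1 in effects.items():
            results.append(StatResult(test=f"RM-ANOVA {effect}",
                                      statistic=0.0, df1=df1,
                                      df2=df1 * (n_sub - 1),
                                      p=1.0, note="zero variance" +
                                      ("; " + note if note else "")))
        return results
    if between is None:
        from statsmodels.stats.anova import AnovaRM
        fit = AnovaRM(cells, depvar=dv, subject=subject,
                      within=list(within)).fit()
        tab = fit.anova_table
        for effect, row in tab.iterrows():
            results.append(StatResult(
                test=f"RM-ANOVA {effect}", statistic=float(row["F Value"]),
                df1=float(row["Num DF"]), df2=float(row["Den DF"]),
                p=float(row["Pr > F"]), note=note))
    else:
        import pingouin as pg
        btw = table.groupby(subject)[between].first().reset_index()
        cells = cells.merge(btw, on=subject)
        if len(within) != 1:
            raise ValueError("mixed design supports exactly one within factor")
        tab = pg.mixed_anova(data=cells, dv=dv, within=within[0],
                             subject=subject, between=between)
        for _, row in tab.iterrows():
            results.append(StatResult(
                test=f"mixed-ANOVA {row['Source']}",
                statistic=float(row["F"]), df1=float(row["DF1"]),
                df2=float(row["DF2"]), p=float(row["p_unc"]), note=note))
    return results


def linear_trend_contrast(table: pd.DataFrame, dv: str, subject: str,
                          bin_col: str = "bin") -> StatResult:
    """Polynomial (linear) trend contrast across ordered bins.

    Each subject's bin means are projected onto centered linear contrast
    weights; the contrast scores are tested against zero with a one-sample
    t, reported as F = t^2 with (1, n-1) degrees of freedom.
    """
    wide = table.pivot_table(index=subject, columns=bin_col, values=dv)
    wide = wide.dropna()
    bins = np.asarray(sorted(wide.columns), float)
    weights = bins - bins.mean()
    scores = wide[sorted(wide.columns)].to_numpy() @ weights
    n = len(scores)
    if n < 2:
        raise ValueError("need >= 2 subjects for the trend contrast")
    t, p = sps.ttest_1samp(scores, 0.0)
    return StatResult(test=f"linear trend across {bin_col}",
                      statistic=float(t ** 2), df1=1, df2=n - 1, p=float(p),
                      direction="increasing" if t > 0 else "decreasing")


def index_choice_correlation(indices: Sequence[float],
                             choice_fractions: Sequence[float]) -> StatResult:
    """Pearson correlation of discrimination indices with choice fractions."""
    x = np.asarray(indices, float)
    y = np.asarray(choice_fractions, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired per-animal values")
    r, p = sps.pearsonr(x, y)
    return StatResult(test="index vs choice Pearson r", statistic=float(r),
                      df1=len(x) - 2, p=float(p),
                      direction="positive" if r > 0 else "negative")


def report(results: Sequence[StatResult]) -> str:
    """Human-readable text report of a batch of tests."""
    width = max((len(r.test) for r in results), default=10)
    lines = ["Behavioral / group statistics", "=" * 29]
    for r in results:
        lines.append(f"{r.test:<{width}s}  {str(r)[len(r.test) + 2:]}")
    return "\n".join(lines)
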