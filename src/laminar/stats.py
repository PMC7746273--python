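"""Group-level repeated-measures statistics and descriptive quantities.

All factors are within subject: amplitudes are reduced per subject to a
(layer x stimulus x task) cell table and tested with repeated-measures
ANOVAs (no sphericity correction by default, matching conventional
reporting of F with uncorrected degrees of freedom) and two-sided paired t
tests.  Error bars use the within-subject SEM: subject means are removed
before computing per-condition SEMs, with the Morey small-sample bias
factor sqrt(C / (C - 1)) applied by default.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.anova import AnovaRM


def rm_anova(table: pd.DataFrame, dv: str = "amplitude", subject: str = "subject",
             within: list[str] | tuple[str, ...] = ("stimulus", "layer"),
             ) -> dict[str, dict[str, float]]:
    """Repeated-measures ANOVA on a complete, balanced long table.

    Returns ``{effect: {"F", "df_num", "df_den", "p"}}`` for every main
    effect and interaction of the within-subject factors.  Missing cells
    (an incomplete crossing) raise.
    """
    within = list(within)
    counts = table.groupby([subject, *within], observed=True)[dv].count()
    n_cells = int(np.prod([table[w].nunique() for w in within])) * table[subject].nunique()
    if len(counts) != n_cells or counts.nunique() != 1:
        raise ValueError("repeated-measures ANOVA requires a complete balanced design")
    if counts.iloc[0] != 1:
        table = table.groupby([subject, *within], observed=True, as_index=False)[dv].mean()
    if float(np.var(table[dv].to_numpy())) < 1e-24:
        # degenerate (constant) data: every SS is 0; define F = 0, p = 1
        out = {}
        levels = {w: table[w].nunique() for w in within}
        n_sub = table[subject].nunique()
        import itertools

        for r in range(1, len(within) + 1):
            for combo in itertools.combinations(within, r):
                df_num = int(np.prod([levels[w] - 1 for w in combo]))
                out[":".join(combo)] = {"F": 0.0, "df_num": float(df_num),
                                        "df_den": float(df_num * (n_sub - 1)),
                                        "p": 1.0}
        return out
    res = AnovaRM(data=table, depvar=dv, subject=subject, within=within).fit()
    out = {}
    for effect, row in res.anova_table.iterrows():
        f = float(row["F Value"])
        p = float(row["Pr > F"])
        if not np.isfinite(f):  # degenerate (e.g. constant) data: SS_effect = 0
            f, p = 0.0, 1.0
        out[str(effect)] = {"F": f, "df_num": float(row["Num DF"]),
                            "df_den": float(row["Den DF"]), "p": p}
    return out


def paired_t(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Two-sided paired t test; df = n - 1.

    A zero-variance, nonzero-mean difference yields an infinite t (flagged
    by the value itself); identical samples yield t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("paired_t needs two equal-length 1-D samples, n >= 2")
    d = x - y
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return {"t": 0.0, "df": n - 1, "p": 1.0}
        warnings.warn("zero-variance differences: t is infinite")
        return {"t": float(np.sign(d.mean()) * np.inf), "df": n - 1, "p": 0.0}
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sp_stats.t.sf(abs(t), df=n - 1)
    return {"t": float(t), "df": n - 1, "p": float(p)}


def within_subject_sem(wide: pd.DataFrame, morey: bool = True) -> pd.Series:
    """Within-subject SEM per condition (columns) over subjects (rows).

    Each subject's mean is removed (and the grand mean restored) before the
    per-condition SEM is taken, so purely between-subject offsets do not
    inflate the error bars; the Morey factor corrects the resulting
    small-sample bias.
    """
    if len(wide) < 2:
        raise ValueError("within-subject SEM needs at least two subjects")
    vals = wide.to_numpy(dtype=float)
    centered = vals - vals.mean(axis=1, keepdims=True) + vals.mean()
    sem = centered.std(axis=0, ddof=1) / np.sqrt(len(wide))
    c = wide.shape[1]
    if morey and c > 1:
        sem = sem * np.sqrt(c / (c - 1))
    return pd.Series(sem, index=wide.columns)


def tsnr(series: np.ndarray, axis: int = -1) -> np.ndarray | float:
    """Temporal signal-to-noise ratio: mean over time divided by SD over time."""
    series = np.asarray(series, dtype=float)
    if series.shape[axis] < 2:
        raise ValueError("tSNR needs at least two time points")
    mean = series.mean(axis=axis)
    sd = series.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(sd == 0, np.sign(mean) * np.inf, mean / sd)
    if np.any(np.isinf(out)):
        warnings.warn("constant series: tSNR is infinite")
    return float(out) if np.isscalar(out) or out.ndim == 0 else out
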