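"""Group-level inferential statistics.

The behavioural analysis tests each group's FMR distribution against the
theoretical point of ambiguity 0.5 with one-tailed one-sample t-tests and
Cohen's d, compares groups with between-subjects factorial ANOVAs (Type-III
sums of squares, partial eta squared, Bonferroni post hocs), and relates
sleep parameters to FMR with uncorrected bivariate Pearson correlations.
A two-factor mixed ANOVA (one within, one between factor) is provided for
repeated ratings such as sleepiness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "AnovaResult",
    "CorrelationResult",
    "one_sample_t",
    "one_sample_t_from_summary",
    "factorial_anova",
    "mixed_anova",
    "pearson",
    "correlate_sleep_behavior",
]


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    d: float  # Cohen's d = |mean - mu0| / s.d.
    tail: str
    mu0: float
    n: int
    mean: float
    sd: float
    degenerate: bool = False


def one_sample_t(values, mu0: float = 0.5, tail: str = "lower") -> TTestResult:
    """One-sample t-test of mean(values) against mu0.

    ``tail`` is "lower" (alternative mean < mu0), "upper", or "two".  The
    default tests for an FMR shift below the 0.5 no-adaptation point, the
    a-priori direction of a negative after-effect.  A zero sample s.d. is
    flagged degenerate.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2")
    n = x.size
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        warnings.warn("zero sample s.d.; t-test degenerate")
        return TTestResult(np.nan, n - 1, np.nan, np.nan, tail, mu0, n, mean, sd, True)
    t = (mean - mu0) / (sd / np.sqrt(n))
    df = n - 1
    if tail == "lower":
        p = float(sps.t.cdf(t, df))
    elif tail == "upper":
        p = float(sps.t.sf(t, df))
    elif tail == "two":
        p = float(2 * sps.t.sf(abs(t), df))
    else:
        raise ValueError("tail must be 'lower', 'upper' or 'two'")
    d = abs(mean - mu0) / sd
    return TTestResult(float(t), df, p, float(d), tail, mu0, n, mean, sd)


def one_sample_t_from_summary(
    mean: float, sd: float, n: int, mu0: float = 0.5, tail: str = "lower"
) -> TTestResult:
    """t and Cohen's d recomputed from printed summary statistics."""
    if sd <= 0 or n < 2:
        raise ValueError("need sd > 0 and n >= 2")
    t = (mean - mu0) / (sd / np.sqrt(n))
    df = n - 1
    if tail == "lower":
        p = float(sps.t.cdf(t, df))
    elif tail == "upper":
        p = float(sps.t.sf(t, df))
    else:
        p = float(2 * sps.t.sf(abs(t), df))
    return TTestResult(float(t), df, p, abs(mean - mu0) / sd, tail, mu0, n, mean, sd)


@dataclass
class AnovaResult:
    table: pd.DataFrame  # effect, sum_sq, df, F, p, np2
    posthoc: pd.DataFrame | None
    dropped_effects: list[str]


def _bonferroni_posthoc(data: pd.DataFrame, dv: str, factor: str) -> pd.DataFrame:
    levels = sorted(data[factor].astype(str).unique())
    pairs = list(combinations(levels, 2))
    rows = []
    for a, b in pairs:
        xa = data.loc[data[factor].astype(str) == a, dv].to_numpy(dtype=float)
        xb = data.loc[data[factor].astype(str) == b, dv].to_numpy(dtype=float)
        t, p = sps.ttest_ind(xa, xb)
        rows.append(
            dict(
                factor=factor,
                A=a,
                B=b,
                mean_A=xa.mean(),
                mean_B=xb.mean(),
                t=float(t),
                p_unc=float(p),
                p_bonf=float(min(1.0, p * len(pairs))),
            )
        )
    return pd.DataFrame(rows)


def factorial_anova(
    data: pd.DataFrame,
    dv: str,
    between: list[str],
    posthoc: list[str] | None = None,
) -> AnovaResult:
    """Between-subjects factorial ANOVA, Type-III SS with effect coding.

    All main effects and interactions are reported with partial eta squared
    (SS_effect / (SS_effect + SS_error)).  Interactions whose cells are not
    all populated are dropped with a warning.  Pairwise Bonferroni-corrected
    comparisons are computed for the factors named in ``posthoc``.
    """
    from itertools import combinations as _combos

    data = data.copy()
    for f in between:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
        data[f] = data[f].astype(str)

    # detect empty cells of the full cross; drop interactions if any
    dropped: list[str] = []
    n_cells = int(np.prod([data[f].nunique() for f in between]))
    occupied = len(data.groupby(between).size())
    include_interactions = True
    if occupied < n_cells and len(between) > 1:
        dropped = ["interactions (empty cells)"]
        include_interactions = False
        warnings.warn("empty design cells; interaction effects dropped")

    effects: list[tuple[str, ...]] = [(f,) for f in between]
    if include_interactions:
        for order in range(2, len(between) + 1):
            effects.extend(_combos(between, order))

    # effect (sum-to-zero) coding per factor; interaction columns are
    # products of the main-effect columns — the parametrization under which
    # drop-one model comparison yields Type-III sums of squares
    main_cols: dict[str, np.ndarray] = {}
    for f in between:
        levels = sorted(data[f].unique())
        cols = np.zeros((len(data), len(levels) - 1))
        for j, lev in enumerate(levels[:-1]):
            cols[:, j] = np.where(
                data[f] == lev, 1.0, np.where(data[f] == levels[-1], -1.0, 0.0)
            )
        main_cols[f] = cols

    def effect_cols(eff: tuple[str, ...]) -> np.ndarray:
        out = main_cols[eff[0]]
        for f in eff[1:]:
            out = np.einsum("ni,nj->nij", out, main_cols[f]).reshape(len(data), -1)
        return out

    y = data[dv].to_numpy(dtype=float)
    blocks = {eff: effect_cols(eff) for eff in effects}
    intercept = np.ones((len(data), 1))

    def ssr_and_rank(mats: list[np.ndarray]) -> tuple[float, int]:
        X = np.hstack([intercept, *mats]) if mats else intercept
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid), int(rank)

    ss_err, rank_full = ssr_and_rank(list(blocks.values()))
    df_resid = float(len(data) - rank_full)

    rows = []
    for eff in effects:
        ss_red, rank_red = ssr_and_rank([m for e, m in blocks.items() if e != eff])
        ss = max(0.0, ss_red - ss_err)
        df_eff = float(rank_full - rank_red)
        if df_eff <= 0 or df_resid <= 0:
            warnings.warn(f"effect {':'.join(eff)} not estimable; reported as NaN")
            f_val = p_val = np.nan
        elif np.isclose(ss, 0.0, atol=1e-12):
            f_val, p_val = 0.0, 1.0  # no effect variance -> F defined as 0
        elif ss_err <= 1e-12:
            f_val, p_val = np.inf, 0.0
        else:
            f_val = (ss / df_eff) / (ss_err / df_resid)
            p_val = float(sps.f.sf(f_val, df_eff, df_resid))
        np2 = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
        rows.append(
            dict(effect=":".join(eff), sum_sq=ss, df=df_eff, df_resid=df_resid,
                 F=f_val, p=p_val, np2=np2)
        )
    table = pd.DataFrame(rows)

    ph = None
    if posthoc:
        ph = pd.concat([_bonferroni_posthoc(data, dv, f) for f in posthoc], ignore_index=True)
    return AnovaResult(table=table, posthoc=ph, dropped_effects=dropped)


def mixed_anova(
    data: pd.DataFrame, dv: str, within: str, between: str, subject: str
) -> pd.DataFrame:
    """Two-factor mixed ANOVA (one within, one between factor)."""
    import pingouin as pg

    return pg.mixed_anova(data=data, dv=dv, within=within, between=between, subject=subject)


@dataclass
class CorrelationResult:
    r: float
    p: float  # two-tailed, uncorrected
    n: int


def pearson(x, y) -> CorrelationResult:
    """Sample Pearson correlation with a two-tailed t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=int(x.size))


def correlate_sleep_behavior(parameters: pd.DataFrame, fmrs: pd.Series) -> pd.DataFrame:
    """Uncorrected Pearson r/p of every sleep parameter against FMR.

    ``parameters`` is a per-subject table (index = subject) of sleep
    parameters (stage epoch counts, SWS, REM, spindle densities, band
    powers); ``fmrs`` is the per-subject FMR series.  Parameters with fewer
    than 3 complete pairs, or constant over the cohort, are skipped with a
    warning.  p-values are two-tailed and uncorrected.
    """
    rows = []
    for col in parameters.columns:
        joined = pd.concat([parameters[col], fmrs], axis=1, join="inner").dropna()
        if len(joined) < 3:
            warnings.warn(f"parameter {col!r}: fewer than 3 complete pairs; skipped")
            continue
        x = joined.iloc[:, 0].to_numpy(dtype=float)
        y = joined.iloc[:, 1].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(f"parameter {col!r}: constant input; skipped")
            continue
        res = pearson(x, y)
        rows.append(dict(parameter=col, r=res.r, p=res.p, n=res.n))
    return pd.DataFrame(rows, columns=["parameter", "r", "p", "n"])
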