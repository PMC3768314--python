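"""Logistic psychometric fitting and the fitted-mean-rating (FMR) statistic.

Each 2AFC response is coded 1 = "extended", 0 = "compressed".  The
probability of responding "extended" at distortion level x is modelled as

    P(extended | x) = 1 / (1 + exp(-beta * (x - alpha)))

with alpha the point of ambiguity on the distortion axis and beta > 0 the
slope.  (alpha, beta) are fitted per subject by maximum likelihood.  The
adaptation statistic FMR is the fitted probability of judging the
undistorted face (x = 0) "extended": 0.5 means no bias, values below 0.5 a
bias toward "compressed" — the negative after-effect expected after
adapting to an extended face.

Subjects whose FMR deviates more than ``z`` (default 2.5) group standard
deviations from the group mean are excluded in a single pass, with the
mean/s.d. computed over the full group including the candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "ResponseTable",
    "PsychometricFit",
    "logistic",
    "fit_psychometric",
    "fmr_at",
    "exclude_outliers",
    "fit_cohort",
]

ALPHA_BOUNDS = (-12.0, 12.0)
BETA_BOUNDS = (1e-6, 10.0)
FTOL = 1e-8


def logistic(x, alpha: float, beta: float):
    """P(extended | x) under the two-parameter logistic observer."""
    return expit(beta * (np.asarray(x, dtype=float) - alpha))


@dataclass
class ResponseTable:
    """Per-subject 2AFC responses: distortion level k and binary response."""

    subject: str
    k: np.ndarray
    response: np.ndarray

    def __post_init__(self):
        self.k = np.asarray(self.k, dtype=int)
        self.response = np.asarray(self.response, dtype=int)
        if self.k.size == 0:
            raise ValueError("empty response table")
        if self.k.shape != self.response.shape:
            raise ValueError("k and response must align")
        if self.k.min() < -6 or self.k.max() > 6:
            raise ValueError("levels must lie in [-6, +6]")
        if not np.isin(self.response, [0, 1]).all():
            raise ValueError("responses must be binary (0=compressed, 1=extended)")
        if np.unique(self.k).size < 2:
            raise ValueError("responses required at >= 2 distinct levels")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, subject: str | None = None) -> "ResponseTable":
        subj = subject if subject is not None else str(df["subject"].iloc[0])
        return cls(subject=subj, k=df["k"].to_numpy(), response=df["response"].to_numpy())

    def counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Aggregate to (levels, n trials, n 'extended') triples."""
        levels = np.unique(self.k)
        n = np.array([(self.k == lv).sum() for lv in levels])
        y = np.array([self.response[self.k == lv].sum() for lv in levels])
        return levels, n, y


@dataclass
class PsychometricFit:
    subject: str
    alpha: float
    beta: float
    fmr: float
    loglik: float
    converged: bool

    def __post_init__(self):
        if not (np.isnan(self.fmr) or 0.0 <= self.fmr <= 1.0):
            raise ValueError("fmr must lie in [0, 1]")


def _neg_loglik(params, levels, n, y):
    alpha, beta = params
    z = beta * (levels - alpha)
    # sum y*z - n*log(1 + e^z), numerically stable
    return float(-(np.sum(y * z) - np.sum(n * np.logaddexp(0.0, z))))


def _moment_start(levels, n, y):
    # linearize: logit(rate) ~ beta*k - beta*alpha on clipped empirical rates
    rate = np.clip(y / n, 0.02, 0.98)
    lo = np.log(rate / (1 - rate))
    slope, intercept = np.polyfit(levels, lo, 1)
    beta0 = float(np.clip(slope, 0.05, BETA_BOUNDS[1]))
    alpha0 = float(np.clip(-intercept / beta0, *ALPHA_BOUNDS))
    return alpha0, beta0


def fit_psychometric(table: ResponseTable) -> PsychometricFit:
    """Bounded multi-start maximum-likelihood fit of (alpha, beta).

    beta is constrained positive (responses are coded so that "extended"
    becomes more likely as k grows).  If every response is identical the
    likelihood has no interior optimum: the fit is flagged non-converged and
    the FMR falls back to the empirical mean with a warning.
    """
    levels, n, y = table.counts()
    if np.all(y == 0) or np.all(y == n):
        warnings.warn(
            f"subject {table.subject}: all responses identical; "
            "reporting empirical mean as FMR, fit flagged non-converged"
        )
        fmr = float(y.sum() / n.sum())
        return PsychometricFit(table.subject, np.nan, np.nan, fmr, np.nan, converged=False)

    starts = [_moment_start(levels, n, y), (0.0, 0.5), (0.0, 2.0)]
    best = None
    for a0, b0 in starts:
        res = minimize(
            _neg_loglik,
            x0=[a0, b0],
            args=(levels.astype(float), n.astype(float), y.astype(float)),
            method="L-BFGS-B",
            bounds=[ALPHA_BOUNDS, BETA_BOUNDS],
            options={"ftol": FTOL, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    alpha, beta = float(best.x[0]), float(best.x[1])
    return PsychometricFit(
        subject=table.subject,
        alpha=alpha,
        beta=beta,
        fmr=float(logistic(0.0, alpha, beta)),
        loglik=-float(best.fun),
        converged=bool(best.success),
    )


def fmr_at(fit: PsychometricFit, x: float) -> float:
    """Fitted probability of an "extended" judgement at distortion level x."""
    return float(logistic(x, fit.alpha, fit.beta))


def exclude_outliers(fmrs, z: float = 2.5) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass z-score exclusion; returns (kept, excluded) index arrays.

    The group mean and s.d. include the candidate outliers; a zero s.d.
    (all values identical) excludes nobody.
    """
    fmrs = np.asarray(fmrs, dtype=float)
    if fmrs.size < 3:
        raise ValueError("outlier exclusion requires >= 3 subjects")
    sd = fmrs.std(ddof=1)
    if sd == 0:
        return np.arange(fmrs.size), np.array([], dtype=int)
    dev = np.abs(fmrs - fmrs.mean())
    excluded = np.flatnonzero(dev > z * sd)
    kept = np.flatnonzero(dev <= z * sd)
    return kept, excluded


def fit_cohort(tables: list[ResponseTable]) -> pd.DataFrame:
    """Tidy per-subject fit table: subject, alpha, beta, fmr, converged."""
    fits = [fit_psychometric(t) for t in tables]
    return pd.DataFrame(
        dict(
            subject=[f.subject for f in fits],
            alpha=[f.alpha for f in fits],
            beta=[f.beta for f in fits],
            fmr=[f.fmr for f in fits],
            loglik=[f.loglik for f in fits],
            converged=[f.converged for f in fits],
        )
    )
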