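"""Aggregation-kinetics analysis and the associated statistical tests.

Amyloid formation monitored by a fluorescence readout (intensity quenching,
antibody densitometry, or the per-image mean fluorescence lifetime) follows
a sigmoidal time course: a lag phase with little detectable fibril mass,
then rapid growth to a plateau.  Traces are fitted with the four-parameter
logistic

    L(t) = Linf + (L0 - Linf) / (1 + exp(k * (t - t50)))

and the lag time is extracted by the standard tangent construction of
amyloid kinetics: the intercept of the maximal-slope tangent with the
baseline, lag = t50 - 2/k (clamped at zero for lag-free kinetics).

Group comparisons use a paired Student t test, or Fisher's least
significant difference test after a one-way ANOVA for multiple comparisons
(protected LSD: pairwise calls are gated on a significant omnibus F).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "KineticTrace",
    "SigmoidFitResults",
    "SigmoidModel",
    "StatResult",
    "normalize_trace",
    "fit_sigmoid",
    "lag_time",
    "half_time_offset",
    "paired_t_test",
    "fisher_lsd",
    "significance_stars",
]

STAR_THRESHOLDS = (0.05, 0.01, 0.001, 0.0001)


@dataclass(frozen=True)
class KineticTrace:
    """A time-resolved aggregation readout.

    times are in hours; values in ns for lifetime traces, arbitrary units
    for intensity/densitometry; errors are optional per-point SD/SEM.
    """

    times: np.ndarray
    values: np.ndarray
    errors: Optional[np.ndarray] = None
    kind: str = "lifetime"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be matching 1-D arrays")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if self.errors is not None:
            e = np.asarray(self.errors, dtype=float)
            if e.shape != t.shape:
                raise ValueError("errors must match times")
            object.__setattr__(self, "errors", e)

    def __len__(self):
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_hr": self.times, "value": self.values})
        df["sem"] = self.errors if self.errors is not None else np.nan
        df["kind"] = self.kind
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "KineticTrace":
        errors = None
        if "sem" in df and df["sem"].notna().any():
            errors = df["sem"].to_numpy(float)
        kind = str(df["kind"].iloc[0]) if "kind" in df and len(df) else "lifetime"
        return cls(times=df["time_hr"].to_numpy(float),
                   values=df["value"].to_numpy(float),
                   errors=errors, kind=kind)


def normalize_trace(trace: KineticTrace, mode: str = "max") -> KineticTrace:
    """Normalize a trace relative to its maximum, or to the [min, max] range."""
    if len(trace) == 0:
        raise ValueError("trace is empty")
    v = trace.values
    if mode == "max":
        peak = v.max()
        if peak == 0:
            raise ValueError("cannot normalize: maximum value is zero")
        return replace(trace, values=v / peak, errors=None)
    if mode == "minmax":
        span = v.max() - v.min()
        if span == 0:
            raise ValueError("degenerate trace: zero range")
        return replace(trace, values=(v - v.min()) / span, errors=None)
    raise ValueError(f"unknown normalization mode {mode!r}")


def _sigmoid(t, L0, Linf, k, t50):
    return Linf + (L0 - Linf) / (1.0 + np.exp(np.clip(k * (t - t50), -500, 500)))


@dataclass(frozen=True)
class SigmoidFitResults:
    """Fitted four-parameter logistic and the derived lag time."""

    L0: float
    Linf: float
    k: float       # 1/hr, > 0
    t50: float     # hr
    rss: float
    converged: bool

    @property
    def lag(self) -> float:
        """Tangent-construction lag time, clamped at zero."""
        return max(self.t50 - 2.0 / self.k, 0.0)

    def predict(self, times) -> np.ndarray:
        return _sigmoid(np.asarray(times, float), self.L0, self.Linf,
                        self.k, self.t50)

    def summary(self) -> str:
        return "\n".join([
            "Sigmoidal aggregation-kinetics fit",
            "-" * 36,
            f"baseline L0      {self.L0:.4g}",
            f"plateau  Linf    {self.Linf:.4g}",
            f"rate k           {self.k:.4g} /hr",
            f"half-time t50    {self.t50:.4g} hr",
            f"lag time         {self.lag:.4g} hr",
            f"rss              {self.rss:.4g}",
            f"converged        {self.converged}",
        ])


class SigmoidFitError(RuntimeError):
    """All optimizer starts failed; carries the best residual seen."""

    def __init__(self, message, best_rss=np.inf):
        super().__init__(message)
        self.best_rss = best_rss


class SigmoidModel:
    """Least-squares sigmoid model for one kinetic trace.

    Multi-start Levenberg-Marquardt: a data-driven initial guess plus
    deterministic perturbed restarts guard against the flat-lag local
    minima typical of aggregation traces.
    """

    def __init__(self, trace: KineticTrace):
        if len(trace) < 5:
            raise ValueError("need at least 5 time points spanning the transition")
        self.trace = trace

    def _starts(self, n_starts: int):
        t, v = self.trace.times, self.trace.values
        L0, Linf = v[0], v[-1]
        span = abs(t[-1] - t[0])
        # midpoint guess: first crossing of the half-amplitude level
        half = 0.5 * (L0 + Linf)
        idx = np.argmin(np.abs(v - half))
        t50 = t[idx]
        k0 = 4.0 / max(span / 4.0, 1e-6)
        yield (L0, Linf, k0, t50)
        rng = np.random.default_rng(0)  # fixed: fits are deterministic
        for _ in range(n_starts - 1):
            yield (L0 + rng.normal(0, 0.05 * (abs(L0) + 1e-9)),
                   Linf + rng.normal(0, 0.05 * (abs(Linf) + 1e-9)),
                   k0 * np.exp(rng.normal(0, 1.0)),
                   t[0] + rng.random() * span)

    def fit(self, n_starts: int = 8) -> SigmoidFitResults:
        t, v = self.trace.times, self.trace.values
        span = max(t[-1] - t[0], 1e-6)
        lo = [-np.inf, -np.inf, 1e-4, t[0] - 2 * span]
        hi = [np.inf, np.inf, 1e4, t[-1] + 2 * span]
        best = None
        for p0 in self._starts(n_starts):
            p0 = np.clip(p0, lo, hi)
            try:
                res = optimize.least_squares(
                    lambda p: _sigmoid(t, *p) - v, p0, bounds=(lo, hi),
                    xtol=1e-12, ftol=1e-12, gtol=1e-12)
            except Exception:
                continue
            rss = float(np.sum(res.fun ** 2))
            if res.success and (best is None or rss < best[0]):
                best = (rss, res.x)
        if best is None:
            raise SigmoidFitError("sigmoid fit failed from all starts")
        rss, (L0, Linf, k, t50) = best
        return SigmoidFitResults(L0=float(L0), Linf=float(Linf), k=float(k),
                                 t50=float(t50), rss=rss, converged=True)


def fit_sigmoid(trace: KineticTrace, n_starts: int = 8) -> SigmoidFitResults:
    """Convenience wrapper: fit the four-parameter logistic to a trace."""
    return SigmoidModel(trace).fit(n_starts=n_starts)


def lag_time(fit: SigmoidFitResults) -> float:
    """Lag phase from the tangent construction, t50 - 2/k, clamped at 0."""
    return fit.lag


def half_time_offset(trace_a: KineticTrace, trace_b: KineticTrace) -> float:
    """t50(a) - t50(b) from independent sigmoid fits.

    Quantifies the temporal offset between paired readouts of the same
    aggregation reaction (e.g. a lifetime trace lagging a fibril-antibody
    trace); the slower (later) readout passed as ``a`` gives a positive
    offset.  Rising traces fit naturally (L0 < Linf in the same form).
    """
    return fit_sigmoid(trace_a).t50 - fit_sigmoid(trace_b).t50


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def significance_stars(p: float) -> str:
    """Asterisk coding: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001."""
    return "*" * sum(p < thr for thr in STAR_THRESHOLDS)


@dataclass(frozen=True)
class StatResult:
    """One hypothesis-test outcome."""

    method: str
    statistic: float
    df: float
    p_value: float
    comparison: str = ""
    significant: bool = False
    stars: str = ""

    def __str__(self):
        return (f"{self.method} {self.comparison}: t={self.statistic:.4g}, "
                f"df={self.df:g}, p={self.p_value:.4g} {self.stars}")


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> StatResult:
    """Two-sided paired Student t test.

    t = mean(d) / (sd(d)/sqrt(n)) on the within-pair differences d = a - b,
    df = n - 1.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be matching 1-D arrays")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            t_stat, p = 0.0, 1.0
        else:
            import warnings
            warnings.warn("zero variance of differences with nonzero mean; "
                          "p -> 0", RuntimeWarning, stacklevel=2)
            t_stat, p = np.inf if d.mean() > 0 else -np.inf, 0.0
    else:
        t_stat = d.mean() / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(abs(t_stat), df=n - 1)
    p = float(min(p, 1.0))
    return StatResult(method="paired_t", statistic=float(t_stat), df=n - 1,
                      p_value=p, comparison="a vs b",
                      significant=p < 0.05, stars=significance_stars(p))


def fisher_lsd(groups: Sequence[Sequence[float]], labels=None,
               alpha: float = 0.05) -> list[StatResult]:
    """Protected Fisher's least-significant-difference test.

    One-way ANOVA supplies the pooled mean-square error; each pair (i, j)
    is then compared with t = (mean_i - mean_j) / sqrt(MSE (1/n_i + 1/n_j)),
    df = N - g, two-sided.  Pairwise significance is gated on the omnibus F
    being significant at ``alpha`` (protected LSD).  The omnibus result is
    returned first, followed by all pairwise comparisons.
    """
    samples = [np.asarray(g, float) for g in groups]
    g = len(samples)
    if g < 3:
        raise ValueError("Fisher's LSD requires at least 3 groups")
    if any(s.size < 2 for s in samples):
        raise ValueError("every group needs n >= 2")
    if labels is None:
        labels = [f"g{i}" for i in range(1, g + 1)]
    ns = np.array([s.size for s in samples])
    means = np.array([s.mean() for s in samples])
    big_n = int(ns.sum())
    grand = np.concatenate(samples).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((s - m) ** 2).sum() for s, m in zip(samples, means)))
    df_b, df_w = g - 1, big_n - g
    mse = ss_within / df_w
    if mse == 0:
        f_stat = 0.0 if ss_between <= 1e-12 else np.inf
    else:
        f_stat = (ss_between / df_b) / mse
    p_f = float(stats.f.sf(f_stat, df_b, df_w)) if np.isfinite(f_stat) else 0.0
    omnibus_sig = p_f < alpha
    results = [StatResult(method="anova_f", statistic=float(f_stat), df=df_w,
                          p_value=p_f, comparison="omnibus",
                          significant=omnibus_sig,
                          stars=significance_stars(p_f) if omnibus_sig else "")]
    for i in range(g):
        for j in range(i + 1, g):
            se = np.sqrt(mse * (1.0 / ns[i] + 1.0 / ns[j]))
            if se == 0:
                t_stat = 0.0 if means[i] == means[j] else np.inf
            else:
                t_stat = (means[i] - means[j]) / se
            p = float(2.0 * stats.t.sf(abs(t_stat), df=df_w)) if np.isfinite(t_stat) else 0.0
            sig = omnibus_sig and p < alpha
            results.append(StatResult(
                method="fisher_lsd", statistic=float(t_stat), df=df_w,
                p_value=p, comparison=f"{labels[i]} vs {labels[j]}",
                significant=sig,
                stars=significance_stars(p) if sig else ""))
    return results


def stat_results_frame(results: Sequence[StatResult]) -> pd.DataFrame:
    """Tabulate StatResults as (comparison, method, statistic, df, p, stars)."""
    return pd.DataFrame([{
        "comparison": r.comparison, "method": r.method,
        "statistic": r.statistic, "df": r.df, "p": r.p_value,
        "stars": r.stars,
    } for r in results])
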