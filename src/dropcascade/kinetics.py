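"""Exponential-plateau kinetics of the ACC-to-crystal transformation.

The number of droplets still containing amorphous calcium carbonate (ACC)
decays toward a plateau as

    N_d_ACC(t) = A * exp(-k * t) + C

where k (1/min) is the first-order transformation rate of the labile
droplet population and C is the inert plateau.  The same model in ratio
form, N_d_ACC / N_d, gives a dimensionless amplitude and plateau.  The
half-life — time for the ACC fraction to fall to 0.5 — is only finite when
the fitted plateau lies below 0.5; otherwise an empirical lower bound (the
latest observation with fraction > 0.5) is all the data support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .acc_detect import TimePointCount


@dataclass
class DecayFit:
    """Fitted y = A*exp(-k*t) + C."""

    form: str  # 'count' | 'ratio'
    A: float
    k: float  # 1/min, constrained >= 0
    C: float
    rss: float
    n_points: int
    no_decay: bool = False  # flagged when the series carries no decay signal

    def __post_init__(self) -> None:
        if self.form not in ("count", "ratio"):
            raise ValueError("form must be 'count' or 'ratio'")
        if self.k < 0:
            raise ValueError("rate k must be nonnegative")
        if self.form == "ratio":
            if not -1e-6 <= self.C <= 1 + 1e-6:
                raise ValueError("ratio-form plateau C must lie in [0, 1]")
            if self.A + self.C > 1 + 0.05:
                raise ValueError("ratio-form A + C exceeds 1")


@dataclass
class HalfLifeBound:
    """Half-life of the ACC fraction: exact, a lower bound, or unreachable."""

    kind: str  # 'exact' | 'lower_bound' | 'unreachable'
    value_min: float | None
    basis: str  # 'model' | 'empirical'


@dataclass
class TimeSeries:
    """Pooled ACC time series: one point per timestep."""

    times: np.ndarray  # mean acquisition time per timestep, min
    n_acc: np.ndarray  # pooled over locations
    n_total: np.ndarray
    spans: list[tuple[float, float]]

    def ratios(self) -> np.ndarray:
        return self.n_acc / self.n_total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                mean_time_min=self.times,
                time_earliest_min=[s[0] for s in self.spans],
                time_latest_min=[s[1] for s in self.spans],
                n_acc=self.n_acc,
                n_droplets=self.n_total,
                acc_ratio=self.ratios(),
            )
        )


def assemble_timeseries(counts: Iterable[TimePointCount]) -> TimeSeries:
    """Pool per-location counts into one point per timestep.

    Counts are summed over locations; the time is the mean of per-location
    acquisition times and the span is their (min, max).  Input order is
    irrelevant — output is sorted by timestep index.  Timesteps with no
    frames are simply absent.
    """
    by_step: dict[int, list[TimePointCount]] = {}
    for c in counts:
        by_step.setdefault(c.timestep_index, []).append(c)
    if not by_step:
        raise ValueError("no count rows supplied")
    times, n_acc, n_tot, spans = [], [], [], []
    for step in sorted(by_step):
        rows = by_step[step]
        ts = [r.mean_time_min for r in rows]
        times.append(float(np.mean(ts)))
        spans.append((float(min(r.time_span_min[0] for r in rows)),
                      float(max(r.time_span_min[1] for r in rows))))
        n_acc.append(sum(r.n_acc for r in rows))
        n_tot.append(sum(r.n_droplets for r in rows))
    return TimeSeries(np.array(times), np.array(n_acc), np.array(n_tot), spans)


def _model(t, A, k, C):
    return A * np.exp(-k * t) + C


def fit_decay(
    times: Sequence[float], values: Sequence[float], form: str = "count"
) -> DecayFit:
    """Least-squares fit of y = A*exp(-k*t) + C with k constrained >= 0.

    Initialization: C0 = min(y), A0 = max(y) - C0, and k0 from a log-linear
    regression of (y - 0.99*C0) against t; parameters are then refined to a
    1e-10 tolerance.  A series with no measurable decay (amplitude ~ 0, or
    k pinned at zero) is returned with ``no_decay`` set.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size:
        raise ValueError("times and values differ in length")
    if t.size < 4:
        raise ValueError(f"need at least 4 points to fit, got {t.size}")
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("times and values must be finite (empty-frame "
                         "timesteps should be excluded before fitting)")

    c0 = float(y.min())
    a0 = float(y.max() - c0)
    resid0 = y - 0.99 * c0
    k0 = 0.0
    pos = resid0 > 0
    if a0 > 0 and pos.sum() >= 2 and np.ptp(t[pos]) > 0:
        slope = np.polyfit(t[pos], np.log(resid0[pos]), 1)[0]
        k0 = max(-float(slope), 0.0)
    if k0 == 0.0:
        k0 = 1.0 / max(float(t.max()), 1.0)

    scale = max(abs(y).max(), 1.0)

    def residuals(p):
        return (_model(t, *p) - y) / scale

    sol = least_squares(
        residuals,
        x0=[a0 if a0 > 0 else scale * 1e-3, k0, c0],
        bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
        xtol=1e-10, ftol=1e-10, gtol=1e-10,
    )
    if not sol.success:
        raise RuntimeError(
            f"decay fit did not converge (status {sol.status}, "
            f"init A={a0}, k={k0}, C={c0}): {sol.message}"
        )
    A, k, C = map(float, sol.x)
    rss = float(np.sum((_model(t, A, k, C) - y) ** 2))
    no_decay = bool(abs(A) <= 1e-8 * scale or k <= 1e-12)
    if form == "ratio":
        C = min(max(C, 0.0), 1.0)
    return DecayFit(form=form, A=A, k=max(k, 0.0), C=C, rss=rss,
                    n_points=int(t.size), no_decay=no_decay)


def evaluate_fit(fit: DecayFit, t: float) -> float:
    """Model value A*exp(-k*t) + C at time ``t`` (minutes, >= 0)."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    return float(_model(t, fit.A, fit.k, fit.C))


def acc_fraction(n_acc: int, n_total: int) -> float:
    """Exact ACC-droplet fraction, reported to 3 decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_acc <= n_total:
        raise ValueError("need 0 <= n_acc <= n_total")
    return round(n_acc / n_total, 3)


def half_life_bound(
    fit: DecayFit | None = None,
    empirical: Sequence[tuple[float, float]] | None = None,
) -> HalfLifeBound:
    """Half-life of the ACC fraction from a ratio-form fit or observations.

    From a fit: t1/2 = ln(A / (0.5 - C)) / k exactly when the plateau C is
    below 0.5; a plateau at or above 0.5 makes the half-life unreachable
    under the fitted model.  From an empirical ``(time, fraction)`` series:
    the latest observation time with fraction > 0.5 is a lower bound.
    """
    if fit is not None:
        if fit.form != "ratio":
            raise ValueError("half-life needs a ratio-form fit")
        if fit.C < 0.5 and fit.k > 0 and fit.A > 0.5 - fit.C:
            t_half = float(np.log(fit.A / (0.5 - fit.C)) / fit.k)
            return HalfLifeBound(kind="exact", value_min=t_half, basis="model")
        return HalfLifeBound(kind="unreachable", value_min=None, basis="model")
    if empirical is not None:
        above = [t for t, frac in empirical if frac > 0.5]
        if not above:
            return HalfLifeBound(kind="lower_bound", value_min=0.0,
                                 basis="empirical")
        return HalfLifeBound(kind="lower_bound", value_min=float(max(above)),
                             basis="empirical")
    raise ValueError("supply a fit or an empirical series")


def bootstrap_rate_ci(
    counts: Sequence[TimePointCount],
    form: str = "ratio",
    n_boot: int = 200,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Nonparametric bootstrap CI for k, resampling locations with replacement.

    The headline point estimate is a plain unweighted fit with no
    uncertainty attached; this interval is an additive feature.
    """
    locs = sorted({c.location_id for c in counts})
    if len(locs) < 2:
        raise ValueError("need at least 2 locations to bootstrap")
    rng = np.random.default_rng(seed)
    ks = []
    by_loc = {loc: [c for c in counts if c.location_id == loc] for loc in locs}
    for _ in range(n_boot):
        sample: list[TimePointCount] = []
        for i, loc in enumerate(rng.choice(locs, size=len(locs), replace=True)):
            for c in by_loc[loc]:
                sample.append(TimePointCount(
                    location_id=f"bs{i}", timestep_index=c.timestep_index,
                    mean_time_min=c.mean_time_min, time_span_min=c.time_span_min,
                    n_droplets=c.n_droplets,
                    n_vaterite_droplets=c.n_vaterite_droplets,
                    n_calcite_droplets=c.n_calcite_droplets, n_acc=c.n_acc))
        series = assemble_timeseries(sample)
        yv = series.ratios() if form == "ratio" else series.n_acc
        try:
            ks.append(fit_decay(series.times, yv, form=form).k)
        except (RuntimeError, ValueError):
            continue
    if not ks:
        raise RuntimeError("all bootstrap fits failed")
    lo, hi = np.quantile(ks, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)
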