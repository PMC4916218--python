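"""Modified-logistic growth-curve fitting and diauxic rate averaging.

Growth curves are OD₆₀₀ time series.  Each exponential phase is fit with the
Zwietering reparameterization of the logistic,

    OD(t) = OD₀ + A / (1 + exp(4·μ·(λ − t)/A + 2)),

whose parameters are directly interpretable: A is the OD rise of the phase,
μ the maximum slope (the tangent at the inflection), and λ the lag — the
time-axis intercept of that tangent.  Diauxic (two-phase) growth is detected
from the smoothed log-OD derivative; the interval-weighted average rate
weights each phase's μ by the biomass (ΔOD) it produced:

    μ_avg = Σ μ_k·ΔOD_k / Σ ΔOD_k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .types import DomainError, SampleCondition


class GrowthFitError(RuntimeError):
    """Logistic fit failed to converge; carries the best attempt, if any."""

    def __init__(self, message: str, best: Optional["LogisticFit"] = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class GrowthCurve:
    """One OD₆₀₀ time series (hours, strictly increasing; OD ≥ 0)."""

    times: np.ndarray
    od: np.ndarray
    condition: Optional[SampleCondition] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", y)
        if t.size != y.size:
            raise DomainError("times and od must have equal length")
        if t.size < 5:
            raise DomainError("a growth curve needs at least 5 points")
        if np.any(np.diff(t) <= 0):
            raise DomainError("times must be strictly increasing")
        if np.any(y < 0):
            raise DomainError("OD values cannot be negative")


def zwietering_od(t, od0, A, mu, lam):
    """Modified-logistic OD(t) = OD₀ + A/(1 + exp(4μ(λ−t)/A + 2))."""
    t = np.asarray(t, dtype=float)
    z = 4.0 * mu * (lam - t) / A + 2.0
    return od0 + A / (1.0 + np.exp(np.clip(z, -500, 500)))


@dataclass(frozen=True)
class LogisticFit:
    od0: float
    A: float
    mu: float
    lam: float
    rss: float

    def predict(self, t):
        return zwietering_od(t, self.od0, self.A, self.mu, self.lam)


@dataclass(frozen=True)
class PhaseFit:
    """One growth phase: logistic parameters plus its time window and ΔOD."""

    A: float
    mu: float
    lam: float
    window: tuple[float, float]
    delta_od: float
    rss: float


@dataclass(frozen=True)
class GrowthFit:
    phases: tuple[PhaseFit, ...]
    mu_avg: float
    diauxic: bool


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    od0 = float(np.min(y))
    A = float(np.max(y) - od0)
    # μ from the steepest discrete OD slope; λ from that tangent's intercept
    # with the baseline.
    dy = np.diff(y) / np.diff(t)
    k = int(np.argmax(dy))
    mu0 = max(float(dy[k]), 1e-6)
    t_star = 0.5 * (t[k] + t[k + 1])
    y_star = 0.5 * (y[k] + y[k + 1])
    lam0 = t_star - (y_star - od0) / mu0
    return od0, A, mu0, lam0


#: multiplicative jitters applied to the (μ, λ) start in the multi-start loop
_MULTISTART = (1.0, 0.5, 0.75, 1.5, 2.0)


def fit_logistic(curve: GrowthCurve) -> LogisticFit:
    """Least-squares modified-logistic fit with multi-start initialization.

    Raises :class:`GrowthFitError` on a flat curve or when no start
    converges; the error carries the best (lowest-RSS) attempt seen.
    """
    t, y = curve.times, curve.od
    if np.max(y) <= np.min(y):
        raise GrowthFitError("flat curve: no growth signal to fit")
    od0, A0, mu0, lam0 = _initial_guess(t, y)
    span = float(t[-1] - t[0])
    best: Optional[LogisticFit] = None
    for jit in _MULTISTART:
        p0 = [od0, max(A0, 1e-4), mu0 * jit, lam0 * jit if lam0 > 0 else lam0 + span * (jit - 1) * 0.1]
        try:
            popt, _ = curve_fit(
                zwietering_od,
                t,
                y,
                p0=p0,
                bounds=(
                    [0.0, 1e-6, 1e-9, t[0] - 10 * span],
                    [np.inf, np.inf, np.inf, t[-1] + 10 * span],
                ),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        resid = y - zwietering_od(t, *popt)
        rss = float(np.dot(resid, resid))
        fit = LogisticFit(od0=popt[0], A=popt[1], mu=popt[2], lam=popt[3], rss=rss)
        if best is None or fit.rss < best.rss:
            best = fit
        # accept early on an essentially perfect fit
        if rss < 1e-12 * max(1.0, float(np.dot(y, y))):
            break
    if best is None:
        raise GrowthFitError("logistic fit did not converge from any start")
    return best


def detect_phases(curve: GrowthCurve) -> list[tuple[int, int]]:
    """Detect 1 or 2 growth phases; returns index windows [start, stop).

    The OD series is smoothed (centered 3-point median, then 3-point mean)
    and differentiated.  In the modified-logistic parameterization the
    derivative peaks at μ for each phase, so a diauxie shows up as a
    rise–dip–rise in dOD/dt: a second phase is declared when the smoothed
    derivative falls below 10% of its running maximum and later re-exceeds
    50% of that maximum, with the split at the intervening derivative
    minimum.  Curves shorter than 8 points, or without a detectable plateau,
    yield a single window.
    """
    t, y = curve.times, curve.od
    n = t.size
    if n < 8:
        return [(0, n)]
    med = np.copy(y)
    med[1:-1] = np.median(np.lib.stride_tricks.sliding_window_view(y, 3), axis=1)
    smooth = np.copy(med)
    smooth[1:-1] = np.convolve(med, np.ones(3) / 3.0, mode="valid")
    deriv = np.gradient(smooth, t)
    runmax = np.maximum.accumulate(np.clip(deriv, 0.0, None))
    dip_start = None
    for i in range(1, n):
        if runmax[i] <= 0:
            continue
        if dip_start is None:
            if deriv[i] < 0.10 * runmax[i]:
                dip_start = i
        else:
            if deriv[i] > 0.50 * runmax[dip_start]:
                # second rise found: split at the derivative minimum in the dip
                split = dip_start + int(np.argmin(deriv[dip_start:i + 1]))
                # guard against degenerate windows; windows stay disjoint
                if split < 5 or n - split < 5:
                    return [(0, n)]
                return [(0, split), (split, n)]
    return [(0, n)]


def weighted_growth_rate(fits: Sequence[PhaseFit]) -> float:
    """Biomass-weighted average rate μ_avg = Σ μ_k·ΔOD_k / Σ ΔOD_k."""
    if not fits:
        raise DomainError("no growth phases supplied")
    weights = [f.delta_od for f in fits if f.delta_od > 0]
    if not weights:
        raise DomainError("all phases produced non-positive ΔOD")
    num = sum(f.mu * f.delta_od for f in fits if f.delta_od > 0)
    return num / sum(weights)


def fit_growth_curve(curve: GrowthCurve) -> GrowthFit:
    """Phase detection + per-phase logistic fits + interval-weighted μ_avg.

    ΔOD per phase is the fitted asymptote rise A (noise-robust), not the raw
    endpoint difference.
    """
    windows = detect_phases(curve)
    phases = []
    for start, stop in windows:
        sub = GrowthCurve(times=curve.times[start:stop], od=curve.od[start:stop])
        fit = fit_logistic(sub)
        phases.append(
            PhaseFit(
                A=fit.A,
                mu=fit.mu,
                lam=fit.lam,
                window=(float(curve.times[start]), float(curve.times[stop - 1])),
                delta_od=fit.A,
                rss=fit.rss,
            )
        )
    return GrowthFit(
        phases=tuple(phases),
        mu_avg=weighted_growth_rate(phases),
        diauxic=len(phases) > 1,
    )


def replicate_growth_summary(
    curves: Sequence[GrowthCurve],
) -> tuple[float, Optional[float], list[GrowthFit]]:
    """Mean and SEM of per-replicate μ_avg across biological replicates.

    SEM is ``None`` for a single replicate (no between-replicate scatter to
    estimate).
    """
    if not curves:
        raise DomainError("no growth curves supplied")
    fits = [fit_growth_curve(c) for c in curves]
    mus = np.array([f.mu_avg for f in fits])
    mean = float(mus.mean())
    sem = float(mus.std(ddof=1) / math.sqrt(mus.size)) if mus.size > 1 else None
    return mean, sem, fits


#: Published interval-weighted growth rates (1/h, mean ± SEM) for
#: D. alaskensis G20 wild type and nfnAB-2 transposon mutants under the five
#: study treatments.  Used as study-condition anchors by the synthetic-data
#: generator envelopes and for cross-checks.
REPORTED_GROWTH_RATES: dict[tuple[str, str], tuple[float, float]] = {
    ("pyruvate/sulfate", "wild-type"): (0.154, 0.029),
    ("pyruvate/sulfate", "nfnA-2"): (0.172, 0.029),
    ("pyruvate/sulfate", "nfnB-2"): (0.168, 0.035),
    ("malate/sulfate", "wild-type"): (0.067, 0.007),
    ("malate/sulfate", "nfnA-2"): (0.014, 0.006),
    ("malate/sulfate", "nfnB-2"): (0.015, 0.004),
    ("fumarate/sulfate", "wild-type"): (0.085, 0.012),
    ("fumarate/sulfate", "nfnA-2"): (0.011, 0.002),
    ("fumarate/sulfate", "nfnB-2"): (0.007, 0.006),
    ("fumarate fermentation", "wild-type"): (0.057, 0.007),
    ("fumarate fermentation", "nfnA-2"): (0.010, 0.002),
    ("fumarate fermentation", "nfnB-2"): (0.015, 0.004),
    ("pyruvate fermentation", "wild-type"): (0.131, 0.007),
    ("pyruvate fermentation", "nfnA-2"): (0.120, 0.001),
    ("pyruvate fermentation", "nfnB-2"): (0.149, 0.012),
}


def mutant_wildtype_rate_ratio(treatment: str) -> float:
    """Mean mutant μ_avg over wild-type μ_avg for one treatment (fraction).

    Computed from the published rate table, e.g. the malate/sulfate and
    fumarate-fermentation treatments both give ≈0.22.
    """
    wt = REPORTED_GROWTH_RATES[(treatment, "wild-type")][0]
    mutants = [
        REPORTED_GROWTH_RATES[(treatment, s)][0] for s in ("nfnA-2", "nfnB-2")
    ]
    return float(np.mean(mutants) / wt)
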