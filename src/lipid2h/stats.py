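"""Lipid-profile quantitation, retention indexing, and study-level statistics.

Covers: relative-abundance profiles against a co-injected internal standard,
Kovats retention indices against an n-alkane ladder, the Pearson correlation
screen over profile/rate/fractionation variables, candidate models for the
growth-rate–fractionation relationship (linear, exponential decay,
hyperbolic, ranked by AICc), and the branched-chain primer mass-balance
inference that isolates the δ²H of the amino-acid-derived primer hydrogen in
anteiso fatty acids.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

from .compounds import FattyAcid, HydrogenInventory, parse_lipid_label
from .isotope import FractionationResult, fractionation
from .types import DeltaValue, DomainError

logger = logging.getLogger("lipid2h")


@dataclass(frozen=True)
class RetentionLadder:
    """An n-alkane retention ladder: carbon numbers vs retention times."""

    carbons: tuple[int, ...]
    times: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.carbons) != len(self.times) or len(self.carbons) < 2:
            raise DomainError("ladder needs >= 2 (carbon, time) rungs")
        if any(b <= a for a, b in zip(self.carbons, self.carbons[1:])):
            raise DomainError("ladder carbon numbers must strictly increase")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise DomainError("ladder retention times must strictly increase")


def kovats_ri(rt: float, ladder: RetentionLadder) -> float:
    """Linear (temperature-programmed) Kovats retention index.

    RI = 100·n + 100·(rt − t_n)/(t_{n+1} − t_n) for the bracketing alkane
    rungs; exact multiples of 100 on the rungs themselves.  Raises on a
    retention time outside the ladder span.
    """
    t = ladder.times
    if rt < t[0] or rt > t[-1]:
        raise DomainError(
            f"retention time {rt} min outside ladder span [{t[0]}, {t[-1]}]"
        )
    # rightmost rung with t_n <= rt (interior bracketing for the last rung)
    k = int(np.searchsorted(t, rt, side="right")) - 1
    k = min(k, len(t) - 2)
    n = ladder.carbons[k]
    step = ladder.carbons[k + 1] - n
    return 100.0 * n + 100.0 * step * (rt - t[k]) / (t[k + 1] - t[k])


@dataclass(frozen=True)
class ProfileSummary:
    """Relative-abundance profile plus branched-chain summary ratios."""

    percent: dict[str, float]       # compound -> % of total (IS excluded)
    amounts: dict[str, float]       # compound -> absolute amount (IS units)
    branched_fraction: float        # % of total from iso+anteiso chains
    anteiso_iso_ratio: float        # anteiso % / iso % (inf if no iso)


def quantify(
    peaks: Sequence[tuple[str, float]],
    internal_standard: tuple[str, float],
) -> ProfileSummary:
    """Quantify peak areas against a co-injected internal standard.

    ``peaks`` is (compound label, area); ``internal_standard`` is
    (label, known amount).  amount_i = area_i/area_IS × known amount;
    percentages exclude the internal standard from the total and are
    invariant to uniform scaling of all areas.
    """
    is_label, is_amount = internal_standard
    is_area = None
    for label, area in peaks:
        if label == is_label:
            is_area = area
            break
    if is_area is None or is_area <= 0:
        raise DomainError(f"internal standard peak {is_label!r} missing or empty")
    amounts: dict[str, float] = {}
    for label, area in peaks:
        if label == is_label:
            continue
        if area < 0:
            raise DomainError(f"negative area for {label!r}")
        amounts[label] = amounts.get(label, 0.0) + area / is_area * is_amount
    total = sum(amounts.values())
    if total <= 0:
        raise DomainError("no analyte signal besides the internal standard")
    percent = {k: 100.0 * v / total for k, v in amounts.items()}
    branched = iso = anteiso = 0.0
    for label, pct in percent.items():
        try:
            fa = parse_lipid_label(label)
        except ValueError:
            continue
        if fa.is_branched:
            branched += pct
            if fa.branching.value == "iso":
                iso += pct
            else:
                anteiso += pct
    ratio = anteiso / iso if iso > 0 else math.inf
    return ProfileSummary(
        percent=percent,
        amounts=amounts,
        branched_fraction=branched,
        anteiso_iso_ratio=ratio,
    )


def correlation_screen(
    table: pd.DataFrame, with_pvalues: bool = False, fdr: float = 0.05
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r over study-cell rows of numeric variables.

    Zero-variance columns are excluded (and logged).  With
    ``with_pvalues=True`` also returns the matrix of Benjamini–Hochberg-
    adjusted two-sided p-values (the screen itself stays descriptive).
    """
    num = table.select_dtypes(include=[np.number])
    if len(num) < 3:
        raise DomainError("correlation screen needs at least 3 rows")
    keep = [c for c in num.columns if num[c].std(ddof=0) > 0]
    dropped = sorted(set(num.columns) - set(keep))
    if dropped:
        logger.info("correlation_screen: dropped zero-variance column(s) %s", dropped)
    num = num[keep]
    corr = num.corr(method="pearson")
    if not with_pvalues:
        return corr
    cols = list(num.columns)
    pmat = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    raw = []
    pairs = []
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            _, p = pearsonr(num[a], num[b])
            raw.append(p)
            pairs.append((a, b))
    # Benjamini–Hochberg step-up adjustment
    order = np.argsort(raw)
    m = len(raw)
    adj = np.empty(m)
    prev = 1.0
    for rank, idx in list(enumerate(order))[::-1]:
        q = min(prev, raw[idx] * m / (rank + 1))
        adj[idx] = q
        prev = q
    for (a, b), q in zip(pairs, adj):
        pmat.loc[a, b] = pmat.loc[b, a] = q
    return corr, pmat


@dataclass(frozen=True)
class RateEpsModelFit:
    """One candidate growth-rate–fractionation model fit."""

    model: str                      # linear | exponential_decay | hyperbolic
    params: dict[str, float]
    rss: float
    aicc: float
    n: int
    converged: bool = True


def _aicc(rss: float, n: int, k: int) -> float:
    if n <= k + 2:
        return math.inf
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_rate_eps_models(
    mu: Sequence[float], eps: Sequence[float]
) -> list[RateEpsModelFit]:
    """Fit ε_total(μ) with linear, exponential-decay and hyperbolic models.

    Models: ε = a + b·μ; ε = ε∞ + c·exp(−k·μ); ε = ε∞ + c/(K + μ).
    Returned sorted by AICc (best first); fits within ΔAICc < 2 of the best
    are statistically indistinguishable (callers should not declare a single
    winner among them).  A model that fails to converge is flagged and
    ranked last.
    """
    mu = np.asarray(mu, dtype=float)
    eps = np.asarray(eps, dtype=float)
    if mu.size != eps.size or mu.size < 5:
        raise DomainError("rate–fractionation fit needs >= 5 (mu, eps) pairs")
    n = mu.size
    fits: list[RateEpsModelFit] = []

    # linear
    X = np.column_stack([np.ones(n), mu])
    beta, *_ = np.linalg.lstsq(X, eps, rcond=None)
    resid = eps - X @ beta
    rss = float(resid @ resid)
    fits.append(
        RateEpsModelFit(
            "linear", {"a": float(beta[0]), "b": float(beta[1])}, rss, _aicc(rss, n, 2), n
        )
    )

    span = float(eps.max() - eps.min()) or 1.0
    mu_scale = float(np.median(mu)) or 0.1

    def expo(m, eps_inf, c, k):
        return eps_inf + c * np.exp(-np.clip(k * m, -500, 500))

    def hyper(m, eps_inf, c, K):
        return eps_inf + c / (K + m)

    for name, fn, p0, bounds in (
        (
            "exponential_decay",
            expo,
            [float(eps[np.argmax(mu)]), -span, 1.0 / mu_scale],
            ([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
        ),
        (
            "hyperbolic",
            hyper,
            [float(eps[np.argmax(mu)]), -span * mu_scale, mu_scale],
            ([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
        ),
    ):
        try:
            popt, _ = curve_fit(fn, mu, eps, p0=p0, bounds=bounds, maxfev=50000)
            resid = eps - fn(mu, *popt)
            rss = float(resid @ resid)
            keys = (
                ("eps_inf", "c", "k") if name == "exponential_decay" else ("eps_inf", "c", "K")
            )
            fits.append(
                RateEpsModelFit(name, dict(zip(keys, map(float, popt))), rss, _aicc(rss, n, 3), n)
            )
        except (RuntimeError, ValueError) as exc:
            logger.warning("rate–eps model %s did not converge: %s", name, exc)
            fits.append(RateEpsModelFit(name, {}, math.inf, math.inf, n, converged=False))
    return sorted(fits, key=lambda f: f.aicc)


def primer_mass_balance(
    delta_anteiso: DeltaValue,
    delta_elong: DeltaValue,
    inventory: HydrogenInventory,
    delta_water: DeltaValue,
    basis: str = "free_acid",
) -> tuple[DeltaValue, FractionationResult, float]:
    """Isolate the δ²H of primer-derived hydrogen in a branched fatty acid.

    An anteiso chain inherits ``h_primer`` hydrogens (9, from the
    isoleucine-derived 2-methylbutyryl primer) while the remaining
    non-exchangeable hydrogens come from chain elongation.  Taking the
    measured straight-chain homolog δ as the elongation-hydrogen proxy,

        δ_primer = (n_tot·δ_anteiso − (n_tot − h_primer)·δ_elong) / h_primer

    with n_tot the non-exchangeable H of the free acid
    (``basis="free_acid"``, default for inference) or of the methyl ester
    (``basis="fame"`` — the basis under which the primer fraction of
    anteiso-C17:0 is exactly 25%).  Returns (δ_primer, ε_primer/water,
    primer fraction); recombining δ_primer and δ_elong with weights
    (h_primer, n_tot − h_primer) reproduces δ_anteiso exactly.
    """
    if inventory.h_primer <= 0:
        raise DomainError("compound has no primer hydrogen to isolate")
    if basis == "free_acid":
        n_tot = inventory.h_nonexch_acid
    elif basis == "fame":
        n_tot = inventory.h_fame
    else:
        raise DomainError(f"unknown basis {basis!r}")
    h_p = inventory.h_primer
    frac = (
        n_tot * delta_anteiso.fraction - (n_tot - h_p) * delta_elong.fraction
    ) / h_p
    sem = (
        math.hypot(
            n_tot * delta_anteiso.sem_fraction,
            (n_tot - h_p) * delta_elong.sem_fraction,
        )
        / h_p
    )
    delta_primer = DeltaValue(frac * 1000.0, reference="V-SMOW", sem=sem * 1000.0)
    eps = fractionation(delta_primer, delta_water)
    return delta_primer, eps, h_p / n_tot


def primer_fractions(inventory: HydrogenInventory) -> dict[str, float]:
    """Primer-H fraction under both denominator conventions."""
    return {
        "free_acid": inventory.h_primer / inventory.h_nonexch_acid,
        "fame": inventory.h_primer / inventory.h_fame,
    }
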