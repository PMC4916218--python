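"""Reduction of raw GC-irMS FAME δ²H to free-acid fractionations.

The chain of operations mirrors standard compound-specific isotope analysis
practice for hydrogen:

1. measured δ vs the co-injected reference ester is re-anchored to V-SMOW by
   multiplicative chaining of ratios,
2. the three methanol-derived methyl hydrogens added by derivatization are
   removed by mass balance, using a methyl δ²H calibrated from co-processed
   isotope standards of known free-acid composition,
3. repeated injections of the same extract (pseudoreplicates) are averaged
   with an instrument-precision floor on the standard error,
4. bracketing quality control discards samples not flanked by standard-mix
   injections within an RMS threshold (7‰ by default), and
5. lipid/water fractionations ε = α − 1 are formed per compound and for the
   hydrogen-weighted pool.

All chained arithmetic uses fractional δ (δ/1000); uncertainties propagate
first-order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .compounds import FattyAcid, HydrogenInventory
from .types import DeltaValue, DomainError, Injection, InjectionRole

__all__ = [
    "MethylCalibration",
    "QCRecord",
    "FractionationResult",
    "reference_to_vsmow",
    "calibrate_methyl",
    "correct_methyl",
    "forward_methyl",
    "bracketing_qc",
    "standard_mix_rms",
    "aggregate_pseudoreplicates",
    "fractionation",
    "pool_fractionation",
    "INSTRUMENT_RMS_PERMIL",
    "QC_THRESHOLD_PERMIL",
]

#: Long-term session RMS on the external 8-FAME standard mixture (‰).
INSTRUMENT_RMS_PERMIL = 5.5
#: Bracketing discard threshold (‰).
QC_THRESHOLD_PERMIL = 7.0


@dataclass(frozen=True)
class MethylCalibration:
    """δ²H of the derivatization-methanol methyl hydrogen, vs V-SMOW."""

    delta_methyl: DeltaValue
    per_standard_estimates: tuple[tuple[str, float], ...]
    spread: float  # ‰, max pairwise disagreement among standards


@dataclass(frozen=True)
class QCRecord:
    """Bracketing verdict for one sample injection."""

    injection_id: str
    rms_before: float  # ‰; inf when no preceding standard exists
    rms_after: float   # ‰; inf when no following standard exists
    passed: bool
    threshold: float = QC_THRESHOLD_PERMIL


@dataclass(frozen=True)
class FractionationResult:
    """Per-lipid fractionation vs media water."""

    fa: Optional[FattyAcid]
    delta_lipid: DeltaValue  # vs V-SMOW
    eps: float               # ‰ vs media water
    eps_sem: float           # ‰


def reference_to_vsmow(
    delta_sample_vs_ref: DeltaValue, delta_ref_vsmow: DeltaValue
) -> DeltaValue:
    """Re-anchor a δ measured against a co-injected reference to V-SMOW.

    δ_s/VSMOW = (1 + δ_s/ref)(1 + δ_ref/VSMOW) − 1, in fractional units;
    the SEM is propagated to first order.
    """
    fs, fr = delta_sample_vs_ref.fraction, delta_ref_vsmow.fraction
    out = (1.0 + fs) * (1.0 + fr) - 1.0
    sem = math.hypot(
        (1.0 + fr) * delta_sample_vs_ref.sem_fraction,
        (1.0 + fs) * delta_ref_vsmow.sem_fraction,
    )
    return DeltaValue(
        out * 1000.0, reference="V-SMOW", sem=sem * 1000.0, n=delta_sample_vs_ref.n
    )


def vsmow_to_reference(
    delta_sample_vsmow: DeltaValue, delta_ref_vsmow: DeltaValue
) -> DeltaValue:
    """Inverse of :func:`reference_to_vsmow` (exact to floating precision)."""
    fs, fr = delta_sample_vsmow.fraction, delta_ref_vsmow.fraction
    out = (1.0 + fs) / (1.0 + fr) - 1.0
    sem = math.hypot(
        delta_sample_vsmow.sem_fraction / (1.0 + fr),
        (1.0 + fs) / (1.0 + fr) ** 2 * delta_ref_vsmow.sem_fraction,
    )
    return DeltaValue(
        out * 1000.0, reference="coinjected-ref", sem=sem * 1000.0, n=delta_sample_vsmow.n
    )


def calibrate_methyl(
    standards: Sequence[tuple[str, HydrogenInventory, DeltaValue, DeltaValue]],
) -> MethylCalibration:
    """Calibrate the methyl-hydrogen δ²H from derivatized isotope standards.

    Each standard contributes an estimate
    δ_Me = (h_fame·δ_meas − h_nonexch·δ_known) / h_methyl_added
    (fractional units); estimates are combined as their unweighted mean.
    A spread above 20‰ between standards triggers a warning but does not
    fail — the disagreement is surfaced for the analyst.

    Parameters
    ----------
    standards
        Tuples of (name, inventory, known free-acid δ vs V-SMOW, measured
        derivatized δ vs V-SMOW).
    """
    if not standards:
        raise DomainError("methyl calibration requires at least one standard")
    estimates: list[tuple[str, float]] = []
    sems: list[float] = []
    for name, inv, known, measured in standards:
        if inv.h_methyl_added <= 0:
            raise DomainError(f"standard {name}: no methyl hydrogen added on derivatization")
        f_me = (
            inv.h_fame * measured.fraction - inv.h_nonexch_acid * known.fraction
        ) / inv.h_methyl_added
        sem = (
            math.hypot(inv.h_fame * measured.sem_fraction, inv.h_nonexch_acid * known.sem_fraction)
            / inv.h_methyl_added
        )
        estimates.append((name, f_me * 1000.0))
        sems.append(sem * 1000.0)
    values = np.array([v for _, v in estimates])
    mean = float(values.mean())
    spread = float(values.max() - values.min()) if len(values) > 1 else 0.0
    if spread > 20.0:
        warnings.warn(
            f"methyl-hydrogen standards disagree by {spread:.1f}‰ (>20‰)",
            stacklevel=2,
        )
    # combined SEM: larger of propagated measurement error and between-standard scatter
    k = len(values)
    sem_prop = math.sqrt(sum(s * s for s in sems)) / k
    sem_scatter = float(values.std(ddof=1)) / math.sqrt(k) if k > 1 else 0.0
    return MethylCalibration(
        delta_methyl=DeltaValue(mean, reference="V-SMOW", sem=max(sem_prop, sem_scatter), n=k),
        per_standard_estimates=tuple(estimates),
        spread=spread,
    )


def correct_methyl(
    delta_fame: DeltaValue, inventory: HydrogenInventory, cal: MethylCalibration
) -> DeltaValue:
    """Strip the derivatization methyl hydrogen from a measured FAME δ²H.

    δ_FA = (h_fame·δ_FAME − h_methyl·δ_Me) / h_nonexch, fractional units.
    """
    if inventory.h_nonexch_acid <= 0:
        raise DomainError("free acid has no non-exchangeable hydrogen")
    f = (
        inventory.h_fame * delta_fame.fraction
        - inventory.h_methyl_added * cal.delta_methyl.fraction
    ) / inventory.h_nonexch_acid
    sem = (
        math.hypot(
            inventory.h_fame * delta_fame.sem_fraction,
            inventory.h_methyl_added * cal.delta_methyl.sem_fraction,
        )
        / inventory.h_nonexch_acid
    )
    return DeltaValue(f * 1000.0, reference="V-SMOW", sem=sem * 1000.0, n=delta_fame.n)


def forward_methyl(
    delta_free_acid: DeltaValue, inventory: HydrogenInventory, delta_methyl: DeltaValue
) -> DeltaValue:
    """Forward mass balance: combine free-acid and methyl δ into the FAME δ.

    Exact inverse of :func:`correct_methyl`; also used by the synthetic-study
    generator to derive measured FAME compositions from truth.
    """
    f = (
        inventory.h_nonexch_acid * delta_free_acid.fraction
        + inventory.h_methyl_added * delta_methyl.fraction
    ) / inventory.h_fame
    return DeltaValue(f * 1000.0, reference="V-SMOW", n=delta_free_acid.n)


def standard_mix_rms(
    injection: Injection,
    known_mix: dict[str, float],
    delta_ref_vsmow: Optional[DeltaValue] = None,
) -> float:
    """RMS misfit (‰) of one standard-mix injection against known values.

    ``known_mix`` maps compound label → known δ²H (‰ vs V-SMOW).  When the
    injection carries the co-injected reference peak and ``delta_ref_vsmow``
    is given, measured values are re-anchored to V-SMOW first.
    """
    diffs = []
    for peak in injection.peaks:
        if peak.compound_label not in known_mix or peak.raw_delta is None:
            continue
        measured = peak.raw_delta
        if delta_ref_vsmow is not None and measured.reference != "V-SMOW":
            measured = reference_to_vsmow(measured, delta_ref_vsmow)
        diffs.append(measured.value - known_mix[peak.compound_label])
    if not diffs:
        return math.inf
    return float(np.sqrt(np.mean(np.square(diffs))))


def bracketing_qc(
    sequence: Sequence[Injection],
    known_mix: dict[str, float],
    threshold: float = QC_THRESHOLD_PERMIL,
    delta_ref_vsmow: Optional[DeltaValue] = None,
) -> list[QCRecord]:
    """Apply the bracketing discard rule to a run-ordered sequence.

    A sample injection passes iff its nearest preceding AND nearest following
    standard-mix injections both have RMS ≤ ``threshold`` against the known
    mix.  Samples at the sequence edges, lacking a bracket on either side,
    fail.  Decreasing the threshold can only shrink the passing set.
    """
    seq = sorted(sequence, key=lambda i: i.run_order)
    standards = [i for i in seq if i.role is InjectionRole.FAME_MIX_STANDARD]
    if not standards:
        raise DomainError("sequence contains no standard-mix injections to bracket with")
    rms_by_order = {
        i.run_order: standard_mix_rms(i, known_mix, delta_ref_vsmow) for i in standards
    }
    std_orders = sorted(rms_by_order)
    records = []
    for inj in seq:
        if inj.role is not InjectionRole.SAMPLE:
            continue
        before = [o for o in std_orders if o < inj.run_order]
        after = [o for o in std_orders if o > inj.run_order]
        rms_before = rms_by_order[before[-1]] if before else math.inf
        rms_after = rms_by_order[after[0]] if after else math.inf
        records.append(
            QCRecord(
                injection_id=inj.injection_id,
                rms_before=rms_before,
                rms_after=rms_after,
                passed=(rms_before <= threshold and rms_after <= threshold),
                threshold=threshold,
            )
        )
    return records


def session_rms(
    sequence: Sequence[Injection],
    known_mix: dict[str, float],
    delta_ref_vsmow: Optional[DeltaValue] = None,
) -> float:
    """Pooled RMS (‰) over all standard-mix injections of a sequence.

    Serves as the instrument-precision floor for pseudoreplicate SEMs; falls
    back to the long-term session value when no standards are present.
    """
    values = [
        standard_mix_rms(i, known_mix, delta_ref_vsmow)
        for i in sequence
        if i.role is InjectionRole.FAME_MIX_STANDARD
    ]
    values = [v for v in values if math.isfinite(v)]
    if not values:
        return INSTRUMENT_RMS_PERMIL
    return float(np.sqrt(np.mean(np.square(values))))


def aggregate_pseudoreplicates(
    reps: Sequence[DeltaValue], instrument_rms: float = INSTRUMENT_RMS_PERMIL
) -> DeltaValue:
    """Average repeated injections of the same extract.

    SEM = max(sd/√n, instrument RMS/√n): the scatter of a handful of
    pseudoreplicates cannot honestly undercut instrument precision, so the
    session RMS acts as a floor (identical replicates still report a
    non-zero SEM).
    """
    if not reps:
        raise DomainError("cannot aggregate an empty replicate list")
    refs = {r.reference for r in reps}
    if len(refs) > 1:
        raise DomainError(f"replicates mix reference frames: {sorted(refs)}")
    n = len(reps)
    values = np.array([r.value for r in reps])
    mean = float(values.mean())
    sd_sem = float(values.std(ddof=1)) / math.sqrt(n) if n > 1 else 0.0
    floor = instrument_rms / math.sqrt(n)
    return DeltaValue(mean, reference=reps[0].reference, sem=max(sd_sem, floor), n=n)


def fractionation(
    delta_lipid: DeltaValue, delta_water: DeltaValue, fa: Optional[FattyAcid] = None
) -> FractionationResult:
    """Apparent lipid/water fractionation ε = α − 1 with α=(1+δ_l)/(1+δ_w).

    Reported in ‰; SEM propagated first-order from both inputs.
    """
    fl, fw = delta_lipid.fraction, delta_water.fraction
    alpha = (1.0 + fl) / (1.0 + fw)
    eps = alpha - 1.0
    sem = math.hypot(
        delta_lipid.sem_fraction / (1.0 + fw),
        (1.0 + fl) / (1.0 + fw) ** 2 * delta_water.sem_fraction,
    )
    return FractionationResult(
        fa=fa, delta_lipid=delta_lipid, eps=eps * 1000.0, eps_sem=sem * 1000.0
    )


def pool_fractionation(
    items: Sequence[tuple[FattyAcid, float, Optional[DeltaValue]]],
    delta_water: DeltaValue,
    weighting: str = "hydrogen",
    common_sems: Optional[Sequence[float]] = None,
) -> tuple[DeltaValue, FractionationResult]:
    """Pool δ²H_total and ε_total of a fatty-acid mixture.

    ``weighting="hydrogen"`` (default) weights each compound by relative
    abundance × non-exchangeable H per molecule — the hydrogen-mass-balance
    reading of a "mass-weighted" pool average; ``weighting="abundance"``
    weights by relative abundance alone.  Compounds without a measured δ are
    excluded (and counted); weights are treated as exact in the SEM.

    ``common_sems`` (‰, aligned with ``items``) carries any error component
    that is fully correlated across compounds — e.g. the shared
    methyl-calibration uncertainty — which combines linearly under the pool
    weights instead of in quadrature.
    """
    from .compounds import hydrogen_inventory

    if weighting not in ("hydrogen", "abundance"):
        raise DomainError(f"unknown weighting mode {weighting!r}")
    if common_sems is not None and len(common_sems) != len(items):
        raise DomainError("common_sems must align with items")
    weights, fracs, sems, csems, ns = [], [], [], [], []
    n_excluded = 0
    for k, (fa, abundance, delta) in enumerate(items):
        if abundance < 0:
            raise DomainError("abundances must be non-negative")
        if delta is None:
            n_excluded += 1
            continue
        w = abundance
        if weighting == "hydrogen":
            w *= hydrogen_inventory(fa).h_nonexch_acid
        weights.append(w)
        fracs.append(delta.fraction)
        sems.append(delta.sem_fraction)
        csems.append(common_sems[k] / 1000.0 if common_sems is not None else 0.0)
        ns.append(delta.n)
    total_w = sum(weights)
    if total_w <= 0:
        raise DomainError("pool average undefined: all abundances zero or unmeasured")
    if n_excluded:
        import logging

        logging.getLogger("lipid2h").info(
            "pool_fractionation: excluded %d compound(s) without measured δ", n_excluded
        )
    w = np.array(weights) / total_w
    f_total = float(np.dot(w, fracs))
    sem_total = float(
        math.hypot(np.sqrt(np.dot(w**2, np.square(sems))), np.dot(w, csems))
    )
    delta_total = DeltaValue(
        f_total * 1000.0, reference="V-SMOW", sem=sem_total * 1000.0, n=min(ns)
    )
    eps_total = fractionation(delta_total, delta_water)
    return delta_total, eps_total
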