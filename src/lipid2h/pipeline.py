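"""End-to-end orchestration: reduce → growth → stats, with a run manifest.

``reduce_study`` turns the raw per-injection tables into per-cell per-lipid
free-acid δ²H, apparent fractionations and the hydrogen-weighted pool
fractionation; ``growth_table`` fits every OD curve; ``stats_tables`` runs
the study-level statistics; ``run_all`` chains everything (optionally from a
simulated study) deterministically.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as l2h_io
from .compounds import (
    COINJECTED_REFERENCE,
    STUDY_FATTY_ACIDS,
    hydrogen_inventory,
    parse_lipid_label,
    polyacid_inventory,
)
from .growth import GrowthCurve, fit_growth_curve, replicate_growth_summary
from .isotope import (
    INSTRUMENT_RMS_PERMIL,
    QC_THRESHOLD_PERMIL,
    aggregate_pseudoreplicates,
    bracketing_qc,
    calibrate_methyl,
    correct_methyl,
    fractionation,
    pool_fractionation,
    reference_to_vsmow,
    session_rms,
)
from .stats import correlation_screen, fit_rate_eps_models, primer_mass_balance
from .types import DeltaValue, DomainError, InjectionRole

CellKey = tuple[str, str, float]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and file."""


class QCEmptyError(PipelineError):
    """Bracketing QC discarded every sample injection."""


@dataclass
class ReduceResult:
    fractionation: pd.DataFrame   # per cell × compound
    eps_total: pd.DataFrame       # per cell
    profile: pd.DataFrame         # per cell × compound (% of total)
    qc: pd.DataFrame              # per sample injection
    session_rms: float            # ‰, pooled over standard-mix injections
    delta_methyl: DeltaValue      # calibrated methyl hydrogen


def _standards_lookup(standards: pd.DataFrame):
    ref_rows = standards[standards["standard_name"] == "coinjected_ref"]
    if ref_rows.empty:
        raise PipelineError("standards.csv: no coinjected_ref row")
    ref = DeltaValue(float(ref_rows.iloc[0]["known_delta_permil"]), reference="V-SMOW")
    known_mix = {
        r["compound"]: float(r["known_delta_permil"])
        for _, r in standards[standards["standard_name"] == "fame_mix"].iterrows()
    }
    methyl_std = {
        r["compound"]: (float(r["known_delta_permil"]), int(r["n_methyl_H_added"]))
        for _, r in standards[standards["standard_name"] == "methyl_standard"].iterrows()
    }
    return ref, known_mix, methyl_std


def _methyl_inventory(name: str, n_methyl: int):
    # fatty-acid standards parse directly; the phthalic diacid is special-cased
    if name == "phthalic-acid":
        return polyacid_inventory(8, 6, 2)
    if name == "myristic-acid":
        return hydrogen_inventory(parse_lipid_label("n-C14:0"))
    try:
        return hydrogen_inventory(parse_lipid_label(name))
    except ValueError:
        raise PipelineError(
            f"unknown methyl-calibration standard {name!r} (n_methyl_H={n_methyl})"
        ) from None


def reduce_study(
    peaks_path: str | Path,
    samples_path: str | Path,
    standards_path: str | Path,
    qc_threshold: float = QC_THRESHOLD_PERMIL,
    weighting: str = "hydrogen",
    out_dir: Optional[str | Path] = None,
) -> ReduceResult:
    """Full isotope reduction of one study.

    Steps: bracketing QC → methyl calibration from the co-processed isotope
    standards → per-extract pseudoreplicate aggregation → V-SMOW anchoring →
    methyl mass-balance correction → biological-replicate averaging →
    per-lipid ε and hydrogen-weighted ε_total per cell.  The shared methyl-
    calibration uncertainty is propagated as a fully correlated component.
    """
    injections, _report = l2h_io.read_peak_table(peaks_path)
    water_by_injection = l2h_io.attach_samples(injections, samples_path)
    standards = l2h_io.read_standards(standards_path)
    ref, known_mix, methyl_std = _standards_lookup(standards)

    qc_records = bracketing_qc(injections, known_mix, qc_threshold, ref)
    qc_df = pd.DataFrame(
        [
            {
                "injection_id": r.injection_id,
                "rms_before_permil": r.rms_before,
                "rms_after_permil": r.rms_after,
                "passed": r.passed,
                "threshold_permil": r.threshold,
            }
            for r in qc_records
        ]
    )
    passed_ids = {r.injection_id for r in qc_records if r.passed}
    floor = session_rms(injections, known_mix, ref)
    if floor == INSTRUMENT_RMS_PERMIL and not math.isfinite(floor):
        floor = INSTRUMENT_RMS_PERMIL

    samples = [
        inj
        for inj in injections
        if inj.role is InjectionRole.SAMPLE and inj.injection_id in passed_ids
    ]

    # --- methyl calibration from co-processed isotope standards ---
    # (session-level constant: uses every standard injection, not gated by
    # the per-sample bracketing rule)
    cal_inputs = []
    for name, (known, n_methyl) in methyl_std.items():
        reps = [
            p.raw_delta
            for inj in injections
            if inj.role is InjectionRole.SAMPLE
            for p in inj.peaks
            if p.compound_label == name and p.raw_delta is not None
        ]
        if not reps:
            continue
        agg = aggregate_pseudoreplicates(reps, instrument_rms=floor)
        measured_vsmow = reference_to_vsmow(agg, ref)
        inv = _methyl_inventory(name, n_methyl)
        cal_inputs.append((name, inv, DeltaValue(known, sem=0.0), measured_vsmow))
    if not cal_inputs:
        raise PipelineError(
            f"reduce: no methyl-calibration standard injections found in {peaks_path}"
        )
    cal = calibrate_methyl(cal_inputs)

    # --- per-cell reduction ---
    lipid_samples = [inj for inj in samples if inj.sample_link is not None]
    if not lipid_samples:
        raise QCEmptyError("reduce: every sample injection was discarded by QC")
    cells: dict[CellKey, dict] = {}
    for inj in lipid_samples:
        cell = inj.sample_link.cell_key()
        entry = cells.setdefault(cell, {"bio": {}, "water": [], "profiles": []})
        bio = entry["bio"].setdefault(inj.sample_link.bio_replicate, {})
        for p in inj.peaks:
            if p.raw_delta is None or p.compound_label == COINJECTED_REFERENCE:
                continue
            if p.compound_label not in STUDY_FATTY_ACIDS:
                continue
            bio.setdefault(p.compound_label, []).append(p.raw_delta)
        entry["water"].append(water_by_injection.get(inj.injection_id, float("nan")))
        areas = [
            (p.compound_label, p.area)
            for p in inj.peaks
            if p.compound_label in STUDY_FATTY_ACIDS
            or p.compound_label == COINJECTED_REFERENCE
        ]
        from .stats import quantify

        try:
            entry["profiles"].append(quantify(areas, (COINJECTED_REFERENCE, 1.0)))
        except DomainError:
            pass

    frac_rows, total_rows, profile_rows = [], [], []
    for (strain, donor, sulfate), entry in sorted(cells.items()):
        water = DeltaValue(float(np.nanmean(entry["water"])), reference="V-SMOW")
        # per-compound free-acid δ per biological replicate
        per_bio: dict[str, list[tuple[DeltaValue, float]]] = {}
        for bio_rep, compounds in sorted(entry["bio"].items()):
            for label, reps in compounds.items():
                agg = aggregate_pseudoreplicates(reps, instrument_rms=floor)
                vsmow = reference_to_vsmow(agg, ref)
                inv = hydrogen_inventory(parse_lipid_label(label))
                # independent (measurement) part; the shared calibration sem
                # is carried separately as a fully correlated component
                corrected = correct_methyl(vsmow, inv, _zero_sem_cal(cal))
                sem_cal = inv.h_methyl_added / inv.h_nonexch_acid * cal.delta_methyl.sem
                per_bio.setdefault(label, []).append((corrected, sem_cal))
        # average across biological replicates
        items, common_sems, compounds_out = [], [], {}
        for label, reps in sorted(per_bio.items()):
            values = np.array([r.value for r, _ in reps])
            sems = np.array([r.sem for r, _ in reps])
            nb = len(reps)
            mean = float(values.mean())
            sem_meas = float(np.sqrt(np.sum(sems**2))) / nb
            if nb > 1:
                sem_meas = max(sem_meas, float(values.std(ddof=1)) / math.sqrt(nb))
            sem_cal = float(np.mean([c for _, c in reps]))  # common across reps
            n_total = int(sum(r.n for r, _ in reps))
            delta_cell = DeltaValue(mean, reference="V-SMOW", sem=sem_meas, n=n_total)
            compounds_out[label] = (delta_cell, sem_cal)
        # abundance profile: mean of per-injection percentages
        prof_acc: dict[str, list[float]] = {}
        for prof in entry["profiles"]:
            for label, pct in prof.percent.items():
                prof_acc.setdefault(label, []).append(pct)
        percents = {k: float(np.mean(v)) for k, v in prof_acc.items()}
        total_pct = sum(percents.values())
        percents = {k: 100.0 * v / total_pct for k, v in percents.items()}

        for label, (delta_cell, sem_cal) in sorted(compounds_out.items()):
            fa = parse_lipid_label(label)
            sem_full = math.hypot(delta_cell.sem, sem_cal)
            delta_rep = DeltaValue(
                delta_cell.value, reference="V-SMOW", sem=sem_full, n=delta_cell.n
            )
            eps = fractionation(delta_rep, water, fa)
            frac_rows.append(
                {
                    "strain": strain,
                    "donor": donor,
                    "sulfate_mM": sulfate,
                    "compound": label,
                    "delta_vsmow_permil": delta_rep.value,
                    "delta_sem_permil": delta_rep.sem,
                    "eps_permil": eps.eps,
                    "eps_sem_permil": eps.eps_sem,
                    "n": delta_rep.n,
                }
            )
            items.append((fa, percents.get(label, 0.0), delta_cell))
            common_sems.append(sem_cal)
        delta_total, eps_total = pool_fractionation(
            items, water, weighting=weighting, common_sems=common_sems
        )
        total_rows.append(
            {
                "strain": strain,
                "donor": donor,
                "sulfate_mM": sulfate,
                "delta_total_permil": delta_total.value,
                "delta_total_sem_permil": delta_total.sem,
                "eps_total_permil": eps_total.eps,
                "eps_total_sem_permil": eps_total.eps_sem,
                "n_compounds": len(items),
                "water_delta_permil": water.value,
            }
        )
        for label, pct in sorted(percents.items()):
            profile_rows.append(
                {
                    "strain": strain,
                    "donor": donor,
                    "sulfate_mM": sulfate,
                    "compound": label,
                    "percent": pct,
                }
            )

    result = ReduceResult(
        fractionation=pd.DataFrame(frac_rows),
        eps_total=pd.DataFrame(total_rows),
        profile=pd.DataFrame(profile_rows),
        qc=qc_df,
        session_rms=floor,
        delta_methyl=cal.delta_methyl,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.fractionation.to_csv(out / "fractionation.csv", index=False)
        result.eps_total.to_csv(out / "eps_total.csv", index=False)
        result.profile.to_csv(out / "profiles.csv", index=False)
        result.qc.to_csv(out / "qc.csv", index=False)
    return result


def _zero_sem_cal(cal):
    from dataclasses import replace

    return replace(
        cal,
        delta_methyl=DeltaValue(
            cal.delta_methyl.value,
            reference=cal.delta_methyl.reference,
            sem=0.0,
            n=cal.delta_methyl.n,
        ),
    )


def growth_table(od_path: str | Path, out_path: Optional[str | Path] = None) -> pd.DataFrame:
    """Fit every OD curve and summarize μ_avg per cell across replicates."""
    if not Path(od_path).exists():
        raise PipelineError(f"growth: input file not found: {od_path}")
    od = l2h_io.read_od_table(od_path)
    rows = []
    for (strain, donor, sulfate), group in od.groupby(
        ["strain", "donor", "sulfate_mM"], sort=True
    ):
        curves = []
        diauxic = False
        for _, sub in group.groupby("bio_rep"):
            sub = sub.sort_values("time_h")
            curves.append(
                GrowthCurve(times=sub["time_h"].to_numpy(), od=sub["od600"].to_numpy())
            )
        mu_avg, mu_sem, fits = replicate_growth_summary(curves)
        diauxic = any(f.diauxic for f in fits)
        treatment = f"{donor}/sulfate" if sulfate > 0 else f"{donor} fermentation"
        rows.append(
            {
                "treatment": treatment,
                "strain": strain,
                "donor": donor,
                "sulfate_mM": sulfate,
                "mu_avg_per_h": mu_avg,
                "mu_sem_per_h": mu_sem if mu_sem is not None else float("nan"),
                "n_bio": len(curves),
                "diauxic": diauxic,
            }
        )
    df = pd.DataFrame(rows)
    if out_path is not None:
        df.to_csv(out_path, index=False)
    return df


def stats_tables(
    reduce_result: ReduceResult,
    growth: pd.DataFrame,
    out_dir: Optional[str | Path] = None,
) -> dict[str, pd.DataFrame]:
    """Study-level statistics over the per-cell results.

    Produces the cell × variable table (selected abundances, μ_avg,
    ε_total), the Pearson correlation screen, the ranked growth-rate–
    fractionation model fits, and the anteiso-primer mass-balance inference
    (both denominator bases) for each cell where the anteiso-C17:0 /
    straight-chain pair was measured.
    """
    keys = ["strain", "donor", "sulfate_mM"]
    prof_wide = reduce_result.profile.pivot_table(
        index=keys, columns="compound", values="percent"
    )
    table = reduce_result.eps_total.set_index(keys)[["eps_total_permil"]].join(
        growth.set_index(keys)[["mu_avg_per_h"]], how="inner"
    )
    screen_cols = ["a-C17:0", "n-C16:0", "n-C16:1 Δ9", "i-C15:0", "n-C18:0"]
    for col in screen_cols:
        if col in prof_wide.columns:
            table[f"pct {col}"] = prof_wide[col]
    table = table.reset_index()

    corr = correlation_screen(table.drop(columns=["strain", "donor"]))
    models = fit_rate_eps_models(
        table["mu_avg_per_h"].to_numpy(), table["eps_total_permil"].to_numpy()
    )
    models_df = pd.DataFrame(
        [
            {
                "model": m.model,
                "rss": m.rss,
                "aicc": m.aicc,
                "delta_aicc": m.aicc - models[0].aicc,
                "converged": m.converged,
                **{f"param_{k}": v for k, v in m.params.items()},
            }
            for m in models
        ]
    )

    # anteiso-C17:0 primer inference, straight-chain homolog as elongation proxy
    primer_rows = []
    frac = reduce_result.fractionation
    inv_a17 = hydrogen_inventory(parse_lipid_label("a-C17:0"))
    for (strain, donor, sulfate), group in frac.groupby(keys):
        g = group.set_index("compound")
        if "a-C17:0" not in g.index:
            continue
        elong_label = "n-C17:0" if "n-C17:0" in g.index else "n-C16:0"
        if elong_label not in g.index:
            continue
        water = DeltaValue(
            float(
                reduce_result.eps_total.set_index(keys).loc[
                    (strain, donor, sulfate), "water_delta_permil"
                ]
            )
        )
        d_a = DeltaValue(
            g.loc["a-C17:0", "delta_vsmow_permil"], sem=g.loc["a-C17:0", "delta_sem_permil"]
        )
        d_e = DeltaValue(
            g.loc[elong_label, "delta_vsmow_permil"],
            sem=g.loc[elong_label, "delta_sem_permil"],
        )
        for basis in ("free_acid", "fame"):
            d_primer, eps_primer, pf = primer_mass_balance(
                d_a, d_e, inv_a17, water, basis=basis
            )
            primer_rows.append(
                {
                    "strain": strain,
                    "donor": donor,
                    "sulfate_mM": sulfate,
                    "basis": basis,
                    "elongation_proxy": elong_label,
                    "delta_primer_permil": d_primer.value,
                    "delta_primer_sem_permil": d_primer.sem,
                    "eps_primer_water_permil": eps_primer.eps,
                    "primer_fraction_pct": 100.0 * pf,
                }
            )
    out_tables = {
        "cell_table": table,
        "correlations": corr.reset_index().rename(columns={"index": "variable"}),
        "rate_eps_models": models_df,
        "primer_inference": pd.DataFrame(primer_rows),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in out_tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
    return out_tables


def run_all(
    study_dir: str | Path,
    out_dir: str | Path,
    qc_threshold: float = QC_THRESHOLD_PERMIL,
    weighting: str = "hydrogen",
    seed: Optional[int] = None,
) -> dict:
    """Run reduce + growth + stats on a study directory; write a manifest.

    ``study_dir`` must hold ``peaks.csv``, ``samples.csv``, ``standards.csv``
    and ``od.csv`` (e.g. from :func:`lipid2h.simulate.generate_study`).
    Returns the manifest dict (also written as ``manifest.json``); re-running
    on identical inputs reproduces identical output checksums.
    """
    study = Path(study_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("peaks.csv", "samples.csv", "standards.csv", "od.csv"):
        if not (study / name).exists():
            raise PipelineError(f"run_all: missing input {name} in {study}")
    reduce_result = reduce_study(
        study / "peaks.csv",
        study / "samples.csv",
        study / "standards.csv",
        qc_threshold=qc_threshold,
        weighting=weighting,
        out_dir=out,
    )
    growth = growth_table(study / "od.csv", out_path=out / "growth.csv")
    stats_tables(reduce_result, growth, out_dir=out)

    def _sha(path: Path) -> str:
        return hashlib.sha256(path.read_bytes()).hexdigest()

    manifest = {
        "seed": seed,
        "qc_threshold_permil": qc_threshold,
        "weighting": weighting,
        "session_rms_permil": reduce_result.session_rms,
        "delta_methyl_permil": reduce_result.delta_methyl.value,
        "qc": {
            "n_samples": int(len(reduce_result.qc)),
            "n_passed": int(reduce_result.qc["passed"].sum()),
        },
        "inputs": {p.name: _sha(study / p.name) for p in study.glob("*.csv")},
        "outputs": {p.name: _sha(p) for p in sorted(out.glob("*.csv"))},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
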