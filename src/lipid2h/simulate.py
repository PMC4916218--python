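"""Seeded synthetic GC-irMS study generator.

Emits a complete mock study — injection sequence (samples, bracketing
standard-mix injections, an alkane ladder, co-processed methyl-calibration
standards), sample sheet, standards table, OD₆₀₀ growth curves, and a truth
table — with the statistical structure the reduction pipeline assumes:

* 15 strain × condition cells (3 strains × 5 treatments), 2 biological
  replicates each, 3–6 pseudoreplicate injections per extract;
* per-compound true δ²H generated inside study-scale envelopes
  (ε_total ∈ [−175, −55]‰, μ ∈ [0.007, 0.172] OD/h) with the observed
  isotopic ordering (C16:1 below C16:0, saturated anteiso below straight,
  iso-C18:0 on top) when ``ordering_flags`` is on;
* measured FAME δ = forward methyl mass balance of truth, re-anchored to the
  co-injected reference, plus Gaussian noise (σ = 5.5‰ by default);
* peak areas proportional to true abundances with 2% relative lognormal
  noise;
* mono-phasic logistic OD curves, two-phase (diauxic) for mutants on malate
  or fumarate.

Regeneration with the same seed is byte-identical; each output file draws
from its own RNG stream spawned from the master seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .compounds import (
    COINJECTED_REFERENCE,
    STUDY_FATTY_ACIDS,
    hydrogen_inventory,
    parse_lipid_label,
    polyacid_inventory,
)
from .growth import zwietering_od
from .isotope import forward_methyl, vsmow_to_reference
from .types import (
    DeltaValue,
    Donor,
    DomainError,
    Strain,
    STUDY_CELLS,
)

# ---------------------------------------------------------------------------
# fixed instrument-side constants of the mock study (not tunable knobs)

#: known δ²H of the co-injected C24:0 reference ester, ‰ vs V-SMOW
REF_DELTA_VSMOW = -179.3
#: known free-acid δ²H of the derivatization isotope standards, ‰ vs V-SMOW
METHYL_STANDARDS = {"myristic-acid": -231.2, "phthalic-acid": -88.3}
#: true δ²H of the derivatization-methanol methyl hydrogen, ‰ vs V-SMOW
DELTA_METHANOL = -185.0
#: the 8-component external FAME mix used for bracketing QC, ‰ vs V-SMOW
FAME_MIX = {
    "fame-mix-1": -250.4,
    "fame-mix-2": -210.5,
    "fame-mix-3": -184.9,
    "fame-mix-4": -166.7,
    "fame-mix-5": -149.1,
    "fame-mix-6": -118.3,
    "fame-mix-7": -91.4,
    "fame-mix-8": -46.8,
}
#: alkane ladder carbon numbers
LADDER_CARBONS = tuple(range(12, 27))

#: baseline relative-abundance profile (%, rough mid-exponential G20 profile)
_BASE_PROFILE = {
    "n-C14:0": 3.0,
    "i-C15:0": 8.0,
    "a-C15:0": 6.0,
    "n-C15:0": 2.0,
    "i-C16:1 Δ9": 2.0,
    "i-C16:0": 5.0,
    "n-C16:1 Δ9": 9.0,
    "n-C16:0": 17.0,
    "i-C17:1 Δ9": 3.0,
    "a-C17:1 Δ9": 4.0,
    "n-C17:1": 2.0,
    "i-C17:0": 6.0,
    "a-C17:0": 11.0,
    "n-C17:0": 2.0,
    "n-C18:1 Δ11": 6.0,
    "i-C18:1 Δ11": 2.0,
    "i-C18:0": 2.0,
    "n-C18:0": 10.0,
}
assert abs(sum(_BASE_PROFILE.values()) - 100.0) < 1e-9


def _alkane_rt(n: float) -> float:
    # 6°C/min ramp: near-linear elution vs carbon number
    return 1.85 * (n - 8.0)


def _compound_rt(label: str) -> float:
    fa = parse_lipid_label(label)
    eff = fa.n_carbon + 0.75  # methyl ester elutes later than the alkane
    if fa.branching.value == "iso":
        eff -= 0.30
    elif fa.branching.value == "anteiso":
        eff -= 0.20
    eff -= 0.15 * fa.n_double_bonds
    return round(_alkane_rt(eff), 4)


@dataclass(frozen=True)
class SimConfig:
    """Synthetic-study configuration (defaults are the study conditions)."""

    seed: int = 0
    n_bio: int = 2
    n_pseudo_min: int = 3
    n_pseudo_max: int = 6
    noise_permil: float = 5.5
    abundance_rel_noise: float = 0.02
    od_rel_noise: float = 0.0
    ordering_flags: bool = True
    eps_total_range: tuple[float, float] = (-175.0, -55.0)
    mu_range: tuple[float, float] = (0.007, 0.172)
    water_delta_base: float = -45.0
    conditions: Optional[tuple[tuple[str, str, float], ...]] = None  # None = all 15

    def cells(self) -> list[tuple[Strain, Donor, float]]:
        if self.conditions is None:
            return list(STUDY_CELLS)
        valid = {(s.value, d.value, so) for s, d, so in STUDY_CELLS}
        out = []
        for strain, donor, sulfate in self.conditions:
            if (strain, donor, float(sulfate)) not in valid:
                raise DomainError(
                    f"unknown study cell ({strain}, {donor}, {sulfate})"
                )
            out.append((Strain(strain), Donor(donor), float(sulfate)))
        return out


@dataclass
class StudyFiles:
    peaks: Path
    samples: Path
    standards: Path
    od: Path
    truth: Path

    def all(self) -> list[Path]:
        return [self.peaks, self.samples, self.standards, self.od, self.truth]


def _fmt(x: float) -> str:
    return f"{x:.10f}"


def _cell_truth(rng: np.random.Generator, cfg: SimConfig, strain, donor, sulfate):
    """Draw per-cell truth: water δ, per-compound ε/δ/abundance, growth phases."""
    water = cfg.water_delta_base + rng.uniform(-3.0, 3.0)
    center = rng.uniform(*cfg.eps_total_range)
    offsets: dict[str, float] = {}
    if cfg.ordering_flags:
        # structured offsets guaranteeing the observed ordering
        base = {label: rng.uniform(-12.0, 12.0) for label in STUDY_FATTY_ACIDS}
        base["n-C16:0"] = rng.uniform(0.0, 10.0)
        base["n-C16:1 Δ9"] = base["n-C16:0"] - rng.uniform(25.0, 45.0)
        for a_lab, n_lab in (("a-C15:0", "n-C15:0"), ("a-C17:0", "n-C17:0")):
            base[a_lab] = base[n_lab] - rng.uniform(12.0, 30.0)
        base["i-C18:0"] = max(base.values()) + rng.uniform(10.0, 25.0)
        offsets = base
    else:
        offsets = {label: rng.normal(0.0, 15.0) for label in STUDY_FATTY_ACIDS}
    eps_true = {label: center + off for label, off in offsets.items()}
    fw = water / 1000.0
    delta_true = {
        label: ((1.0 + e / 1000.0) * (1.0 + fw) - 1.0) * 1000.0
        for label, e in eps_true.items()
    }
    # abundances: Dirichlet-style jitter around the baseline profile
    raw = np.array([_BASE_PROFILE[label] for label in STUDY_FATTY_ACIDS])
    jitter = rng.lognormal(mean=0.0, sigma=0.15, size=raw.size)
    ab = raw * jitter
    ab = 100.0 * ab / ab.sum()
    abundance = dict(zip(STUDY_FATTY_ACIDS, ab))
    # growth phases
    diauxic = strain is not Strain.WILD_TYPE and donor in (Donor.MALATE, Donor.FUMARATE)
    od0 = 0.02
    if diauxic:
        mu1 = rng.uniform(*cfg.mu_range)
        mu2 = mu1 * rng.uniform(0.65, 0.95)
        A1 = rng.uniform(0.22, 0.38)
        A2 = rng.uniform(0.14, 0.28)
        lam1 = rng.uniform(3.0, 8.0)
        r1, r2 = A1 / mu1, A2 / mu2
        plateau = 0.4 * (r1 + r2) + 6.0
        lam2 = lam1 + 1.4 * r1 + plateau
        phases = [(A1, mu1, lam1), (A2, mu2, lam2)]
        t_end = lam2 + 2.2 * r2
    else:
        mu = rng.uniform(*cfg.mu_range)
        A = rng.uniform(0.5, 0.9)
        lam = rng.uniform(3.0, 8.0)
        phases = [(A, mu, lam)]
        t_end = lam + 2.4 * A / mu
    return {
        "water": water,
        "eps_true": eps_true,
        "delta_true": delta_true,
        "abundance": abundance,
        "phases": phases,
        "od0": od0,
        "t_end": t_end,
        "diauxic": diauxic,
    }


def _diauxic_od(t: np.ndarray, od0: float, phases) -> np.ndarray:
    od = np.full_like(t, od0, dtype=float)
    for A, mu, lam in phases:
        od += zwietering_od(t, 0.0, A, mu, lam)
    return od


def _measured_raw_delta(delta_fa_vsmow: float, label: str) -> float:
    """Forward model: free-acid truth → FAME → vs co-injected reference (‰)."""
    inv = hydrogen_inventory(parse_lipid_label(label))
    fame = forward_methyl(
        DeltaValue(delta_fa_vsmow),
        inv,
        DeltaValue(DELTA_METHANOL),
    )
    return vsmow_to_reference(fame, DeltaValue(REF_DELTA_VSMOW)).value


def generate_study(cfg: SimConfig, out_dir: str | Path) -> tuple[StudyFiles, pd.DataFrame]:
    """Generate all pipeline input files plus the truth table.

    Returns the file paths and the truth table (also written to
    ``truth.csv``).  Same config + seed → byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    rng_truth, rng_peaks, rng_od, rng_layout = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    cells = cfg.cells()
    truth = {
        (s.value, d.value, so): _cell_truth(rng_truth, cfg, s, d, so)
        for s, d, so in cells
    }

    peak_rows: list[dict] = []
    sample_rows: list[dict] = []
    run_order = 0

    def add_peak(inj_id, role, compound, rt, area, delta=None):
        peak_rows.append(
            {
                "injection_id": inj_id,
                "run_order": run_order,
                "role": role,
                "compound": compound,
                "rt_min": _fmt(rt),
                "area": _fmt(area),
                "delta_raw_permil": "" if delta is None else _fmt(delta),
                "delta_sem_permil": "" if delta is None else _fmt(0.0),
            }
        )

    def noise() -> float:
        return float(rng_peaks.normal(0.0, cfg.noise_permil)) if cfg.noise_permil > 0 else 0.0

    def add_fame_mix_injection():
        nonlocal run_order
        run_order += 1
        inj_id = f"mix-{run_order:04d}"
        for label, known in FAME_MIX.items():
            raw = vsmow_to_reference(
                DeltaValue(known), DeltaValue(REF_DELTA_VSMOW)
            ).value
            add_peak(
                inj_id, "fame_mix_standard", label, _alkane_rt(14 + 1.3 * int(label[-1])),
                5.0e4, raw + noise(),
            )
        add_peak(inj_id, "fame_mix_standard", COINJECTED_REFERENCE,
                 _compound_rt(COINJECTED_REFERENCE), 8.0e4, 0.0)

    # --- alkane ladder (one injection, no isotope data) ---
    run_order += 1
    for n in LADDER_CARBONS:
        add_peak("ladder-0001", "alkane_ladder", f"alkane-C{n}", _alkane_rt(n), 4.0e4)

    # --- methyl-calibration standards, derivatized alongside the samples ---
    std_inventories = {
        "myristic-acid": hydrogen_inventory(parse_lipid_label("n-C14:0")),
        "phthalic-acid": polyacid_inventory(8, 6, 2),
    }
    add_fame_mix_injection()
    since_mix = 0
    for name, known in METHYL_STANDARDS.items():
        inv = std_inventories[name]
        fame_true = forward_methyl(
            DeltaValue(known), inv, DeltaValue(DELTA_METHANOL)
        )
        raw_true = vsmow_to_reference(fame_true, DeltaValue(REF_DELTA_VSMOW)).value
        for rep in range(6):
            if since_mix >= 5:
                add_fame_mix_injection()
                since_mix = 0
            run_order += 1
            since_mix += 1
            inj_id = f"std-{name.split('-')[0]}-{rep + 1}"
            add_peak(inj_id, "sample", name, _compound_rt("n-C14:0") if name.startswith("m") else 9.8,
                     6.0e4, raw_true + noise())
            add_peak(inj_id, "sample", COINJECTED_REFERENCE,
                     _compound_rt(COINJECTED_REFERENCE), 8.0e4, 0.0 + noise())

    # --- sample injections, bracketed every <=5 by the FAME mix ---
    for strain, donor, sulfate in cells:
        cell = truth[(strain.value, donor.value, sulfate)]
        for bio in range(1, cfg.n_bio + 1):
            n_pseudo = int(rng_layout.integers(cfg.n_pseudo_min, cfg.n_pseudo_max + 1))
            for rep in range(1, n_pseudo + 1):
                if since_mix >= 5:
                    add_fame_mix_injection()
                    since_mix = 0
                run_order += 1
                since_mix += 1
                inj_id = (
                    f"s-{strain.value}-{donor.value}-{int(sulfate)}mM-b{bio}-r{rep}"
                )
                is_area = 8.0e4
                for label in STUDY_FATTY_ACIDS:
                    raw_true = _measured_raw_delta(cell["delta_true"][label], label)
                    area = (
                        cell["abundance"][label] / 100.0 * 8.0e5
                    )
                    if cfg.abundance_rel_noise > 0:
                        area *= float(
                            rng_peaks.lognormal(0.0, cfg.abundance_rel_noise)
                        )
                    add_peak(inj_id, "sample", label, _compound_rt(label), area,
                             raw_true + noise())
                add_peak(inj_id, "sample", COINJECTED_REFERENCE,
                         _compound_rt(COINJECTED_REFERENCE), is_area, 0.0 + noise())
                sample_rows.append(
                    {
                        "injection_id": inj_id,
                        "strain": strain.value,
                        "donor": donor.value,
                        "sulfate_mM": _fmt(sulfate),
                        "bio_rep": bio,
                        "water_delta_permil": _fmt(cell["water"]),
                    }
                )
    add_fame_mix_injection()

    # --- OD curves ---
    od_rows = []
    for strain, donor, sulfate in cells:
        cell = truth[(strain.value, donor.value, sulfate)]
        n_pts = 60 if cell["diauxic"] else 48
        t = np.linspace(0.0, cell["t_end"], n_pts)
        for bio in range(1, cfg.n_bio + 1):
            od = _diauxic_od(t, cell["od0"], cell["phases"])
            if cfg.od_rel_noise > 0:
                od = od * rng_od.lognormal(0.0, cfg.od_rel_noise, size=od.size)
            for ti, yi in zip(t, od):
                od_rows.append(
                    {
                        "strain": strain.value,
                        "donor": donor.value,
                        "sulfate_mM": _fmt(sulfate),
                        "bio_rep": bio,
                        "time_h": _fmt(ti),
                        "od600": _fmt(yi),
                    }
                )

    # --- standards table ---
    std_rows = [
        {
            "standard_name": "coinjected_ref",
            "compound": COINJECTED_REFERENCE,
            "known_delta_permil": _fmt(REF_DELTA_VSMOW),
            "n_methyl_H_added": 3,
        }
    ]
    for name, known in METHYL_STANDARDS.items():
        std_rows.append(
            {
                "standard_name": "methyl_standard",
                "compound": name,
                "known_delta_permil": _fmt(known),
                "n_methyl_H_added": std_inventories[name].h_methyl_added,
            }
        )
    for label, known in FAME_MIX.items():
        std_rows.append(
            {
                "standard_name": "fame_mix",
                "compound": label,
                "known_delta_permil": _fmt(known),
                "n_methyl_H_added": 3,
            }
        )
    for n in LADDER_CARBONS:
        std_rows.append(
            {
                "standard_name": "alkane_ladder",
                "compound": f"alkane-C{n}",
                "known_delta_permil": "",
                "n_methyl_H_added": 0,
            }
        )

    # --- truth table ---
    truth_rows = []
    for (strain, donor, sulfate), cell in truth.items():
        for label in STUDY_FATTY_ACIDS:
            truth_rows.append(
                {
                    "strain": strain,
                    "donor": donor,
                    "sulfate_mM": _fmt(sulfate),
                    "key": "lipid",
                    "compound": label,
                    "delta_vsmow_permil": _fmt(cell["delta_true"][label]),
                    "eps_permil": _fmt(cell["eps_true"][label]),
                    "abundance_pct": _fmt(cell["abundance"][label]),
                    "value": "",
                }
            )
        truth_rows.append(
            {
                "strain": strain, "donor": donor, "sulfate_mM": _fmt(sulfate),
                "key": "water_delta_permil", "compound": "",
                "delta_vsmow_permil": "", "eps_permil": "", "abundance_pct": "",
                "value": _fmt(cell["water"]),
            }
        )
        for k, (A, mu, lam) in enumerate(cell["phases"], start=1):
            for key, val in (("A", A), ("mu", mu), ("lambda", lam)):
                truth_rows.append(
                    {
                        "strain": strain, "donor": donor, "sulfate_mM": _fmt(sulfate),
                        "key": f"phase{k}_{key}", "compound": "",
                        "delta_vsmow_permil": "", "eps_permil": "",
                        "abundance_pct": "", "value": _fmt(val),
                    }
                )
        mu_avg = sum(A * mu for A, mu, _ in cell["phases"]) / sum(
            A for A, _, _ in cell["phases"]
        )
        truth_rows.append(
            {
                "strain": strain, "donor": donor, "sulfate_mM": _fmt(sulfate),
                "key": "mu_avg", "compound": "", "delta_vsmow_permil": "",
                "eps_permil": "", "abundance_pct": "", "value": _fmt(mu_avg),
            }
        )
    for key, val in (
        ("delta_methanol_permil", DELTA_METHANOL),
        ("ref_delta_vsmow_permil", REF_DELTA_VSMOW),
        ("noise_permil", cfg.noise_permil),
        ("seed", float(cfg.seed)),
    ):
        truth_rows.append(
            {
                "strain": "", "donor": "", "sulfate_mM": "", "key": key,
                "compound": "", "delta_vsmow_permil": "", "eps_permil": "",
                "abundance_pct": "", "value": _fmt(val),
            }
        )

    files = StudyFiles(
        peaks=out / "peaks.csv",
        samples=out / "samples.csv",
        standards=out / "standards.csv",
        od=out / "od.csv",
        truth=out / "truth.csv",
    )
    pd.DataFrame(peak_rows).to_csv(files.peaks, index=False)
    pd.DataFrame(sample_rows).to_csv(files.samples, index=False)
    pd.DataFrame(std_rows).to_csv(files.standards, index=False)
    pd.DataFrame(od_rows).to_csv(files.od, index=False)
    truth_df = pd.DataFrame(truth_rows)
    truth_df.to_csv(files.truth, index=False)
    return files, truth_df


def inject_qc_failures(
    study_dir: str | Path, fraction: float, seed: int = 0
) -> list[str]:
    """Corrupt a fraction of the standard-mix injections past the QC gate.

    Every mix peak of each chosen injection is shifted by +25‰ so its RMS
    against the known mix far exceeds the 7‰ discard threshold.  Returns the
    manifest of corrupted injection ids; ``peaks.csv`` is rewritten in place.
    """
    if not 0.0 <= fraction <= 1.0:
        raise DomainError("fraction must be within [0, 1]")
    path = Path(study_dir) / "peaks.csv"
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    mix_ids = sorted(df.loc[df["role"] == "fame_mix_standard", "injection_id"].unique())
    n_bad = int(round(fraction * len(mix_ids)))
    rng = np.random.default_rng(seed)
    bad = sorted(rng.choice(mix_ids, size=n_bad, replace=False).tolist()) if n_bad else []
    mask = df["injection_id"].isin(bad) & df["compound"].str.startswith("fame-mix-")
    df.loc[mask, "delta_raw_permil"] = df.loc[mask, "delta_raw_permil"].map(
        lambda s: _fmt(float(s) + 25.0)
    )
    df.to_csv(path, index=False)
    return bad


def file_checksums(files: Sequence[Path]) -> dict[str, str]:
    """SHA-256 checksums keyed by file name (for run manifests)."""
    return {
        Path(p).name: hashlib.sha256(Path(p).read_bytes()).hexdigest() for p in files
    }
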