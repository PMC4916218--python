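"""Isotope arithmetic: V-SMOW anchoring, methyl mass balance, QC, pooling."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lipid2h.compounds import hydrogen_inventory, parse_lipid_label
from lipid2h.isotope import (
    aggregate_pseudoreplicates,
    bracketing_qc,
    calibrate_methyl,
    correct_methyl,
    forward_methyl,
    fractionation,
    pool_fractionation,
    reference_to_vsmow,
    vsmow_to_reference,
)
from lipid2h.types import (
    DeltaValue,
    DomainError,
    Injection,
    InjectionRole,
    PeakRecord,
)

deltas = st.floats(min_value=-900.0, max_value=500.0, allow_nan=False)


# --- reference chaining ---------------------------------------------------

def test_reference_chain_identity():
    out = reference_to_vsmow(DeltaValue(0.0, "coinjected-ref"), DeltaValue(-50.0))
    assert out.value == pytest.approx(-50.0, abs=1e-12)


def test_reference_chain_worked_example():
    # (1-0.100)(1-0.050) - 1 = -0.1450
    out = reference_to_vsmow(DeltaValue(-100.0, "coinjected-ref"), DeltaValue(-50.0))
    assert out.value == pytest.approx(-145.0, abs=1e-9)


@given(x=deltas, r=deltas)
def test_reference_chain_inverse(x, r):
    ref = DeltaValue(r)
    forward = reference_to_vsmow(DeltaValue(x, "coinjected-ref"), ref)
    back = vsmow_to_reference(forward, ref)
    assert back.value == pytest.approx(x, abs=1e-9)


# --- methyl calibration / correction -------------------------------------

MYRISTIC = hydrogen_inventory(parse_lipid_label("n-C14:0"))
C16 = hydrogen_inventory(parse_lipid_label("n-C16:0"))


def test_calibrate_methyl_worked_example():
    # (30·(-250) - 27·(-230)) / 3 = -430
    cal = calibrate_methyl([("myristic", MYRISTIC, DeltaValue(-230.0), DeltaValue(-250.0))])
    assert cal.delta_methyl.value == pytest.approx(-430.0, abs=1e-9)


def test_calibrate_methyl_uniform_pool_identity():
    cal = calibrate_methyl([("m", MYRISTIC, DeltaValue(-230.0), DeltaValue(-230.0))])
    assert cal.delta_methyl.value == pytest.approx(-230.0, abs=1e-9)


def test_calibrate_methyl_combines_standards():
    # engineer two standards whose estimates are exactly -430 and -436
    meas2 = (MYRISTIC.h_nonexch_acid * (-230.0) + 3 * (-436.0)) / MYRISTIC.h_fame
    cal = calibrate_methyl(
        [
            ("s1", MYRISTIC, DeltaValue(-230.0), DeltaValue(-250.0)),
            ("s2", MYRISTIC, DeltaValue(-230.0), DeltaValue(meas2)),
        ]
    )
    assert cal.delta_methyl.value == pytest.approx(-433.0, abs=1e-9)
    assert cal.spread == pytest.approx(6.0, abs=1e-9)


def test_calibrate_methyl_warns_on_large_spread():
    meas2 = (MYRISTIC.h_nonexch_acid * (-230.0) + 3 * (-460.0)) / MYRISTIC.h_fame
    with pytest.warns(UserWarning, match="disagree"):
        calibrate_methyl(
            [
                ("s1", MYRISTIC, DeltaValue(-230.0), DeltaValue(-250.0)),
                ("s2", MYRISTIC, DeltaValue(-230.0), DeltaValue(meas2)),
            ]
        )


def test_calibrate_methyl_empty_error():
    with pytest.raises(DomainError):
        calibrate_methyl([])


def test_correct_methyl_worked_example():
    # (34·(-180) - 3·(-430)) / 31 = -155.806...
    cal = calibrate_methyl([("m", MYRISTIC, DeltaValue(-230.0), DeltaValue(-250.0))])
    out = correct_methyl(DeltaValue(-180.0), C16, cal)
    assert out.value == pytest.approx(-4830.0 / 31.0, abs=1e-9)


def test_correct_methyl_uniform_pool_identity():
    cal = calibrate_methyl([("m", MYRISTIC, DeltaValue(-180.0), DeltaValue(-180.0))])
    out = correct_methyl(DeltaValue(-180.0), C16, cal)
    assert out.value == pytest.approx(-180.0, abs=1e-9)


@given(
    d_fame=st.floats(min_value=-500.0, max_value=200.0),
    d_me=st.floats(min_value=-600.0, max_value=200.0),
)
def test_methyl_mass_balance_round_trip(d_fame, d_me):
    cal = calibrate_methyl(
        [("m", MYRISTIC, DeltaValue(d_me), forward_methyl(DeltaValue(d_me), MYRISTIC, DeltaValue(d_me)))]
    )
    assert cal.delta_methyl.value == pytest.approx(d_me, abs=1e-6)
    free = correct_methyl(DeltaValue(d_fame), C16, cal)
    try:
        back = forward_methyl(free, C16, cal.delta_methyl)
    except DomainError:
        return  # free-acid estimate outside the physical domain
    assert back.value == pytest.approx(d_fame, abs=1e-9)


# --- bracketing QC --------------------------------------------------------

KNOWN_MIX = {f"c{i}": -100.0 - 10.0 * i for i in range(8)}


def _mix_injection(order, offsets=None):
    offsets = offsets or {}
    return Injection(
        injection_id=f"mix{order}",
        run_order=order,
        role=InjectionRole.FAME_MIX_STANDARD,
        peaks=[
            PeakRecord(c, 10.0 + i, 1.0, DeltaValue(KNOWN_MIX[c] + offsets.get(c, 0.0)))
            for i, c in enumerate(KNOWN_MIX)
        ],
    )


def _sample_injection(order):
    return Injection(
        injection_id=f"s{order}",
        run_order=order,
        role=InjectionRole.SAMPLE,
        peaks=[PeakRecord("n-C16:0", 14.0, 1.0, DeltaValue(-160.0))],
    )


def test_qc_all_exact_passes():
    seq = [_mix_injection(1), _sample_injection(2), _mix_injection(3)]
    records = bracketing_qc(seq, KNOWN_MIX)
    assert [r.passed for r in records] == [True]
    assert records[0].rms_before == pytest.approx(0.0)


def test_qc_single_bad_compound_fails_neighbours():
    # one compound off by 21‰ among 8: RMS = 21/sqrt(8) ≈ 7.42 > 7
    bad = _mix_injection(3, offsets={"c0": 21.0})
    seq = [_mix_injection(1), _sample_injection(2), bad, _sample_injection(4), _mix_injection(5)]
    records = {r.injection_id: r for r in bracketing_qc(seq, KNOWN_MIX)}
    assert records["s2"].rms_after == pytest.approx(21.0 / math.sqrt(8), abs=1e-9)
    assert not records["s2"].passed
    assert not records["s4"].passed


def test_qc_unbracketed_edge_sample_fails():
    seq = [_sample_injection(1), _mix_injection(2), _sample_injection(3), _mix_injection(4)]
    records = {r.injection_id: r for r in bracketing_qc(seq, KNOWN_MIX)}
    assert not records["s1"].passed  # nothing precedes it
    assert records["s3"].passed


def test_qc_requires_standards():
    with pytest.raises(DomainError):
        bracketing_qc([_sample_injection(1)], KNOWN_MIX)


def test_qc_threshold_monotonicity():
    rng = np.random.default_rng(11)
    seq = []
    order = 0
    for block in range(6):
        order += 1
        seq.append(_mix_injection(order, offsets={c: float(rng.normal(0, 6)) for c in KNOWN_MIX}))
        for _ in range(3):
            order += 1
            seq.append(_sample_injection(order))
    order += 1
    seq.append(_mix_injection(order))
    passing = []
    for thr in (12.0, 9.0, 7.0, 5.0, 3.0, 1.0):
        records = bracketing_qc(seq, KNOWN_MIX, threshold=thr)
        passing.append({r.injection_id for r in records if r.passed})
    for larger, smaller in zip(passing, passing[1:]):
        assert smaller <= larger


# --- pseudoreplicate aggregation ------------------------------------------

def test_aggregate_single_replicate_uses_floor():
    out = aggregate_pseudoreplicates([DeltaValue(-150.0)], instrument_rms=5.5)
    assert (out.value, out.sem, out.n) == (-150.0, 5.5, 1)


def test_aggregate_three_replicates():
    reps = [DeltaValue(v) for v in (-148.0, -150.0, -152.0)]
    out = aggregate_pseudoreplicates(reps, instrument_rms=5.5)
    sd_sem = np.std([-148, -150, -152], ddof=1) / math.sqrt(3)
    assert out.value == pytest.approx(-150.0)
    assert sd_sem == pytest.approx(2.0 / math.sqrt(3), abs=1e-9)
    assert out.sem == pytest.approx(max(sd_sem, 5.5 / math.sqrt(3)), abs=1e-12)
    assert out.n == 3


def test_aggregate_identical_replicates_keeps_floor():
    reps = [DeltaValue(-150.0)] * 4
    out = aggregate_pseudoreplicates(reps, instrument_rms=5.5)
    assert out.sem == pytest.approx(5.5 / 2.0)


def test_aggregate_empty_error():
    with pytest.raises(DomainError):
        aggregate_pseudoreplicates([])


# --- fractionation ---------------------------------------------------------

def test_fractionation_identities():
    assert fractionation(DeltaValue(-80.0), DeltaValue(-80.0)).eps == pytest.approx(0.0, abs=1e-12)
    assert fractionation(DeltaValue(-200.0), DeltaValue(0.0)).eps == pytest.approx(-200.0, abs=1e-12)


def test_fractionation_worked_example():
    # 0.850/1.050 - 1 = -0.190476...
    out = fractionation(DeltaValue(-150.0), DeltaValue(50.0))
    assert out.eps == pytest.approx((0.850 / 1.050 - 1.0) * 1000.0, abs=1e-9)
    assert out.eps == pytest.approx(-190.48, abs=0.005)


@given(d1=deltas, d2=deltas, w=deltas)
def test_fractionation_monotonicity(d1, d2, w):
    lo, hi = sorted((d1, d2))
    if hi - lo < 1e-6:
        return
    water = DeltaValue(w)
    assert fractionation(DeltaValue(lo), water).eps < fractionation(DeltaValue(hi), water).eps
    # and strictly decreasing in water
    assert (
        fractionation(DeltaValue(d1), DeltaValue(lo)).eps
        > fractionation(DeltaValue(d1), DeltaValue(hi)).eps
    )


@given(x=deltas, r=deltas, w=deltas)
def test_chained_alpha_consistency(x, r, w):
    """Anchoring then fractionating equals one exact α multiplication chain."""
    eps_via_ops = fractionation(
        reference_to_vsmow(DeltaValue(x, "coinjected-ref"), DeltaValue(r)), DeltaValue(w)
    ).eps
    alpha = (1 + x / 1000.0) * (1 + r / 1000.0) / (1 + w / 1000.0)
    assert eps_via_ops == pytest.approx((alpha - 1.0) * 1000.0, abs=1e-9)


# --- pool fractionation ----------------------------------------------------

FA16 = parse_lipid_label("n-C16:0")
FA18 = parse_lipid_label("n-C18:0")
FA161 = parse_lipid_label("n-C16:1")


def test_pool_symmetric_mean():
    # equal abundance, equal H counts → arithmetic mean
    items = [(FA16, 50.0, DeltaValue(-100.0)), (FA16, 50.0, DeltaValue(-200.0))]
    delta_total, _ = pool_fractionation(items, DeltaValue(0.0))
    assert delta_total.value == pytest.approx(-150.0, abs=1e-12)


def test_pool_single_lipid():
    delta_total, eps_total = pool_fractionation(
        [(FA16, 100.0, DeltaValue(-123.4))], DeltaValue(0.0)
    )
    assert delta_total.value == pytest.approx(-123.4, abs=1e-12)
    assert eps_total.eps == pytest.approx(-123.4, abs=1e-9)


def test_pool_matches_atom_enumeration_oracle():
    """Hydrogen-weighted pooling equals explicit per-atom bookkeeping."""
    items = [
        (FA16, 50.0, DeltaValue(-100.0)),
        (FA18, 30.0, DeltaValue(-200.0)),
        (FA161, 20.0, DeltaValue(-50.0)),
    ]
    # oracle: lay out every non-exchangeable H atom of every molecule
    atoms = []
    for fa, moles, delta in items:
        h = hydrogen_inventory(fa).h_nonexch_acid
        atoms.extend([delta.value] * int(moles * h))
    expected = float(np.mean(atoms))
    delta_total, _ = pool_fractionation(items, DeltaValue(0.0), weighting="hydrogen")
    assert delta_total.value == pytest.approx(expected, abs=1e-9)


def test_pool_abundance_mode_ignores_h_counts():
    items = [(FA16, 50.0, DeltaValue(-100.0)), (FA18, 50.0, DeltaValue(-200.0))]
    delta_total, _ = pool_fractionation(items, DeltaValue(0.0), weighting="abundance")
    assert delta_total.value == pytest.approx(-150.0, abs=1e-12)


def test_pool_excludes_missing_delta_and_bounds():
    items = [
        (FA16, 60.0, DeltaValue(-100.0)),
        (FA18, 30.0, DeltaValue(-200.0)),
        (FA161, 10.0, None),
    ]
    delta_total, _ = pool_fractionation(items, DeltaValue(0.0))
    assert -200.0 <= delta_total.value <= -100.0


@given(
    ab=st.lists(st.floats(0.1, 100.0), min_size=2, max_size=6),
    ds=st.lists(deltas, min_size=6, max_size=6),
)
def test_pool_within_component_bounds(ab, ds):
    items = [(FA16, a, DeltaValue(d)) for a, d in zip(ab, ds)]
    delta_total, _ = pool_fractionation(items, DeltaValue(0.0))
    values = [d.value for _, _, d in items]
    assert min(values) - 1e-9 <= delta_total.value <= max(values) + 1e-9


def test_pool_all_zero_abundance_error():
    with pytest.raises(DomainError):
        pool_fractionation([(FA16, 0.0, DeltaValue(-100.0))], DeltaValue(0.0))
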