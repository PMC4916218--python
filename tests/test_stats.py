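"""Quantitation, Kovats indexing, correlation screen, model fits, primer inference."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lipid2h.compounds import hydrogen_inventory, parse_lipid_label, polyacid_inventory
from lipid2h.stats import (
    RetentionLadder,
    correlation_screen,
    fit_rate_eps_models,
    kovats_ri,
    primer_mass_balance,
    primer_fractions,
    quantify,
)
from lipid2h.types import DeltaValue, DomainError

IS = ("n-C24:0", 1.0)


# --- quantitation ----------------------------------------------------------

def test_quantify_equal_areas():
    prof = quantify([("n-C16:0", 100.0), ("n-C18:0", 100.0), ("n-C24:0", 50.0)], IS)
    assert prof.percent["n-C16:0"] == pytest.approx(50.0)
    assert prof.percent["n-C18:0"] == pytest.approx(50.0)


def test_quantify_ratio_identity():
    prof = quantify([("n-C16:0", 80.0), ("n-C24:0", 80.0)], IS)
    assert prof.amounts["n-C16:0"] == pytest.approx(1.0)


def test_quantify_2_1_1():
    prof = quantify(
        [("n-C16:0", 200.0), ("n-C18:0", 100.0), ("n-C14:0", 100.0), ("n-C24:0", 10.0)], IS
    )
    assert prof.percent["n-C16:0"] == pytest.approx(50.0)
    assert prof.percent["n-C18:0"] == pytest.approx(25.0)
    assert prof.percent["n-C14:0"] == pytest.approx(25.0)


def test_quantify_missing_is_error():
    with pytest.raises(DomainError):
        quantify([("n-C16:0", 100.0)], IS)


@given(scale=st.floats(0.01, 1000.0))
def test_quantify_scale_invariance(scale):
    peaks = [("n-C16:0", 150.0), ("a-C17:0", 50.0), ("n-C24:0", 30.0)]
    base = quantify(peaks, IS)
    scaled = quantify([(c, a * scale) for c, a in peaks], IS)
    for k in base.percent:
        assert scaled.percent[k] == pytest.approx(base.percent[k], rel=1e-9)


def test_quantify_branched_summaries():
    prof = quantify(
        [("i-C15:0", 100.0), ("a-C17:0", 300.0), ("n-C16:0", 600.0), ("n-C24:0", 100.0)], IS
    )
    assert prof.branched_fraction == pytest.approx(40.0)
    assert prof.anteiso_iso_ratio == pytest.approx(3.0)


# --- Kovats ----------------------------------------------------------------

LADDER = RetentionLadder(carbons=(14, 15, 16, 17), times=(10.0, 12.0, 14.5, 17.5))


def test_kovats_exact_on_rungs():
    assert kovats_ri(14.5, LADDER) == pytest.approx(1600.0)
    assert kovats_ri(10.0, LADDER) == pytest.approx(1400.0)
    assert kovats_ri(17.5, LADDER) == pytest.approx(1700.0)


def test_kovats_midpoint():
    assert kovats_ri(16.0, LADDER) == pytest.approx(1650.0)


def test_kovats_worked_example():
    ladder = RetentionLadder(carbons=(14, 15), times=(10.0, 12.0))
    assert kovats_ri(11.5, ladder) == pytest.approx(1475.0)


def test_kovats_out_of_span():
    with pytest.raises(DomainError):
        kovats_ri(9.0, LADDER)
    with pytest.raises(DomainError):
        kovats_ri(18.0, LADDER)


@given(st.floats(10.0, 17.5))
def test_kovats_strictly_increasing(rt):
    eps = 0.01
    if rt + eps <= 17.5:
        assert kovats_ri(rt + eps, LADDER) > kovats_ri(rt, LADDER)


def test_ladder_validation():
    with pytest.raises(DomainError):
        RetentionLadder(carbons=(14,), times=(10.0,))
    with pytest.raises(DomainError):
        RetentionLadder(carbons=(14, 15), times=(12.0, 10.0))


# --- correlation screen ----------------------------------------------------

def test_correlation_identities():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    df = pd.DataFrame({"x": x, "neg2x": -2 * x, "y": [1.0, 3.0, 2.0, 5.0]})
    corr = correlation_screen(df)
    assert corr.loc["x", "x"] == pytest.approx(1.0)
    assert corr.loc["x", "neg2x"] == pytest.approx(-1.0)
    # hand-computed Pearson r for x vs y: 5.5/sqrt(5*8.75)
    assert corr.loc["x", "y"] == pytest.approx(5.5 / math.sqrt(5 * 8.75), abs=1e-9)
    assert np.allclose(corr.values, corr.values.T)
    assert np.all(np.abs(corr.values) <= 1.0 + 1e-12)


def test_correlation_drops_constant_columns_and_needs_rows():
    df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "const": [5.0, 5.0, 5.0]})
    corr = correlation_screen(df)
    assert "const" not in corr.columns
    with pytest.raises(DomainError):
        correlation_screen(df.iloc[:2])


def test_correlation_pvalues_bh():
    rng = np.random.default_rng(5)
    df = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
    df["e"] = df["a"] * 2 + rng.normal(0, 1e-3, 20)
    corr, pmat = correlation_screen(df, with_pvalues=True)
    assert pmat.loc["a", "e"] < 0.05  # the engineered association survives BH
    assert np.allclose(pmat.values, pmat.values.T)


# --- growth-rate vs fractionation models -----------------------------------

def test_linear_model_self_consistency():
    mu = np.linspace(0.01, 0.17, 12)
    eps = -170.0 + 600.0 * mu
    fits = fit_rate_eps_models(mu, eps)
    assert fits[0].model == "linear"
    assert fits[0].rss == pytest.approx(0.0, abs=1e-12)


def test_exponential_recovery():
    rng = np.random.default_rng(7)
    mu = np.linspace(0.007, 0.172, 15)
    eps = -60.0 + (-120.0) * np.exp(-10.0 * mu) + rng.normal(0, 1.0, mu.size)
    fits = {f.model: f for f in fit_rate_eps_models(mu, eps)}
    f = fits["exponential_decay"]
    assert f.converged
    assert f.params["k"] == pytest.approx(10.0, rel=0.10)
    assert f.params["c"] == pytest.approx(-120.0, rel=0.10)
    assert f.params["eps_inf"] == pytest.approx(-60.0, rel=0.10)


def test_study_scale_fit_reports_all_models():
    rng = np.random.default_rng(3)
    mu = np.sort(rng.uniform(0.007, 0.172, 15))
    eps = np.interp(mu, [0.007, 0.172], [-59.0, -171.0]) + rng.normal(0, 6.0, 15)
    fits = fit_rate_eps_models(mu, eps)
    assert {f.model for f in fits} == {"linear", "exponential_decay", "hyperbolic"}
    assert all(fits[i].aicc <= fits[i + 1].aicc for i in range(len(fits) - 1))


@pytest.mark.parametrize("model", ["linear", "exponential_decay", "hyperbolic"])
def test_each_generator_model_selected_on_own_data(model):
    mu = np.linspace(0.01, 0.17, 15)
    if model == "linear":
        eps = -170.0 + 650.0 * mu
    elif model == "exponential_decay":
        eps = -60.0 - 120.0 * np.exp(-18.0 * mu)
    else:
        eps = -180.0 + 4.0 / (0.02 + mu)
    fits = fit_rate_eps_models(mu, eps)
    assert fits[0].model == model


def test_model_fit_needs_five_points():
    with pytest.raises(DomainError):
        fit_rate_eps_models([0.1, 0.2], [-100.0, -90.0])


# --- primer mass balance ----------------------------------------------------

A17 = hydrogen_inventory(parse_lipid_label("a-C17:0"))
WATER = DeltaValue(0.0)


def test_primer_fraction_fame_basis_is_25pct():
    _, _, frac = primer_mass_balance(
        DeltaValue(-200.0), DeltaValue(-170.0), A17, WATER, basis="fame"
    )
    assert frac == pytest.approx(0.25)
    both = primer_fractions(A17)
    assert both["fame"] == pytest.approx(9 / 36)
    assert both["free_acid"] == pytest.approx(9 / 33)


def test_primer_uniform_pool_identity():
    d, _, _ = primer_mass_balance(DeltaValue(-200.0), DeltaValue(-200.0), A17, WATER)
    assert d.value == pytest.approx(-200.0, abs=1e-9)


def test_primer_worked_example_free_acid():
    # (33·(-200) - 24·(-170)) / 9 = -280
    d, eps, frac = primer_mass_balance(
        DeltaValue(-200.0), DeltaValue(-170.0), A17, WATER, basis="free_acid"
    )
    assert d.value == pytest.approx(-280.0, abs=1e-9)
    assert eps.eps == pytest.approx(-280.0, abs=1e-9)  # water at 0‰
    assert frac == pytest.approx(9 / 33)


@given(da=st.floats(-250, 0), de=st.floats(-250, -50))
def test_primer_recombination_is_exact(da, de):
    d, _, _ = primer_mass_balance(DeltaValue(da), DeltaValue(de), A17, WATER)
    n_tot, h_p = A17.h_nonexch_acid, A17.h_primer
    recombined = (h_p * d.value + (n_tot - h_p) * de) / n_tot
    assert recombined == pytest.approx(da, abs=1e-9)


def test_primer_requires_primer_hydrogen():
    phthalic = polyacid_inventory(8, 6, 2)  # no biosynthetic primer
    with pytest.raises(DomainError):
        primer_mass_balance(DeltaValue(-200.0), DeltaValue(-170.0), phthalic, WATER)
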