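"""Recruitment curves, the delay-difference update, and MSY calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reservetarget.demography import (
    PopState,
    StockParams,
    beverton_holt_recruitment,
    delay_difference_step,
    equilibrium_yield,
    find_FMSY,
    ricker_recruitment,
)


@pytest.mark.parametrize("h", np.round(np.arange(0.25, 1.01, 0.05), 2).tolist())
def test_beverton_holt_steepness_identities(h):
    """R(L0) = R0 exactly, and steepness is the fraction of R0 obtained at
    20% of natural settlement."""
    sp = StockParams(s=0.6, p=0.6, h=float(h))
    assert beverton_holt_recruitment(sp.L0, sp) == pytest.approx(sp.R0, rel=1e-12)
    assert beverton_holt_recruitment(0.2 * sp.L0, sp) == pytest.approx(h * sp.R0, rel=1e-12)


def test_beverton_holt_limiting_cases():
    # h = 0.2: pure proportionality (beta = 0)
    sp = StockParams(s=0.6, p=0.6, h=0.2)
    for L in (0.1, 0.5, 1.3):
        assert beverton_holt_recruitment(L, sp) == pytest.approx(L * sp.R0 / sp.L0)
    # h = 1: recruitment independent of larval supply
    sp1 = StockParams(s=0.6, p=0.6, h=1.0)
    assert beverton_holt_recruitment(0.01, sp1) == pytest.approx(sp1.R0)
    assert beverton_holt_recruitment(3.0, sp1) == pytest.approx(sp1.R0)
    assert beverton_holt_recruitment(0.0, sp1) == 0.0


def test_recruitment_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        StockParams(s=0.6, p=0.6, h=0.15)
    sp = StockParams(s=0.6, p=0.6, h=0.7)
    with pytest.raises(ValueError):
        beverton_holt_recruitment(-0.1, sp)
    with pytest.raises(ValueError):
        StockParams(s=0.6, p=0.6, h=0.2, recruitment_form="ricker")


@given(L=st.floats(0.0, 5.0), h=st.floats(0.25, 1.0))
@settings(max_examples=60, deadline=None)
def test_beverton_holt_monotone_in_larval_supply(L, h):
    sp = StockParams(s=0.6, p=0.6, h=h)
    eps = 1e-6
    assert beverton_holt_recruitment(L + eps, sp) >= beverton_holt_recruitment(L, sp) - 1e-15


def test_ricker_as_printed():
    """Eq as printed: R(L0) = R0; R(0.2 L0) = 0.2 (5h-1) R0; beta vanishes at
    h = 0.4; overcompensation for h > 0.4."""
    sp = StockParams(s=0.6, p=0.6, h=0.7, recruitment_form="ricker")
    assert ricker_recruitment(sp.L0, sp) == pytest.approx(sp.R0, rel=1e-12)
    assert ricker_recruitment(0.2 * sp.L0, sp) == pytest.approx(
        0.2 * (5 * 0.7 - 1) * sp.R0, rel=1e-12)  # = 0.5 R0, not h R0
    sp4 = StockParams(s=0.6, p=0.6, h=0.4, recruitment_form="ricker")
    assert sp4.ricker_beta == pytest.approx(0.0, abs=1e-14)
    assert ricker_recruitment(2.5, sp4) == pytest.approx(2.5 * sp4.R0 / sp4.L0)
    # overcompensation: recruitment declines again at large larval supply
    big = ricker_recruitment(10 * sp.L0, sp)
    peak = ricker_recruitment(1.0 / sp.ricker_beta, sp)
    assert big < peak


def test_delay_difference_step_hand_calculation():
    """Single-step arithmetic oracle fixed by hand before the build."""
    sp = StockParams(s=0.7, p=0.6, h=0.7, w_L=1.0, w_Lm1=0.6)
    state = PopState(B_prev=1.0, B_prev2=1.0, R_prev=0.2, s_prev=0.7, s_prev2=0.7)
    # 0.7*1*1.6 - 0.6*0.49*1 - 0.6*0.7*0.6*0.2 + 0.2 = 0.9756
    assert delay_difference_step(state, 0.2, sp) == pytest.approx(0.9756, abs=1e-12)


def test_delay_difference_step_no_growth_limit():
    sp = StockParams(s=0.7, p=0.0, h=0.7, w_L=1.0, w_Lm1=0.0)
    state = PopState(B_prev=0.8, B_prev2=0.3, R_prev=0.5, s_prev=0.6, s_prev2=0.9)
    assert delay_difference_step(state, 0.1, sp) == pytest.approx(0.6 * 0.8 + 0.1)


def test_unfished_equilibrium_is_fixed_point(ref_stock):
    """500 years at u = 0 from B0 moves biomass by < 1e-10."""
    _, B = equilibrium_yield(ref_stock, 0.0)
    assert abs(B - ref_stock.B0) < 1e-10


def test_equilibrium_yield_boundaries(ref_stock):
    y0, B0 = equilibrium_yield(ref_stock, 0.0)
    assert y0 == 0.0 and B0 == pytest.approx(1.0)
    y99, B99 = equilibrium_yield(StockParams(s=0.6, p=0.6, h=0.5), 0.99)
    assert y99 == pytest.approx(0.0, abs=1e-9)
    assert B99 == pytest.approx(0.0, abs=1e-9)


def _forward_sim_yield(params, u, years=1000):
    """Independent long-horizon oracle: plain-python annual loop."""
    B = Bp = params.B0
    R = params.R0
    s1 = s2 = params.s
    for _ in range(years):
        survivors = max(
            s1 * (B * (1 + params.p)) - params.p * s1 * s2 * Bp
            - params.p * s1 * params.w_Lm1 * R, 0.0)
        L = params.L0 * survivors / params.S0
        R_new = params.recruitment(L)
        B_new = survivors + params.w_L * R_new
        Bp, B, R = B, B_new, R_new
        s2, s1 = s1, params.s * (1 - u)
    return u * B


@pytest.mark.parametrize("u", [0.1, 0.25, 0.4])
def test_equilibrium_yield_matches_long_forward_simulation(ref_stock, u):
    y, _ = equilibrium_yield(ref_stock, u)
    assert y == pytest.approx(_forward_sim_yield(ref_stock, u), rel=1e-6)


def test_find_fmsy_against_exhaustive_grid(ref_stock):
    """Grid + golden-section search agrees with a 0.0005-step exhaustive scan
    to within one grid step."""
    u_msy, msy = find_FMSY(ref_stock)
    grid = np.arange(0.0005, 0.9, 0.0005)
    yields = np.array([equilibrium_yield(ref_stock, float(u))[0] for u in grid])
    u_grid = grid[np.argmax(yields)]
    assert abs(u_msy - u_grid) <= 0.0005 + 1e-9
    assert msy >= yields.max() - 1e-9
    # yield at the optimum dominates a coarser grid everywhere
    coarse = np.arange(0.001, 0.999, 0.01)
    assert all(msy + 1e-9 >= equilibrium_yield(ref_stock, float(u))[0] for u in coarse)


def test_bmsy_in_recovery_target_band():
    """Equilibrium biomass at MSY sits in the 15%-50% of unfished band for
    the snapper life history."""
    from reservetarget.synthetic_data import species_preset
    stock = species_preset("snapper").stock
    u_msy, _ = find_FMSY(stock)
    _, B = equilibrium_yield(stock, u_msy)
    assert 0.15 <= B / stock.B0 <= 0.50


def test_yield_curve_unimodal_for_beverton_holt():
    """Continuity/unimodality on a sampled parameter grid: the yield curve
    rises to a single interior maximum then falls."""
    for (s, p, h) in [(0.5, 0.6, 0.6), (0.7, 0.8, 0.8), (0.3, 0.5, 0.7)]:
        sp = StockParams(s=s, p=p, h=h)
        us = np.arange(0.02, 0.99, 0.02)
        ys = np.array([equilibrium_yield(sp, float(u))[0] for u in us])
        k = int(np.argmax(ys))
        assert np.all(np.diff(ys[: k + 1]) >= -1e-9)
        assert np.all(np.diff(ys[k:]) <= 1e-9)
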