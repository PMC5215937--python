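"""Two-zone implicit simulator: mixing, concentration, and limits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import reservetarget as rt
from reservetarget._engine import (
    StockArrays,
    concentrated_rate,
    coverage_curves_batch,
    equilibrate_batch,
)
from reservetarget.implicit_sim import (
    ExchangeParams,
    ImplicitScenario,
    catch_vs_coverage,
    effective_fishing_rate,
    redistribute,
    run_implicit,
)


@given(pr=st.floats(0, 50), pf=st.floats(0, 50), x=st.floats(0, 1), C=st.floats(0, 1))
@settings(max_examples=100, deadline=None)
def test_redistribute_conserves_total(pr, pf, x, C):
    r2, f2 = redistribute(pr, pf, x, C)
    assert r2 + f2 == pytest.approx(pr + pf, abs=1e-10)
    assert r2 >= -1e-12 and f2 >= -1e-12


def test_redistribute_examples():
    assert redistribute(3.0, 7.0, 0.0, 0.4) == (3.0, 7.0)
    r, f = redistribute(6.0, 4.0, 1.0, 0.25)
    assert (r, f) == (pytest.approx(2.5), pytest.approx(7.5))
    r, f = redistribute(10.0, 0.0, 0.1, 0.5)
    assert (r, f) == (pytest.approx(9.5), pytest.approx(0.5))


def test_effective_fishing_rate_arithmetic():
    assert effective_fishing_rate(0.4, 0.5) == pytest.approx(0.8)
    assert effective_fishing_rate(0.3, 0.0) == pytest.approx(0.3)
    with pytest.warns(UserWarning):
        assert effective_fishing_rate(0.6, 0.5) == 1.0
    with pytest.raises(ValueError):
        effective_fishing_rate(0.4, 1.0)


def test_effort_conserving_concentration_properties():
    u = 0.4
    assert concentrated_rate(u, 0.0) == pytest.approx(u)
    for C in (0.2, 0.5, 0.9):
        up = concentrated_rate(u, C)
        assert u < up < 1.0
        # instantaneous-rate arithmetic: -ln(1-u') = -ln(1-u)/(1-C)
        assert -np.log(1 - up) == pytest.approx(-np.log(1 - u) / (1 - C))


def test_no_reserve_matches_single_population(ref_stock):
    scen = ImplicitScenario(stock=ref_stock, overfishing_multiple=1.3)
    res = run_implicit(scen)
    y, B = rt.equilibrium_yield(ref_stock, scen.u_base)
    assert res.catch == pytest.approx(y, rel=1e-8)
    assert res.biomass_total == pytest.approx(B, rel=1e-8)


def test_sealed_reserve_recovers_to_carrying_capacity(ref_stock):
    """With no exchange, the reserve zone returns to its share of unfished
    biomass regardless of fishing outside."""
    scen = ImplicitScenario(stock=ref_stock, exchange=ExchangeParams(0.0, 0.0),
                            overfishing_multiple=1.8, coverage=0.25)
    res = run_implicit(scen)
    assert res.biomass_reserve == pytest.approx(0.25 * ref_stock.B0, rel=1e-6)


@pytest.mark.parametrize("concentration", ["effort", "linear"])
def test_well_mixed_limit_reduces_to_single_population(ref_stock, ref_arrays, concentration):
    """d = m = 1: the two-zone system equals the closed population fished at
    the realized seascape-wide removal rate u'(1 - C)."""
    C, u0 = 0.3, 0.2
    res = equilibrate_batch(ref_arrays, np.array([u0]), np.ones(1), np.ones(1), C,
                            concentration=concentration)
    u_eq = float(concentrated_rate(u0, C, concentration)) * (1 - C)
    y, B = rt.equilibrium_yield(ref_stock, u_eq)
    assert res["catch"][0] == pytest.approx(y, rel=1e-10)
    assert res["B_r"][0] + res["B_f"][0] == pytest.approx(B, rel=1e-10)


def test_scalar_loop_matches_vectorised_engine(ref_stock, ref_arrays):
    scen = ImplicitScenario(stock=ref_stock, exchange=ExchangeParams(d=0.4, m=0.15),
                            overfishing_multiple=1.5, coverage=0.3)
    r = run_implicit(scen)
    res = equilibrate_batch(ref_arrays, np.array([scen.u_base]),
                            np.array([0.4]), np.array([0.15]), 0.3)
    assert r.catch == pytest.approx(res["catch"][0], abs=1e-10)
    assert r.biomass_reserve == pytest.approx(res["B_r"][0], abs=1e-10)


def test_catch_vs_coverage_single_point_and_baseline(ref_stock):
    scen = ImplicitScenario(stock=ref_stock, exchange=ExchangeParams(d=0.3),
                            overfishing_multiple=1.4)
    curve = catch_vs_coverage(scen, np.array([0.0]))
    base = run_implicit(ImplicitScenario(stock=ref_stock,
                                         exchange=ExchangeParams(d=0.3),
                                         overfishing_multiple=1.4,
                                         u_msy=scen.u_msy, msy=scen.msy))
    assert curve["catch"][0] == pytest.approx(base.catch, rel=1e-10)
    full = catch_vs_coverage(scen, np.round(np.arange(0, 0.51, 0.05), 2))
    assert full["catch"][0] == pytest.approx(curve["catch"][0])
    assert full["catch"].shape == (11,)


def test_sealed_heavy_overfishing_catch_non_increasing(ref_stock):
    """With no exchange, reserves only remove ground: catch declines with C."""
    scen = ImplicitScenario(stock=ref_stock, exchange=ExchangeParams(0.0, 0.0),
                            overfishing_multiple=1.8)
    curve = catch_vs_coverage(scen, np.round(np.arange(0, 0.71, 0.05), 2))
    assert np.all(np.diff(curve["catch"]) <= 1e-9)


def test_high_dispersal_heavy_overfishing_interior_optimum(ref_stock):
    scen = ImplicitScenario(stock=ref_stock, exchange=ExchangeParams(d=0.8),
                            overfishing_multiple=1.8)
    curve = catch_vs_coverage(scen)
    j = int(np.argmax(curve["catch"]))
    assert 0 < curve["coverages"][j] < 0.6
    assert curve["catch"][j] > curve["catch"][0]


def test_moderate_overfishing_mostly_delivers_pgy(rng):
    """At 1.1-1.2 x F_MSY nearly all sampled stocks still catch >= 0.8 MSY."""
    from reservetarget.synthetic_data import SamplerSpec, sample_stocks
    from reservetarget._engine import fmsy_batch

    stocks = sample_stocks(SamplerSpec(n=60), rng=rng, n=60)
    st_arr = StockArrays.from_stocks(stocks)
    u_msy, msy = fmsy_batch(st_arr)
    u = np.minimum(rng.uniform(1.1, 1.2, 60) * u_msy, 0.995)
    res = equilibrate_batch(st_arr, u, np.zeros(60), np.zeros(60), 0.0)
    assert np.mean(res["catch"] >= 0.8 * msy) >= 0.8
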