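"""Policy reference points and the scenario-grid runner."""

import numpy as np
import pandas as pd
import pytest

from reservetarget.reference_points import (
    ReferencePoints,
    _max_sustain_vec,
    _opt_rebuild_vec,
    classify_outcome,
    max_sustain_coverage,
    opt_rebuild_coverage,
    run_scenario_grid,
)
from reservetarget.synthetic_data import make_fixture_curve


def test_max_sustain_on_monotone_decline():
    """A linear decline crossing the PGY threshold at 54% coverage."""
    C, catch = make_fixture_curve("monotone", catch0=1.0, pgy=0.8, cross_at=0.54)
    got = max_sustain_coverage(C, catch, 0.8)
    assert got == pytest.approx(0.54, abs=0.011)


def test_max_sustain_undefined_when_not_initially_good():
    C, catch = make_fixture_curve("monotone", catch0=0.7, pgy=0.8, cross_at=0.5)
    assert max_sustain_coverage(C, catch, 0.8) is None


def test_max_sustain_first_crossing_ignores_recovery():
    """A dip below PGY followed by recovery: the pre-dip coverage counts, not
    the later re-crossing (checked against an exhaustive scan)."""
    C, catch = make_fixture_curve("dip_recover", catch0=1.0, pgy=0.8,
                                  dip_at=0.2, recover_at=0.4)
    got = max_sustain_coverage(C, catch, 0.8)
    # independent scan: largest C with all catch >= pgy up to C
    best = None
    for j in range(len(C)):
        if np.all(catch[: j + 1] >= 0.8):
            best = C[j]
    assert got == pytest.approx(best)
    assert got < 0.2


def test_opt_rebuild_on_unimodal_curve():
    C, catch = make_fixture_curve("unimodal", peak_at=0.30, gain=1.5)
    cov, gain = opt_rebuild_coverage(C, catch)
    assert cov == pytest.approx(0.30)
    assert gain == pytest.approx(1.5)


def test_opt_rebuild_undefined_for_declining_curve():
    C, catch = make_fixture_curve("monotone", catch0=1.0, pgy=0.8, cross_at=0.5)
    assert opt_rebuild_coverage(C, catch) is None


def test_opt_rebuild_plateau_tie_breaks_to_smallest_coverage():
    C = np.round(np.arange(0.0, 0.51, 0.01), 2)
    catch = np.full_like(C, 1.0)
    catch[(C >= 0.2) & (C <= 0.4)] = 1.3  # flat plateau
    cov, gain = opt_rebuild_coverage(C, catch)
    assert cov == pytest.approx(0.2)
    assert gain == pytest.approx(1.3)


def test_classify_outcome_partition_and_boundaries(rng):
    assert classify_outcome(1.0, 0.8, 0.8) == "green"  # boundary inclusive
    assert classify_outcome(0.7, 0.5, 0.8) == "red"
    assert classify_outcome(0.5, 0.7, 0.8) == "yellow"
    for _ in range(200):
        c0, cC, pgy = rng.uniform(0, 2, 3)
        cls = classify_outcome(c0, cC, pgy)
        assert cls in ("green", "yellow", "red")
        assert (cls == "green") == (cC >= pgy)
        if cls != "green":
            assert (cls == "red") == (cC < c0)


def test_vectorised_reference_points_match_scalar(rng):
    """The grid runner's vectorised first-crossing/argmax agree with the
    scalar operations on random curves."""
    C = np.round(np.arange(0.0, 0.96, 0.01), 2)
    curves = np.abs(rng.normal(1.0, 0.3, size=(40, C.size))).cumsum(axis=1)
    curves = curves / curves.max(axis=1, keepdims=True)
    curves = curves[:, ::-1].copy()  # roughly declining, noisy
    curves += rng.uniform(0, 0.2, size=curves.shape)
    pgy = np.full(40, 0.5)
    ms = _max_sustain_vec(curves, C, pgy)
    oc, og, defined = _opt_rebuild_vec(curves, C)
    for i in range(40):
        scalar_ms = max_sustain_coverage(C, curves[i], 0.5)
        if scalar_ms is None:
            assert np.isnan(ms[i])
        else:
            assert ms[i] == pytest.approx(scalar_ms)
        scalar_opt = opt_rebuild_coverage(C, curves[i])
        if scalar_opt is None:
            assert not defined[i]
        else:
            assert oc[i] == pytest.approx(scalar_opt[0])
            assert og[i] == pytest.approx(scalar_opt[1])


def test_reference_points_from_curve_bundle():
    C, catch = make_fixture_curve("unimodal", peak_at=0.25, gain=1.4, catch0=0.5)
    rp = ReferencePoints.from_curve(C, catch, msy=1.0, at_coverage=0.25)
    assert rp.pgy_threshold == pytest.approx(0.8)
    assert rp.opt_rebuild_coverage == pytest.approx(0.25)
    assert rp.outcome_class in ("green", "yellow", "red")


def test_single_scenario_grid_reproduces_run_implicit(ref_stock):
    """A grid restricted to one exchange cell and one stock equals the
    direct scenario run."""
    import reservetarget as rt

    grid = run_scenario_grid("moderate", n_per_cell=3, seed=5,
                             adult_categories=("N",), larval_categories=("2",),
                             coverage_grid=np.round(np.arange(0, 0.31, 0.05), 2))
    row = grid.scenarios.iloc[0]
    stock = rt.StockParams(s=row.s, p=row.p, h=row.h)
    scen = rt.ImplicitScenario(stock=stock,
                               exchange=rt.ExchangeParams(d=row.d, m=row.m),
                               overfishing_multiple=1.0)
    scen.u_msy, scen.msy = row.u_msy, row.msy
    scen.overfishing_multiple = row.u / row.u_msy
    curve = rt.catch_vs_coverage(scen, grid.coverages)
    assert np.allclose(curve["catch"], grid.curves[0], rtol=1e-10)


def test_grid_reproducible_under_seed():
    g1 = run_scenario_grid("heavy", n_per_cell=4, seed=9,
                           adult_categories=("N", "2"), larval_categories=("1",),
                           coverage_grid=np.round(np.arange(0, 0.21, 0.05), 2))
    g2 = run_scenario_grid("heavy", n_per_cell=4, seed=9,
                           adult_categories=("N", "2"), larval_categories=("1",),
                           coverage_grid=np.round(np.arange(0, 0.21, 0.05), 2))
    pd.testing.assert_frame_equal(g1.scenarios, g2.scenarios)
    assert np.array_equal(g1.curves, g2.curves)
    # summaries are plain aggregations of the per-scenario table
    pd.testing.assert_frame_equal(g1.summary(), g2.summary())


def test_grid_rejects_unknown_categories():
    with pytest.raises(ValueError):
        run_scenario_grid("mild")
    with pytest.raises(ValueError):
        run_scenario_grid("moderate", adult_categories=("X",))
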