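"""Policy reference points and scenario-grid summaries.

Two management reference points are read off each catch-vs-coverage curve:

* the maximum reserve coverage that sustains "pretty good yield" (PGY, catch
  at or above 80% of MSY) — the largest coverage C such that catch stays at or
  above the PGY threshold for every coverage up to C (first-crossing rule);
  defined only for fisheries whose pre-reserve catch already meets PGY;
* the optimum rebuilding coverage — the coverage maximising equilibrium
  catch, defined only when some positive coverage strictly beats the
  no-reserve catch (ties broken to the smallest coverage).

Fishery outcomes at a queried coverage are classified green (catch >= PGY),
yellow (reserves increased catch but below PGY) or red (reserves decreased
catch below the no-reserve level).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._engine import StockArrays, U_CAP, coverage_curves_batch, fmsy_batch
from .implicit_sim import DEFAULT_COVERAGE_GRID
from .synthetic_data import SamplerSpec, sample_stocks

__all__ = [
    "OVERFISHING_CATEGORIES",
    "EXCHANGE_CATEGORIES",
    "ReferencePoints",
    "max_sustain_coverage",
    "opt_rebuild_coverage",
    "classify_outcome",
    "ScenarioGridResult",
    "run_scenario_grid",
]

PGY_FRACTION = 0.8

# Overfishing intensity categories, in multiples of F_MSY.
OVERFISHING_CATEGORIES: dict[str, tuple[float, float]] = {
    "moderate": (1.1, 1.2),
    "considerable": (1.3, 1.5),
    "heavy": (1.6, 2.0),
}

# Exchange categories for adults (A) and larvae (L): N = no exchange,
# 1 = 10-20%, 2 = 30-50%, 3 = 60-100%.
EXCHANGE_CATEGORIES: dict[str, tuple[float, float]] = {
    "N": (0.0, 0.0),
    "1": (0.1, 0.2),
    "2": (0.3, 0.5),
    "3": (0.6, 1.0),
}


def _validate_curve(coverages, catch):
    coverages = np.asarray(coverages, dtype=float)
    catch = np.asarray(catch, dtype=float)
    if coverages.size == 0:
        raise ValueError("empty catch-vs-coverage curve")
    if coverages.shape != catch.shape:
        raise ValueError("coverages and catch must have the same shape")
    if coverages[0] != 0.0:
        raise ValueError("curve must include the no-reserve point C = 0")
    if np.any(np.diff(coverages) <= 0):
        raise ValueError("coverages must be strictly increasing")
    return coverages, catch


def max_sustain_coverage(coverages, catch, pgy_threshold: float) -> float | None:
    """Largest coverage on the grid with catch >= PGY at every coverage up to
    it (first-crossing rule); None if the fishery is not initially at PGY."""
    coverages, catch = _validate_curve(coverages, catch)
    if catch[0] < pgy_threshold:
        return None
    below = catch < pgy_threshold
    if not below.any():
        return float(coverages[-1])
    first = int(np.argmax(below))
    if first == 0:  # cannot happen given the guard, kept for clarity
        return None
    return float(coverages[first - 1])


def opt_rebuild_coverage(coverages, catch) -> tuple[float, float] | None:
    """Coverage maximising catch, with the gain relative to the pre-reserve
    catch; None unless some positive coverage strictly increases catch.
    Ties break to the smallest coverage."""
    coverages, catch = _validate_curve(coverages, catch)
    j = int(np.argmax(catch))  # argmax returns the first (smallest C) maximum
    if catch[j] <= catch[0] or coverages[j] == 0.0:
        return None
    gain = float(catch[j] / catch[0]) if catch[0] > 0 else float("inf")
    return float(coverages[j]), gain


def classify_outcome(catch_no_reserve: float, catch_at_C: float,
                     pgy_threshold: float) -> str:
    """Green if catch at the queried coverage meets PGY; red if reserves
    decreased catch; yellow if reserves increased catch but not to PGY."""
    if min(catch_no_reserve, catch_at_C, pgy_threshold) < 0:
        raise ValueError("catches and threshold must be non-negative")
    if catch_at_C >= pgy_threshold:
        return "green"
    if catch_at_C < catch_no_reserve:
        return "red"
    return "yellow"


@dataclass
class ReferencePoints:
    """Reference points of one scenario's catch-vs-coverage curve."""

    msy: float
    pgy_threshold: float
    catch_no_reserve: float
    max_sustain_coverage: float | None
    opt_rebuild_coverage: float | None
    max_catch_gain: float | None
    outcome_class: str | None = None

    @classmethod
    def from_curve(cls, coverages, catch, msy: float,
                   at_coverage: float | None = None) -> "ReferencePoints":
        coverages, catch = _validate_curve(coverages, catch)
        pgy = PGY_FRACTION * msy
        opt = opt_rebuild_coverage(coverages, catch)
        outcome = None
        if at_coverage is not None:
            j = int(np.argmin(np.abs(coverages - at_coverage)))
            outcome = classify_outcome(catch[0], catch[j], pgy)
        return cls(
            msy=msy, pgy_threshold=pgy, catch_no_reserve=float(catch[0]),
            max_sustain_coverage=max_sustain_coverage(coverages, catch, pgy),
            opt_rebuild_coverage=None if opt is None else opt[0],
            max_catch_gain=None if opt is None else opt[1],
            outcome_class=outcome,
        )


def _max_sustain_vec(curves: np.ndarray, coverages: np.ndarray,
                     pgy: np.ndarray) -> np.ndarray:
    """Vectorised first-crossing maximum-sustain coverage (NaN = undefined)."""
    below = curves < pgy[:, None]
    any_below = below.any(axis=1)
    first = np.where(any_below, np.argmax(below, axis=1), curves.shape[1])
    out = coverages[np.maximum(first - 1, 0)]
    out = np.where(first == 0, np.nan, out)        # not initially at PGY
    out = np.where(below[:, 0], np.nan, out)
    return out


def _opt_rebuild_vec(curves: np.ndarray, coverages: np.ndarray):
    """Vectorised rebuild optimum: (coverage, gain, defined)."""
    j = np.argmax(curves, axis=1)
    best = np.take_along_axis(curves, j[:, None], axis=1)[:, 0]
    catch0 = curves[:, 0]
    defined = (best > catch0) & (coverages[j] > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(catch0 > 0, best / catch0, np.inf)
    return np.where(defined, coverages[j], np.nan), np.where(defined, gain, np.nan), defined


@dataclass
class ScenarioGridResult:
    """Per-scenario records and curves of one scenario-grid run."""

    scenarios: pd.DataFrame
    curves: np.ndarray
    coverages: np.ndarray
    overfishing: str
    seed: int

    def summary(self) -> pd.DataFrame:
        """Mean +/- SD of the two reference points per (A, L) category cell,
        plus the share of scenarios initially at PGY (mirrors the layout of
        the per-category tables the curves feed)."""
        df = self.scenarios
        rows = []
        for (a_cat, l_cat), g in df.groupby(["A_cat", "L_cat"], sort=True):
            rows.append({
                "overfishing": self.overfishing,
                "A_cat": a_cat, "L_cat": l_cat, "n": len(g),
                "frac_init_pgy": g["init_pgy"].mean(),
                "max_sustain_mean": g["max_sustain"].mean(),
                "max_sustain_sd": g["max_sustain"].std(),
                "opt_rebuild_mean": g["opt_C"].mean(),
                "opt_rebuild_sd": g["opt_C"].std(),
                "frac_rebuildable": g["rebuildable"].mean(),
                "frac_collapsed_baseline": g["collapsed0"].mean(),
            })
        return pd.DataFrame(rows)

    def outcome_fractions(self, at_coverages=(0.1, 0.2, 0.3)) -> pd.DataFrame:
        """Fraction of scenarios in each outcome class at queried coverages."""
        pgy = PGY_FRACTION * self.scenarios["msy"].to_numpy()
        catch0 = self.curves[:, 0]
        rows = []
        for C in at_coverages:
            j = int(np.argmin(np.abs(self.coverages - C)))
            catchC = self.curves[:, j]
            green = catchC >= pgy
            red = ~green & (catchC < catch0)
            yellow = ~green & ~red
            rows.append({"coverage": self.coverages[j],
                         "green": green.mean(), "yellow": yellow.mean(),
                         "red": red.mean()})
        return pd.DataFrame(rows)


def run_scenario_grid(
    overfishing: str = "moderate",
    n_per_cell: int = 2000,
    seed: int = 0,
    adult_categories=("N", "1", "2", "3"),
    larval_categories=("N", "1", "2", "3"),
    coverage_grid: np.ndarray | None = None,
    sampler: SamplerSpec | None = None,
) -> ScenarioGridResult:
    """Run one overfishing category of the generic scenario grid.

    For every (adult, larval) exchange-category cell, ``n_per_cell`` stocks
    are sampled, F_MSY calibrated per stock, the overfishing multiple and the
    exchange fractions drawn uniformly within their category intervals, and
    the full catch-vs-coverage curve equilibrated.  Restricting both category
    lists to one entry and ``n_per_cell`` to 1 reproduces a single
    :func:`reservetarget.implicit_sim.run_implicit` scenario.
    """
    if overfishing not in OVERFISHING_CATEGORIES:
        raise ValueError(f"unknown overfishing category {overfishing!r}")
    for cat in tuple(adult_categories) + tuple(larval_categories):
        if cat not in EXCHANGE_CATEGORIES:
            raise ValueError(f"unknown exchange category {cat!r}")
    coverages = DEFAULT_COVERAGE_GRID if coverage_grid is None else np.asarray(
        coverage_grid, dtype=float)
    rng = np.random.default_rng(seed)

    cells = [(a, l) for a in adult_categories for l in larval_categories]
    n_total = n_per_cell * len(cells)
    spec = sampler if sampler is not None else SamplerSpec(n=n_total, seed=None)
    stocks = sample_stocks(spec, rng=rng, n=n_total)
    st = StockArrays.from_stocks(stocks)

    mult_lo, mult_hi = OVERFISHING_CATEGORIES[overfishing]
    mult = rng.uniform(mult_lo, mult_hi, size=n_total)

    a_cat = np.repeat([c[0] for c in cells], n_per_cell)
    l_cat = np.repeat([c[1] for c in cells], n_per_cell)
    d = np.empty(n_total)
    m = np.empty(n_total)
    for cat, arr in (("A", m), ("L", d)):
        labels = a_cat if cat == "A" else l_cat
        for name, (lo, hi) in EXCHANGE_CATEGORIES.items():
            sel = labels == name
            arr[sel] = 0.0 if hi == 0.0 else rng.uniform(lo, hi, size=sel.sum())

    u_msy, msy = fmsy_batch(st)
    u = np.minimum(mult * u_msy, U_CAP)
    capped = mult * u_msy > U_CAP

    res = coverage_curves_batch(st, u, d, m, coverages)
    curves = res["curves"]
    pgy = PGY_FRACTION * msy

    max_sus = _max_sustain_vec(curves, coverages, pgy)
    opt_C, opt_gain, rebuildable = _opt_rebuild_vec(curves, coverages)
    j20 = int(np.argmin(np.abs(coverages - 0.2)))
    j30 = int(np.argmin(np.abs(coverages - 0.3)))
    jmax = np.argmax(curves, axis=1)

    df = pd.DataFrame({
        "overfishing": overfishing,
        "A_cat": a_cat, "L_cat": l_cat,
        "s": st.s, "p": st.p, "h": st.h,
        "mult": mult, "u_msy": u_msy, "msy": msy, "u": u, "u_capped": capped,
        "d": d, "m": m,
        "catch0": curves[:, 0], "collapsed0": res["baseline"]["collapsed"],
        "init_pgy": curves[:, 0] >= pgy,
        "max_sustain": max_sus,
        "opt_C": opt_C, "opt_gain": opt_gain, "rebuildable": rebuildable,
        "argmax_C": coverages[jmax],
        "catch_at_20": curves[:, j20], "catch_at_30": curves[:, j30],
        "below_pgy_at_20": curves[:, j20] < pgy,
        "below_pgy_at_30": curves[:, j30] < pgy,
    })
    return ScenarioGridResult(scenarios=df, curves=curves, coverages=coverages,
                              overfishing=overfishing, seed=seed)
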