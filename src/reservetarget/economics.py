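"""Profit accounting, stock-effect profitability threshold, myopic open-access
effort dynamics, and discounting.

Profit is P = Y - E*theta (optionally with the cost term discounted at annual
rate D), with yield Y and effort cost E expressed in the same arbitrary
units.  Within the bioeconomic runs, effort is the seascape-wide annual
exploitation fraction and its cost unit is chosen so that the break-even
("stock effect") biomass density equals theta% of the unfished level: theta=1
reproduces the default fishery in which stocks are exploited until they are
effectively no longer available, while theta > 1 introduces a profitability
threshold at which fishing stops before biological collapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._engine import concentrated_rate
from .implicit_sim import ImplicitScenario, TwoZoneSystem

__all__ = ["EconParams", "profit", "open_access_step", "run_bioeconomic",
           "theta_for_biomass_threshold", "BioeconResult", "COST_COEF"]

# Cost per unit effort as a fraction of B0: break-even biomass density is
# theta * COST_COEF * B0, i.e. theta percent of unfished.
COST_COEF = 0.01


@dataclass(frozen=True)
class EconParams:
    """Socio-economic scenario parameters.

    dE_max is the maximum relative change in effort after two consecutive
    years of gains or losses (0 = constant effort); ``aggressive`` reduces
    effort only once profits are negative; ``horizon`` is the assessment
    horizon in years (long-term default 100; short-term analyses use 10).
    """

    theta: float = 1.0
    dE_max: float = 0.0
    discount_rate: float = 0.0
    aggressive: bool = False
    horizon: int = 100

    def __post_init__(self) -> None:
        if self.theta < 1.0:
            raise ValueError("theta is interpreted as >= 1 (1 = no threshold)")
        if self.dE_max < 0:
            raise ValueError("dE_max must be >= 0")
        if self.discount_rate < 0:
            raise ValueError("discount rate must be >= 0")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1 year")


def theta_for_biomass_threshold(frac_virgin_biomass: float) -> float:
    """theta such that fishing becomes unprofitable when the fished-area
    biomass density falls to the given fraction of unfished biomass."""
    if frac_virgin_biomass <= 0:
        raise ValueError("threshold fraction must be positive")
    return frac_virgin_biomass / COST_COEF


def profit(Y: float, E: float, theta: float = 1.0, D: float = 0.0,
           t: float = 0.0) -> float:
    """P = Y - E*theta / (1 + D)^t, with Y (revenue) and E (effort cost) in
    the same arbitrary units; D = 0 or t = 0 reduces to P = Y - E*theta."""
    if Y < 0 or E < 0:
        raise ValueError("yield and effort must be non-negative")
    return Y - E * theta / (1.0 + D) ** t


def open_access_step(E_t: float, P_prev: float, P_now: float, dE_max: float,
                     aggressive: bool = False) -> float:
    """Myopic open-access effort update E_{t+1} = E_t * delta.

    With both profits positive, delta is the profit ratio clamped to
    [1 - dE_max, 1 + dE_max] (profits doubling with dE_max = 1 doubles
    effort; halving halves it).  With non-positive profits the step is
    sign-based at the maximum magnitude.  In aggressive mode effort is only
    ever reduced when the current profit is negative.
    """
    if E_t < 0 or dE_max < 0:
        raise ValueError("effort and dE_max must be non-negative")
    if dE_max == 0:
        return E_t
    if P_prev > 0 and P_now > 0:
        delta = np.clip(P_now / P_prev, 1.0 - dE_max, 1.0 + dE_max)
    elif P_now <= 0:
        delta = 1.0 - dE_max
    else:  # recovery from non-positive to positive profit
        delta = 1.0 + dE_max
    if aggressive and delta < 1.0 and P_now >= 0:
        delta = 1.0
    return float(E_t * delta)


@dataclass
class BioeconResult:
    """Trajectory and horizon summary of one bioeconomic run."""

    trajectory: pd.DataFrame
    profit_at_horizon: float
    mean_profit: float
    final_effort: float
    collapsed: bool


def run_bioeconomic(scenario: ImplicitScenario, econ: EconParams,
                    perturb=None, rng: np.random.Generator | None = None) -> BioeconResult:
    """Couple the two-zone annual loop with effort dynamics and the
    stock-effect shutoff.

    Effort starts at the scenario's exploitation fraction and responds to
    profits every two years; when theta > 1 and the prospective profit is
    negative, effort is suspended for the year (fishing resumes once the
    stock has recovered above the profitability threshold).  Profits are
    reported at the configured horizon.
    """
    scenario.calibrate()
    stock = scenario.stock
    C = scenario.coverage
    # cost per unit of base effort u: break-even at a fished-zone biomass
    # density of theta% of unfished (Y/E = B_f/(1-C) at harvest)
    cost_unit = COST_COEF * stock.B0
    sys = TwoZoneSystem(stock, scenario.exchange.d, scenario.exchange.m, C,
                        perturb=perturb, rng=rng)

    E = scenario.u_base
    B_f_prev = float(sys.state.B_f[0])
    rows = []
    profits = [None, None]  # P_{t-1}, P_t for the biannual update
    for t in range(1, econ.horizon + 1):
        E = min(E, 0.995)  # cap on the seascape-wide annual rate
        # stock effect: suspend effort for the year if it cannot be profitable
        applied = E
        if econ.theta > 1.0 and E > 0:
            u_eff = float(concentrated_rate(E, C))
            prospective = u_eff * B_f_prev - E * cost_unit * econ.theta
            if prospective < 0:
                applied = 0.0
        out = sys.step(applied)
        Y = out["catch"]
        P = profit(Y, applied * cost_unit, econ.theta, econ.discount_rate, t)
        rows.append({"year": t, "B_r": out["B_r"], "B_f": out["B_f"],
                     "Y": Y, "E": applied, "P": P})
        B_f_prev = out["B_f"]
        profits = [profits[1], P]
        if econ.dE_max > 0 and t % 2 == 0 and profits[0] is not None:
            E = open_access_step(E, profits[0], profits[1], econ.dE_max,
                                 econ.aggressive)

    traj = pd.DataFrame(rows)
    collapsed = bool(traj["B_f"].iloc[-1] < 1e-6 * stock.B0 * (1.0 - C)
                     and traj["P"].iloc[-1] <= 0)
    return BioeconResult(
        trajectory=traj,
        profit_at_horizon=float(traj["P"].iloc[-1]),
        mean_profit=float(traj["P"].mean()),
        final_effort=float(traj["E"].iloc[-1]),
        collapsed=collapsed,
    )
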