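"""Two-zone (reserve vs fished) spatially implicit annual simulator.

Each year starts with a spawning event, followed by larval mixing between
zones (fraction ``d`` of each zone's larvae pooled and re-allocated
area-proportionally), settlement and recruitment with zone-wise density
dependence, the delay-difference biomass update, adult mixing (fraction
``m``), and harvest of the fished zone at a concentrated rate: total fishing
effort is constant, so closing a fraction C of the seascape intensifies
fishing in the remainder.  The default concentration rule is
effort-conserving, u' = 1 - (1 - u)^(1/(1-C)), i.e. F' = F/(1 - C) applied
to the instantaneous rate implied by the annual fraction u; the linear
first-order rule u' = u/(1 - C) (capped at total removal) is available as an
option and as the :func:`effective_fishing_rate` helper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _engine
from ._engine import (StockArrays, ZoneState, concentrated_rate,
                      equilibrate_batch, coverage_curves_batch)
from .demography import (
    COLLAPSE_FLOOR,
    EQ_CONSEC,
    EQ_MAX_YEARS,
    EQ_TOL,
    StockParams,
    find_FMSY,
)

__all__ = [
    "ExchangeParams",
    "ImplicitScenario",
    "SimResult",
    "redistribute",
    "effective_fishing_rate",
    "TwoZoneSystem",
    "run_implicit",
    "catch_vs_coverage",
    "DEFAULT_COVERAGE_GRID",
]

# 0-95% in 1% steps; C = 1 leaves no fishable area and is excluded.
DEFAULT_COVERAGE_GRID = np.round(np.arange(0.0, 0.96, 0.01), 2)

# Stochastic scenarios have no fixed point; summaries use the mean over the
# last STATIONARY_WINDOW of STOCHASTIC_YEARS years.
STOCHASTIC_YEARS = 500
STATIONARY_WINDOW = 100


@dataclass(frozen=True)
class ExchangeParams:
    """Bidirectional larval (d) and adult (m) exchange fractions across
    reserve boundaries."""

    d: float = 0.0
    m: float = 0.0

    def __post_init__(self) -> None:
        for name, val in (("d", self.d), ("m", self.m)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"exchange fraction {name} must be in [0, 1], got {val}")


@dataclass
class ImplicitScenario:
    """One spatially implicit fishery scenario.

    ``overfishing_multiple`` scales the MSY exploitation fraction; ``u_msy``
    may be supplied if F_MSY has already been calibrated for the stock,
    otherwise it is computed on first use.
    """

    stock: StockParams
    exchange: ExchangeParams = field(default_factory=ExchangeParams)
    overfishing_multiple: float = 1.0
    coverage: float = 0.0
    u_msy: float | None = None
    msy: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage < 1.0:
            raise ValueError("coverage C must be in [0, 1): C = 1 leaves no fishable area")
        if self.overfishing_multiple <= 0:
            raise ValueError("overfishing multiple must be positive")

    def calibrate(self) -> None:
        if self.u_msy is None:
            self.u_msy, self.msy = find_FMSY(self.stock)

    @property
    def u_base(self) -> float:
        """Seascape-wide annual exploitation fraction F (before effort
        concentration), capped just below total removal."""
        self.calibrate()
        return min(self.overfishing_multiple * self.u_msy, _engine.U_CAP)


@dataclass
class SimResult:
    """Equilibrium (or stationary-window) outcome of one scenario."""

    biomass_reserve: float
    biomass_fished: float
    catch: float
    recruitment_reserve: float
    recruitment_fished: float
    converged: bool
    collapsed: bool
    years: int
    u_eff: float
    u_capped: bool
    poached: float = 0.0
    trajectory: dict | None = None

    @property
    def biomass_total(self) -> float:
        return self.biomass_reserve + self.biomass_fished


def redistribute(pool_reserve: float, pool_fished: float, exchange_fraction: float,
                 C: float):
    """Pool a fraction of each zone and re-allocate with share C to the
    reserve and 1 - C to the fished zone.  Totals are conserved exactly."""
    if not 0.0 <= exchange_fraction <= 1.0:
        raise ValueError("exchange fraction must be in [0, 1]")
    if not 0.0 <= C <= 1.0:
        raise ValueError("C must be in [0, 1]")
    if np.any(np.asarray(pool_reserve) < 0) or np.any(np.asarray(pool_fished) < 0):
        raise ValueError("pools must be non-negative")
    return _engine._mix(pool_reserve, pool_fished, exchange_fraction, C)


def effective_fishing_rate(u: float, C: float) -> float:
    """Effort concentration F' = F / (1 - C), capped at total removal."""
    if not 0.0 <= u < 1.0:
        raise ValueError("u must be in [0, 1)")
    if not 0.0 <= C < 1.0:
        raise ValueError("C must be in [0, 1); C = 1 leaves no fishable area")
    u_eff = u / (1.0 - C)
    if u_eff > 1.0:
        warnings.warn(
            f"effective fishing rate {u_eff:.3f} exceeds total removal; capped at 1",
            stacklevel=2,
        )
        return 1.0
    return u_eff


class TwoZoneSystem:
    """Stepping interface to the two-zone model for one scenario.

    Used directly by the open-access economics loop and the perturbation
    machinery; :func:`run_implicit` drives it to equilibrium.  Perturbation
    hooks (recruitment stochasticity, poaching cap, pre-settlement density
    dependence) are injected by :mod:`reservetarget.perturbations`.
    """

    def __init__(self, stock: StockParams, d: float, m: float, C: float,
                 start: ZoneState | None = None, perturb=None,
                 rng: np.random.Generator | None = None,
                 concentration: str = "effort"):
        if not 0.0 <= C < 1.0:
            raise ValueError("C must be in [0, 1)")
        self.concentration = concentration
        self.stock = stock
        self.arrays = StockArrays.from_stocks([stock])
        self.d = float(d)
        self.m = float(m)
        self.C = float(C)
        self.perturb = perturb
        self.rng = rng
        self.state = start.copy() if start is not None else ZoneState.unfished(self.arrays, C)
        self.poached_total = 0.0

    def step(self, u_base: float) -> dict:
        """Advance one year at seascape-wide exploitation ``u_base``.

        Returns the year's pre-harvest zone biomasses, recruitment, catch and
        poached biomass (if the poaching cap is active).
        """
        st, state, C = self.arrays, self.state, self.C
        u_eff = float(concentrated_rate(u_base, C, self.concentration))

        # survivors of previously recruited fish spawn at the start of year
        S_r = np.maximum(state.s1_r * (
            state.B_r * (1.0 + st.p) - st.p * state.G_r
            - st.p * st.w_Lm1 * state.R_r
        ), 0.0)
        S_f = np.maximum(state.s1_f * (
            state.B_f * (1.0 + st.p) - st.p * state.G_f
            - st.p * st.w_Lm1 * state.R_f
        ), 0.0)
        L_r = (st.L0 / st.S0) * S_r
        L_f = (st.L0 / st.S0) * S_f

        pert = self.perturb
        if pert is not None and pert.presettlement_dd:
            from .perturbations import presettlement_global_stage
            L_r, L_f = presettlement_global_stage(L_r, L_f, self.stock)

        L_r, L_f = _engine._mix(L_r, L_f, self.d, C)

        if pert is not None and pert.presettlement_dd:
            from .perturbations import presettlement_local_stage
            R_r = presettlement_local_stage(L_r, self.stock, C)
            R_f = presettlement_local_stage(L_f, self.stock, 1.0 - C)
        else:
            R_r = st.recruit(L_r, C)
            R_f = st.recruit(L_f, 1.0 - C)

        if pert is not None and pert.recruit_stochasticity:
            from .perturbations import apply_recruitment_stochasticity
            R_r, R_f = apply_recruitment_stochasticity((R_r, R_f), self.rng)

        B_r = S_r + st.w_L * R_r
        B_f = S_f + st.w_L * R_f
        # adult mixing: moving fish carry their demographic memory
        G_r = state.s1_r * state.B_r
        G_f = state.s1_f * state.B_f
        B_r, B_f = _engine._mix(B_r, B_f, self.m, C)
        G_r, G_f = _engine._mix(G_r, G_f, self.m, C)
        R_r, R_f = _engine._mix(R_r, R_f, self.m, C)

        poached = 0.0
        if pert is not None and pert.poaching:
            from .perturbations import apply_poaching
            B_r, poached = apply_poaching(B_r, C * st.B0)
            self.poached_total += float(np.sum(poached))

        catch = u_eff * B_f

        self.state = ZoneState(
            B_r=B_r, B_f=B_f, G_r=G_r, G_f=G_f, R_r=R_r, R_f=R_f,
            s1_r=st.s.copy(), s1_f=st.s * (1.0 - u_eff),
        )
        return {
            "B_r": float(B_r[0]), "B_f": float(B_f[0]),
            "R_r": float(R_r[0]), "R_f": float(R_f[0]),
            "catch": float(catch[0]), "u_eff": u_eff,
            "poached": float(np.sum(poached)),
        }


def run_implicit(scenario: ImplicitScenario, record_trajectory: bool = False,
                 perturb=None, rng: np.random.Generator | None = None,
                 max_years: int = EQ_MAX_YEARS,
                 concentration: str = "effort") -> SimResult:
    """Equilibrium biomass, recruitment and catch of one implicit scenario.

    Deterministic scenarios iterate to the fixed point (relative biomass
    change < 1e-8 for 5 consecutive years); non-convergence is flagged and
    treated as collapsed.  With recruitment stochasticity switched on, the
    run uses a fixed horizon and reports stationary-window means.
    """
    scenario.calibrate()
    u_base = scenario.u_base
    u_raw = scenario.overfishing_multiple * scenario.u_msy
    C = scenario.coverage
    stochastic = perturb is not None and perturb.recruit_stochasticity

    sys = TwoZoneSystem(scenario.stock, scenario.exchange.d, scenario.exchange.m,
                        C, perturb=perturb, rng=rng, concentration=concentration)
    horizon = STOCHASTIC_YEARS if stochastic else max_years
    traj = {"B_r": [], "B_f": [], "catch": [], "R_r": [], "R_f": [], "poached": []}
    consec = 0
    total_prev = float(sys.state.B_r[0] + sys.state.B_f[0])
    converged = False
    collapsed = False
    years = horizon
    for year in range(1, horizon + 1):
        out = sys.step(u_base)
        for key in traj:
            traj[key].append(out[key])
        total = out["B_r"] + out["B_f"]
        if not stochastic:
            if total < COLLAPSE_FLOOR * scenario.stock.B0:
                converged, collapsed, years = True, True, year
                break
            rel = abs(total - total_prev) / max(total_prev, COLLAPSE_FLOOR)
            consec = consec + 1 if rel < EQ_TOL else 0
            total_prev = total
            if consec >= EQ_CONSEC:
                converged, years = True, year
                break

    arrays = {k: np.asarray(v) for k, v in traj.items()}
    if stochastic:
        window = slice(-STATIONARY_WINDOW, None)
        summary = {k: float(arrays[k][window].mean()) for k in arrays}
        converged = True
    else:
        summary = {k: float(arrays[k][-1]) for k in arrays}
        if not converged and len(arrays["B_r"]) >= 3:
            # geometric tail extrapolation per zone at the year cap
            from .demography import geometric_tail_limit
            stars = {}
            for key in ("B_r", "B_f"):
                v = arrays[key]
                stars[key] = geometric_tail_limit(
                    float(v[-1]), float(v[-1] - v[-2]), float(v[-2] - v[-3]))
            if all(v is not None for v in stars.values()) and \
                    stars["B_r"] + stars["B_f"] >= COLLAPSE_FLOOR * scenario.stock.B0:
                summary["B_r"], summary["B_f"] = stars["B_r"], stars["B_f"]
                summary["catch"] = float(
                    concentrated_rate(u_base, C, concentration)) * stars["B_f"]
                converged = True
        if collapsed or not converged:
            summary = {k: 0.0 for k in summary}
        if not converged:
            collapsed = True

    return SimResult(
        biomass_reserve=summary["B_r"], biomass_fished=summary["B_f"],
        catch=summary["catch"],
        recruitment_reserve=summary["R_r"], recruitment_fished=summary["R_f"],
        converged=converged, collapsed=collapsed, years=years,
        u_eff=float(concentrated_rate(u_base, C, concentration)),
        u_capped=u_raw / (1.0 - C) > 1.0,
        poached=summary["poached"],
        trajectory=arrays if record_trajectory else None,
    )


def catch_vs_coverage(scenario: ImplicitScenario,
                      coverage_grid: np.ndarray | None = None,
                      perturb=None, rng: np.random.Generator | None = None,
                      concentration: str = "effort"):
    """Equilibrium catch over a grid of reserve coverages for one scenario.

    Returns a dict with ``coverages``, ``catch``, ``collapsed`` and the
    scenario's calibrated MSY.  The C = 0 entry equals the no-reserve fishery.
    """
    scenario.calibrate()
    coverages = DEFAULT_COVERAGE_GRID if coverage_grid is None else np.asarray(
        coverage_grid, dtype=float)
    if coverages.size == 0:
        raise ValueError("empty coverage grid")
    if np.any(coverages < 0) or np.any(coverages > 0.99):
        raise ValueError("coverage grid must lie within [0, 0.99]")

    if perturb is None or not perturb.any_active:
        st = StockArrays.from_stocks([scenario.stock])
        res = coverage_curves_batch(
            st, np.array([scenario.u_base]),
            np.array([scenario.exchange.d]), np.array([scenario.exchange.m]),
            coverages, concentration=concentration,
        )
        return {
            "coverages": coverages,
            "catch": res["curves"][0],
            "collapsed": res["collapsed"][0],
            "msy": scenario.msy,
        }

    catch = np.empty(coverages.size)
    collapsed = np.empty(coverages.size, dtype=bool)
    for j, C in enumerate(coverages):
        scen_c = ImplicitScenario(
            stock=scenario.stock, exchange=scenario.exchange,
            overfishing_multiple=scenario.overfishing_multiple,
            coverage=float(C), u_msy=scenario.u_msy, msy=scenario.msy,
        )
        r = run_implicit(scen_c, perturb=perturb, rng=rng,
                         concentration=concentration)
        catch[j] = r.catch
        collapsed[j] = r.collapsed
    return {"coverages": coverages, "catch": catch, "collapsed": collapsed,
            "msy": scenario.msy}
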