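"""Single-population recruitment and biomass dynamics plus MSY calibration.

The population model is a Deriso-Schnute delay-difference formulation: total
biomass is updated annually from the two previous biomass states, the previous
recruitment, and the current recruitment, with adult survival ``s`` and Brody
growth coefficient ``p`` standing in for full age structure.  Density
dependence acts on the survival of larvae to recruitment age, through either a
Beverton-Holt curve parameterised by steepness ``h`` (the fraction of maximum
recruitment obtained when larval supply is 20% of its unfished level) or a
Ricker curve with overcompensation.

Harvest is an annual exploitation fraction ``u``: the catch is ``u * B`` taken
after growth, and the total survival entering the biomass update is
``s * (1 - u)``.  MSY and F_MSY are found by equilibrating the closed
single-population system over a grid of ``u`` and refining the maximum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "StockParams",
    "PopState",
    "beverton_holt_recruitment",
    "ricker_recruitment",
    "delay_difference_step",
    "equilibrium_yield",
    "find_FMSY",
    "EQ_TOL",
    "EQ_CONSEC",
    "EQ_MAX_YEARS",
    "COLLAPSE_FLOOR",
]

# Equilibrium detection: relative biomass change below EQ_TOL for EQ_CONSEC
# consecutive years, hard cap EQ_MAX_YEARS.  Biomass below COLLAPSE_FLOOR
# (relative to B0) is a collapsed (zero) equilibrium.
EQ_TOL = 1e-8
EQ_CONSEC = 5
EQ_MAX_YEARS = 500
COLLAPSE_FLOOR = 1e-12


@dataclass(frozen=True)
class StockParams:
    """Life-history and recruitment constants of one species scenario.

    Parameters
    ----------
    s : float
        Natural annual survival of adults (= 1 - natural mortality), in (0, 1).
    p : float
        Brody growth coefficient, in [0, 1).
    h : float
        Steepness, in [0.2, 1] for Beverton-Holt (0.2 is the proportional
        limit) and (0.2, 1] for Ricker.
    w_L, w_Lm1 : float
        Fixed weights of fish at and prior to recruitment.  ``w_L`` defaults
        to 1 by normalisation; ``w_Lm1`` defaults to ``0.5 * p * w_L``
        (pre-recruits weigh a growth-dependent fraction of recruits;
        calibrated so the sampled-stock ensemble reproduces the expected
        yield-curve flatness around MSY) when not given.
    B0 : float
        Unfished biomass (the single free scale, default 1).
    L0 : float
        Natural larval settlement at B0 (normalised, default 1).
    recruitment_form : str
        "beverton_holt" or "ricker".
    """

    s: float
    p: float
    h: float
    w_L: float = 1.0
    w_Lm1: float | None = None
    B0: float = 1.0
    L0: float = 1.0
    recruitment_form: str = "beverton_holt"

    def __post_init__(self) -> None:
        if not 0.0 < self.s < 1.0:
            raise ValueError(f"natural survival s must be in (0, 1), got {self.s}")
        if not 0.0 <= self.p < 1.0:
            raise ValueError(f"Brody growth p must be in [0, 1), got {self.p}")
        if self.recruitment_form not in ("beverton_holt", "ricker"):
            raise ValueError(f"unknown recruitment form {self.recruitment_form!r}")
        hmin_inclusive = self.recruitment_form == "beverton_holt"
        if (self.h < 0.2 if hmin_inclusive else self.h <= 0.2) or self.h > 1.0:
            lo = "[0.2" if hmin_inclusive else "(0.2"
            raise ValueError(f"steepness h must be in {lo}, 1], got {self.h}")
        if self.w_Lm1 is None:
            object.__setattr__(self, "w_Lm1", 0.5 * self.p * self.w_L)
        if self.w_Lm1 > self.w_L:
            raise ValueError("w_Lm1 (pre-recruitment weight) must not exceed w_L")
        if self.B0 <= 0 or self.L0 <= 0 or self.w_L <= 0:
            raise ValueError("B0, L0 and w_L must be positive")

    @property
    def R0(self) -> float:
        """Unfished recruitment: the unique value making B0 a fixed point of
        the delay-difference update at zero harvest."""
        denom = self.w_L - self.p * self.s * self.w_Lm1
        return self.B0 * (1.0 - self.s) * (1.0 - self.p * self.s) / denom

    @property
    def S0(self) -> float:
        """Unfished survivor (spawning) biomass: B0 minus the same-year
        recruit term, i.e. the biomass of previously recruited fish present at
        the start-of-year spawning event."""
        return self.B0 - self.w_L * self.R0

    @property
    def bh_beta(self) -> float:
        return (5.0 * self.h - 1.0) / (4.0 * self.h * self.R0)

    @property
    def bh_alpha(self) -> float:
        return self.L0 / self.R0 - self.bh_beta * self.L0

    @property
    def ricker_beta(self) -> float:
        if self.h <= 0.2:
            raise ValueError("Ricker recruitment requires h > 0.2")
        return math.log(5.0 * self.h - 1.0) / (0.8 * self.L0)

    @property
    def ricker_alpha(self) -> float:
        return math.log(self.R0 / self.L0) + self.ricker_beta * self.L0

    def recruitment(self, L, area: float = 1.0):
        """Recruits from larval supply ``L`` for a sub-population occupying a
        fraction ``area`` of the habitat (density dependence scales with the
        local share of carrying capacity)."""
        if self.recruitment_form == "ricker":
            return ricker_recruitment(L, self, area=area)
        return beverton_holt_recruitment(L, self, area=area)


@dataclass
class PopState:
    """Lagged state of one (sub-)population for the delay-difference update."""

    B_prev: float
    B_prev2: float
    R_prev: float
    s_prev: float
    s_prev2: float

    def __post_init__(self) -> None:
        if min(self.B_prev, self.B_prev2, self.R_prev) < 0:
            raise ValueError("biomass and recruitment must be non-negative")
        if not (0.0 <= self.s_prev <= 1.0 and 0.0 <= self.s_prev2 <= 1.0):
            raise ValueError("survivals must lie in [0, 1]")

    @classmethod
    def unfished(cls, params: StockParams, area: float = 1.0) -> "PopState":
        return cls(
            B_prev=area * params.B0,
            B_prev2=area * params.B0,
            R_prev=area * params.R0,
            s_prev=params.s,
            s_prev2=params.s,
        )


def beverton_holt_recruitment(L, params: StockParams, area: float = 1.0):
    """Beverton-Holt recruitment with steepness: R = L / (alpha + beta L).

    ``alpha = L0/R0 - beta L0`` and ``beta = (5h - 1) / (4 h R0)``, so that
    R(L0) = R0 and R(0.2 L0) = h R0.  For a sub-population holding a fraction
    ``area`` of the habitat, L0 and R0 scale with area, which leaves alpha
    unchanged and scales beta by 1/area.  ``h = 0.2`` is the proportional
    limit (beta = 0, R = L R0/L0).
    """
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("larval supply must be non-negative")
    if area < 0:
        raise ValueError("area fraction must be non-negative")
    if area == 0:
        return np.zeros_like(L) if L.ndim else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = L / (params.bh_alpha + (params.bh_beta / area) * L)
    out = np.where(L == 0, 0.0, out)  # covers the h = 1 (alpha = 0) corner
    return float(out) if out.ndim == 0 else out


def ricker_recruitment(L, params: StockParams, area: float = 1.0):
    """Ricker recruitment with overcompensation: R = L exp(alpha - beta L),
    beta = ln(5h - 1) / (0.8 L0), alpha = ln(R0/L0) + beta L0."""
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("larval supply must be non-negative")
    if area < 0:
        raise ValueError("area fraction must be non-negative")
    if area == 0:
        return np.zeros_like(L) if L.ndim else 0.0
    out = L * np.exp(params.ricker_alpha - (params.ricker_beta / area) * L)
    return float(out) if out.ndim == 0 else out


def delay_difference_step(state: PopState, R_t, params: StockParams):
    """One annual Deriso-Schnute biomass update.

    B_t = s_{t-1} B_{t-1} (1 + p) - p s_{t-1} s_{t-2} B_{t-2}
          - p s_{t-1} w_{L-1} R_{t-1} + w_L R_t, floored at zero.

    The survivals held in ``state`` already combine natural survival and
    harvest.
    """
    s1, s2 = state.s_prev, state.s_prev2
    B = (
        s1 * state.B_prev * (1.0 + params.p)
        - params.p * s1 * s2 * state.B_prev2
        - params.p * s1 * params.w_Lm1 * state.R_prev
        + params.w_L * R_t
    )
    return max(B, 0.0) if np.ndim(B) == 0 else np.maximum(B, 0.0)


def _iterate_single(params: StockParams, u: float, state: PopState | None = None,
                    max_years: int = EQ_MAX_YEARS):
    """Iterate the closed single-population system at exploitation ``u``.

    Each year the survivors of previously recruited fish spawn (larval output
    L0-scaled to the unfished survivor biomass), larvae recruit, and the
    delay-difference update adds the new recruits; catch is u * B_t taken
    after growth, entering the next year as survival s * (1 - u).

    Returns (B_star, converged, years, state).  ``B_star`` is the pre-harvest
    equilibrium biomass (catch = u * B_star).
    """
    if state is None:
        state = PopState.unfished(params)
    st = PopState(state.B_prev, state.B_prev2, state.R_prev,
                  state.s_prev, state.s_prev2)
    consec = 0
    B_prev_seen = st.B_prev
    hist = [st.B_prev] * 3  # three-year history for tail extrapolation
    for year in range(1, max_years + 1):
        survivors = st.s_prev * (
            st.B_prev * (1.0 + params.p)
            - params.p * st.s_prev2 * st.B_prev2
            - params.p * params.w_Lm1 * st.R_prev
        )
        survivors = max(survivors, 0.0)
        L = params.L0 * survivors / params.S0
        R = params.recruitment(L)
        B = max(survivors + params.w_L * R, 0.0)
        s_tot = params.s * (1.0 - u)
        st = PopState(B, st.B_prev, R, s_tot, st.s_prev)
        if B < COLLAPSE_FLOOR * params.B0:
            return 0.0, True, year, st
        rel = abs(B - B_prev_seen) / max(B_prev_seen, COLLAPSE_FLOOR)
        consec = consec + 1 if rel < EQ_TOL else 0
        B_prev_seen = B
        hist = [hist[1], hist[2], B]
        if consec >= EQ_CONSEC:
            return B, True, year, st
    B_star = geometric_tail_limit(hist[2], hist[2] - hist[1], hist[1] - hist[0])
    if B_star is not None and B_star >= COLLAPSE_FLOOR * params.B0:
        return B_star, True, max_years, st
    return B_prev_seen, False, max_years, st


def geometric_tail_limit(current: float, d_cur: float, d_prev: float) -> float | None:
    """Closed-form limit of a geometrically contracting sequence
    (Aitken extrapolation); None when the tail is not contracting."""
    if d_prev == 0.0:
        return current
    lam = d_cur / d_prev
    if abs(lam) >= 0.99995:
        return None
    star = current + d_cur * lam / (1.0 - lam)
    if not np.isfinite(star) or star < 0:
        return None
    return float(star)


def equilibrium_yield(params: StockParams, u: float) -> tuple[float, float]:
    """Equilibrium catch and biomass of the closed population fished at
    annual exploitation fraction ``u``.

    Iterates spawn -> recruit -> delay-difference step -> harvest u*B to
    equilibrium from the unfished state.  A run that does not converge within
    the year cap is treated as collapsed (yield 0).
    """
    if not 0.0 <= u < 1.0:
        raise ValueError(f"harvest fraction u must be in [0, 1), got {u}")
    B, converged, _, _ = _iterate_single(params, u)
    if not converged:
        warnings.warn("equilibrium not reached within year cap; treated as collapsed")
        return 0.0, 0.0
    return u * B, B


def find_FMSY(params: StockParams, coarse_step: float = 0.005) -> tuple[float, float]:
    """Exploitation fraction maximising equilibrium yield, and the MSY.

    Grid scan over u in (0, 1) followed by bounded golden-section refinement
    of the (unimodal, for Beverton-Holt recruitment) yield curve.
    """
    grid = np.arange(coarse_step, 1.0, coarse_step)
    yields = np.array([equilibrium_yield(params, float(u))[0] for u in grid])
    if not np.any(yields > 0):
        raise ValueError("yield curve is identically zero: degenerate parameters")
    i = int(np.argmax(yields))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda u: -equilibrium_yield(params, float(u))[0],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-5},
    )
    u_msy = float(res.x)
    msy = float(-res.fun)
    if msy <= 0:
        raise ValueError("no positive yield found: degenerate parameters")
    return u_msy, msy
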