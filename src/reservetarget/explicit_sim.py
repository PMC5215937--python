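"""Spatially explicit annual simulator on the 1-D seascape grid.

Per-cell demography follows the same delay-difference dynamics as the
implicit model; larvae and adults are redistributed by Gaussian kernels (or
arbitrary connectivity matrices), and a fleet of mobile fishers allocates a
constant total effort over fished cells.  Local effort compounds the
baseline annual harvest rate (u_i = 1 - (1 - u0)^e_i, with e_i the effort in
cell i relative to the uniform no-reserve baseline), so one effort unit per
cell on the homogeneous seascape harvests exactly u0 and concentration never
reaches total removal — the spatial counterpart of the implicit model's
effort-conserving concentration rule.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .demography import (
    COLLAPSE_FLOOR,
    EQ_CONSEC,
    EQ_MAX_YEARS,
    EQ_TOL,
    StockParams,
    find_FMSY,
)
from ._engine import U_CAP as _U_CAP
from .implicit_sim import STATIONARY_WINDOW, STOCHASTIC_YEARS
from .spatial_structure import (
    KernelSpec,
    ReserveNetworkSpec,
    Seascape,
    build_kernel,
    generate_reserve_network,
)

__all__ = ["ExplicitScenario", "ExplicitResult", "distribute_fishers", "run_explicit"]


@dataclass
class ExplicitScenario:
    """One spatially explicit fishery scenario.

    ``larval_kernel`` and ``adult_kernel`` may be :class:`KernelSpec` objects
    (discretised on the seascape) or pre-built redistribution matrices (rows =
    source cells); ``adult_kernel`` may be None for sedentary adults.  The
    reserve network is either a spec (drawn at run time) or an explicit mask.
    ``overfishing_multiple`` scales the baseline total effort, which is
    normalised so one effort unit per cell delivers MSY on the homogeneous
    no-reserve seascape.
    """

    stock: StockParams
    seascape: Seascape
    larval_kernel: KernelSpec | np.ndarray
    adult_kernel: KernelSpec | np.ndarray | None = None
    network: ReserveNetworkSpec | None = None
    reserve_mask: np.ndarray | None = None
    overfishing_multiple: float = 1.0
    fisher_movement: float = 0.0
    u_msy: float | None = None
    msy: float | None = None
    boundary: str = "reflecting"

    def __post_init__(self) -> None:
        if self.overfishing_multiple <= 0:
            raise ValueError("overfishing multiple must be positive")
        if self.fisher_movement < 0:
            raise ValueError("fisher movement parameter must be >= 0")
        if self.network is not None and self.reserve_mask is not None:
            raise ValueError("give either a network spec or an explicit mask, not both")

    def calibrate(self) -> None:
        """F_MSY on the homogeneous no-reserve seascape (identical to the
        closed single-population calibration)."""
        if self.u_msy is None:
            self.u_msy, self.msy = find_FMSY(self.stock)

    def kernel_matrix(self, which: str) -> np.ndarray:
        spec = self.larval_kernel if which == "larval" else self.adult_kernel
        if spec is None:
            return np.eye(self.seascape.n_cells)
        if isinstance(spec, np.ndarray):
            if spec.shape != (self.seascape.n_cells,) * 2:
                raise ValueError("connectivity matrix shape must match the seascape")
            return spec
        return build_kernel(spec, self.seascape, boundary=self.boundary)


@dataclass
class ExplicitResult:
    """Per-cell equilibrium outcome for a batch of reserve networks.

    Cell-indexed arrays have shape (n_networks, n_cells); totals have shape
    (n_networks,).
    """

    biomass: np.ndarray
    catch: np.ndarray
    effort: np.ndarray
    recruitment: np.ndarray
    reserve_masks: np.ndarray
    converged: np.ndarray
    collapsed: np.ndarray
    years: np.ndarray
    total_catch: np.ndarray
    total_biomass: np.ndarray
    poached: np.ndarray


def distribute_fishers(biomass: np.ndarray, reserve_mask: np.ndarray,
                       omega: float, total_effort: float) -> np.ndarray:
    """Allocate constant total effort over fished cells with a gravity weight.

    Effort in cell i is proportional to B_i ** omega over fished cells:
    omega = 0 gives uniform effort, omega = 1 the ideal free distribution
    (catch per unit effort spatially uniform at equilibrium), larger omega an
    increasing concentration on the highest-biomass cells (the edges of
    reserves).  Total effort is conserved exactly.
    """
    biomass = np.atleast_2d(np.asarray(biomass, dtype=float))
    reserve_mask = np.atleast_2d(np.asarray(reserve_mask, dtype=bool))
    fished = ~reserve_mask
    if not fished.any(axis=1).all():
        raise ValueError("no fishable cells")
    if omega == 0:
        w = fished.astype(float)
    else:
        w = np.where(fished, np.maximum(biomass, 0.0) ** omega, 0.0)
    wsum = w.sum(axis=1, keepdims=True)
    degenerate = wsum[:, 0] == 0.0
    if degenerate.any():
        warnings.warn("all fished cells at zero biomass; uniform effort fallback",
                      stacklevel=2)
        w[degenerate] = fished[degenerate].astype(float)
        wsum = w.sum(axis=1, keepdims=True)
    return total_effort * w / wsum


def run_explicit(scenario: ExplicitScenario, n_networks: int = 1,
                 rng: np.random.Generator | None = None,
                 perturb=None, max_years: int = EQ_MAX_YEARS,
                 start_biomass: np.ndarray | None = None) -> ExplicitResult:
    """Equilibrium per-cell biomass, catch and effort for a batch of networks.

    The annual loop per cell: spawn proportional to local biomass, larval
    kernel redistribution, recruitment against the local carrying capacity
    B0,i, delay-difference update, adult kernel redistribution, effort
    allocation over fished cells and harvest.  All ``n_networks`` random
    networks (or the single given mask) run in lock-step.
    """
    scenario.calibrate()
    sea = scenario.seascape
    stock = scenario.stock
    n = sea.n_cells

    if scenario.reserve_mask is not None:
        masks = np.atleast_2d(np.asarray(scenario.reserve_mask, dtype=bool))
        if masks.shape[0] == 1 and n_networks > 1:
            masks = np.repeat(masks, n_networks, axis=0)
    elif scenario.network is not None:
        if rng is None:
            rng = np.random.default_rng()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            masks = np.array([
                generate_reserve_network(scenario.network, sea, rng)
                for _ in range(n_networks)
            ])
    else:
        masks = np.zeros((n_networks, n), dtype=bool)
    k = masks.shape[0]

    K_l = scenario.kernel_matrix("larval")
    K_a = scenario.kernel_matrix("adult")

    q = sea.habitat_quality  # local carrying-capacity multipliers
    B0_cell = stock.B0 * q
    R0_cell = stock.R0 * q
    alpha = stock.ricker_alpha if stock.recruitment_form == "ricker" else stock.bh_alpha
    beta = stock.ricker_beta if stock.recruitment_form == "ricker" else stock.bh_beta
    spawn_scale = stock.L0 / stock.S0  # unfished survivors produce L0
    # one effort unit per cell on the homogeneous no-reserve seascape
    # harvests exactly u0 = overfishing_multiple * u_MSY; local effort
    # compounds that rate (constant total effort, never total removal)
    u0 = min(scenario.overfishing_multiple * scenario.u_msy, _U_CAP)
    total_effort = float(n)

    # state arrays (k, n): start from the unfished (or supplied) field;
    # G = s_prev * B_prev is the survival-weighted biomass memory of the
    # delay-difference update (moves with the fish under the adult kernel)
    if start_biomass is None:
        B = np.broadcast_to(B0_cell, (k, n)).copy()
        R_prev = np.broadcast_to(R0_cell, (k, n)).copy()
    else:
        B = np.atleast_2d(np.asarray(start_biomass, dtype=float)).copy()
        if B.shape[0] == 1:
            B = np.repeat(B, k, axis=0)
        R_prev = np.broadcast_to(R0_cell, (k, n)) * B / np.maximum(B0_cell, 1e-300)
    G = stock.s * B
    s1 = np.full((k, n), stock.s)

    stochastic = perturb is not None and perturb.recruit_stochasticity
    if stochastic and rng is None:
        rng = np.random.default_rng()
    horizon = STOCHASTIC_YEARS if stochastic else max_years

    consec = np.zeros(k, dtype=int)
    converged = np.zeros(k, dtype=bool)
    collapsed = np.zeros(k, dtype=bool)
    total_prev = B.sum(axis=1)
    years = np.zeros(k, dtype=int)
    poached_total = np.zeros(k)
    window = []  # stationary window for stochastic runs
    eq = {}
    B_m1, B_m2, B_m3 = B.copy(), B.copy(), B.copy()  # tail-extrapolation history
    last_u = np.zeros((k, n))
    last_E = np.zeros((k, n))

    B0_total = float(B0_cell.sum())
    for year in range(1, horizon + 1):
        # survivors of previously recruited fish spawn at the start of year
        S = s1 * (B * (1.0 + stock.p) - stock.p * G - stock.p * stock.w_Lm1 * R_prev)
        np.maximum(S, 0.0, out=S)
        L = spawn_scale * S
        if perturb is not None and perturb.presettlement_dd:
            from .perturbations import presettlement_global_field
            L = presettlement_global_field(L, stock, B0_total / stock.B0)
        L = L @ K_l
        if perturb is not None and perturb.presettlement_dd:
            from .perturbations import presettlement_local_field
            R = presettlement_local_field(L, stock, q)
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                if stock.recruitment_form == "ricker":
                    R = L * np.exp(alpha - (beta / q) * L)
                else:
                    R = np.where(L > 0, L / (alpha + (beta / q) * L), 0.0)
        if stochastic:
            R = R * rng.uniform(0.0, 1.0)

        B_new = S + stock.w_L * R
        # adult movement: fish carry their demographic memory
        G_new = s1 * B
        B_new = B_new @ K_a
        G_new = G_new @ K_a
        R = R @ K_a

        if perturb is not None and perturb.poaching:
            cap = 0.5 * B0_cell
            excess = np.where(masks, np.maximum(B_new - cap, 0.0), 0.0)
            poached_total += excess.sum(axis=1)
            B_new = B_new - excess

        E = distribute_fishers(B_new, masks, scenario.fisher_movement, total_effort)
        E = np.where(masks, 0.0, E)  # full compliance: no effort in reserves
        # effort-conserving harvest: local effort E_i relative to the uniform
        # no-reserve baseline compounds the baseline annual rate u0
        u_cell = 1.0 - (1.0 - u0) ** E
        catch = u_cell * B_new

        B, G, R_prev = B_new, G_new, R
        s1 = stock.s * (1.0 - u_cell)
        B_m3, B_m2, B_m1 = B_m2, B_m1, B
        last_u, last_E = u_cell, E

        total = B.sum(axis=1)
        if stochastic:
            if year > horizon - STATIONARY_WINDOW:
                window.append((B.copy(), catch.copy(), E.copy(), R.copy()))
        else:
            active = ~converged
            dead = total < COLLAPSE_FLOOR * B0_total
            rel = np.abs(total - total_prev) / np.maximum(total_prev, COLLAPSE_FLOOR)
            consec = np.where(rel < EQ_TOL, consec + 1, 0)
            now = active & ((consec >= EQ_CONSEC) | dead)
            collapsed |= active & dead
            if now.any():
                for name, val in (("B", B), ("catch", catch), ("E", E), ("R", R)):
                    eq.setdefault(name, np.zeros((k, n)))[now] = val[now]
                years[now] = year
            converged |= now
            total_prev = total
            if converged.all():
                break

    if stochastic:
        Bm = np.mean([wdw[0] for wdw in window], axis=0)
        catchm = np.mean([wdw[1] for wdw in window], axis=0)
        Em = np.mean([wdw[2] for wdw in window], axis=0)
        Rm = np.mean([wdw[3] for wdw in window], axis=0)
        converged = np.ones(k, dtype=bool)
        years = np.full(k, horizon)
        eq = {"B": Bm, "catch": catchm, "E": Em, "R": Rm}
    else:
        for name in ("B", "catch", "E", "R"):
            eq.setdefault(name, np.zeros((k, n)))
        not_conv = ~converged
        if not_conv.any():
            # geometric tail extrapolation per cell at the year cap
            d_cur = B_m1 - B_m2
            d_prev = B_m2 - B_m3
            with np.errstate(invalid="ignore", divide="ignore"):
                lam = np.where(d_prev != 0, d_cur / np.where(d_prev != 0, d_prev, 1.0), 0.0)
            contracting = np.abs(lam) < 0.99995
            star = np.where(contracting, B_m1 + d_cur * lam / (1.0 - lam), B_m1)
            ok_net = not_conv & contracting.all(axis=1) & \
                np.isfinite(star).all(axis=1) & (star >= 0).all(axis=1)
            if ok_net.any():
                eq["B"][ok_net] = star[ok_net]
                eq["catch"][ok_net] = (last_u * star)[ok_net]
                eq["E"][ok_net] = last_E[ok_net]
                eq["R"][ok_net] = R_prev[ok_net]
                converged |= ok_net
        bad = ~converged
        for name in ("B", "catch", "E", "R"):
            eq[name][bad] = 0.0
        eq["catch"][collapsed] = 0.0
        eq["B"][collapsed] = 0.0
        years[bad] = horizon
        collapsed |= bad

    return ExplicitResult(
        biomass=eq["B"], catch=eq["catch"], effort=eq["E"], recruitment=eq["R"],
        reserve_masks=masks, converged=converged, collapsed=collapsed, years=years,
        total_catch=eq["catch"].sum(axis=1), total_biomass=eq["B"].sum(axis=1),
        poached=poached_total,
    )
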