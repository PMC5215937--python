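"""Additional-scenario machinery: recruitment stochasticity, poaching,
pre-settlement density dependence, habitat-quality gradients, stylised
asymmetric connectivity patterns, and systematic reserve placement.

Each perturbation is a hook into the annual loop of the implicit or explicit
simulator; with every switch off the pipeline is bitwise identical to the
base model.  The connectivity generators are synthetic stand-ins that
reproduce the defining signatures of measured dispersal patterns among
neighbouring reef patches: "advective" (maximal upstream/downstream
asymmetry), "patchy" (maximal number of isolated patch groups) and
"hotspots" (maximal spread in among-patch dispersal), plus a fully
"unidirectional" variant of the baseline kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .demography import StockParams
from .spatial_structure import Seascape

__all__ = [
    "PerturbationConfig",
    "apply_recruitment_stochasticity",
    "apply_poaching",
    "apply_presettlement_dd",
    "presettlement_global_stage",
    "presettlement_local_stage",
    "presettlement_global_field",
    "presettlement_local_field",
    "apply_habitat_gradient",
    "synth_connectivity",
    "place_reserves_systematic",
    "CONNECTIVITY_PATTERNS",
]

CONNECTIVITY_PATTERNS = ("unidirectional", "advective", "patchy", "hotspots")
PLACEMENT_STRATEGIES = ("random", "best_habitat", "worst_habitat",
                        "max_export", "max_retention")


@dataclass
class PerturbationConfig:
    """Switches for the additional modelling scenarios."""

    recruit_stochasticity: bool = False
    poaching: bool = False
    presettlement_dd: bool = False
    habitat_gradient: bool = False
    habitat_magnitude: float = 1.0
    connectivity_pattern: str | None = None
    placement: str = "random"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.connectivity_pattern is not None and \
                self.connectivity_pattern not in CONNECTIVITY_PATTERNS:
            raise ValueError(f"unknown connectivity pattern {self.connectivity_pattern!r}")
        if self.placement not in PLACEMENT_STRATEGIES:
            raise ValueError(f"unknown placement strategy {self.placement!r}")
        if not 0.0 <= self.habitat_magnitude <= 1.0:
            raise ValueError("habitat gradient magnitude must lie in [0, 1]")
        if self.placement in ("best_habitat", "worst_habitat") and not self.habitat_gradient:
            raise ValueError("habitat-informed placement requires the habitat gradient")
        if self.placement in ("max_export", "max_retention") and \
                self.connectivity_pattern is None:
            raise ValueError("connectivity-informed placement requires a connectivity pattern")

    @property
    def any_active(self) -> bool:
        return bool(self.recruit_stochasticity or self.poaching
                    or self.presettlement_dd)


def apply_recruitment_stochasticity(recruits, rng: np.random.Generator):
    """Scale the year's total recruitment by one global mortality factor drawn
    uniformly between 0 and 1 (long-run mean recruitment is halved)."""
    if rng is None:
        raise ValueError("recruitment stochasticity requires an rng")
    factor = rng.uniform(0.0, 1.0)
    if isinstance(recruits, tuple):
        return tuple(r * factor for r in recruits)
    return recruits * factor


def apply_poaching(B_reserve, B0_reserve):
    """Cap reserve biomass at 50% of its unfished level; the excess is removed
    as illegal catch (tracked, never credited to yield)."""
    cap = 0.5 * np.asarray(B0_reserve, dtype=float)
    B = np.asarray(B_reserve, dtype=float)
    excess = np.maximum(B - cap, 0.0)
    return B - excess, excess


# --- pre-settlement density dependence -------------------------------------
#
# The single post-settlement Beverton-Holt map L -> L/(alpha + beta L) is
# split into two equally important stages, one global (before dispersal) and
# one local (after settlement): L -> L/(sqrt(alpha) + b L) with
# b_global = beta/(2 sqrt(alpha)) and b_local = beta/2.  Composition of the
# two stages reproduces the unperturbed map exactly at proportional larval
# allocation, so the homogeneous unfished equilibrium is unchanged.

def _check_bh(stock: StockParams) -> None:
    if stock.recruitment_form != "beverton_holt":
        raise ValueError("pre-settlement density dependence is defined for "
                         "Beverton-Holt recruitment only")
    if stock.bh_alpha <= 0:
        raise ValueError("pre-settlement split requires alpha > 0 (h < 1)")


def presettlement_global_stage(L_r, L_f, stock: StockParams):
    """Global stage applied to the pooled larval output before dispersal."""
    _check_bh(stock)
    ra = math.sqrt(stock.bh_alpha)
    b_g = stock.bh_beta / (2.0 * ra)
    L_tot = L_r + L_f
    factor = np.where(L_tot > 0, 1.0 / (ra + b_g * L_tot), 0.0)
    return L_r * factor, L_f * factor


def presettlement_local_stage(L, stock: StockParams, area):
    """Local stage applied after settlement, against the zone's area share."""
    _check_bh(stock)
    ra = math.sqrt(stock.bh_alpha)
    b_l = stock.bh_beta / 2.0
    area = np.asarray(area, dtype=float)
    safe = np.where(area > 0, area, 1.0)
    L = np.asarray(L, dtype=float)
    out = np.where(L > 0, L / (ra + (b_l / safe) * L), 0.0)
    return np.where(area > 0, out, 0.0)


def presettlement_global_field(L: np.ndarray, stock: StockParams,
                               total_area: float) -> np.ndarray:
    """Global stage for per-cell fields: one factor per network row, with the
    density dependence scaled to the seascape's total carrying capacity."""
    _check_bh(stock)
    ra = math.sqrt(stock.bh_alpha)
    b_g = stock.bh_beta / (2.0 * ra)
    L_tot = L.sum(axis=-1, keepdims=True)
    return L / (ra + (b_g / total_area) * L_tot)


def presettlement_local_field(L: np.ndarray, stock: StockParams,
                              quality: np.ndarray) -> np.ndarray:
    """Local stage for per-cell fields against local carrying capacity."""
    _check_bh(stock)
    ra = math.sqrt(stock.bh_alpha)
    b_l = stock.bh_beta / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(L > 0, L / (ra + (b_l / quality) * L), 0.0)


def apply_presettlement_dd(L_r, L_f, stock: StockParams, C: float):
    """Full two-stage pipeline for the two-zone model (global stage, then
    local stages per zone), returning zone recruitment."""
    L_r, L_f = presettlement_global_stage(L_r, L_f, stock)
    return (presettlement_local_stage(L_r, stock, C),
            presettlement_local_stage(L_f, stock, 1.0 - C))


def apply_habitat_gradient(seascape: Seascape, rng: np.random.Generator,
                           magnitude: float = 1.0) -> Seascape:
    """Random per-cell carrying-capacity multipliers: B0,i drawn uniformly on
    (1 - magnitude, 1]; magnitude 1 spans any proportion of the local maximum."""
    if not 0.0 <= magnitude <= 1.0:
        raise ValueError("magnitude must lie in [0, 1]")
    if magnitude == 0.0:
        quality = np.ones(seascape.n_cells)
    else:
        quality = 1.0 - magnitude * rng.uniform(0.0, 1.0, size=seascape.n_cells)
    return Seascape(seascape.n_cells, seascape.cell_width, quality,
                    seascape.reserve_mask.copy())


def synth_connectivity(pattern: str, n_patches: int = 50,
                       rng: np.random.Generator | None = None,
                       base_sigma: float = 2.0, shift: float = 3.0) -> np.ndarray:
    """Synthetic column-stochastic larval connectivity matrix among patches.

    Column j holds the settlement distribution of larvae produced at patch j
    (columns sum to 1: larval conservation).  Patterns: "unidirectional"
    (baseline kernel truncated to one flow direction), "advective" (kernel
    displaced downstream), "patchy" (isolated groups of patches), "hotspots"
    (per-patch dispersal scales drawn bimodally, maximising the spread of
    among-patch dispersal).
    """
    if pattern not in CONNECTIVITY_PATTERNS:
        raise ValueError(f"unknown connectivity pattern {pattern!r}")
    if n_patches < 2:
        raise ValueError("need at least two patches")
    if rng is None:
        rng = np.random.default_rng()
    idx = np.arange(n_patches)
    dest = idx[:, None]
    src = idx[None, :]

    if pattern == "unidirectional":
        K = np.exp(-0.5 * ((dest - src) / base_sigma) ** 2)
        K[dest < src] = 0.0  # flow towards higher indices only
    elif pattern == "advective":
        K = np.exp(-0.5 * ((dest - src - shift) / base_sigma) ** 2)
    elif pattern == "patchy":
        group = 5
        K = np.exp(-0.5 * ((dest - src) / base_sigma) ** 2)
        K[(dest // group) != (src // group)] = 0.0
    else:  # hotspots
        sigmas = np.where(rng.random(n_patches) < 0.5, 0.3,
                          rng.uniform(4.0, 10.0, size=n_patches))
        K = np.exp(-0.5 * ((dest - src) / sigmas[None, :]) ** 2)

    colsum = K.sum(axis=0, keepdims=True)
    return K / np.where(colsum > 0, colsum, 1.0)


def net_displacement(K: np.ndarray) -> float:
    """Mean signed displacement (in patch units) of a column-stochastic
    connectivity matrix; 0 for symmetric kernels."""
    n = K.shape[0]
    idx = np.arange(n)
    return float(((idx[:, None] - idx[None, :]) * K).sum() / n)


def place_reserves_systematic(strategy: str, coverage: float,
                              seascape: Seascape | None = None,
                              connectivity: np.ndarray | None = None,
                              rng: np.random.Generator | None = None) -> np.ndarray:
    """Greedy top-k reserve placement by the strategy's per-cell score.

    "best_habitat"/"worst_habitat" rank cells by habitat quality;
    "max_export" ranks patches by the off-diagonal column sum of the
    connectivity matrix (larvae exported to other patches); "max_retention"
    by the diagonal (local retention).  "random" picks cells uniformly.
    """
    if strategy not in PLACEMENT_STRATEGIES:
        raise ValueError(f"unknown placement strategy {strategy!r}")
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must lie in (0, 1)")

    if strategy in ("best_habitat", "worst_habitat", "random"):
        if seascape is None:
            raise ValueError(f"{strategy} placement requires a seascape")
        n = seascape.n_cells
        k = max(int(round(coverage * n)), 1)
        if strategy == "random":
            if rng is None:
                rng = np.random.default_rng()
            chosen = rng.choice(n, size=k, replace=False)
        else:
            order = np.argsort(seascape.habitat_quality, kind="stable")
            chosen = order[-k:] if strategy == "best_habitat" else order[:k]
    else:
        if connectivity is None:
            raise ValueError(f"{strategy} placement requires a connectivity matrix")
        n = connectivity.shape[0]
        k = max(int(round(coverage * n)), 1)
        export = connectivity.sum(axis=0) - np.diag(connectivity)
        score = export if strategy == "max_export" else np.diag(connectivity)
        chosen = np.argsort(score, kind="stable")[-k:]
    mask = np.zeros(n, dtype=bool)
    mask[chosen] = True
    return mask
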