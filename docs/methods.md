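# Methods

## Population model

Biomass dynamics use the Deriso–Schnute delay-difference formulation: the
whole stock is one biomass pool with explicit one-year lags standing in for
age structure. The state carried from year to year is the triple
(B, G, R) with `G = s_prev · B_prev` the survival-weighted biomass memory and
R the previous recruitment, so the annual update is

```
survivors S_t = s1 · [ B(1+p) − pG − p w_{L-1} R ]        (floored at 0)
B_t          = S_t + w_L R_t
```

`s1` is the total survival experienced during the previous year (natural
survival s times the fraction escaping harvest). Two structural choices
matter and are deliberate:

* **Spawners are the survivors `S_t`, not last year's standing biomass.**
  The update contains same-year recruitment (`w_L R_t`), so the start-of-year
  spawning event can only draw on previously recruited fish that survived to
  it. Spawning from pre-mortality biomass would make populations immune to
  depletion (eggs would be produced before any mortality is applied), which
  destroys the entire overfishing gradient the analysis is about. Larval
  output is normalised so the unfished survivor biomass `S0 = B0 − w_L R0`
  produces the natural settlement `L0`.
* **Moving fish carry their demographic memory.** Adult exchange (the
  two-zone `m`, or the explicit home-range kernel) is applied to the whole
  (B, G, R) triple, not to biomass alone. This makes the fully mixed limit
  (d = m = 1) reduce *exactly* to the closed single-population model fished
  at the realized seascape-wide rate — a property the tests assert to
  machine precision — instead of drifting a few percent away.

Recruitment is Beverton–Holt with steepness by default
(`R = L/(α + βL)`, `α = L0/R0 − βL0`, `β = (5h−1)/(4hR0)`; identities
`R(L0) = R0`, `R(0.2 L0) = h R0`; `h = 0.2` is the proportional limit,
`h = 1` constant recruitment). The Ricker alternative is implemented exactly
as `R = L·e^{α−βL}` with `β = ln(5h−1)/(0.8 L0)`,
`α = ln(R0/L0) + βL0`; note that this parameterisation gives
`R(0.2 L0) = 0.2(5h−1)R0`, which is *not* the Beverton–Holt steepness
identity — it is kept as-is rather than silently re-calibrated.

`R0` is solved in closed form from the unfished fixed point:
`R0 = B0(1−s)(1−ps) / (w_L − p s w_{L-1})`, leaving `B0 = 1` the single free
scale.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| s | natural annual adult survival | sampled | 1 − mortality, mortality ~ U(0.18, 0.88) yr⁻¹ |
| p | Brody growth coefficient | sampled U(0.5, 0.95) | e^{−K} for von Bertalanffy K ≈ 0.05–0.7 |
| h | steepness | trunc-normal 0.7 ± 0.2 on [0.5, 0.9] | typical recruitment compensation of exploited stocks |
| w_L | weight at recruitment | 1 | normalisation |
| w_{L-1} | weight one year pre-recruitment | 0.5·p·w_L | see below |
| d, m | larval/adult exchange fractions | scenario | categories N = 0, 1: 10–20%, 2: 30–50%, 3: 60–100% |
| u' rule | effort concentration | effort-conserving | see below |

**Pre-recruit weight.** The ratio `w_{L-1}/w_L` controls how strongly the
delay terms damp the yield curve past MSY, and hence what fraction of stocks
still delivers PGY (catch ≥ 0.8 MSY) at a given overfishing multiple. With
`w_{L-1} = p·w_L` the sampled ensemble keeps PGY for only ~38% of stocks at
1.3–1.5 × F_MSY; with `w_{L-1} = 0.5·p·w_L` the ensemble reproduces the
expected ≈97% / ≈48% / <2% gradient over the moderate / considerable / heavy
overfishing categories. The factor was calibrated once against that gradient
and is exposed as a plain field. (The growth-range default, by contrast,
turned out to have almost no effect on these summaries.)

**Effort concentration.** Total effort is constant, so closing a fraction C
concentrates fishing. The default rule is effort-conserving:
`u' = 1 − (1−u)^{1/(1−C)}`, which is precisely F′ = F/(1−C) applied to the
instantaneous rate `F = −ln(1−u)` and never reaches total removal. The
first-order rule `u' = u/(1−C)` (capped at 1) is retained as the
`effective_fishing_rate` helper and as a `concentration="linear"` option; it
makes every no-exchange fishery fall below PGY at 20% coverage by arithmetic
and was found to overstate concentration damage across the board.

## Spatial structure

The seascape is a 1-D coastline (default 100 km in 1,000 cells of 100 m;
the analysis runs use 250 cells of 400 m, which resolves the ≥ 7 km
dispersal kernels comfortably). Kernels are Gaussian distance-decay
functions; the scale parameter is set directly to the measured mean
dispersal/home-range distance (snapper larvae 7.4 km, grouper 8.6 km;
adult home ranges 0.2 and 1.0 km). This is deliberately conservative: it
understates long-distance dispersal relative to matching E|X| to the mean
(σ = mean·√(π/2)), and it places the 15-km-reserve export fraction at
38.6% / 43.9% for the two species, inside the expected 35–45% band, where
the E|X| convention would land above it. Boundaries are reflecting (mirror
images, preserving uniform fields to machine precision); a periodic option
exists for sensitivity tests.

Reserve networks alternate negative-binomial reserve-size draws (moment
matched to the target mean ± SD, minimum one cell) and gap draws (mean
O = S(1−C)/C, coefficient of variation 1), laid out around the circular
coastline from a random phase; draws whose realized coverage misses the
target by more than 20% relative are resampled. At extreme coverage the
gaps collapse below the grid scale and the sampler degrades to a few large
reserves.

Per-cell fishing: effort is allocated over fished cells with gravity weight
`B_i^ω` and compounds the baseline annual rate, `u_i = 1 − (1−u0)^{e_i}`
with `e_i` the local effort relative to the uniform no-reserve baseline.
ω = 0 gives uniform effort, ω = 1 equalises catch per unit effort (ideal
free distribution, verified to ~2% in the tests), ω = 3 concentrates effort
against reserve boundaries.

## Numerics

* Equilibrium: relative change of total biomass < 1e-8 for 5 consecutive
  years, cap 500 years. Populations contracting geometrically towards zero
  never satisfy a relative criterion and are flagged collapsed (yield 0)
  once biomass falls below 1e-12·B0.
* Near the collapse bifurcation the contraction ratio approaches 1 and the
  cap is reached while the population is still slowly approaching a small
  positive equilibrium; the tail is then summed in closed form (Aitken
  extrapolation per zone/cell, accepted while |λ| < 0.99995). Without this,
  near-critical scenarios would be misclassified as collapsed and the
  coverage curves would show spurious cliffs.
* Reserve sweeps start from the fished equilibrium (the pre-reserve state),
  with a recolonisation floor of 1e-4·B0 per zone so that reserves can
  rebuild an extirpated fishery; the deterministic equilibria were verified
  to be independent of the starting state across the parameter ranges used.
* F_MSY: vectorised 0.02-grid scan plus local 0.002 refinement for
  ensembles; the scalar `find_FMSY` adds bounded golden-section refinement
  and agrees with an exhaustive 0.0005 grid to one step.
* Reference-point rules: maximum sustain coverage uses the first crossing of
  the PGY threshold (later re-crossings do not count); the rebuild optimum
  is the argmax with ties broken to the smallest coverage; both are computed
  on the 1%-step coverage grid with no interpolation.
* Stochastic runs have no fixed point; summaries are means over the last
  100 of 500 years. All randomness flows from explicit
  `numpy.random.Generator` seeds; equal config + seed gives byte-identical
  outputs.

## Synthetic scenario generator

The sampler emulates the joint life-history variation of well-studied fish
stocks: mortality uniform on 18–88% yr⁻¹, Brody growth coupled to mortality
through a Gaussian copula with rank correlation −0.5 (fast-turnover stocks
approach asymptotic size faster), steepness truncated-normal 0.7 ± 0.2 on
[0.5, 0.9]. It does not reproduce the empirical joint distribution of any
particular stock database — the correlation and growth range are declared
stand-ins — so the grid summaries are tolerance-based rather than exact
reproductions, and passing tests show the *mechanisms* behave correctly, not
that any particular real fishery is predicted. The synthetic connectivity
patterns likewise reproduce defining signatures (maximal advective
asymmetry, isolated patch groups, maximal dispersal spread) rather than any
measured current field.

## Economics

Profit is `P = Y − Eθ/(1+D)^t` with yield Y and effort cost E in common
arbitrary units. Within the bioeconomic runs effort is the seascape-wide
annual exploitation fraction, and the cost unit is 0.01·B0 per unit effort,
so the stock-effect break-even biomass density is θ% of unfished: θ = 1 is
effectively "fished until no longer available", and
`theta_for_biomass_threshold(0.05)` gives the θ for a 5%-of-virgin
threshold. Open-access effort updates every two years by
`δ = clamp(P_t/P_{t-1}, 1−dE_max, 1+dE_max)` when both profits are positive
(matching the doubling/halving anchors exactly), with sign-based steps of
magnitude dE_max otherwise; aggressive fisheries reduce effort only at
negative profit. This δ is locally stable, so open-access dynamics without
reserves settle rather than boom-bust-collapse; the aggressive mode does
reproduce the qualitative story (deep depletion without reserves, profits
restored by ~30% coverage).

## Problem sizes used in the shipped runs

Grid summaries: 2,000 stocks × 16 exchange cells × 3 overfishing categories
(96,000 scenarios), each with its own F_MSY calibration and a 96-point
coverage sweep — about 7 minutes on one CPU via the vectorised engine.
Explicit species runs: 250-cell coastline, 30 coverage levels × 100 random
networks per species. These sizes were chosen so a full reproduction runs on
a desktop in minutes; enlarging them changes the summary statistics by well
under a percentage point.

## Known limitations

* The grid means of the two coverage reference points are sensitive to the
  exchange semantics and the concentration rule; under this implementation
  the mean maximum-sustain coverage across the full 16-cell grid sits near
  42% (moderate overfishing), with the no-exchange rows — which are forced
  low by arithmetic — pulling the equal-weight mean down (excluding them
  gives ≈52%).
* In the spatially explicit model the heavy-overfishing catch-vs-coverage
  curves form long shallow plateaus (ever more fished cells sit within
  larval reach of reserves as coverage grows), so the argmax of the median
  curve is noisy across ~30–50% coverage rather than a sharp optimum.
* The fraction of moderate scenarios whose curve peaks *exactly* at 20%
  coverage on a 1% grid is near zero by construction for smooth unimodal
  curves; "maximum benefit around 20%" statements are better read off
  `opt_C ≤ 0.2` (~24% of scenarios here).
* Trophic interactions, behavioural effects, catch regulations and
  inter-specific density dependence are out of scope by design; the 1-D
  coastline abstraction ignores 2-D seascape geometry.
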