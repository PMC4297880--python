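# Methods

## Scope and state variables

`phytopond` simulates a spatially homogeneous, continuously diluted
(chemostat) microalgal culture in a flat pond of optical depth τ under
natural solar forcing, and accounts for the production of total biomass
carbon and of *excess carbon* (Cex) — carbon fixed in surplus of immediate
structural demand, the proxy for biofuel feedstock (lipid/carbohydrate).
The state is six pools per m³ of culture: algal carbon `Cb`, nitrogen `Nb`,
phosphorus `Pb` and chlorophyll `Chl`, plus dissolved inorganic N (`Sn`)
and P (`Sp`). Temperature, CO₂ and pH are assumed externally regulated at
their optima and are not modelled; iron and silicate quotas, NH₄/NO₃
partitioning, organic-matter exudation and photoinhibition are outside
scope.

## Solar forcing

Instantaneous surface PAR is

    PFD(φ, d, θ) = SC · f_par · c(φ) · max(0, sin φ sin δ + cos φ cos δ cos θ)

with latitude φ, solar declination δ(d) = −0.4093·cos(2π(d+10)/365) rad,
and hour angle θ (zero at solar noon). `SC` (default 2800 µmol photons
m⁻² s⁻¹) is the top-of-atmosphere PAR scale and `f_par` (0.9) the usable
fraction; both are configuration, calibrated once as described below. The
clearness index `c(φ)` (fraction of extraterrestrial radiation reaching
the surface on an average day) is a piecewise-linear table over |φ|; the
shipped default — 0.52 at the equator, 0.48 at 20°, 0.55 at 35°, 0.45 at
55°, 0.50 at 65° — is a **synthetic stand-in** for station climatology,
kept inside the observed 0.45–0.7 band; a two-column CSV hook accepts real
data. A formulation scaling the flux by the *arccosine* of the zenith
cosine rather than the cosine itself appears in some descriptions of this
forcing; it is dimensionally inconsistent for a flux, and the standard
cosine-of-zenith form is the only implemented option.

## Cell model

All rate closures are small named functions (swappable by substitution) in
`physiology`:

- **Quota-controlled growth.** For quota Q with bounds (Qmin, Qmax) the
  normalized growth factor is `u = (1+KQ)·q/(q+KQ)` with
  `q = (Q−Qmin)/(Qmax−Qmin)` clipped to [0, 1]; `u(Qmin)=0`, `u(Qmax)=1`.
  `KQN = 10` gives the near-linear N:C response, `KQP = 0.1` the steep
  luxury-storage P:C response typical of microalgae. Multi-nutrient control
  is a minimum law, `U = Um·min(uN, uP)`.
- **Transport.** `V = Vscale·Um·Qmax · S/(S+Ks) · ((Qmax−Q)/(Qmax−Qmin))^h`
  with `h = 0.5` and `Vscale = 3`: uptake stays de-repressed until the
  quota is nearly full, so a replete, fast-growing cell can hold N:C near
  NCmax (with a linear feedback and small headroom the quota lags growth
  and the cell is spuriously diagnosed as carbon-storing).
- **Excess carbon.** Diagnostic of the N quota:
  `cex = max(0, 1 − NC/NCmax)`, ceiling `cex_max = 1 − NCmin/NCmax`. The
  default bounds NCmin = 0.055, NCmax = 0.15 gN gC⁻¹ put the ceiling at
  63 % of cell carbon (a deliberate calibration of the quota bounds, not a
  model prediction). Cex is not a separate state pool; the harvested
  feedstock flux is `D·Cb·cex`.
- **Photosynthesis ceiling.** `Pqm = Um·(1+r_basal)·Pq_surge·(1−cex/cex_max)^hCex`.
  The surge factor (1.25) lets fixation exceed balanced-growth demand so
  storage can fill under N stress; the shut-off exponent `hCex = 0.3`
  makes fixation persist until the store is nearly full, which is what
  lets slow, N-starved cultures approach the 63 % ceiling (a gradual
  exponent ≥ 1 pins equilibrium Cex near 15–20 % instead). As the N quota
  falls to NCmin the ceiling goes to zero — this, not hard clipping, is
  what keeps the quota above its floor.
- **Respiration.** `R = r_basal·Um + r_growth·PS` with r_basal = 0.05 and
  r_growth = 0.2. Together with the surge factor these make a replete cell
  at continuous saturating light net exactly `Um`, so the Droop-consistency
  limit (equilibrium growth → Um as NC → NCmax) holds by construction.
- **Photoacclimation.** Chl:C relaxes at rate `kChl` (default `Um`) toward
  `target = min(ChlCmax·uN·(1−PS/Pqm) + ChlC_floor, ChlCmax)`: pigment
  rises in dim light, falls under N stress or light-saturated
  photosynthesis. ChlCmax = 0.06 gChl gC⁻¹ (typical, non-selected
  pigmentation); the floor (0.015) is the residual pigment retained under
  extreme stress.

## Optics

Light decays as `I(z) = I₀·e^(−kz)` with `k = k_bg + ε_chl·Chl`
(k_bg = 0.1 m⁻¹, ε_chl = 18 m² gChl⁻¹ — the linear form is a modelling
choice). The local Smith response `P = Pqm·x/√(1+x²)`,
`x = I·α·ChlC/Pqm`, integrates over depth in closed form:

    PS = Pqm/(kτ) · [asinh(x₀) − asinh(x₀·e^(−kτ))]

implemented with `asinh` for stability at small argument and with the
analytic τ→0 limit (the local surface rate). A property test holds the
closed form to numerical depth quadrature within 10⁻⁵ relative. No
photoinhibition: the Smith curve is kept for its analytic integral even
though it can overestimate photosynthesis near a bright surface.

## Chemostat assembly and integration

    dCb/dt  = (PS − R − D)·Cb          dSn/dt = D(N_in − Sn) − VN·Cb
    dNb/dt  = VN·Cb − D·Nb             dSp/dt = D(P_in − Sp) − VP·Cb
    dPb/dt  = VP·Cb − D·Pb             dChl/dt = ρChl·Cb − D·Chl

Fixed-step RK4 (default dt = 0.002 d ≈ 2.9 min; forcing is smooth and the
system only mildly stiff, and determinism is wanted for testing), one
spin-up year discarded so the reported year is the periodic annual state —
verified insensitive to the inoculum for non-washout runs. The compiled
(numba) kernel and the readable reference derivative are asserted equal to
machine precision.

Numerical guards, all mass-conserving for N and P:

- *Clearance cap*: uptake flux per unit medium is capped at 100 d⁻¹ × the
  dissolved pool, bounding the Michaelis–Menten stiffness in the last few
  percent of drawdown (KsN = 0.03, KsP = 0.005 g m⁻³ are small); an
  overdraft that still slips through a step is repaid from the cell pool.
- *Quota confinement*: N:C (P:C) exceeding its replete bound — night
  respiration shrinks Cb under replete quotas — is released back to the
  dissolved pool. The lower bound is maintained dynamically by the Pqm
  shut-off, never by mass-destroying clips.
- Chl is clipped to [0, ChlCmax·Cb]; pigment carries no conservation law.

With D = 0 the total N and P drift stays below 10⁻⁶ relative over a
two-year integration; halving dt changes annual means by < 0.5 %.

**Washout** is flagged (not raised) when algal C sits below 10⁻⁶ of the
inoculum for more than 30 consecutive days; a flagged year is reported as
zero production, matching the harvest-flux reading of production (D times
a vanished standing stock).

## Production accounting

Production is the harvest flux `VP = D·Cb` (volumetric) and `AP = VP·τ`
(areal), likewise `VXP = D·Cb·cex` and `AXP = VXP·τ`; the identities are
exact by construction. Annual means are trapezium-rule integrals over the
reported year; quarterly means use calendar quarters with Q1 =
January–March in the northern hemisphere and the labels rotated by two
quarters south of the equator. Two reporting constants: carbon is 31 % of
dry weight, and fuel carbon density is 720 gC L⁻¹ (used only in the
dry-weight / litres conversions).

## Optimization

`grid_search` is the authoritative reference: exhaustive evaluation with
ties broken toward smaller D, then smaller τ (the resource-frugal
preference — lower dilution and shallower ponds use less water and
nutrient). `evolve` is a (μ+λ) evolution strategy (μ = 8, λ = 16, Gaussian
mutation with σ = 10 % of each axis range decaying by 0.93 per generation,
box clipping, elitist selection), deterministic per seed; evaluations are
memoized by operating point so identical points never re-simulate.

## Calibration (done once, frozen)

Four constants were calibrated jointly against typical field production
levels and then frozen: SC = 2800, α = 0.45 gC gChl⁻¹
(µmol m⁻² s⁻¹)⁻¹ d⁻¹, ε_chl = 18 m² gChl⁻¹, ChlC_floor = 0.015. Under
this calibration the simulator reproduces the expected operating
behaviour: the biomass-optimal dilution rate is ≈ 25 % of Um across the
four preset strains (feedstock-optimal ≈ 15 %), strain S washes out
between D = 0.3 and 0.35 d⁻¹ under equatorial forcing, equatorial annual
AP is ≈ 1.1 (strain S, D = 0.2) and ≈ 2.1 gC m⁻² d⁻¹ (strain F, D = 0.35),
and peak feedstock production is ≈ 0.9 g Cex m⁻² d⁻¹ at 15°, τ = 0.1 m,
D = 0.25, half-strength medium — all recomputed by the test suite and
`scripts/acceptance.py`, never asserted as constants.

## Problem sizes

The shipped sweeps, tests and the acceptance script integrate with
dt = 0.005 d and one spin-up year, on coarsened grids (D step 0.02–0.04,
seven-point log τ grid, three latitudes for the depth scan); these are the
package's validated default study sizes, chosen inside the integrator's
convergence range. The full-resolution surfaces (latitude step 5°, finer
D/τ grids) run through `experiments.run_sweep`, which caches per-point
results on disk keyed by the sweep's configuration hash and is resumable.

## What the synthetic inputs do and do not emulate

The clearness table and the solar-geometry forcing emulate *average*
seasonal and latitudinal light availability; they carry no weather
stochasticity, spectral structure, or direct/diffuse partitioning, and the
pond is optically homogeneous with no surface reflection geometry. The
four preset strains differ only in maximum growth rate (0.347, 0.693,
1.040, 1.386 d⁻¹); all other physiology is shared. Passing tests therefore
demonstrate the internal consistency of the model and the robustness of
the *relative* operating conclusions (optima, ratios, thresholds), not
site-specific absolute yields, which inherit the uncertainty of the
calibration constants above.

## Known limitations

- Excess C is a diagnostic of N:C, not a dynamic pool: its composition
  (lipid vs carbohydrate) and any remobilization kinetics are not resolved.
- P limitation acts on growth only through uptake and quota dynamics, not
  through the fixation ceiling (which reads the N quota alone); the f/2
  media family is N-limiting given the default quota bounds, so this path
  is never exercised by the shipped scenarios.
- The 30-day chemostat-balance check assumes no seasonal trend inside the
  window; away from the equator it is meaningful only over windows that
  average the seasonal cycle (the full-year check holds at any latitude).
- Continuous dilution only: semi-batch harvesting and real-time
  (predictor–corrector) control of D are not implemented.
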