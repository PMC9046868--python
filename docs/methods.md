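# Methods

## Model

The simulator integrates a phenotype-structured population model of a
melanoma section under targeted therapy. The state of the system is the
cell number density `c(t, x, y)` over two spatial coordinates
`x ∈ [0,1]²` (a 2D tissue section) and two structural coordinates
`y ∈ [0,1]²` (an abstract 2D gene-expression map on which cell identity
varies continuously), plus five 2D environment fields: the immobile
extracellular nutritional environment (ECNE) `v`, the diffusible nutrient
`n`, acid `a`, and the two drug concentrations `w_B` (BRAF/MEK inhibitors)
and `w_H` (a hypothetical treatment, HCT, aimed at the BRAF/MEKi-tolerant
states). All quantities are dimensionless except time (days).

The density obeys the continuity equation
`∂c/∂t = −∇x·Fx − ∇y·Fy + S` with

* spatial flux `Fx = −D_x (1−ρ/ρ_max)₊ ∇x c + c (χ_n ∇x n + χ_v ∇x v)`,
  where `ρ(x) = ∫ c dy` is the local total density. The volume-filling
  factor multiplies the diffusive term (a config switch moves it onto the
  taxis term instead);
* structural flux `Fy = c Φ(y) − D_y(y) ∇y c`, with drift
  `Φ(y) = (−k_adv (y1 − a(y2)), 0)` where the attractor abscissa
  `a(y2)` interpolates linearly between the proliferative anchor at the
  south edge and the SMC anchor at the north edge, and diagonal Fickian
  diffusivity `D_y = diag(D_h(y2), D_v(y1))`, `D_h` increasing linearly
  south→north and `D_v` a parabola maximal at the west/east edges and
  minimal centrally. These are the simplest monotone/parabolic/linear
  forms consistent with the qualitative transition structure among the
  six states; they are pluggable via configuration;
* source `S = P(y) · n/(n_half+n) · (1−ρ/ρ_max)₊ · c − Σ_i δ_i ψ_i(y) w_i c`
  with `P(y) = p_max G(y; y_prolif, σ_P)(1 − s_SMC G(y; y_SMC, σ_S))`
  (G: Gaussian bump peaking at 1). Drug kill is bilinear in concentration
  and a state-dependent response `ψ_i(y) ∈ [0,1]` — a clipped Gaussian
  mixture with per-component centers, weights and widths, optionally
  multiplied by an attenuation dip (used to carve the reduced BRAF/MEKi
  efficacy in the pigmented north-west).

Environment kinetics: `v` restores logistically and is degraded by acid
and slowly naturally (no transport — matrix is immobile); `n` diffuses, is
produced by the ECNE and consumed by cells; `a` diffuses, is produced by
cells and decays; drugs diffuse, are administered uniformly in space while
dosing is on, clear at rate `λ_w` and are taken up by cells at rate
`ε_w ρ`. The uptake term matters: a dense tumor dilutes its own drug
exposure, so the core of a large tumor is partially shielded (cooperative
protection) while a minimal-residual-disease remnant faces the full
concentration `dose/λ_w`.

## Cell-state geography

Six states are represented as closed discs (radius 0.15, nearest-anchor
tie-break) around anchors on the unit state square: proliferative
(0.20, 0.20), invasive (0.85, 0.50), pigmented (0.20, 0.85), NCSC
(0.85, 0.85), SMC (0.50, 0.90), URC (0.80, 0.15). The URC anchor is
placed in the *south-east*: the horizontal-diffusion route linking it to
the proliferative state and the east/south span of the HCT response are
only geometrically consistent with that placement. The discs are a
partial cover — most of the plane is "unassigned" intermediate states —
and the atlas is fully configurable, so alternative geographies need no
code changes.

## Treatment policies

`continuous` doses one drug from the start day onward; `sequential` swaps
to a second drug at a fixed switch day; `adaptive` doses one drug and
decides daily: on above an upper burden threshold, off below a lower one,
previous state retained inside the band (hysteresis). Thresholds are
fractions of the burden at treatment start. At most one drug is dosed at
any time, and the dose is held constant across one integrator step.

## Numerics

Space and state are discretized with cell-centered uniform finite volumes
(24 cells per axis by default; 331,776 4D cells). Fluxes are evaluated at
faces: first-order upwind for advection/taxis, central differences with
arithmetically face-averaged coefficients for diffusion, zero-flux
boundaries everywhere. The scheme is conservative by construction;
transport changes total mass only at round-off (verified to 1e-10 relative
over 10⁴ steps in the suite).

Time integration is explicit second-order Heun with one global step.
Stability bounds for the individual mechanisms (spatial diffusion of the
fastest species `h²/4D`, structural diffusion, advection CFL, the fastest
linear reaction rate including kill at the drug's equilibrium
concentration) are combined *harmonically* — `dt = safety / Σ 1/dt_k`,
safety 0.8 by default — because the mechanisms act simultaneously and the
minimum of the individual bounds alone is not stable for their sum.
Negative values produced by the scheme are clipped to zero and the clipped
mass is recorded per step (≤1e-8 of the burden per step in the reference
runs). Manufactured-solution tests confirm second-order convergence for
diffusion and first-order for upwind advection; the hot loop is a fused
numba kernel, cross-checked to round-off against the composable numpy
operators that define the scheme.

The initial condition is a naive tumor: cell-averaged (error-function)
Gaussians, spatial σ=0.1 at the domain center × structural σ=0.1 at the
proliferative anchor, total mass 1; ECNE dented by 50% under the tumor,
nutrient at its local equilibrium, no acid or drug. Cell averaging rather
than center sampling keeps the finite-volume density consistent with the
particle oracle's exact Gaussian samples.

## Particle oracle

An independent Euler–Maruyama simulator propagates weighted particles
under the same drift and diffusion: `dY = [Φ + ∇·D_y] dt + √(2 D_y) dW`
(the divergence-of-D Itô correction makes the particle law solve the
divergence-form Fickian equation; it is computed by central differences of
the diffusivity profiles so it stays correct for any configured profile —
for the default profiles, each diagonal entry depends only on the *other*
coordinate and the correction vanishes). Boundaries reflect, matching
zero-flux. The canned agreement check runs a transport-only instance —
8²×8² grid, mid-domain blob (σ=0.12), constant `D_y = 2·10⁻³`,
`k_adv = 0.01`, crowding/taxis/sources off, 2×10⁵ particles, 5 days — and
the total-variation distance between the particle histogram and the PDE
density is ≈0.036, within the 0.05 acceptance band. The instance is
chosen transport-only and mid-domain so that the comparison isolates the
operator: wall-truncated initial data and reaction terms would otherwise
dominate the distance with representation artifacts.

## Reference parameter set and calibration

The shipped defaults (`src/melsim/data/reference.yaml`) are a calibrated
reference set, versioned with the code. Calibration targets, in order of
priority: (i) untreated doubling time of roughly two weeks (realized:
12.3 days over the pre-treatment window); (ii) a three-phase
shrink/MRD/regrow response under continuous BRAF/MEKi with resistance
onset about four months into dosing (realized: 133 days); (iii) early
failure of HCT alone; (iv) the scenario ordering
HCT < BRAF/MEKi < BRAF→HCT < HCT→BRAF in time-to-resistance with the
lowest final burden under HCT→BRAF.

Choices that the calibration fixed, and why:

* **Pre-treatment growth (50 days).** Naive tumors already contain
  invasive cells; dosing begins only after the naive distribution has
  developed realistic east-side tails. All response metrics are measured
  against the burden at treatment start.
* **Weak advection (k_adv = 1.5e-3/day).** The state-attractor drift sets
  the cellular hierarchy but must not drain the off-attractor resistant
  pocket faster than it proliferates; with stronger drift the URC pocket
  cannot sustain regrowth at all.
* **Dormancy blanket (σ_S = 0.5, depth 0.9).** The SMC-centered growth
  suppression covers the whole treatment-induced north (SMC, NCSC and
  pigmented flanks). Without it the pigmented state — geometrically out of
  reach of both drug profiles — becomes a universal escape engine and all
  BRAF-facing scenarios resist at the same time.
* **Drug uptake (ε_w = 0.1).** Provides the burden-dependent drug
  dilution that lets a large tumor under mild HCT grow through treatment
  ("no response → immediate resistance") while the same drug pins a
  post-BRAF remnant, which is what separates the two sequential orders.
* **Response profiles.** BRAF/MEKi: proliferative component σ=0.18
  (weight 1) + invasive component σ=0.10 (weight 0.5), NW attenuation
  depth 0.5; the tight invasive component is required so BRAF kill does
  not spill onto the adjacent URC refuge. HCT: invasive + URC components,
  σ=0.25, matching its wider span. δ=1 for both; doses 0.7 (BRAF/MEKi)
  and 0.8 (HCT).
* **Sequential switch at day 110, adaptive thresholds (0.3, 0.5)** of the
  start-of-treatment burden, daily decisions.

## Derived metrics

* **Burden**: midpoint quadrature of `c`; series recorded every step.
* **Phases**: the burden from treatment start is smoothed with a moving
  average spanning `min_duration` (10 days), classified by slope against
  ±`slope_tol`·(start burden)/day (0.002), short runs merged into their
  longer neighbor.
* **Time to resistance**: first upward crossing of the start-of-treatment
  burden *after* the burden has dropped at least 5% below it (resistance
  presupposes a response; if the tumor never responds, resistance is
  immediate). Crossings are interpolated linearly.
* **Heterogeneity**: trace of the mass-weighted covariance of the
  structural distribution (per-axis variances summed), plus a mode count
  of the Gaussian-smoothed structural marginal (strict 8-neighbor maxima
  above 5% of the peak).
* **Zoning**: per subpopulation, the spatial field `m_s(x)` integrates
  `c` over the state's disc; the overlap matrix holds spatial cosine
  similarities and the zonation index is 1 − mean off-diagonal overlap
  over *occupied* states (≥0.5% of total mass — the numerical residue of
  an extinct state has no meaningful spatial pattern and would otherwise
  dominate the index).

## What the reference runs show — and what they do not

The reference scenarios reproduce, deterministically: the three-phase
response with heterogeneity rising ~5-fold into MRD; strictly ordered
resistance times across the four dosing strategies with the lowest final
burden under HCT→BRAF/MEKi; and adaptive therapy cycling (4 on/off cycles)
with a ~3× higher final zonation index than continuous dosing. These are
emergent properties of the calibrated reference set, not fitted curves:
the underlying rate constants are order-of-magnitude choices, so the
*ordinal* statements are the robust output, and absolute times carry no
more precision than the calibration targets themselves. The spatial
zonation signal in particular is weak in absolute terms (indices of order
1e-3) because the simulated tumor spans only ~10 grid cells and drug
administration is spatially uniform; vessel-localized drug and nutrient
sources would sharpen it and are out of scope.

## Limitations

* Phenomenological structural dynamics: the advection/diffusion profiles
  encode qualitative transition statements, not inferred rates.
* Uniform drug administration; no pharmacokinetic compartments, toxicity
  constraints, immune compartment, or genetic resistance.
* Single global explicit step (an IMEX treatment of stiff decay terms is
  the natural extension if stiffer parameter regimes are explored).
* First-order upwind transport adds numerical state diffusion of order
  `|Φ| Δy / 2`, which slightly accelerates rare-state leakage at coarse
  resolution; the reference conclusions are reported at 24 cells/axis.
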