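# Methods

## Model overview

The package simulates one multicellular spheroid (radius *R* = 0.5 mm) in a
spherical shell of culture medium (outer radius *H* = 6 mm) whose free
surface sits at atmospheric oxygen tension p_air = 160 mmHg. A single
irradiation of dose *D* is delivered at constant instantaneous dose rate Ḋ
over the window T = D/Ḋ (FLASH: 90 Gy/s, conventional: 0.075 Gy/s; no pulse
substructure). Everything downstream is deterministic; there is no
randomness anywhere in the model.

Units: oxygen tension in mmHg throughout, converted to concentration
(1 μM ≡ 0.77 mmHg) only where ROS production is driven by dissolved oxygen;
lengths in mm at the API (cm internally, matching cm²/s diffusivities);
dose in Gy, rates per second.

## Steady-state oxygen and the free anoxic core

Before irradiation the oxygen field solves

    D_sph (1/r²) d/dr(r² dps/dr) = Sm    (spheroid, where ps > 0)
    D_med (1/r²) d/dr(r² dps/dr) = 0     (medium)

with ps(H) = p_air, continuity of ps *and of dps/dr* at r = R, and — when
consumption outruns supply — an anoxic core r ≤ r0 where ps ≡ 0 and
consumption switches off (quiescent cells), its edge fixed by the smooth-fit
pair ps(r0) = ps′(r0) = 0.

Two modelling notes:

* **Interface condition.** Matching the *derivative* (not the flux
  D·dps/dr) is the stated model and the default. A consequence worth
  knowing: the medium diffusivity then cancels from the solution entirely —
  the medium is source-free, so its profile A + B/r is fixed by the slope at
  R and the value at H regardless of D_med. The physically conventional
  flux-continuity variant is available via `ModelParams(flux_continuity=True)`
  and produces a smaller core (faster effective medium transport).
* **No-core branch.** When the no-core solution already satisfies
  ps(0) ≥ 0, regularity at the origin (ps′(0) = 0) replaces the smooth-fit
  pair and r0 = 0. The transition is continuous: the core-existence
  indicator is the sign of the value mismatch at R evaluated at r0 = 0.

The closed-form shell solution is
ps(r) = Sm/(6 D_sph)·(r² + 2 r0³/r − 3 r0²), and r0 is found by Brent
root-finding on the value-matching condition at R (bracketed on [0, R];
the mismatch is −p_air < 0 at r0 = R, so a root exists whenever the no-core
branch fails). With p_air > 0 a (possibly very thin) oxygenated rim always
exists; full anoxia is only approached as p_air → 0, which parameter
validation rejects.

**Finite-difference oracle.** An independent conservative scheme solves
d/dr(r² D* p′) = r² f on a piecewise-uniform grid (2/3 of cells inside the
spheroid, nodes at 0, R, H), with the anoxic region handled as an obstacle
problem: the smallest clamp count whose solution is non-negative everywhere
is located by bisection (feasibility is monotone in the clamped-core size).
Under derivative continuity the equation is divided through by the local
diffusivity (D* ≡ 1, f = Sm/D_sph), which reproduces the stated interface
condition exactly; the flux variant assigns each face the diffusivity of the
region it lies in (the jump sits exactly on the node at R). The scheme is
empirically second order (measured orders ≈ 2.00 over 500→2000 cells) and
agrees with the closed form to ~1e-5 of p_air at 2000 cells.

## Radiolytic depletion

During the pulse, p(r,t) = max(ps(r) − S_ROD·t, 0): linear depletion at rate
S_ROD = L_ROD·Ḋ with no rediffusion (the pulse is far shorter than the
diffusion time across the spheroid). Inside the anoxic core nothing changes
— FLASH and conventional delivery are indistinguishable there.

A structural consequence the tests assert: because S_ROD scales with Ḋ while
T scales with 1/Ḋ, the oxygen lost per unit *dose* is rate-independent, and
so is the FLASH kill integral at fixed L_ROD. The conventional limit is
therefore modelled by setting S_ROD = 0 exactly (depletion at 0.075 Gy/s is
negligible against metabolism), not by letting Ḋ → 0.

## ΔROS kinetics

Only the FLASH-minus-conventional ROS difference matters for the paired
comparison, and it obeys the linear ODE

    dΔ/dt = cp·(p(r,t) − ps(r))_μM − k_ROS·Δ,    Δ(0) = 0,

solved in closed form for the piecewise-linear forcing (ramp until the local
depletion time t_d = ps/S_ROD, constant afterwards; `expm1` keeps the small-
k·t regime accurate). Δ ≤ 0 always, bounded by the full-depletion fixed
point −cp·ps_μM/k_ROS, exactly linear in cp, and identically zero whenever
cp = 0, S_ROD = 0 or ps = 0. An adaptive RK45 integration at rtol 1e-10
(split at the forcing kink) serves as the oracle.

k_ROS is treated as a first-order rate (s⁻¹): the ODE applies it linearly to
Δ, and the parameter table lists s⁻¹, although one text occurrence writes
μM⁻¹s⁻¹ — a source inconsistency resolved in favour of the linear form.

## Survival

* Conventional: ln SF = −α(ps)·D − β(ps)·D² (closed form; p ≈ ps throughout
  a conventional delivery).
* FLASH: ln SF = ∫₀ᵀ −[α(p(r,t)) + 2β(p(r,t))·Ḋ·t]·Ḋ dt
  (+ kr/(1 + e^{a + b·Δ[ROS](r,t)}) dt when the ROS term is on), by adaptive
  quadrature (scipy `quad`, epsabs 1e-10) with a forced breakpoint at t_d
  where the integrand's derivative jumps.
* OER orientation: OER(p) = (m·p + K)/(p + K), increasing from 1 (anoxic)
  to m = 2.6, half-saturation K = 1.9 mmHg, applied multiplicatively
  (α = α₀·OER). This is the orientation under which falling oxygen tension
  protects cells; the published formula rendering is typographically
  ambiguous, and the inverse orientation is available via
  `SurvivalParams(oer_inverted=True)` for sensitivity analysis.
* Analytic oracle: with p linear in t, OER(p(t)) = q0 + q1/(p + K) makes the
  kill integrand elementary; the piecewise antiderivative (ramp segment by
  substitution u = p, anoxic tail in closed form) validates the quadrature
  to ~1e-15 relative in the tests.
* The relief term can only raise survival (Δ ≤ 0 ⇒ term ≥ kr/(1+e^a) ≈ 0);
  ln SF is clipped at 0 with a RuntimeWarning should the credit ever exceed
  the kill (never observed with the shipped presets).

**Aggregation.** The "overall" surviving fraction is the volume-weighted
mean of SF(r) on the linear scale, ∫₀ᴿ SF·r²dr / ∫₀ᴿ r²dr, assuming uniform
cell density and counting the quiescent core cells as survivors. This was a
genuinely open choice (cell-number weighting with non-uniform density and
core exclusion are defensible alternatives); uniform density is the minimal
assumption, and because the core cells are the most radioresistant they
dominate the aggregate at high dose under any weighting that includes them.

**ROS integration window.** The relief term is integrated over the pulse
window [0, T] only, matching the kill model's bounds; post-irradiation ROS
dynamics are not credited. A quantitative consequence users should know:
with the shipped constants and T = 0.111 s, |Δ[ROS]| reaches only ~1e-4 μM
by beam-off (healthy cells), so b·Δ ≈ −0.02 and the relief contributes only
~1e-6 to ln SF. Within this window the tumor/healthy differential response
is therefore carried almost entirely by the oxygenation difference (Sm = 4.2
vs 3.2 mmHg/s ⇒ anoxic cores of 0.266 vs 0.128 mm), with the ROS term a
small correction in the stated direction. Crediting the minutes-long
post-pulse ROS deficit would require a beam-off forcing model (p frozen, not
further depleting) and is deliberately out of scope.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| R, H | spheroid / medium radius | 0.5, 6 | mm |
| D_sph, D_med | O₂ diffusivity, spheroid / medium | 2.2e-5, 2.7e-5 | cm²/s |
| p_air | tension at the air interface | 160 | mmHg |
| Sm | metabolic consumption (tumor / healthy) | 4.2 / 3.2 | mmHg/s |
| L_ROD | depletion per unit dose (measured) | 0.17 | mmHg/Gy |
| S_ROD | depletion rate (measured / historical) | 15.3 / 160 | mmHg/s |
| cp | ROS production coefficient (tumor / healthy) | 0.8e-4 / 1e-3 | 1/s |
| k_ROS | ROS clearance (tumor / healthy) | 0.8e-3 / 1e-2 | 1/s |
| α₀, β₀ | anoxic LQ coefficients | 0.44, 0.44 | 1/Gy, 1/Gy² |
| m, K | OER ceiling / half-saturation | 2.6, 1.9 | —, mmHg |
| kr, a, b | relief amplitude / offset / slope | 3e-2, 8, 200 | 1/s, —, 1/μM |

The `fig4-global-ros` preset carries the alternative global calibration
(cp = 4.5e-4, k_ROS = 0.5e-2) used to emulate the historical S_ROD = 160
depletion-only behaviour at the measured S_ROD = 15.3.

The historical conventional-rate depletion figure of 0.02 mmHg/s is
inconsistent with both published L_ROD values (1.78·0.075 ≈ 0.13,
0.17·0.075 ≈ 0.013) and is not reproduced; conventional delivery uses
S_ROD = 0 exactly.

## Numerical choices

* r0 root-finding: Brent on [0, R], xtol 1e-10 mm.
* Default closed-form output grid: 1000 uniform points on [0, R] + 500 on
  [R, H]; `solve_steady_oxygen(r_grid=...)` evaluates exactly on any grid.
* FD oracle: 2000 cells default, bisection over clamp counts (≤ log₂ n
  banded solves), complementarity satisfied up to one grid cell at the free
  boundary.
* Quadrature: `quad` with epsabs 1e-10, epsrel 1e-9, `points=[t_d]`.
* Survival aggregation grid: trapezoidal rule; `n_r` controls resolution
  (200 default in scenarios; the aggregate changes by < 1e-3 relative
  between 200 and 1000 points).
* Degenerate inputs: dose = 0 returns ln SF = 0 without quadrature; S_ROD=0
  or kr = 0 fall back to the constant-oxygen closed form exactly.

## What the tests do and do not establish

The suite verifies internal consistency (every closed form against an
independent numerical route), the stated qualitative physics (core
expansion, pointwise FLASH sparing, dose-trend of the sparing gap, the
tumor/healthy differential), and exact parameter-level facts
(0.17 × 90 = 15.3 mmHg/s; the sigmoid's near-zero value at Δ = 0). It does
not validate the model against experimental survival data: the published
figure-level curves are plotted, not tabulated, so no quantitative
figure-level comparison is asserted anywhere.

## Known limitations

* No vascular reoxygenation, no oxygen rediffusion during or after the
  pulse, no multi-fraction schedules, no pulse substructure.
* cp and k_ROS are cell-type constants; in reality they may depend on
  oxygen tension and dose rate.
* No repair kinetics, intertrack effects, or TCP/NTCP statistics; the LQ
  model is used as stated.
* The ROS relief is integrated over the pulse only (see above), which makes
  it a minor contributor at the shipped parameterization.
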