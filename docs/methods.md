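# Methods

This note documents the models implemented in `nanotwin`, the choices
made where the formulation was genuinely open, and what the bundled data
can and cannot validate.

## Stabilizer screening by interfacial Gibbs energy

Nanosizing raises the dissolution equilibrium constant according to
`GEE = Gms + Gmi = R T ln(K2/K1)`.  The surface term is the
Ostwald–Freundlich form `Gms = (2 γ V_m / r)(1 − C/r)` with
`C = 1.5 (V_m/N_A)^{1/3}`; the surface tension comes from the molecular
correlation `γ = −0.33 k_B T (N_A ρ / M_r)^{2/3} [ln(S_0/55.6) + 5]`,
where `S_0` is the aqueous drug solubility in mol L⁻¹ and 55.6 mol L⁻¹
is the molarity of pure water (for sparingly soluble drugs the bracket
is negative, so γ is positive).  The interfacial term is

    Gmi = 1.7 ε_API σ_API ρ_stab / (Δ σ_cross ε_cross m_stab) · γ V_m / r

with the cross segment diameter and energy from the Lorentz–Berthelot
rules (arithmetic / geometric means).  Pair-potential depths are stored
as `u/k` in Kelvin and converted to Joules through `k_B` at the point of
use.  Copolymer segment numbers follow the group-contribution
coefficients 0.052/g (ethylene oxide) and 0.037/g (propylene oxide),
weighted by the group mass fractions; the EO mass fractions of
Poloxamer-188 (0.8) and -407 (0.7) are config inputs with those
literature-typical defaults.

**Caveats.** As printed, the `Gmi` prefactor is not dimensionally
closed, and the molecular-layer spacing Δ and the API segment parameters
of Itraconazole are not tabulated anywhere we can reach.  `Gmi` is
therefore exercised by unit tests against direct scalar evaluation and
by its scaling laws (linear in γ and ρ_stab, inverse in `m_stab`), while
*ranking* uses the bundled reference `Gmi` records directly
(units-as-printed).  Equation-of-state property curves (density, heat
capacity vs temperature) are tabulated inputs behind a linear-in-T
interpolation contract, not recomputed.

## Wet-milling population balance

State: mass fractions over a geometric size grid, coarsest bin first
(20 bins spanning 5–0.05 μm by default, covering the case-study feed
D50 of 1.5 μm and product sizes ~0.3 μm).  Batch grinding is
first-order breakage; the resulting linear autonomous ODE system is
integrated with a stiff solver (`scipy.integrate.solve_ivp`, BDF,
rtol 1e-8 / atol 1e-12) using the constant lower-triangular system
matrix as the analytic Jacobian.  The matrix-exponential solution of
small systems serves as an independent oracle in the tests.

**Fragment discretization.** The kernels specify a cumulative fragment
distribution `B(x_i; x_j)` (mass fraction finer than `x_i` when a
particle of size `x_j` breaks).  The parent size of column `j` is taken
as the *lower edge* of bin `j`, so the coarsest fragment bin starts
exactly at the parent size and `B = 1` there; interior entries are
differences of `B` across bin edges and the finest bin absorbs the
sub-grid tail, making every column sum to exactly 1 (conservative by
construction).  The finest bin is a sink (`S = 0`), so mass never leaves
the grid and `Σw = 1` holds along every trajectory to 1e-8.

**Kernels.**

* *de Vegt*: `S(i) = c · E_kin E_fract P_y / (ρ V H x_i K_1C)` with
  `E_kin = W_m,kin ρ V_i` and
  `E_fract = 0.896 (π(1−ν²)/Υ)^{2/3} (0.0183 δ² (V_0/V_i)^{1/4})^{5/3}`
  evaluated at bin representative sizes (spherical volumes).  The
  combined size dependence is exactly `x^{0.75}`.  The cumulative
  fragment distribution is `(x_i/x_j)^{1.25}`; the exponent is exposed
  as a parameter defaulting to 1.25.  The printed rate mixes units
  (a volumetric fracture energy inside an energy ratio); it is
  implemented as written with the mismatch absorbed into `c`.  The
  mechanical constants of Itraconazole (hardness, yield pressure, K_1C,
  solubility parameter, elastic moduli, unit-cell volume, specific
  impact energy) are not tabulated in the source material; the defaults
  in `MaterialMechanics` are documented placeholders typical of a
  brittle organic crystal, and only the product `c ×` (constants) is
  identifiable — fits report the effective rate constant.
* *Austin*: `S = a (x/x_crit)^d`, exactly zero below the critical size
  `x_crit` (default: the finest grid edge, as no value is printed);
  `B = φ (x_i/x_j)^γ + (1−φ)(x_i/x_j)^β`.
* *Kapur*: `S = A x^k`, `B = (x_i/x_j)^e`.  With `e = 1.25` the
  fragment matrix is identical to de Vegt's.

**D50.** Median of the cumulative undersize curve by log-linear
interpolation between bin edges; a fully loaded single bin returns its
geometric-mean representative size.

**Fitting.** Maximum likelihood with i.i.d. Gaussian D50 errors reduces
to least squares on the D50 profile.  The scalar de Vegt constant is
minimized by bounded search on `log10 c`; Austin and Kapur use bounded
trust-region least squares from a fixed, seeded 8-point Latin-hypercube
multistart, plus (a) a data-driven start whose rate matches the observed
effective decay and (b) a warm start at the nested simpler family's
optimum — de Vegt ⊂ Kapur (`e = 1.25, k = 0.75`) ⊂ Austin (`φ = 1`).
The warm starts make the fitted error non-increasing with model
complexity, which is the structural content of the family comparison.
Kapur's prefactor is searched as the rate at 1 μm
(`A1 = A·(10⁻⁶)^k`, log-scaled in [1e-6, 1e-1] s⁻¹) because the raw `A`
spans ~10 decades as `k` varies and uniform starts land on zero-gradient
plateaus.  The feed PSD for fitting and simulation is lognormal with
the fed D50 (1.5 μm) and geometric SD 1.5 — a typical width for a
pre-milled crystalline feed; it is a config input.

**Fit metric.** All fits report `mse_percent = 100 · mean[(pred −
obs)²]` with D50 in μm.  Because milled D50 values are of order 1 μm
this reads like a percentage, and it reproduces the reported polynomial
fit quality of the case study exactly; the scale-invariant alternative
`100 · mean[err²]/mean[obs²]` is provided as `metrics.relative_mse`.

## Surrogate data augmentation

Default architecture 1–8–8–1: sigmoid hidden units (bounded, smooth
nonlinearity), ReLU output (regression with non-negative sizes), He
initialization (zero-mean normal, variance 2/fan-in).  Times are min-max
scaled to [0, 1] and targets scaled by the maximum D50.  The output bias
is initialized so the ReLU pre-activation is centered on the mean scaled
target — a dead output unit would never receive a gradient.  Training is
full-batch gradient descent (rate 0.05, 20 000 epochs, seed 42 by
default); the analytic backpropagation gradient is verified against
central finite differences in the tests, and training is bit-reproducible
given (data, seed, hyperparameters).  The three experimental replicates
are pooled as independent samples of one comminution profile.

The polynomial surrogate defaults to order 2 (the order is a flag).
The dense reference profile used for breakage fitting is the order-2
polynomial evaluated on a 61-point grid over 0–3600 s; the polynomial is
preferred over the ANN for this role because it is deterministic and
seed-free, and the two surrogates agree to ~5% on average over the
sampled span (the quadratic's endpoint bias dominates the tails).

## Spray drying

Classes: solids size intervals (the milled PSD lumped into ≤ 4 groups —
the solids size only routes bookkeeping weights, so a coarse lumping
loses nothing) × 5 quantile bins of a lognormal droplet-diameter law
(median 20 μm, geometric SD 1.8 — typical of a lab-scale two-fluid
nozzle; no values are printed in the source).  Per class, a dry-basis
moisture and an enthalpy state; the gas phase is a single well-mixed
zone (vapor mass + gas enthalpy).  Droplet surface area shrinks with the
remaining liquid volume (sphere geometry); the printed unit of the area
symbol (m² s⁻¹) is treated as a typo for m².

Drying rate: `Ṅ = f · (h/λ) A (T_v − T_wb)` with the wet-bulb
temperature from the adiabatic-saturation balance and saturation
pressures from the Magnus correlation (610.94 Pa, 17.625, 243.04 °C;
accepted −45…135 °C).  The relative drying rate `f` is a pluggable
hindrance law; the default is 1 above a critical moisture (1 kg/kg dry
basis, configurable) and linear below, so the rate vanishes on a dry
particle.  The heat-transfer coefficient is a config scalar
(1000 W m⁻² K⁻¹ default; no transfer correlation is in scope).  The
latent heat is referenced at 273.15 K and corrected by
`(Cp_vap − Cp_liq)(T − T_ref)` at the evaporation temperature, which
makes the enthalpy bookkeeping exact under constant heat capacities.

**Energy states.** The integrated states are enthalpies (droplet `H_p`,
gas `H_g`), with temperatures diagnosed from them.  Both conserved
totals — water and enthalpy — are then *linear* in the state vector, and
a linear multistep method preserves linear invariants exactly: the
closure audits (accumulation vs. cumulative inlet − outlet flows,
integrated as quadrature states by the same scheme) hold to Newton
tolerance (~1e-14 observed), not merely to truncation order.  With
temperature states the enthalpy closure was only O(h²).

Operating defaults follow the bundled case study (110 °C, 800 L/h air,
5 L chamber, 1.75 g solids in 9 mL water over 1 h).  The droplet
residence time defaults to chamber volume / air flow (22.5 s) but is an
independent input: it is held fixed in design-space scans, where air
temperature and flow vary only the gas-side balances (in a dryer of this
size the residence time is set by droplet inertia and geometry).  Under
the defaults the droplets dry fully well within the residence time;
responses in the transient regime are probed with shorter residence
settings.  Final moisture is reported per class and mass-weighted.

## Fixed-step BDF integrator

`bdf_coefficients(k)` solves the Vandermonde exactness conditions
(`Σ_l a_l (−l)^m = δ_{m,1}`, m = 0…k), giving (1, −1) at order 1 and
(3/2, −2, 1/2) at order 2.  Each step substitutes the BDF derivative
into the residual `F(t, x, ẋ) = 0` and solves for the new state by
modified Newton: forward-difference Jacobian (relative perturbation
1e-8), LU-factored and *reused across steps*, refreshed when the
iteration stalls; convergence is a component-wise relative residual
norm below 1e-10 (state derivatives span many orders of magnitude, so an
absolute norm is meaningless).  Startup is self-starting: the first
k − 1 values come from implicit-Euler substeps, refined enough
(`h²/m ≤ h^k`) not to spoil the nominal order — measured orders on a
linear decay problem are 1.00 / 2.01 / 3.00 for k = 1–3.  The
spray-drying path uses k = 2 with step = residence time / 400 (order 2
is L-stable, and the step resolves the hindered-drying knee; the
falling-rate transition can undershoot zero moisture by a step-local
error at coarser steps — moistures are floored at zero for reporting,
while the closure audits use the raw states so they remain exact).  The
milling path uses the adaptive library solver instead (the system is
linear and constant — an adaptive stiff solver with the exact Jacobian
is both faster and tighter); the fixed-step module is cross-checked
against closed forms and the library solver in the tests.

## Limitations

* The synthetic aspects of the study conditions — feed PSD width,
  droplet-size law, mill mechanics, heat-transfer coefficient, critical
  moisture — stand in for unmeasured quantities; passing tests show the
  balances, kernels and fitting machinery are correct and mutually
  consistent, not that these particular defaults describe any specific
  physical mill or dryer.
* The interfacial Gibbs-energy prefactor is implemented as printed and
  is exercised by scaling laws and scalar oracles only; stabilizer
  ranking rests on the bundled reference records.
* The milling balance is breakage-only (no agglomeration, no media
  hydrodynamics); the dryer gas phase is zero-dimensional with no
  atomization physics or glass-transition/crystallinity prediction.
* The de Vegt best-fit error against a smooth polynomial reference is
  ~0.06%; reported errors against other references depend strongly on
  the reference's shape, and single-parameter fits should be read as
  qualitative (initial/final size) descriptions, consistent with the
  family's intended use.
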