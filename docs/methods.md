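# Methods

## Model and assumptions

All four systems assume ideal dilute-solution mass action at fixed
temperature: activities equal concentrations, binding is rigid 1:1 (or
2:1 for the dimer) with a single site per partner, and no cooperativity,
allostery or kinetics enter anywhere. A multi-site protein with
independent identical sites can be treated by counting sites as the
"protein" concentration; genuinely cooperative systems (Hill-type
binding) are out of scope. Nonspecific binding is modelled in the
two-receptor system as an abundant weak receptor (large c_P′, large
K_D′), whose binding curve is effectively linear in the range where the
specific receptor saturates.

Thermodynamic conversions use K_A = 1/K_D and ΔG = R T ln K_D with the
numerical value of K_D in mol/L inside the logarithm (the usual
standard-state convention, which fixes the reference concentration at
1 mol/L). Defaults: R = 8.314 J K⁻¹ mol⁻¹, T = 298.15 K; both
overridable through `ThermoContext`.

## Numerics

**Quadratic systems.** Both closed forms are evaluated in the conjugate
(rationalized) form — e.g. [PL] = 2 c_P c_L/(S + √(S² − 4 c_P c_L))
rather than (S − √·)/2 — because the subtractive form loses all
significant digits when K_D is many orders below the totals. The
discriminant is clamped at zero against rounding. With these forms the
solvers stay accurate for K_D down to 10⁻¹⁸ mol/L and totals up to
10³ mol/L.

**Cubic systems.** Eliminating the complexes reduces each competition
system to g(x) = x(1 + c₁/(K₁+x) + c₂/(K₂+x)) − c_total, where x is the
free receptor (competing ligands) or free ligand (competing receptors).
g is strictly increasing with g(0) < 0 ≤ g(c_total), so (0, c_total]
brackets a unique root. We deliberately solve this monotone scalar
equation rather than the expanded cubic polynomial: the polynomial
coefficients span ~20 orders of magnitude at extreme parameters and the
explicit cubic formulas are numerically fragile, while the bracketed
form cannot escape or diverge.

**Root finder.** `solve_bracketed_root` combines Newton iteration
(analytic derivative where the caller supplies one, finite-difference
otherwise) with bisection: any Newton step that leaves the current
bracket, or a derivative magnitude below 10⁻³⁰⁰, falls back to a
bisection step, and the bracket is contracted every iteration, so
convergence is guaranteed for monotone functions. Tolerances: relative
1e-12 on the root variable, iteration cap 200; exceeding the cap raises
`NumericalFailureError` rather than returning a bad value. Equilibrium
states satisfy conservation to 1e-9 relative and reproduce each K_D
through mass action to 1e-6 relative (tested on 1000 random parameter
sets spanning 1e-9..1e-1 mol/L against pure-bisection oracles).

**Degenerate inputs.** Zero totals short-circuit to the exact empty
state (no division by a vanishing bracket). A zero competitor total
reduces each cubic system to the corresponding quadratic system
bit-for-bit within 1e-9 relative.

## Sweeps and display conventions

Sweep grids are log-uniform with endpoints included; the default is 300
points over 1e-9..1e-1 mol/L (the interactive slider span). The
default density is a rendering choice — curves of these systems are
smooth in log-x, and 300 points keep SVG paths visually continuous.

Relative y values count **monomer-equivalents**: the dimer contributes
2[P2]/c_P, so protein fractions always sum to one. Free-concentration x
axes exist only where one fixed free value determines the rest of the
state without a solve (homodimer: [P]; ligand binding and competing
receptors: [L]); the relative scale is not offered for competing
receptors, where the two proteins have different totals and a single
fraction denominator would mislead — absolute linear concentrations are
shown instead. Log-scale plots floor values at 1e-18 mol/L so zero
concentrations remain drawable.

Mass concentrations in tables use component-sum molar masses for
complexes (mass of PL = mass of P + mass of L); this is not a free
choice — any other convention violates conservation of total mass along
a sweep. Two-significant-figure display strings mirror the precision of
slider labels; full double precision is kept everywhere internally.

## Fitting

The objective is the unweighted sum of squared residuals on the y scale
the user selected (relative fraction or absolute concentration), with
the model curve evaluated through exactly the same code path as a sweep.
Maximum saturation is fixed at 1; there is no amplitude or baseline
parameter.

The grid emulates two-digit slider positions: mantissas 1.0–9.9 in
steps of 0.1 per decade over 1e-9..1e-1 mol/L (721 positions). Methods:

* **single pass** — exhaustive scan of the Cartesian product (global on
  the grid; limited to ≤3 free parameters);
* **two pass** — coarse scan at quarter-decade mantissas {1.0, 1.8,
  3.2, 5.6}, then every full-resolution position within one decade of
  the coarse winner. Equal to single-pass on unimodal landscapes; can
  land in the wrong basin on multimodal ones, which the result flags
  when the fine pass terminates at its window edge;
* **iterative** — coordinate descent to adjacent grid positions from a
  user guess; converges to the nearest local minimum;
* **continuous** — Nelder–Mead refinement in log₁₀-parameter space,
  bounded to the grid span, started from the single-pass optimum (or a
  supplied guess). The objective is normalized by its starting value so
  stopping tolerances are scale-free: absolute SSR magnitudes range from
  ~1e-16 (concentration-scale residuals) to ~1e-1 (fraction residuals).

Ties on the grid break toward the lexicographically smallest parameter
tuple for determinism. Quarter-decade coarse mantissas are a geometry
choice (≈ ×1.78 spacing) that keeps the true optimum within the fine
window for any landscape whose SSR basin is wider than half a decade.

On the packaged dimer dissociation series the grid methods give
K_D = 1.6 × 10⁻⁸ mol/L and the continuous refiner 1.56 × 10⁻⁸ mol/L.
On the packaged metal-binding isotherm the SSR minimum — confirmed by a
dense brute-force scan at mantissa step ~0.0002 — lies at 4.32 × 10⁻⁷
mol/L, one grid step below the 4.5 × 10⁻⁷ originally displayed for this
dataset; the original tool's coarser internal positions presumably could
not resolve the difference (SSR 0.0565 vs 0.0568). The tests therefore
pin the brute-force oracle, not the displayed value.

## Synthetic data

The generator samples any model curve on a log-uniform design and adds
seeded additive Gaussian noise on the observed scale, clipping fractions
to [0, 1]. That emulates the *shape* of titration data well enough for
recovery tests (12 points spanning two decades around K_D, noise sd
0.02 → median recovered K_D within 5% over 20 seeds) but deliberately
ignores real instrument error structure: heteroscedastic intensities,
counting statistics, x-axis (concentration) uncertainty, baselines and
saturation amplitudes. Passing recovery tests therefore demonstrate the
estimator's correctness under its own assumptions, not field accuracy on
arbitrary instruments.

## Limitations

* No cooperativity, no more than two competitors, no kinetics.
* The fitter reports no uncertainties; for confidence intervals or
  orthogonal-distance regression use a dedicated statistics package.
* Grid methods quantize results to two significant figures by design;
  use the continuous method when that matters.
* Parameter validation accepts 1e-18..1e3 mol/L but warns outside
  1e-9..1e-1, where plots and grid fitting are calibrated.
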