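# Methods

## Model and assumptions

The package models an enzyme-coated micro-disk electrode idealized as a
hemispherical film between the electrode surface (dimensionless radius
R = 1) and the film boundary (R = q = r₁/r₀). At steady state, with
Michaelis–Menten kinetics, the dimensionless substrate S and hydrogen
peroxide H satisfy

    S'' + (2/R)S' − γE·S/(1+αS) = 0,   S'(1) = 0,  S(q) = 1,
    H'' + (2/R)H' + γS·S/(1+αS) = 0,   H(1) = H(q) = 0.

Assumptions inherited from the model: steady state (no transient term),
spherically symmetric transport, constant diffusivities, enzyme uniformly
distributed, peroxide consumed instantly at both boundaries (Dirichlet
zeros), and no electrode-current conversion (the amperometric signal is out
of scope — no conversion formula is part of the model).

Two scaling conventions required choices:

- The peroxide concentration scale is set equal to the bulk substrate
  concentration (C\*\_H = C\*\_S). This is the unique choice under which the
  peroxide balance keeps the dimensionless form above with
  γS = k_cat·C_E·r₀²/(D_H·K_M).
- In the kinetic scheme the reverse-binding rate constant is named `k_rev`
  and enters the Michaelis constant as K_M = (k_rev + k_cat)/k₁; the
  constructor enforces this identity to 1e−12 relative when all three rate
  constants are supplied.

## Reference solver

Uniform grid, second-order central differences in the expanded form
S'' + (2/R)S' (the conservative (R²S')'/R² form would be equally valid; the
expanded form is the contract because it mirrors the governing equation as
written). The Neumann condition at R = 1 uses the second-order one-sided
3-point stencil; the outer Dirichlet row is exact.

The nonlinear substrate system is solved by damped Newton iteration with the
analytic banded Jacobian (rate derivative γE/(1+αs)²), initial guess S ≡ 1,
backtracking factor 0.5. If plain Newton fails, γE is ramped geometrically
from γE/100 over 8 continuation steps. Convergence is declared when either
the residual max-norm falls below `newton_tol` (default 1e−12) or a full
Newton step is smaller than `newton_tol` in the max-norm relative to the
solution scale. The second criterion matters on fine grids: the discrete
residual contains 1/h² factors, so its attainable floor in double precision
is ~64·ε/h² (≈3e−9 at n = 4001) even when S itself is converged to machine
precision; the step-size criterion sees through that floor.

The peroxide equation is linear given S: an interior-only tridiagonal solve
with the boundary zeros imposed exactly (solving the full system including
Dirichlet rows lets partial pivoting contaminate the boundary values at the
1e−11 level). Independently, the harmonic combination W = γS·S + γE·H
satisfies W'' + (2/R)W' = 0 — the rate terms cancel — so W = a + b/R with
b = γS·q·(S(1)−1)/(q−1) and a = γS·S(1) − b fixed by the boundary values.
`solve_coupled` computes H both ways and raises if they disagree beyond
1e−6 max-norm; the linear-solve H is the one exported. The same identity
provides a solver-independent diagnostic (`harmonic_invariant_residual`):
fit a + b/R to W by least squares and report the max deviation scaled by γS.

Oracles: the α = 0 limit has the exact solution
S = (C/R)[cosh(m(R−1)) + sinh(m(R−1))/m], m = √γE; the α → ∞ limit has
S = 1 + k(R²−q²)/6 + (k/3)(1/R − 1/q), k = γE/α, flagged invalid when it
predicts S ≤ 0. Grid-refinement studies against the α = 0 oracle confirm
the expected O(h²) convergence (log–log slope 2 ± 0.2 over
n ∈ {251, 501, 1001, 2001}).

Default n = 4001 for reference runs; 1143 (q = 5) and 1251 (q = 1.5) when
emulating the study datasets.

## Closed-form approximations

The MADM, HAM and HPM expressions are transcriptions of the published
closed forms, evaluated exactly as printed. Both MADM and HAM S-profiles
are quadratics in R satisfying all four boundary conditions identically;
both are first-order perturbative in a = γE/(1+α), so for the strongly
saturated study cases (a ≈ 0.3, q = 5) they disagree with the reference
solver at O(1) — this is reported, not corrected. HAM's convergence-control
parameter h defaults to −1 (the standard convention; the value behind the
published comparison is unstated). At h = −1 and case-1 parameters the HAM
formula yields S(1) = −139/101 ≈ −1.376: out of physical range, returned
as printed with the interpretation left to the caller.

The HPM result is kept in its own scaled variables (CSP, CHP) because the
printed scaling definition is typographically ambiguous; converting it to
S/H would require guessing the intended scale. For CHP the grouping
½(qρ − ρ² − q + ρ) = ½(q−ρ)(ρ−1) was adopted — the only reading of the
printed term sequence that vanishes at both film boundaries as the peroxide
must.

## Surrogate

A 1–H–1 multilayer perceptron (default H = 60; 181 trainable parameters):
log-sigmoid hidden units, linear output (targets are order-1 and unscaled),
input affinely mapped from [1, q] to [−1, 1]. Initialization is
Nguyen–Widrow over the scaled range, deterministic given a seed.

Training is full-batch Levenberg–Marquardt on the training-set
sum-of-squares: solve (JᵀJ + μI)δ = Jᵀe with the analytic Jacobian of the
per-point errors; an accepted step (training MSE decreased) multiplies μ by
0.1, a rejected one by 10 and retries, aborting at μ = 1e10. Stops on
gradient tolerance (max-norm of the MSE gradient ≤ 1e−7), μ overflow, 1000
epochs, or 6 consecutive validation-MSE increases; the weights at the best
validation MSE are returned. Data are split 70/15/15 train/validation/test
uniformly at random per seed. (The published split "75/15/15" sums to 105%;
70/15/15 is the self-consistent reading and the convention of the tooling
that reports such splits.)

On the study profiles the trained surrogate reaches best-validation MSE of
1e−13–1e−10 in 10–200 epochs (well under a second per run); the LM step
verifiably interpolates between gradient descent (large μ) and Gauss–Newton
(small μ), and accepted steps never increase the training MSE.

## Metrics

MAD, TIC, NSE and ENSE = 1 − NSE follow the printed formulas. Notably the
NSE denominator is centred on the mean of the *predictions*, not the
observations; that printed form is the default and the standard
observation-centred NSE is available via `nse_form="observation-mean"`.
Degenerate denominators (all-zero series for TIC, zero-variance denominator
for NSE) raise rather than return a silent zero. Error histograms use
uniform right-open bins with the final bin closed. The stability study
retrains over consecutive seeds (default 20) on the same dataset and
reports min/mean/std of MSE, MAD, TIC and ENSE computed against the
reference solution on the full grid (whether published stability tables
used the full grid or only test points is unstated; the full grid is the
default and a flag selects the test subset).

## Study conditions

Two built-in scenarios: thick film (q = 5, 1143-point grid) and thin film
(q = 1.5, 1251-point grid), each with cases (α, γE) ∈ {(100, 30), (50, 20),
(10, 10)} and γS = γE (equal diffusivities, D_H = D_S; γS per case is not
published separately). The nominal dataset domains "0 to 5" and "0 to 1.5"
are read as R ∈ [1, 5] and R ∈ [1, 1.5] — the only reading consistent with
the boundary conditions and with the published comparison table spanning
R = 1.0–5.0 with S = 1 at R = 5.

The reference datasets are noise-free solver output; the synthetic setting
therefore exercises interpolation of a smooth 1-D function, not robustness
to measurement noise, model misspecification or experimental drift. Passing
tests show the solver/surrogate/metrics machinery is correct and stable, not
that the surrogate would perform identically on laboratory data.

## Known limitations

- The published comparison table's interior values are not reproducible
  from the printed model: evaluating the printed MADM formula at case-1
  parameters gives S(1) = 21/101 ≈ 0.208 versus the tabulated 0.7025, and
  the saturated-limit bound contradicts the tabulated numerical S(1); the
  tests therefore anchor on boundary identities and limit oracles instead
  of interior table values.
- Transient operation, adaptive meshing and electrode-current conversion
  are out of scope.
- The LM implementation is dense and full-batch: appropriate for ~181
  parameters and ~1e3 points, not for large networks.
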