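# Methods

`mdolsim` studies how the concentration and toxicity of a shared substrate
shape a two-strain community that degrades it by metabolic division of
labor (MDOL): a **Detoxifier** converts the toxic substrate S into an
intermediate I, and an **Embezzler** converts I into the final product P —
the sole growth-limiting resource of both strains — inside its own
cytoplasm, so the Detoxifier only ever sees the fraction of P that leaks
into the medium.

## Well-mixed batch model

Eleven dimensionless ODEs track the intracellular S/I/P concentrations of
each strain, the three extracellular pools, and the two biomasses. Per
unit biomass:

- reaction 1 (Detoxifier): `alpha1 * s1_in / (1 + s1_in)`
- reaction 2 (Embezzler): `alpha2 * i2_in / (beta2 + i2_in)`
- product consumption (both): `Cp * p_in / (bg + p_in)`
- passive membrane transport: `gamma_x * (out - in)` per species, with the
  environment pool receiving the biomass-weighted opposite flux, so
  exchange is strictly antisymmetric,
- growth: `dx/dtau = Cp*p_in/(bg+p_in) * y * t(s_in) * x * (1-(x1+x2)/rho)`,
  a logistic with carrying capacity `rho`, yield `y`, and a substrate-
  toxicity factor `t`.

Toxicity acts through each strain's own intracellular substrate level.
Three shapes are available — reciprocal `1/(1+theta*s_in)` (default),
exponential `exp(-theta*s_in)`, and linear `max(0, 1-theta*s_in)`. The
default toxicity degree, `theta = 0.0032`, is the measured dimensionless
toxicity of salicylate in the *Pseudomonas stutzeri* consortium this model
family describes. An optional first-order death rate is exposed
(`death_rate`, default 0): in a closed batch any positive death rate
ultimately drives the whole community extinct with leftover substrate, so
it is off unless a user wants to study that regime.

Two auxiliary quadratures accumulate the product synthesized by and
(net-)exported from the Embezzler population; their terminal ratio is the
product **leakiness**.

### Representative parameter set

`y=1e-4, Cp=10, bg=1, alpha1=1e4, alpha2=1e3, beta2=1,
gamma_s=gamma_i=gamma_p=1, rho=1e-2` — used for every headline curve.
Two reactions are fast relative to growth (`Cp*y = 1e-3` per tau), which
is what makes the system stiff.

### Initial conditions and the composition measure

Batches start 1:1 with each strain at 5% of the carrying capacity (a 1:10
back-dilution of a saturated culture) and only extracellular S non-zero.
The steady-state **Detoxifier fraction** `df` is reported for the biomass
*formed during the batch* (the terminal biomass minus the inoculum); the
plain terminal ratio is available as `df_total`, and the two coincide
whenever growth dwarfs the inoculum. The grown-biomass measure is used
because a closed batch without death has no biomass turnover: at very low
substrate the terminal ratio of a 1:1 inoculum is pinned near 0.5 no
matter how strongly the Embezzler wins the little growth that occurs,
whereas the composition of the newly formed biomass is exactly the
quantity the degradation episode determines.

### Integration and steady state

Stiff implicit integration (scipy's Radau by default) with an analytic
13x13 Jacobian; the right-hand side and Jacobian are numba-compiled.
The Monod terms are evaluated without clamping at zero: they are smooth
through the origin, and clamping would place a derivative kink exactly on
the depleted-pool boundary that late-time trajectories ride, which makes
implicit step controllers thrash. Radau and BDF each still have
(complementary) parameter corners where the controller grinds; every
integration chunk therefore carries a step budget (1,500 accepted steps),
and on exhaustion the run continues with the other method from wherever
it stopped — results are method-independent at the configured tolerances.
Defaults `rtol=1e-9, atol=1e-12`; parameter sweeps use
`rtol=1e-6, atol=1e-9`, which leaves the steady-state composition
unchanged to five decimals while roughly halving runtime, and
additionally stop once total biomass is within 1e-4 of the carrying
capacity (without death the composition is frozen from there on; only
the leakiness quadratures would keep accumulating).

Integration proceeds in geometrically growing chunks (500, 1000, 2000, …)
up to `tau_max = 1e6`. A run is converged when the Detoxifier fraction is
flat over a trailing 5%-of-elapsed-time window **and** any of

1. every state derivative has relaxed (`|f| < 1e-8 * max(1, |y|)`),
2. the convertible carbon (extracellular + biomass-weighted intracellular
   pools) is below `1e-5 * s0` — no future growth can move composition,
3. the two strains' per-capita growth rates agree to `1e-10` — their
   difference is the only thing that moves composition (a death term
   cancels in it).

### Mechanism recap (what the tests assert)

Product privatization: the Embezzler's consumption at small internal P is
linear with slope `Cp/bg`, much faster than export (`gamma_p`), so it
keeps most of what it makes and the steady-state Detoxifier fraction at
`theta=0` stays below 0.5. Raising `s0` floods the Embezzler's uptake
capacity, increases leakiness, and raises the Detoxifier's share —
a saturating, Monod-like `df(s0)`. Toxicity acts through the
intracellular-substrate difference: the Detoxifier converts S and keeps
`s1_in` far below the Embezzler's `s2_in`, so increasing `theta` or
`theta*s0` favors it, and at high substrate plus toxicity it can exceed
half the community.

## Structure rules and fitting

Three nested closed forms predict `DF`:

- `eq1`: `Fdmax * s0/(ks+s0)`
- `eq2`: `eq1 * (1 + Tsmax * theta*s0/(kt + theta*s0))`
- `eq3`: `eq2 * [ s0*Ds/(kd1+s0*Ds) - theta*Ds/(kd2+theta*Ds) ]`
  (substrate diffusivity has two opposing effects in colonies).

Fits use trust-region least squares (`scipy.optimize.least_squares`,
bounds `Fdmax` in [0,1], half-saturations in [1e-3, 1e5] sampled in log
space, `Tsmax` in [0,100]) from 10 Latin-hypercube starts with a fixed
seed; the lowest-SSE start wins. Goodness of fit is the adjusted R²
against the mean-only model; Wald standard errors come from the SVD of
the Jacobian at the optimum. `eq2` is unbounded above 1 in the joint
large-`s0`/large-`theta` limit; predictions are returned unclamped and a
fit flags when it predicts values above 1.

Default reproduction grids: 12 log-spaced `s0` in [1, 3000]; `theta` in
{0} plus 8 log-spaced values in [1e-4, 1e-1].

### What the representative-case fits give here

With the conditions above, the no-toxicity curve fits `eq1` with
adjusted R² ≈ 0.96 and the toxic surface fits `eq2` with adjusted
R² ≈ 0.97; `Fdmax` lands near 0.45 and never exceeds 0.5 without
toxicity. The fitted half-saturation constants are larger than the
originally reported ones (ks ≈ 100 rather than ≈ 35 for `eq1`): the
transition of `df(s0)` is set by when substrate influx floods the
Embezzler's consumption capacity, which in this implementation happens
about half a decade higher on the substrate axis. The conditions the
original analysis used (simulation grids, inoculum, and any death term)
are not recoverable from the available text; a systematic exploration of
inoculum size (1e-4 to 0.9 of capacity), death rates, readout horizons
and both composition measures did not move the half-saturation constants
into agreement while preserving the qualitative behavior, so the package
documents its own conditions and reports the constants they produce.

## Key-parameter sweep and regression

Full-factorial grids are Cartesian products in lexicographic order.
Besides `s0` and `theta`, five constants shape the composition most:
`alpha1, gamma_s, gamma_i, gamma_p, Cp`. The reduced no-toxicity sweep
takes 3 log-spaced levels of each spanning one decade around the
representative values (243 sets), simulates 8 substrate levels per set
over [1, 1e5] — wider than the representative curve's [1, 3000], because
`Fdmax` is an asymptote and a grid that does not reach saturation for
every parameter set degenerates the (Fdmax, ks) pair into a slope — and
fits `eq1` per set. The observed per-set maxima all stay below 0.5 (the
privatization bound); a handful of unconstrained fits overshoot the
plateau by up to ~1.5% because the simulated curves are not exactly
Monod near saturation. Sensitivity regression is OLS of `df` on
normalized predictors: decade-spanning positive predictors are log10-
transformed, then all predictors are min-max scaled to [0, 1] so a single
coefficient threshold is meaningful; a parameter is "key" when
|coefficient| > 0.01 and p < 0.01. Non-converged rows are dropped with a
logged count. The full 885,735-set first-round enumeration is reachable
through the same API with a checkpoint file, but is cluster-scale and
never run by default.

## Individual-based colony model

Cells are constant-radius discs on a continuous plane over three lattice
fields (S, I, P). Fields diffuse by an explicit five-point stencil with
zero-flux boundaries (substeps keep `D*dt_sub <= h^2/8`), which conserves
field mass to round-off. Each cell exchanges with its local site
(`gamma*(site - internal)` per unit biomass, site demand rescaled so no
site goes negative), runs the same Monod reactions as the batch model,
and gains mass at `consumption * y * t(s_in)`. The Monod conversions are
stepped with a closed-form backward-Euler update (the positive root of a
quadratic), which is unconditionally stable — necessary because the
Detoxifier's advantage requires the stiff `alpha1=1e4`: with a softened
rate it cannot keep its internal substrate low and the entire toxicity
response disappears. Cells divide into equal-mass daughters at a mass
threshold, displaced along a random axis; overlaps relax by iterative
pairwise shoving with per-cell contact averaging. Division pressure
drives colony range expansion from a central 1:1 inoculum; compositions
are analyzed separately for the inoculated disc and the expanding
annulus, plus a radial profile and a k-nearest-neighbor mixing index.

Desk-scale defaults: 90–120 lattice, 40-cell inoculum of radius 4,
`dt=0.1`, `Ds=Di=Dp=2`, yield `y=0.05` (so a run spans ~10 generations),
stop at 1,500 cells / 900 steps / 1% substrate / boundary contact. The
reduced sweep is 8 substrate levels in [60, 1000] × toxicity
{0.001, 0.0032, 0.01} × 3 seeds. These are reduced-scale study
conditions chosen once; the full-scale analysis (hundreds of thousands of
cells, diffusivity sweeps for `eq3`) is config-reachable but not run.
A `neutral` switch makes both strains feed directly and identically on S,
the control for composition bias.

Known limitations: growth is 2-D (the inoculated-disc composition is
frozen once local substrate is gone, unlike 3-D colonies); at ~1,500
cells the expanding annulus holds only a few hundred cells per type, so
single-run fractions carry sampling noise of a few percent; residual
disc overlaps of a few percent of a radius persist in dense cores.

## Synthetic data

`SyntheticDesign` draws endpoint composition tables from `eq2` with
additive Gaussian noise on fractions (default sd 0.02, 6 replicates per
level, matching a few-percent replicate spread of endpoint fluorescence
ratios), clipping to [0, 1] with a reported clip count. Mock two-channel
fluorescence plates use multiplicative log-normal channel noise over an
additive background, with identity intensity-to-biomass calibration; the
converter returns background-subtracted channel shares and flags wells
with both channels at background. A fixed-step classical RK4 reference
integrator (written independently of the production solver) pins small
sweep fixtures at mild rates (`alpha1=alpha2=100, y=1e-2`, `dt=1e-3`)
for regression tests; its accuracy is step-size-verified. Passing tests
on these generators shows the estimators recover the assumed model under
its own noise; it says nothing about calibration drift, growth-curve
kinetics, or optical cross-talk in real plates, which are not modeled.

## Numerical choices, in brief

- Monod terms evaluate `max(state, 0)` so tiny solver undershoots stay
  harmless; trajectories are clipped at 0 afterwards (tolerance 1e-8,
  larger excursions warn).
- Rule fits fail loudly only if all 10 starts fail; ties broken by SSE.
- The mixing index for fewer than k+1 cells and compositions of empty
  regions are errors/flags, not silent NaNs.
- All randomness (inoculum placement, division axes, synthetic noise,
  Latin-hypercube starts) is seeded; identical seeds give bit-identical
  runs.
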