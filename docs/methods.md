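# Methods

## The model

`fruitflux` simulates water and sugar transport between a peach fruit and
the parent plant during late (stage III) growth, when a fruit gains or
loses water hour by hour while steadily importing sugar. The network has
five vascular/apoplastic compartments — pedicel xylem (px) and phloem (pp),
fruit xylem (fx) and phloem (fp), and the fruit apoplast (fa) — plus the
fruit symplast (fs), which is the storage compartment whose content defines
fresh-weight change.

Water potential decomposes as Ψw = Ψp + Ψπ with the osmotic term
Ψπ = −R·T·C. Two closure hypotheses make the vascular system tractable:

1. the fruit xylem and fruit phloem are locally equilibrated in *water*
   potential (Ψw,fx = Ψw,fp), and
2. xylem sap is effectively solute-free, so the xylem pressure potential
   equals the xylem water potential (Ψp,fx = Ψw,fx; likewise in the
   pedicel, Ψp,px = Ψw,pp).

Flows between conduits (pedicel→fruit xylem, pedicel→fruit phloem,
fruit xylem→apoplast) are pressure-driven, `U = K·ΔΨp`, with bulk
conductances K (g h⁻¹ MPa⁻¹) for the pedicel paths and an area-specific
conductivity k (g h⁻¹ MPa⁻¹ cm⁻²) times the fruit surface area for the
in-fruit path. Flows across membranes (phloem→apoplast, apoplast→symplast)
are water-potential-driven, `U = k·A_f·ΔΨw`. Sugar moves by Münch mass
flow into the fruit phloem (`S = M_S·C_pp·U_pp_fp`), by a lumped
diffusion-plus-active efflux into the apoplast (`S = M_S·v_fp_fa·A_f·C_fp`;
apoplastic sucrose is taken as negligible because invertase splits it
rapidly), and by active hexose uptake into the symplast
(`S = M_H·v_fa_fs·C_fa·DW`), where the uptake coefficient is *net* of
respiration — the gross coefficient and the respired fraction are not
separately identifiable from growth data, so only the net product is
modelled.

At each hour the vascular compartments are assumed to hold no net storage
(quasi-steady state). Conservation of water (two laws) and of sugar (two
laws) then gives a 4×4 *linear* system in the unknowns
(Ψp,fp, Ψp,fa, C_fp, C_fa). Everything else — the six pairwise water
flows, three sugar flows, the lateral xylem↔phloem transfer
U_fx_fp = U_px_fx − U_fx_fa — follows algebraically.

Units are gram-based throughout: g, h, MPa, cm², K, and concentrations in
mol per g of solution. With sap density taken as 1 g cm⁻³ the gas constant
is numerically 8.314 (MPa g mol⁻¹ K⁻¹). Molar masses: sucrose 342.30,
hexose 180.16 g mol⁻¹.

### Girdled variant

Girdling severs the phloem below the pedicel. The model imposes
U_pp_fp = U_fp_fa = 0, which forces every sugar flow to zero and reduces
the system to a water-only 2×2 in (Ψp,fx, Ψp,fa) with the chain
U_px_fx = U_fx_fa = U_fa_fs + T_fa. The girdled state reports C_fp = C_fa = 0
and the fruit "phloem" pressure at the xylem value, purely so that control
and girdled records share one shape. The test suite verifies that this
reduced solver is the K_pp_fp, k_fp_fa, v_fp_fa → 0 limit of the full one.

### Two solution routes

The numeric route assembles the 4×4 matrix (fixed unknown ordering
Ψp,fp, Ψp,fa, C_fp, C_fa; fixed row ordering: vascular water, fruit water,
phloem sugar, fruit sugar) and LU-solves it, batched over hours.
`closed_form.py` independently eliminates the system symbolically with
sympy once per session and lambdifies the four solution expressions. The
two routes agree to better than 1e-8 relative on randomized valid inputs
(checked at n = 1000 in the suite); conservation residuals at solved states
are at machine precision (asserted < 1e-9 g h⁻¹ for water, < 1e-12 for
sugar).

Negative solved concentrations are physically impossible; they signal
boundary conditions outside the regime the parameters can support (e.g. a
phloem pressure gradient pointing out of the fruit). Such states are
returned as-is with a `NonPhysicalSolutionWarning` and a `nonphysical`
flag — never clipped — so that calibration can penalize them instead of
being silently biased.

## Diurnal drivers

Three windowed drivers are flat at a night base between 18.00 and 06.00 h
and follow a 24 h-period sine inside 06.00–18.00 h, reaching their extreme
at 12.00 h and rejoining the base continuously at both edges (a 12 h
window with the extreme a quarter-period after the window opens is the
only sine satisfying these constraints):

| driver | night base | midday extreme |
|---|---|---|
| pedicel water potential (MPa), all treatments | −0.5 | −1.3 |
| pedicel phloem sugar (g g⁻¹), 30 leaf-to-fruit | 0.12 | 0.28 |
| pedicel phloem sugar (g g⁻¹), 5 leaf-to-fruit | 0.08 | 0.24 |
| symplast water potential (MPa) | ψ_night (per scenario) | 1.2·ψ_night |

Fruit transpiration per unit area is a full-day sinusoid between
2.74×10⁻⁴ g cm⁻² h⁻¹ (05.00 h) and 2.63×10⁻³ (17.00 h), multiplied by the
fruit surface area. Temperature defaults to a constant 293.15 K (a July
mean; it only enters through R·T, a < 5% effect across plausible diurnal
ranges) and can be overridden with an hourly series.

The six scenario presets are C30_94, C30_95, C5_95 (control) and G30_94,
G30_95, G5_95 (girdled); C/G × leaf-to-fruit ratio × campaign year. Their
night symplast potentials are the calibrated values −1.7, −1.7, −1.3,
−0.89, −1.1 and −0.91 MPa respectively.

### Allometry and the reference fruit

'Suncrest' allometries link diameter, weight and area:
W = 0.003·D^2.58 (W in g, D in mm) and A_f = 6.049·W^0.601 (cm²); dry
weight is 10% of the daily mean fresh weight and is held fixed within a
simulated day, as is the surface area (an hourly-geometry mode exists
behind a flag; over a ~2% diurnal weight excursion it changes weights by
< 0.2%).

Absolute fruit size is needed to run the model but is not directly quoted.
The calibration, however, is quoted in *dual* form for the three
conductivities — k (per cm²) and the bulk K = k·A_f at the reference fruit
(5 leaf-to-fruit control, 1995): 0.74/0.011, 0.076/0.0011 and 0.64/0.0091.
The ratios pin the reference surface area, A_f = mean(K/k) = 68.9 cm²,
i.e. W ≈ 57.3 g. The heavy-crop-load preset weight is therefore *derived*
from these duals at run time. An earlier working choice of 100 g was
rejected because it breaks the midday flow pattern (no xylem→phloem
transfer) and inflates the night recirculation fraction to ~33%; the
derived 57 g reproduces all of the reference statistics simultaneously.
The light-load (30 leaf-to-fruit) preset is 130 g, a representative late
stage-III size for a lightly cropped tree; only the inflow shares and dry
gain are quoted for that treatment and both are insensitive to ±30 g.

## Day simulation and diagnostics

A day is 24 independent steady-state solves (Δ = 1 h by default). Fresh
weight integrates the symplast water + sugar inflow with a left-Riemann
rule, anchored so that W(09.00 h) equals the supplied initial weight;
hours before the anchor are filled by backward accumulation. Refining the
time step shifts the quadrature by O(Δ).

`summarize_flows` reports:

- **inflow shares** — positive parts of U_pp_fp and U_px_fx integrated
  over the day; phloem/(phloem+xylem). Backflow hours contribute to
  separate outflow tallies, never negative inflow. Undefined ratios
  (zero denominators) are `None`, not 0.
- **night recirculation** — mean over 18.00–06.00 h of
  (−U_fx_fp)/U_pp_fp: the share of phloem-entering water diverted
  laterally into the fruit xylem.
- **relative variations** — |(max−min)/max| for the symplast water inflow
  (which changes sign during the day) and |(max−min)/min| for the sugar
  uptake and the two fruit sugar concentrations (strictly positive).
- **dry-mass gain** — the sugar uptake integrated over 24 h.

`classify_pattern` labels an hour from the signs of (U_px_fx, U_fx_fp):
(+, −) is the night pattern (xylem inflow, phloem→xylem transfer), (−, +)
the midday pattern (xylem backflow, xylem→phloem transfer), anything else
transitional. `input_sweep` re-runs the day with the sugar driver scaled
as a whole (both base and extreme) or with only the midday minimum of the
pedicel water potential scaled, probing deeper water stress at an
unchanged night base.

At the calibrated parameters the control heavy-load day shows xylem
backflow during 10.00–14.00 h, night phloem→xylem transfer of ~20% of the
phloem inflow, buffered fruit sugar concentrations (relative variation
~1.4 against 2.0 in the pedicel input) and near-linear symplast sugar
accumulation — the regulated-uptake behaviour the model was built to
expose.

## Calibration

Parameters (2 pedicel conductances, 3 conductivities, 2 sugar-transport
coefficients, plus one night symplast potential per scenario) are
estimated by minimizing two objectives simultaneously: the mean hourly
fresh-weight RMSE over the control scenarios (RMSE_C) and over the girdled
scenarios (RMSE_G). Each observed series is anchored at its own measured
weight at 09.00 h, so absolute size is not a free parameter. Nonphysical
solutions add a penalty of 100 g × (fraction of flagged hours); an
unsolvable candidate scores 10⁶ on both axes.

The Pareto front is located with NSGA-II: binary tournament on
(rank, crowding distance), simulated-binary crossover (η = 15, p = 0.9),
polynomial mutation (η = 20, p = 1/n), population 100 × 200 generations by
default, fully seeded. Positive parameters are searched in log10 space
(their plausible ranges span decades; default bounds are ±2 orders of
magnitude around the reference values), potentials linearly in
[−3, −0.2] MPa. The reported solution is the front member minimizing
(RMSE_C + RMSE_G)/2, tie-broken by RMSE_C then lexicographically; the
returned front also folds in the best mean-RMSE individual seen anywhere
in the run, which makes the selected objective monotone in the evaluation
budget for a fixed seed.

`refine` optionally polishes the selected solution with bounded
trust-region least squares on the stacked hourly weight residuals of all
series. The genetic search locates the basin; the least-squares step
sharpens it far beyond mutation resolution. On noise-free synthetic data
generated at the reference parameters, a reduced budget (population 60,
60 generations, ~10⁴ model days, well under a minute on one CPU) followed
by refinement recovers every parameter essentially exactly; the suite
asserts the pedicel conductances within 10% and the symplast potentials
within 0.1 MPa.

## Synthetic observations

The original LVDT gauge recordings were never published, so
`synthetic_data` generates series with the study's structure: per scenario,
a fixed number of replicate fruits monitored for a total number of
fruit-days (defaults 3/31, 5/29, 7/29 for the 1994 treatment and the
corresponding smaller 1995 counts). Control/girdled fruits are forward
simulations at chosen "true" parameters from a lognormally jittered
initial weight (10% CV, unit median — fruit-to-fruit size heterogeneity);
detached fruits lose exactly the transpiration integral. Gaussian gauge
noise (default sd 0.02 mm — an artifact choice; the real gauge error is
unreported) is applied on the *diameter* scale, so weight noise inherits
the allometry's curvature.

What the generator does **not** emulate: gauge drift and thermal
artifacts, day-to-day growth across a multi-day monitoring window (a
fruit's days are independent one-day realizations around the same base
weight), weather-driven transpiration variability, and any deviation of
real drivers from the idealized sinusoids. Passing recovery tests
therefore show that the estimation machinery is correct and the model
identifiable under its own assumptions — not that field data of this
shape would constrain the parameters equally well.

## Numerical choices and edge cases

- Unknown and row ordering of the linear system are fixed (documented
  above) so tests are bit-stable; a fixed seed reproduces every stochastic
  result bitwise.
- Driver evaluation wraps hours modulo 24 (drivers are 24 h-periodic by
  construction); only non-finite hours are rejected.
- The singular-system error carries the condition number and, in day runs,
  the offending hour.
- Quiescent inputs (equal potentials, no sugar, no transpiration) solve to
  the exact equilibrium with all flows zero and classify as transitional.
- Girdled states hold exact (bitwise) zeros for phloem and sugar flows.
- CSV artifacts serialize floats at 17 significant digits and are parsed
  in round-trip mode, so write→read is exact.

## Limitations

Sorbitol (roughly a third of peach phloem sap sugar) is ignored, which
underestimates phloem pressure somewhat; apoplastic sucrose and its
inversion kinetics are lumped into one efflux coefficient; there is no
explicit lateral xylem–phloem conductance (the equal-water-potential
hypothesis stands in for it); compartments store nothing within an hour;
and a simulated day does not feed back onto geometry unless the
hourly-geometry flag is set. Multi-day growth trajectories and within-fruit
spatial gradients are out of scope.
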