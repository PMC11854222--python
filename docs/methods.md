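# Methods

## The model

`lfrelease` models the release of lactoferrin (Lf, an ~80 kDa iron-binding
glycoprotein) from freeze-dried calcium-alginate microparticles immersed in a
release medium. The particle population is lumped into three well-mixed
compartments:

* the **solid** polymer matrix, volume `V_s` (cm³, constant over a run);
* the **adsorbed liquid** inside the swollen particle, volume `V_ads(t)`;
* the external **bulk** medium, volume `V_b(t)`.

Two phenomena run simultaneously and are coupled through the swelling state:

**Swelling.** Liquid uptake is first order toward a plateau,

    dV_ads/dt = k_v (V_max − V_ads),     dV_b/dt = −dV_ads/dt,

with closed form `V_ads(t) = V_max − (V_max − V_ads0) e^(−k_v t)`. The
analytic curve is used as the integrator oracle and as the fitting model for
weight data. `V_max` is constructed as `V_h · W_s` (hydration capacity ×
dry charge mass), the only dimensionally consistent combination of the
configured parameters.

**Two-film transfer.** Protein moves solid → adsorbed liquid → bulk through
two resistances in series. With phase concentrations `C_s = n_s/V_s`,
`C_ads = n_ads/V_ads`, `C_b = n_b/V_b` and the partition constant
`H_Lf = C_s/C_ads` at solid/liquid equilibrium:

    J_sl = β_sl (C_s/H_Lf − C_ads)        [solid-liquid film]
    J_ll = β_ll (C_ads − C_b)             [liquid-liquid film]

    dn_s/dt   = −J_sl · V_ads
    dn_ads/dt = (J_sl − J_ll) · V_ads
    dn_b/dt   = +J_ll · V_ads

The adsorbed-phase balance is sometimes written with the two flux terms
sign-swapped (`+J_ll − J_sl`); that variant leaks `2(J_ll − J_sl)V_ads` from
the total mole balance whenever the fluxes differ, and forward simulation
under the reference parameters inflates the inventory by 10²–10⁴× within
minutes. The conserving form is therefore the default; the sign-swapped
variant is kept behind `mode="as_printed"` purely to demonstrate the defect.

**Dissolution.** An optional event time `t_dissolve` models acid-driven
particle disintegration: at that instant all protein still in the solid and
adsorbed phases transfers to the bulk and the state is frozen (fluxes and
swelling stop). The event time is a user input; the model contains no
degradation kinetics that would predict it.

**Equilibrium.** Without dissolution the system relaxes to `C_ads = C_b = c`,
`C_s = H_Lf·c`, with

    c = N_total / (H_Lf·V_s + V_max + V_b∞),   V_b∞ = V_b0 + V_ads0 − V_max,

so the terminal bulk fraction is `V_b∞ / (H_Lf·V_s + V_max + V_b∞)` — about
0.9976 for the reference 40 cm³ batch. This closed form is the oracle for
long-horizon simulations.

## Parameters

| name | meaning | unit | reference values |
|---|---|---|---|
| `k_v` | swelling rate constant | 1/min | 0.00335 |
| `V_h` | hydration capacity | cm³/g | 3.82 |
| `W_s` | dry particle charge | g | 0.023–0.025 |
| `V_s` | solid-phase volume | cm³ | 2.4e-4 |
| `V_ads0` | initial adsorbed volume | cm³ | 1e-8 (sentinel) |
| `V_b0` | initial bulk volume | cm³ | 20 or 40 |
| `H_Lf` | partition constant C_s/C_ads | – | 1.3–1.6e-4 |
| `β_sl` | solid-liquid transfer coefficient | 1/min | 41–3000 |
| `β_ll` | liquid-liquid transfer coefficient | 1/min | 0.48–1.01 |
| `n_s0` | initial protein charge | mol | 0.012/75 000 etc. |
| `mw_lf` | molar mass for g↔mol conversion | g/mol | 75 000 |

Notes on the reference values, taken as given inputs:

* `V_s = 2.4e-4 cm³` for ~0.024 g of dry solid implies an implausibly high
  solid density; it is nevertheless used verbatim since only the product
  `H_Lf·V_s` (≈3e-8 cm³) enters the equilibrium, where it is negligible
  against `V_max ≈ 0.1 cm³`.
* `V_ads0 = 1e-8 cm³` is a strictly positive sentinel that keeps
  `C_ads = n_ads/V_ads` finite at t = 0; it is configurable.
* `mw_lf = 75 000 g/mol` follows the reference parameter sheets even though
  lactoferrin is usually quoted at ~80 kDa; it only rescales mole amounts.
* Water density 1.0 g/cm³ converts adsorbed mass to adsorbed volume.

## Dynamics under the reference parameters (what to expect)

Transfer is much faster than swelling (`β_ll ≈ 1/min` vs `k_v ≈ 0.003/min`),
and the solid/adsorbed exchange is faster still (effective rate
`β_sl·V_ads/(H_Lf·V_s)` ≈ 10⁶/min). Consequences worth knowing:

* The release fraction rises with time constant ≈ 1/β_ll (minutes), then
  **overshoots** its equilibrium slightly and relaxes back over the swelling
  timescale: the growing adsorbed phase re-absorbs protein at equal
  concentration. `n_b` is therefore *not* monotone in general; it is monotone
  when swelling is fast relative to transfer. `V_ads` is always nondecreasing.
* `β_sl` is structurally near-unidentifiable from release curves — the
  exchange it governs equilibrates orders of magnitude faster than anything
  observable. `fit_release` frees only (`β_ll`, `H_Lf`) by default;
  three-parameter fits are available but `β_sl` comes back essentially
  unconstrained (recovery within an order of magnitude is the realistic
  expectation).
* `H_Lf` is identifiable from *noiseless* curves through a small (≈10⁻³ in
  fraction units) early-time lag, but is swamped by measurement noise of
  SD 0.008; only `β_ll` is robustly recoverable from noisy data.

## Numerics

* Integrator: `scipy.integrate.solve_ivp` with LSODA (stiffness-switching;
  the solid/adsorbed exchange makes the system stiff). Relative tolerance
  1e-9 by default; absolute tolerances scaled per component to the initial
  magnitudes (volumes ~`V_b0`, moles ~`N_total` ≈ 1.6e-7).
* The conserving right-hand side cancels algebraically, so conservation
  errors are rounding-level (~1e-15 relative in practice, against acceptance
  bands of 1e-6 for moles and 1e-9 for volume).
* Fitting: bounded least squares (`scipy.optimize.least_squares`, trust
  region reflective) in log10-parameter space — the transport parameters span
  four orders of magnitude. Bounds `[1e-8, 1e6]` 1/min for the β's and
  `[1e-8, 1]` for `H_Lf`. Multi-start from a seeded Latin hypercube
  (`scipy.stats.qmc`) of 8 points by default; starts whose forward simulation
  fails are discarded with a warning. Finite-difference step 1e-3 in log10
  space: the default square-root-of-eps steps sit below the ODE-integrator
  noise floor and stall the flat `H_Lf` direction. Termination tolerances
  1e-12, max 500 evaluations per start. Identical seeds give bit-identical
  results.
* The k_v fit uses the analytic swelling curve (no ODE solves), converting
  weights via `V_ads(t_i) = (W(t_i) − W(0))/ρ_water`. Default
  `v_max_policy="fixed_from_plateau"` pins `V_max` at the observed plateau;
  `co_fit` frees it. On the packaged weight table the plateau policy gives
  `k_v ≈ 0.0030 1/min`, within the ±15% band around the reported 0.00335 —
  the original fitting protocol (weighting, V_max handling, points used) is
  not fully specified, and plausible protocols scatter over roughly
  0.0028–0.0035 1/min.
* Objective: unweighted SSE on the measured quantity by default; optional
  1/sd² weighting.

## Synthetic data

The release curves that drive estimation are only available as plots in the
source study, so the generator stands in for them: it forward-simulates the
conserving model under a batch configuration, samples the requested
observable (release fraction or bulk concentration), and adds additive
Gaussian noise — homoscedastic, SD 0.008 in fraction units, the study's
stated replicate scatter. Release fractions are clipped to [0, 1] after
noising (they are physical fractions). Swelling weights get a noise-free
t = 0 point (the dry-mass reference is weighed once). Default release
sampling times (0.5–2880 min, log-like spacing) resolve both the fast
transfer transient and the slow swelling tail.

The generator does **not** emulate: the aliquot-withdrawal/return sampling
protocol, particle-size variability, heteroscedastic assay noise, or any
pH-dependence. Passing recovery tests therefore demonstrate estimator
correctness under the model's own assumptions, not robustness to those
real-data effects.

Problem sizes used by the test suite and the acceptance script: 20 sampling
times per release curve, 50 (suite) or 25 (script) noisy replicates for the
recovery study, 100 random parameter draws for the closed-form sweep, and a
51-point log grid for conservation and sensitivity checks.

## Scalar metrics

* Swelling degree `Q(%) = (M_sw − M_d)/M_d × 100`; the packaged weight table
  endpoints give 362.9%, while the packaged swelling-degree table reports
  326.7 ± 5.9 at 48 h — the two come from distinct experiments and are both
  kept as fixtures.
* Encapsulation efficiency `EE(%) = (m − m_f)/m × 100`.
* `summarize_batches` uses the sample (n−1) standard deviation — it
  reproduces the reported across-batch SD of 8.3 (population SD gives 7.4).
  The exact mean of the five packaged EE values is 65.76%, which rounds to
  65.8; the commonly quoted 65.7 reflects truncation of the same number.

## Known limitations

* Lumped compartments: no spatial diffusion profile, no particle-size
  distribution, no pH-dependent rate laws.
* `V_b` decreases as the particle swells; the experimental aliquot-return
  protocol is not modelled.
* The dissolution event is instantaneous and must be supplied by the user.
* Time series mixing hours and minutes are handled at ingest only (`t_h`
  columns converted to minutes); all internal times are minutes.
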