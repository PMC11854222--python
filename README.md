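# lfrelease

Swelling and release kinetics of lactoferrin-loaded calcium-alginate
microparticles.

Alginate microgels are a standard carrier for labile proteins: they gel
gently with Ca²⁺, protect the cargo, and release it when the particle swells
or dissolves in the target environment. `lfrelease` implements the lumped
compartment model used to describe that process for freeze-dried particles
charged with lactoferrin (Lf), together with parameter estimation from
time-series data, the bench-top descriptive metrics, and a synthetic-data
generator for testing the whole estimation pipeline. It is aimed at
controlled-release and biomaterials groups who want a reproducible,
scriptable version of this analysis instead of a one-off optimizer run.

## The model

The particle is three well-mixed compartments — solid matrix (volume `V_s`),
adsorbed liquid inside the particle (`V_ads`), external bulk (`V_b`) — with
two simultaneous phenomena:

**First-order swelling**

    dV_ads/dt = k_v (V_max − V_ads),      dV_b/dt = −dV_ads/dt

**Two-film mass transfer** (concentrations `C_i = n_i / V_i`, partition
constant `H_Lf = C_s/C_ads`):

    J_sl = β_sl (C_s/H_Lf − C_ads)
    J_ll = β_ll (C_ads − C_b)

    dn_s/dt = −J_sl V_ads,   dn_ads/dt = (J_sl − J_ll) V_ads,   dn_b/dt = +J_ll V_ads

plus an optional instantaneous dissolution event that sends all remaining
protein to the bulk. Without dissolution the system relaxes to the partition
equilibrium, bulk fraction `V_b∞ / (H_Lf V_s + V_max + V_b∞)`.

Scalar metrics: swelling degree `Q(%) = (M_sw − M_d)/M_d × 100` and
encapsulation efficiency `EE(%) = (m − m_f)/m × 100`.

Three reference batch configurations (40 mL stirred, 20 mL stirred, 20 mL
stagnant) and the reference swelling/EE tables ship as packaged fixtures;
see `docs/methods.md` for the full parameter table, numerical choices and
known limitations (including why `β_sl` is near-unidentifiable and why the
bulk inventory can transiently overshoot its equilibrium).

## Worked example

```python
import numpy as np
from lfrelease import simulate_release, equilibrium_state
from lfrelease.synthetic import load_batch_config, study_fixtures
from lfrelease.fitting import fit_kv

b1 = load_batch_config("batch1")          # 40 mL stirred bulk
t = np.array([0.0, 1, 5, 30, 300, 2880])  # minutes
traj = simulate_release(b1, t)
for ti, f in zip(t, traj.release_fraction):
    print(f"t={ti:6.0f} min   released {100*f:6.2f} %")
eq = equilibrium_state(b1)
print(f"equilibrium bulk fraction: {eq.n_b/b1.n_total:.4f}")

weights = study_fixtures().swelling_weights
res = fit_kv(weights, dry_mass=float(weights.y[0]))
print(f"fitted k_v: {res.estimates['k_v']:.5f} 1/min")
```

prints

```
t=     0 min   released   0.00 %
t=     1 min   released  63.64 %
t=     5 min   released  99.36 %
t=    30 min   released  99.98 %
t=   300 min   released  99.85 %
t=  2880 min   released  99.76 %
equilibrium bulk fraction: 0.9976
fitted k_v: 0.00295 1/min
```

Release is transfer-limited at minute scale (β_ll ≈ 1/min), briefly
overshoots, and settles at the analytic partition equilibrium of 99.76%
released — almost the entire charge, because the partition constant retains
only a ~3·10⁻⁸ cm³ equivalent volume in the solid against a 40 cm³ bulk. The
fitted swelling constant from the packaged weight table is 0.00295 1/min
with the plateau-pinned `V_max` policy.

The same steps are available from the shell:

```sh
lfrelease simulate-release --config batch1 --t-end 2880 --out run1
lfrelease fit-swelling --data weights.csv --out fit1
lfrelease metrics --ee 55.4,62.6,78.1,67.9,64.8
```

Every CLI run writes a `manifest.json` (inputs, seed, options, version)
sufficient to re-execute it.

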