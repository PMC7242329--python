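# ciliaflow

Hydrodynamic self-organization of ciliary beating on a bronchial epithelium.

In human airways, mucus is propelled by carpets of beating cilia, and
effective clearance needs the beat directions to organize over distances far
beyond a single cell.  `ciliaflow` implements a two-dimensional hydrodynamic
model of this self-organization for people studying mucociliary transport and
active carpets: the mucus film is a depth-averaged Newtonian flow over a
periodic, hexagonally tiled epithelium, driven at ciliated elements by a
constant-magnitude force density **f**<sub>c</sub> and damped everywhere by a
periciliary-layer (PCL) friction **f**<sub>v</sub> = −κ**U**.  Each ciliated
element's beat angle θ<sub>c</sub> relaxes toward the local element-averaged
flow direction θ<sub>f</sub> at fixed angular speed Ω (a streamwise-alignment
rule with dead band θ₀ and optional rotational noise).  The flow is solved
with a D2Q9 BGK lattice-Boltzmann scheme with Guo forcing.

Two non-dimensional parameters control the physics:

* **ciliary density** φ = S<sub>c</sub>/S, the ciliated area fraction;
* **interaction length** λ = √(μ<sub>m</sub>/κ)/D, the hydrodynamic
  screening length of one element's forcing in units of the element size D
  (physiologically λ ≈ (δ<sub>p</sub>/D)·√(μ<sub>m</sub>/μ<sub>p</sub>), so
  λ grows with mucus viscosity);

plus a Reynolds number Re = ρ<sub>m</sub>DU₀/μ<sub>m</sub> ≪ 1, with
U₀ = |f<sub>c</sub>|/κ the force-balance velocity scale.

Emergent regimes are classified from the steady flow by the polarization
𝒫 = |mean(U/|U|)| and the integral length Λ of the vorticity
autocorrelations: *poorly aligned* (𝒫 < 0.9, Λ < 1.5), *swirly*
(𝒫 < 0.9, Λ ≥ 1.5) and *fully aligned* (𝒫 ≥ 0.9), in which the mean
transport speed obeys |Ū| = (|f<sub>c</sub>|/κ)·φ.  The emergent vortex
scale Λ′ (first zero of the ensemble-averaged vorticity autocorrelation, in
units of D) scales like Λ′ ≈ λ^1.5·φ.

## Worked example

Physiological estimates (single-cilium force F = 6×10⁻¹¹ N, n<sub>c</sub> =
250 cilia on a cell of radius 2.5 µm, PCL 10 µm thick with water-like
viscosity, mucus viscosity 10⁻² Pa·s, mature epithelium φ = 0.7):

```sh
$ ciliaflow physio --mu-m 1e-2 --phi 0.7
{"lambda": 1.5811388300841898, "fc_N_per_m2": 381.97186342054874,
 "kappa_Pa_s_per_m2": 9999999.999999998, "U0_m_per_s": 3.819718634205488e-05,
 "mean_velocity_m_per_s": 2.6738030439438412e-05}
```

λ ≈ 1.58 is the lower end of the physiological range (mucus ~10× more
viscous than the PCL); the predicted clearance speed ≈ 2.7×10⁻⁵ m/s is the
fully-aligned transport velocity |Ū| = (f_c/κ)·φ, close to measured
tracheal clearance rates.  Replacing mucus by culture medium
(`--mu-m 1e-3`) gives λ = 0.5, below the alignment transition — the model's
account of why ciliary order degrades when mucus is washed off.

A coupled simulation on a reduced 40×40-element periodic box:

```python
from ciliaflow import simulate_run, spawn_run_seeds

res, rec, prof = simulate_run(0.55, 4.0, domain_elements=(40, 40),
                              seeds=spawn_run_seeds(1, 1000), omega_factor=2.0)
print(rec.label, round(rec.polarization, 3))   # fully_aligned 0.995
```

At φ = 0.55, λ = 4 the carpet self-organizes from random beat angles into a
near-unidirectional flow (𝒫 ≈ 0.99) whose mean speed is 0.55·U₀ to within
a percent — the analytic force balance.  At (φ, λ) = (0.1, 1) the same call
yields a poorly organized state (𝒫 ≈ 0.1) whose localized recirculations
span a few element diameters (ensemble swirl size ≈ 3.5 D on a
60×60-element box).

## Layout

| module | contents |
| --- | --- |
| `ciliaflow.geometry` | periodic hexagonal tiling, rasterization, ciliated assignment |
| `ciliaflow.lbm` | D2Q9 BGK solver, Guo forcing, lattice-unit mapping |
| `ciliaflow.alignment` | streamwise-alignment rule, noise, run-to-steady loop |
| `ciliaflow.statistics` | 𝒫, vorticity, autocorrelations, Λ, Λ′, regime classifier |
| `ciliaflow.experiments` | phase diagram, swirl ensembles, scaling fit, virtual bronchus, physiology |
| `ciliaflow.io` | YAML configs, HDF5 snapshots, deterministic fixtures |
| `ciliaflow.cli` | `ciliaflow run / sweep / swirls / bronchus / physio` |

See `docs/methods.md` for the model assumptions, numerical choices,
termination rules and known limitations.
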