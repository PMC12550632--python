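# cfmavidity

Cell-avidity analysis for centrifuge force microscopy (CFM) detachment
assays, with a built-in stochastic simulator of multivalent bond rupture.

## The problem

A CFM spins a microscope inside a benchtop centrifuge, applying the same
body force to every cell adhered to a functionalized surface while a
camera counts the cells remaining in each frame.  One run yields hundreds
to a thousand single-cell unbinding events; sweeping the rotor speed
applies a programmable force ramp.  Turning those per-frame counts into
binding kinetics requires a chain of models, which this package implements
as a tested, reusable library for experimentalists analysing CFM (or
similar bulk force-spectroscopy) data:

- **Force model.**  A cell of diameter *d* and density ρ_cell in medium of
  density ρ_med at radius *r* and angular speed ω feels
  `F = m_eff · r · ω²` with `m_eff = (π/6) d³ (ρ_cell − ρ_med)`.
  Defaults (10 μm, 1.07 g/mL, 1.00 g/mL) give 0.36 pN under gravity and
  ~482 pN at 3000 rpm.  `design_ramp` builds stair-step rpm schedules
  realising a target linear loading rate (pN/s).
- **Detachment curves.**  Robust (median-windowed) normalization of noisy
  per-frame counts into fraction-bound curves, plus the *adhesion
  frequency* — the fraction of cells surviving a 2-minute, ~0.3 pN
  gravity interval that sheds unbound cells.
- **Population lifetime.**  Curves under a ramp follow a stretched
  exponential `f(t) = 1 − g + g·exp(−(t/τ)^β)`; τ is the population
  lifetime, β absorbs the force-accelerated off-rate, g the detachable
  fraction.
- **Universal curve.**  With Poisson(λ)-distributed bonds per cell,
  `AF(λ) = 1 − e^(−λ)` and `τ(λ) = k·λ + x₀`.  Fitting (k, x₀) across
  trials collapses data from all surface densities onto one curve; *k*
  measures per-bond strength under the ramp without knowing receptor
  densities.
- **Off-rate vs force.**  A binned hazard estimate
  `ΔN / (N_available · Δt)` per force bin.
- **Simulator.**  Exact (inverse-cumulative-hazard) sampling of
  load-sharing parallel Bell bonds under gravity-plus-ramp schedules,
  emitting count traces with realistic detection jitter — used to
  validate every stage and to calibrate bond kinetics to a target *k*.
- **Imaging.**  Synthetic dual-channel (target/monolayer) frame stacks
  and a deterministic difference-of-Gaussians cell counter.

See `docs/methods.md` for model details, defaults, and limitations.

## Worked example

Simulate eight trials across a bond-number sweep, fit each, and fit the
cross-trial universal curve:

```python
import numpy as np
import cfmavidity as cfm

cell = cfm.CellParams()          # 10 um, 1.07 g/mL in 1.00 g/mL medium
print("gravity force:", round(cfm.gravity_force(cell), 2), "pN")

protocol = cfm.design_ramp(4.0, f_max_pn=480.0, t_start_s=120.0,
                           hold_duration_s=240.0, cell=cell)
points = []
for i, lam in enumerate(np.linspace(0.3, 4.5, 8)):
    trial = cfm.simulate_trial(cfm.BondModel(lam=lam, k0=5e-4, f_beta_pn=25.0),
                               protocol, cell=cell, n_cells=1000, seed=i)
    af = cfm.adhesion_frequency(trial.count_trace, t_centrifuge_s=120.0)
    curve = cfm.build_detachment_curve(trial.count_trace, t_origin_s=120.0)
    fit = cfm.fit_stretched_exponential(curve)
    print(f"lam={lam:.2f}  AF={af.adhesion_frequency:.3f}  "
          f"tau={fit.tau_s:6.1f} s  beta={fit.beta:.2f}")
    points.append(cfm.TrialPoint(af.adhesion_frequency, fit.tau_s))

uc = cfm.fit_universal_curve(points)
print(f"universal curve: k={uc.k:.1f} s, x0={uc.x0:.1f} s")
```

Output:

```
gravity force: 0.36 pN
lam=0.30  AF=0.279  tau=  37.7 s  beta=4.57
lam=0.90  AF=0.596  tau=  43.5 s  beta=3.14
lam=1.50  AF=0.744  tau=  51.6 s  beta=2.69
lam=2.10  AF=0.838  tau=  59.7 s  beta=2.48
lam=2.70  AF=0.929  tau=  68.6 s  beta=2.58
lam=3.30  AF=0.967  tau=  76.2 s  beta=2.47
lam=3.90  AF=0.972  tau=  86.0 s  beta=2.69
lam=4.50  AF=0.982  tau=  96.3 s  beta=2.85
universal curve: k=15.0 s, x0=31.0 s
```

Adhesion frequency tracks `1 − e^(−λ)` (measured 0.28 vs 0.26 expected at
λ = 0.3; 0.98 vs 0.99 at λ = 4.5), lifetimes grow linearly with mean bond number,
and the fitted slope k ≈ 15 s per bond recovers the per-bond strength the
simulator was given.  The positive offset x₀ reflects the force a single
bond must accumulate before rupture becomes likely.

The same stages are exposed on the command line:

```sh
cfm force --rpm 3000                  # 481.804 (pN)
cfm design-ramp --rate-pn-s 4 --out ramp.csv
cfm simulate --lam 2 --n-cells 1000 --seed 1 --out trace.csv
cfm detach --counts trace.csv         # adhesion frequency JSON
cfm fit-curve --counts trace.csv      # stretched-exponential fit JSON
cfm run --config run.yaml             # full pipeline -> report.json
```

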