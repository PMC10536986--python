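# cholbench

Quantitative quality benchmarking of binary POPC–cholesterol membrane
simulations against NMR and X-ray scattering observables.

Molecular dynamics force fields disagree substantially on how cholesterol
orders, thickens and slows a phosphatidylcholine bilayer. `cholbench` is
aimed at force-field developers and membrane simulators who want a single
number — per observable and per cholesterol concentration — for how far a
simulation sits from experiment. It works on *tabulated* observables
(order-parameter tables, electron density profiles, MSD curves); it never
parses trajectories itself.

## What it computes

**C–H bond order parameters.** S_CH = ⟨3 cos²θ − 1⟩/2 for each C–H bond
of the palmitate and oleate chains, with equivalent CH₂/CH₃ hydrogens
averaged (the forked oleate-C2 pair is kept separate, ordered by
magnitude). Simulation and experiment are linearly interpolated onto a
common (carbon × mol % CHOL) grid, subtracted, and reduced to a relative
deviation in % per concentration; deviations within the experimental
uncertainty of ±0.02 are masked in the signed deviation maps.

**X-ray form factors.** F(q) = ∫ (ρ(z) − ρ_w) cos(qz) dz from the electron
density contrast; the positions of the first two minima of |F(q)| — a
scale-free fingerprint of bilayer dimensions — are tracked versus
cholesterol content. Peak-to-peak bilayer thickness is twice the distance
from the (5-point-smoothed) electron density maximum to the bilayer
center. Area per phospholipid is the box area over the phospholipids per
leaflet, with block-averaged standard errors; the partial area of
cholesterol follows as dA_tot/dN_chol.

**Lateral diffusion.** D_PBC comes from a straight-line fit of the
leaflet-drift-corrected MSD over the 10–100 ns lag window (slope = 4D).
Because periodic boundaries bias membrane diffusion, D_PBC measured at
several box edges L is extrapolated with the periodic Saffman–Delbrück
model in the immobile-interleaflet-friction limit,

    D_PBC(L) = D_∞ + (k_B T)/(4π μ_m h) [ ln(L/L_SD) − ξ − (2π/L_SD) W(L, H) ],

where L_SD = μ_m h/(2 μ_f) is the Saffman–Delbrück length,
ξ = ln(2π^{3/2}/Γ(3/4)²) − γ_E ≈ 1.4265 is the exact square-lattice
hydrodynamic constant, and W(L, H) is the water-slab lattice sum with
H = (L_z − h)/2 the half water-layer thickness (see `docs/methods.md`).
The two free parameters — the infinite-system D_∞ and the membrane shear
viscosity μ_m — are exactly the quantities comparable to experiment.
Uncertainties are propagated by refitting 10,000 Gaussian-perturbed
replicas of the D_PBC series.

**Cumulative quality.** The relative deviations from the two acyl chains,
the two form-factor minima and the diffusion coefficient stack into one
cumulative deviation profile per force field.

## Worked example

Fit the finite-size model to a synthetic D_PBC(L) series generated with
known ground truth (D_∞ = 10 µm²/s, μ_m = 80 mPa·s) at the three box
sizes of a small/medium/large simulation set, with 3 % noise:

```python
import numpy as np
from cholbench import MembraneGeometry, mc_error_propagation
from cholbench.synthetic import gen_finite_size_series

geom = MembraneGeometry(L_z=9.0, h=3.9, T=298.0, mu_f=0.3228)
series, truth = gen_finite_size_series(
    d_inf=10.0, mu_m=80.0, geom=geom,
    L_list=[4.4, 9.0, 18.1], rel_noise=0.03, seed=42,
)
for L, d, derr in series.points:
    print(f"L = {L:5.1f} nm   D_PBC = {d:.3f} +/- {derr:.3f} um^2/s")
result = mc_error_propagation(series, n=10000, seed=42)
print(f"D_inf = {result.d_inf:.2f} +/- {result.d_inf_err:.2f} um^2/s")
print(f"mu_m  = {result.mu_m:.1f} mPa s   (MC median {np.median(result.mu_m_samples):.1f})")
print(f"L_SD  = {result.l_sd:.0f} nm")
```

prints

```
L =   4.4 nm   D_PBC = 3.603 +/- 0.108 um^2/s
L =   9.0 nm   D_PBC = 4.184 +/- 0.126 um^2/s
L =  18.1 nm   D_PBC = 5.162 +/- 0.155 um^2/s
D_inf = 10.25 +/- 0.62 um^2/s
mu_m  = 75.9 mPa s   (MC median 76.0)
L_SD  = 459 nm
```

The apparent diffusion in a 4.4 nm box is nearly three times slower than
the infinite-system value — the finite-size correction is not a small
refinement — and the noisy 3-point series still recovers the generating
parameters within the propagated uncertainty.

The same analyses are scriptable from the shell:

```
cholbench synth fss --seed 1 --out demo/
cholbench thickness --density demo/density.csv
cholbench diffusion --msd s.xvg m.xvg l.xvg --L 4.4 9.0 18.1 \
    --Lz 8.9 8.6 8.5 --h 3.9 --mc 10000 --seed 1
cholbench quality --config study.yaml --out report/
```

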