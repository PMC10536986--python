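# Methods

This note records the models, conventions and numerical choices behind
`cholbench`, and what the synthetic fixtures do and do not establish
about real data.

## Units and containers

All internal quantities use one canonical system: nm, nm⁻¹, ns, µm²/s,
mPa·s, K and e/nm³. The hydrodynamic formulas mix Boltzmann energies
(Joules) with viscosities and lengths, and a single unit system with
converters only at the I/O boundary prevents silent unit errors. The
slope-to-diffusion conversion is the only place a numeric factor appears:
a 2D MSD slope in nm²/ns equals 4D, and 1 nm²/ns = 1000 µm²/s, so
D [µm²/s] = slope × 250.

## Order parameters

S_CH values are stored signed. ¹³C NMR experiments measure magnitudes
only; datasets flagged `unsigned` are compared through |S_CH|. Hydrogens
of freely rotating CH₂/CH₃ groups carry the same order parameter in both
simulation and experiment, so they are averaged to one value per carbon.
The group error is the *mean* of the member errors, not mean/√n: the
hydrogens are not independent measurements. The two oleate-C2 hydrogens
lack rotational averaging; their values are kept separate ("forked"),
ordered by decreasing magnitude so that the larger branch of a simulated
fork is compared with the larger experimental branch. Averaging is
idempotent: a forked pair and already-averaged carbons pass through
unchanged. Headgroup and glycerol-backbone bonds share the chain tag
`headgroup-glycerol`, are never averaged, and are excluded from the
acyl-chain quality metrics by default.

## Interpolation and the deviation metric

Observables measured at a handful of cholesterol concentrations are
linearly interpolated onto a dense grid, by default 0–46 mol % in 1 %
steps: the common span of typical simulated (0–47 mol %) and measured
(0–60 mol %) series. Interpolation is exact at the knots and refuses any
query outside the measured span — extrapolated deviations would be
artifacts. Surfaces use separable linear interpolation on the regular
(coordinate × concentration) grid; when per-concentration z-grids or
carbon supports differ, profiles are first resampled onto the
intersection of the supports and dropped points are logged. No smoothing
splines or uncertainty-aware interpolation: with ≲6 concentrations,
anything beyond piecewise-linear invents structure.

The relative deviation at concentration c is

    dev(c) = mean over coordinate of |sim − exp| /
             mean over coordinate of |exp| × 100 %

(for scalar tracks, pointwise |sim − exp|/|exp| × 100). Normalizing the
mean absolute difference by the equally reduced mean |exp| keeps the
ratio of two like quantities; it is invariant under joint rescaling of
both inputs and reduces to the pointwise relative error for uniform
scalings. A zero normalizer raises an error naming the concentration
rather than emitting an infinite deviation. Signed deviation surfaces
keep the convention that negative values mean the simulation is more
ordered (S_CH too negative) than experiment, and carry a mask marking
|Δ| ≤ 0.02, the estimated experimental uncertainty of the order
parameters.

The density-profile deviation averages over the full z range of the
profiles; the membrane-region restriction is configurable through the
coordinate grid argument but is not the default.

## Density profiles, thickness and form factors

Profiles are smoothed with a centered 5-point moving mean (the window
shrinks symmetrically to 3 and 1 points at the edges, so endpoint values
are preserved) and symmetrized, (ρ(z) + ρ(−z))/2, before analysis;
multilamellar-vesicle experiments and scattering-density-profile models
are symmetric by construction, and leaflet asymmetry beyond 2 % relative
is logged before it is averaged away. Bilayer thickness is twice the
distance from the headgroup electron-density maximum to the bilayer
center; a qualifying peak must exceed both neighbors with a prominence of
at least 1 % of the profile range (guarding against plateau noise), and
ties within one grid spacing resolve to the peak at larger |z|, the
conservative (thicker) reading.

Form factors are computed as |∫(ρ(z) − ρ_w) cos(qz) dz| by trapezoidal
quadrature on a default q-grid of 0.01–10 nm⁻¹ in 0.005 nm⁻¹ steps. The
symmetrization makes the sine part vanish identically. Minima of |F| are
located on the grid and refined by parabolic interpolation through the
three surrounding points; against the analytic slab transform the refined
positions are accurate to well below one grid spacing. Only minima
*positions* enter the quality metric — they are independent of the
normalization conventions that differ between experimental form-factor
datasets.

Area per phospholipid divides the mean box area by the phospholipids per
leaflet (cholesterol not counted); its standard error is the standard
deviation of 5 contiguous block means divided by √5. The partial area of
cholesterol is dA_tot/dN_chol by central finite differences on the
nonuniform N_chol(x) = n_PC·x/(1−x) grid, one-sided at the ends; negative
values are the condensing effect.

## Finite-size diffusion model

The transcribed box-size dependence, in the limit of infinite
interleaflet friction (the leaflets move as one sheet), is

    D_PBC(L) = D_∞ + (k_B T)/(4π μ_m h) [ ln(L/L_SD) − ξ − (2π/L_SD) W(L, H) ]

with L_SD = μ_m h/(2 μ_f). It derives from membrane hydrodynamics on a
periodic square lattice: the difference between the lattice sum and the
infinite-plane integral of the in-plane mobility kernel
G(k) = 1/(μ_m h k² + 2 μ_f k tanh(kH)). In the fitting regime
(L ≪ L_SD, membrane-dominated momentum transport μ_m h ≫ 2 μ_f H) the
membrane term of G dominates every lattice mode and the difference
evaluates to the logarithmic bracket above. The constant ξ is the finite
part of the square-lattice sum Σ′ 1/|n|² under a circular cutoff,

    ξ = ln(2π^{3/2}/Γ(3/4)²) − γ_E = 1.42647,

known in closed form through the Laurent expansion of the Epstein zeta
function 4ζ(s)β(s) at s = 1 (the unit tests re-derive it by direct
lattice summation). The water term, W(L, H) = (1/L²) Σ′ tanh(|k|H)/|k|³
over k = 2πn/L, is the leading correction from momentum uptake by the two
water slabs of half-thickness H = (L_z − h)/2 separating the membrane
from its periodic images; tanh appears because identical motion of the
periodic image membranes makes the mid-water plane stress-free. For
typical geometries it shifts D_PBC by well under 1 %, but it carries the
H-dependence of the correction. The sum is truncated at |n| ≤ 64 with
the analytic 2π/n_max tail appended, and cached per (L, H).

Two caveats are intrinsic to the physics, not the implementation. First,
the correction is logarithmic in L at fixed water content, so D_PBC
crosses D_∞ near L ≈ e^ξ L_SD (kilometer scale for realistic
viscosities) instead of approaching it monotonically from below; the
model is a fitting form for the regime L ≪ L_SD, not a uniform
large-box limit. Second, when D_PBC is constant across L the correction
term carries no information and μ_m is unidentifiable; the fit flags
this (correction below 1 % of the mean D_PBC) instead of reporting a
meaningless viscosity.

The fit itself is nonlinear least squares in (log D_∞, log μ_m) — the
log parameterization enforces positivity without bounded solvers — with
initialization D_∞ = max(D_PBC), μ_m = 100 mPa·s. On noiseless 3-point
input the recovery is exact to machine precision and independent of ±50 %
perturbations of the initialization. Defaults T = 298 K and
μ_f = 0.3228 mPa·s (a TIP3P-water value at 298 K) are overridable per
dataset; h and H are treated as constants of the series, averaged over
the box sizes.

Monte-Carlo error propagation refits 10,000 replicas with each D_PBC
perturbed by a Gaussian of its stated error (in practice the
leaflet-to-leaflet difference of the diffusion estimate). The replicas
are fitted by a batched, damped Gauss–Newton iteration with analytic
Jacobians (validated against per-replica Levenberg–Marquardt to 10⁻⁶);
log-parameters are clamped to [10⁻⁶, 10⁶] µm²/s and [10⁻³, 10⁹] mPa·s so
that replicas whose noise flattens or inverts the D(L) trend saturate at
the correction-free ceiling rather than overflow. The D_∞ spread is
reported as a standard deviation; the μ_m samples are returned raw
because their distribution is often strongly skewed (the ceiling samples
are its extreme tail) and a Gaussian summary would mislead. The sample
mean of D_∞ carries a second-order bias from the fit's curvature, of
order 2 % of the spread at 5 % input noise — negligible against the
reported uncertainty but not exactly zero, which is why the tests bound
it relative to the spread rather than asserting exact unbiasedness.

## MSD computation

Leaflet drift — the mean displacement of each leaflet's members relative
to the first frame — is subtracted from its members before the MSD is
accumulated, so collective monolayer sliding does not register as
diffusion; both leaflets are then averaged jointly. The MSD uses every
time origin through the FFT autocorrelation decomposition (O(T log T)
per particle and dimension, validated against the O(T²) brute force); a
stride option decimates origins for speed. The default 10–100 ns fit
window excludes the short-lag rattling regime and the poorly averaged
longest lags.

## Synthetic fixtures

The generators emulate the *structure* of real inputs, with every ground
truth returned alongside the data:

- **SDP-style densities** — error-function plateaus plus Gaussian
  headgroup peaks at ±z_H (default 1.9 nm) and a Gaussian methyl trough;
  amplitudes resemble a PC bilayer (water 333 e/nm³, chains 290 e/nm³,
  headgroup peak ≈ +130 e/nm³). The defaults place the analytic peak at
  z_H to within ~6 pm, far below the 20 pm grid spacing, so thickness
  recovery tests are meaningful at one-grid-spacing tolerance.
- **Slab densities** — top-hat contrast with the closed-form transform
  |2Δρ sin(qd)/q| as oracle. A grid point falling exactly on the
  discontinuity carries the mean of the two sides, the correct
  band-limited sample, keeping trapezoidal quadrature at O((qΔz)²) error.
- **Order-parameter profiles** — per-carbon baselines shaped like POPC
  chains (plateau ≈ −0.2, terminal decay, double-bond dip, forked C2)
  scaled by 1 + gain·min(c, saturation) with default gain 0.02/mol % and
  saturation 40 mol %, roughly doubling the order over the studied range
  as cholesterol does; optional seeded Gaussian noise.
- **Brownian trajectories** — independent Gaussian steps of per-axis
  variance 2D·dt, with optional common per-leaflet drift.
- **D_PBC(L) series** — the forward model above with multiplicative
  seeded noise and matching stated errors.

Passing recovery tests on these fixtures establishes that the analysis
chain is self-consistent and numerically correct — linear responses are
interpolated exactly, known diffusion coefficients and thicknesses are
recovered, a generator matched to the synthetic "experiment" scores
better than a mismatched one. It does *not* establish biophysical
accuracy of any force field, nor that real observables satisfy the
generators' simplifications (noise-free concentration response, linear
ordering gain, Gaussian headgroup peaks, uncorrelated Brownian steps).

All randomness flows through `numpy.random.default_rng(seed)` per call;
no generator touches global state.

## Known limitations

- No trajectory parsing; observables must arrive tabulated.
- The finite-size model assumes infinite interleaflet friction and
  membrane-dominated momentum transport; very low membrane viscosities
  (μ_m h ≲ 2 μ_f H) would need the full mobility kernel.
- Form-factor comparisons use minima positions only; amplitude-level
  comparison would require a common normalization convention between
  experimental datasets.
- The quality metric weighs all carbons (or z-points) equally; no
  uncertainty weighting within a profile.
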