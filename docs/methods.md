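# Methods

Conventions, formulas and algorithmic choices used throughout `xrrfilm`.
Lengths are in Å, electron densities in e⁻/Å³, wave-vector transfers in Å⁻¹,
surface excesses in mg/m², tensions in mN/m, concentrations in mM unless a
function says otherwise.

## 1. Slab model and electron-density profile

An interface is an ordered stack of N slabs between air (ρ_air, default 0)
and the aqueous subphase (ρ_sub, default 0.334 e⁻/Å³). Slab 1 touches air;
z increases into the subphase with z = 0 at the air-side interface. Each
interface j at depth z_j is smoothed by capillary-wave roughness σ_j; a
single shared σ per sample can be enforced.

The smoothed profile is the cumulative error-function form

ρ(z) = ρ_air + Σ_j ½ [1 + erf((z − z_j)/(√2 σ_j))] Δρ_j,

with Δρ_j the density step at interface j. This reduces to the sharp stack
at σ → 0 and has the correct asymptotes ρ(−∞) = ρ_air, ρ(+∞) = ρ_sub.
erf is the standard error function (scipy.special.erf).

The film excess integral ∫ [ρ(z) − ρ_ref(z)] dz, with ρ_ref the bare sharp
air/subphase step at z = 0, equals Σ_i d_i (ρ_i − ρ_sub) independent of σ
(erf smoothing conserves areal electron density); the reference step is
integrated analytically so the identity holds to the accuracy of the
trapezoid rule on the smooth part alone.

## 2. Reflectivity

Geometry: q_z = (4π/λ) sin α. The critical wave vector of a sharp interface
is q_c = 4√(π r_e Δρ) with the classical electron radius
r_e = 2.8179403 × 10⁻⁵ Å; for water q_c ≈ 0.02175 Å⁻¹. The Fresnel
reflectivity R_F(q_z) = |(q_z − k_z)/(q_z + k_z)|² uses the complex
k_z = √(q_z² − q_c²), which automatically yields R_F = 1 below q_c (total
external reflection). Absorption is neglected: at λ ≈ 1.3 Å, organic films
and water are effectively transparent at these q_z.

The Parratt recursion runs bottom-up over interfaces with per-medium
vertical wave vectors k_j = ½√(q_z² − 16π r_e (ρ_j − ρ_air)), interface
Fresnel coefficients r_j = (k_j − k_{j+1})/(k_j + k_{j+1}) and the Möbius
update r_tot ← (r_j + r_tot e^{2i k_{j+1} d_j})/(1 + r_j r_tot
e^{2i k_{j+1} d_j}). Roughness enters either as

- **Névot–Croce (NC) factors** r_j ← r_j exp(−2 k_j k_{j+1} σ_j²) — fast and
  accurate for σ well below the slab thicknesses, or
- **fine slicing**: the erf-smoothed profile is rendered as 0.25 Å sharp
  slices (padding 5σ on both sides) and the recursion is run without damping
  factors. This is the accuracy route; it is selected automatically whenever
  max σ > d_min/2, the regime where NC degrades (the reference monolayers, with
  σ ≈ 3.6 Å against a ~5 Å headgroup slab, always take this route).

Two caveats are handled explicitly. Below the critical edge the NC
exponential can marginally exceed 1 (imaginary wave vectors turn damping
into amplification); |R|² is capped at 1. In deep interference minima
(R ~ 10⁻⁹) of thick rough stacks, NC deviates from the exact smoothed
profile by up to ~1.6% — the fine-sliced route is used where that matters.

Correctness is established against an independent oracle: an Abelès
characteristic-matrix implementation (2×2 transfer matrices per layer) on an
independent 0.1 Å slicing, agreeing with the engine to ≤ 0.5% relative over
0.016–0.6 Å⁻¹ on 50 random stacks. The numba-jitted kernel matches the pure
numpy fallback to ~1e-14.

## 3. Inference

The likelihood is Gaussian in log R: reflectivity spans ~9 decades, and for
small relative errors the log-space noise scale equals dr/r. A bounded
trust-region least-squares fit on log R provides the point estimate and the
Jacobian.

The posterior is sampled with emcee. Two non-default choices matter for
this problem class:

- **Ridge-seeded initialization.** At capillary roughness the posterior of a
  thin-slab stack contains a long curved valley (e.g. the split of the total
  thickness between tail and headgroup slabs is nearly unidentified when σ
  blurs the internal interface). An ensemble started in a small ball at the
  optimum needs thousands of steps to diffuse along that valley and
  systematically under-reports the uncertainty. Instead, the least-identified
  parameter (largest Laplace sd relative to its bound width) is profiled:
  pinned on a 14-point grid across its bounds with the remaining parameters
  re-optimized (warm-started outward from the optimum), and walkers are drawn
  from the profiled points with weights ∝ exp(−Δχ²/2) (points with Δχ² < 9),
  plus 1% relative jitter.
- **Differential-evolution moves** (80% DEMove, 20% DESnookerMove), which mix
  much better than stretch moves along curved degenerate valleys.

Chains are seeded (numpy RandomState from the fit seed) and bit-identical
across runs. Parameters are reported as posterior medians with 16/84%
percentile bounds; the larger bound is the conservative symmetric error.
Calibration was verified by simulation: at 2% noise, 12 walkers and 500
steps, the 16–84% intervals cover the generating values in ~74% of checks
(nominal 68%) pooled over 5 parameters × 20 seeds.

Derived quantities (areas, excesses, hydration numbers) carry first-order
uncertainties via independent-input propagation with central finite
differences.

## 4. Composition from electron balances

Species are bookkept as fragments: oleic acid C₁₈H₃₄O₂ (158 e⁻ = tail C₁₇H₃₃
135 + head CO₂H 23, M = 282.46), water (10 e⁻, M = 18.015), PS80 as the
monooleate average C₆₄H₁₂₄O₂₆ (716 e⁻ by direct count, tail C₁₇H₃₃,
M = 1310). Electron counts are always computed from the chemical formula.

For a single-surfactant two-slab film: A_s = n_tail/(ρ₁d₁),
N_W = (ρ₂d₂A_s − n_head)/10, Γ = M/(N_A A_s) × 10²¹ mg/m² (A_s in Å²),
Γ_W = N_W M_W/(N_A A_s) likewise. For multi-species films, a per-slab
partition assigns each species' (and water's) electrons across slabs as
fractions summing to one; one electron balance per slab forms a linear
system in the per-area molecule counts, solved by least squares with a
non-negativity refit when needed. Forward-constructed stacks invert exactly
(round-trip tested to 1e-6). A molar-volume balance (29.9 Å³ per water) is
reported as a per-slab residual, never enforced: the electron balances alone
determine the composition.

## 5. Tension isotherms

Below the cmc, γ(c) = γ₀ − RTΓ_∞ ln(1 + c/a) (Szyszkowski; Γ_∞ in mol/m²,
a in mol/L, γ in mN/m, γ₀ = 72.5 mN/m at T = 296.15 K default), the tension
law conjugate to the Langmuir isotherm θ = c/(a + c). Above the cmc the
tension plateaus.

The cmc is located as the breakpoint of a continuous two-segment
piecewise-linear fit of γ vs ln c (grid search plus refinement); a plateau is
accepted when the upper segment is much flatter than the descending branch
(|s₂| < 0.25 |s₁|). This is reproducible where a visual "becomes independent
of concentration" criterion is not; its smoothing bias at the kink is ~1.5%
on noiseless data, well inside the 10% acceptance slack. (Γ_∞, a) are then
refit by weighted least squares (log-parameterized) on the sub-cmc points,
which recovers generating values exactly on noiseless data. At least five
sub-plateau points are required; the synthetic generator therefore defaults
to a 12-point log-spaced ladder over the measured 0.0012–0.12 mM range (the
original 5-point measurement ladder, exposed as a constant, has only three
sub-cmc points).

Equilibrium tensions from relaxation traces are the mean of the trailing 10%
time window.

## 6. Synthetic data and scenarios

Reflectivity curves carry multiplicative Gaussian noise r = R(1 + ε),
ε ~ N(0, 0.02) by default, with dr = 0.02 r — the natural model for
normalized data with no count scale; tension data carry additive Gaussian
noise (0.3 mN/m default). All generators take a single seed and are
byte-deterministic.

Scenarios: the two fitted OA monolayer stacks (depositions of 45.4 and
34.9 Å²/molecule); a two-slab PS80 layer forward-constructed from its
measured excesses at the cmc (Γ_PS80 = 1.79, Γ_W = 1.63 mg/m²; 25% of head
electrons in the compact first layer by default); and a three-slab mixed
OA/PS80 film from Γ_OA = 1.34, Γ_PS80 = 1.09, Γ_W = 1.51 mg/m². Each
scenario's composition inverts exactly from its own slabs, so recovery tests
have a closed loop from composition → slabs → reflectivity → fit →
composition.
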