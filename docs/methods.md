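# Methods

This note records the models implemented in `mabcluster`, the parameter
choices that matter, the numerical decisions, and what the tests do and do
not establish.

## Molecular model and units

The antibody is a rigid, planar Y of nine touching hard beads (diameter
σ): an equilateral triangle of three beads, plus three arms of three
beads whose innermost bead is a triangle vertex.  The tail arm points
radially away from its vertex; the two upper arms run at 60° to each
other and 150° to the tail.  The verbal description (angles plus
touching beads) fixes the construction completely once two conventions
are chosen:

* **Tangent-circle diameter.**  d_Y is measured about the *centroid of the
  central triangle* (the molecule's geometric center), giving 6.155 σ.
  About the center of mass it would be 6.64 σ and the smallest enclosing
  circle gives 6.09 σ; only the centroid convention matches the reference
  value 6.16 σ.
* **Mass convention for R_g.**  Point masses at bead centers give
  R_g = 1.72975 σ, exactly the calibration value, and are the default;
  the solid-sphere convention (adds 0.15 σ² to the mean-square radius)
  is available.

Patch sites sit on the outward pole of each terminal arm bead (0.5 σ from
the bead center along the arm axis): one *A* on the tail, two *B* on the
arms.  The square-well range is site-to-site, 0.2633 σ by default.

Physical units: σ = R_g^exp / R_g^model = 4.7 nm / 1.72975 σ = 2.717 nm.
The concentration conversion 1 mg/mL = 8.229·10⁻⁵ σ⁻³ is stored as a
literal constant because the published conversion chain is internally
rounded; deriving it from Avogadro's number, M₁ = 150 kDa and σ gives a
value ~2 % lower (`UnitSystem.derived()`), a discrepancy we document
rather than resolve.

## Wertheim TPT1

Free energy per particle: ideal + Carnahan–Starling (CS) excess at packing
fraction φ = ρ(π/6)σ_HS³ with σ_HS = 2.95 σ, plus the bonding term
ln X_A − X_A/2 + 2(ln X_B − X_B/2) + 3/2.  The site fractions solve the
1A+2B mass-action pair; substituting the bookkeeping identity
(1 − X_A) = 2(1 − X_B) reduces it to a quadratic whose root is evaluated
in a cancellation-free form (stable down to X_A → 0).

**Bond integral.**  Δ = v_b · g · (e^{1/T} − 1).  The contact-value factor
g defaults to **1**: with a single bonding volume calibrated so that
⟨s⟩_w = 4.5 at 147 mg/mL (v_b ≈ 8.6·10⁻³ σ³ at T = 0.11), the g = 1 mode
also reproduces ⟨s⟩_w = 1.62 at 26 mg/mL to three digits, while the
CS-contact mode g = (1 − φ/2)/(1 − φ)³ would give 1.43.  The
density-independent Δ is therefore taken to be the published convention;
the CS-contact mode remains available (`g_mode="cs-contact"`).

**Compressibility.**  S(0) = [∂(βP)/∂ρ]⁻¹.  βP is assembled analytically
(CS compressibility factor; bonding pressure −ρ(1 − X_A)(1 + ρ d lnΔ/dρ),
which follows from the stationarity of the TPT1 functional) and the outer
ρ-derivative is a Richardson-extrapolated central difference (relative
step 10⁻⁴).  Tests validate it against the closed-form CS compressibility
(Δ = 0) and against nested finite differences of the free energy to 10⁻⁶.

Temperature enters only through ε₀ = 1/T: T = 0.11 (ε₀ = 9.09 k_BT) for
the 17 mM ionic-strength condition, T = 0.114 (8.77 k_BT) for 57 mM.

## Hyperbranched cluster statistics

n(s) = [(2s)!/(s!(s+1)!)] p^{s−1}(1−p)^{s+1}, normalized to Σ n = 1
("probability of finding a cluster of size s").  Factorials are evaluated
in log space (the Catalan prefactor overflows doubles near s = 86).  The
truncation s_max is adaptive: the analytic geometric tail bound (ratio
4p(1−p)) must fall below 10⁻¹⁰, capped at 10⁵.  Averages:
⟨s⟩_n = 1/(1−2p), ⟨s⟩_w = (1−2p²)/(1−2p)²; `invert_weight_average`
bisects the strictly increasing closed form.  An independent tree-counting
oracle (convolution recursion over the two B-subtrees of the root) pins
the transcription in the tests to 10⁻¹².

## Cluster form and structure factors

All models share the factorization s·P_c(q) = P₁(q)·S_c(q).

* **Debye** sum over explicit monomer centers (used for simulation
  clusters and the 9-bead P₁).
* **fjc**: S_c = (1/s)Σ_{ij} x^{|i−j|}, x = sin(qb)/(qb), b = 12 nm.  The
  geometric closed form in (1−x)⁻² loses ~9 digits near x → 1, so it is
  evaluated by an algebraically identical Horner recursion (and, inside
  the polydisperse average, by a running-sum recurrence over s, total cost
  O(s_max·n_q)).  R_g = b√(s/6) asymptotically.
* **fc**: Fisher–Burford envelope P_L(q) = [1 + (2/(3d_F))q²R_g²]^{−d_F/2}
  with R_g = R₁(s/k)^{1/d_F} (d_F = 2.5, k = 0.71, R₁ = 6 nm), embedding
  radius R_c = R_g√((d_F+2)/d_F), internal volume fraction
  φ_int = A_φ·s·(R₁/R_c)³, and Percus–Yevick internal correlations:
  **S_c,fc(q) = s·P_L(q) + (1 − P_L(q))·S_HS(q, φ_int)**.  This assembly
  is exact at both ends (S_c(0) = s, S_c(∞) = 1) and reduces to the
  pure-envelope form 1 + (s−1)P_L when A_φ → 0.  With the printed inputs
  the fc radius at s = 10 evaluates to 17.28 nm against the printed
  17.4 nm — consistent once one notes k = 0.71 is itself rounded
  (k ≈ 0.698 reproduces 17.4).  The model is restricted to s ≥ 2 and only
  trusted for s ≳ 15; it is excluded from the default polydisperse
  pipeline (fjc is the default), matching its published range of validity.
* fjc and fc coincide within a few percent only between the Guinier
  regime and the nearest-neighbor dip (qb ≲ 1.3); at the dip they differ
  by order unity, which is the behaviour the published comparison shows on
  a log scale.  The agreement test uses that window.

Polydisperse averaging: ⟨S_c(q)⟩_w = Σ n(s)·s·S_c(s,q) / Σ n(s)·s, with
the far tail dropped once its weight contribution is below 10⁻¹⁰ of the
total.  q is handled in nm⁻¹ internally; disk curves carry Å⁻¹ (exact
factor 10).

## Cluster-fluid observables

* φ_HS = A·φ·⟨s⟩_n^{3/d_F−1}, A = 1.4, d_F = 2.0 (cluster-volume
  fractality); ρ_cluster = ρ/⟨s⟩_n.
* Baxter sticky hard spheres: λ is the smaller (physical) root of
  (φ/12)λ² − (τ + φ/(1−φ))λ + (1+φ/2)/(1−φ)² = 0, and with
  μ = λφ(1−φ), S_SHS(0) = (1−φ)⁴/(1+2φ−μ)²; τ = 2.5 shared across both
  ionic strengths.  τ → ∞ recovers the PY hard-sphere limit (tested to
  10⁻⁴).
* RPA closure: S_c^eff(q) = 1/(1 + ν f(q)) with ν = 1/S_SHS(0) − 1 and
  f(q) = (⟨S_c(q)⟩_w − 1)/(⟨s⟩_w − 1), the normalized inter-monomer part
  of the mean cluster structure factor (f(0) = 1, f(∞) = 0), so the q = 0
  boundary condition is exact and S_c^eff → 1 at large q.  In the
  monomer-only limit (⟨s⟩_w → 1) f degenerates to 0/0; there the sphere
  form factor at R₁ is used as the interaction range, since the
  coarse-grained scattering objects are the monomer spheres themselves.
* S^eff(q) = ⟨S_c(q)⟩_w·S_c^eff(q); ⟨N_app⟩_w = ⟨s⟩_w·S_SHS(0);
  I(q)/c = K·M₁·P₁(q)·⟨S_c(q)⟩_w·S_c^eff(q);
  η_r = (1 − φ_HS/φ_g)^{−γ} with γ = 3.0, φ_g = 0.63 (γ = 2.8 reproduces
  the plain hard-sphere comparison curve).
* Monodisperse mode (cluster size = nearest integer to ⟨s⟩_w) is exposed
  alongside the polydisperse default, reproducing the two-step comparison
  in the original analysis.

No polydisperse correction to the sticky-sphere S(0) is attempted (no
closed form exists); this is a known limitation that slightly
underestimates the low-q structure factor at high concentration.

## Monte Carlo

Metropolis MC of N rigid molecules in a cubic periodic box: per sweep, N
single-particle moves, translation or rotation with equal probability.
Orientations are unit quaternions; rotations are small-angle axis-angle
perturbations (re-normalized every move).  Hard-core overlaps reject
unconditionally; the A–B square well contributes −ε₀ per site pair within
range.  Pair interactions use a center-of-mass distance prescreen
(cutoff 6.91 σ, below L/2 at all densities used); at desk scale (N = 200)
this direct O(N) loop costs the same as a cell list would and keeps the
kernels simple.  Kernels are numba-compiled; a given (configuration,
seed) is bit-reproducible.

Desk protocol: amplitudes 0.8 σ / 1.0 rad (≈35 % acceptance at the
working density — the criterion by which they were set), 3·10⁴
equilibration sweeps (energy plateau at c = 61.7 mg/mL; the smaller
0.35 σ/0.4 rad amplitudes had not plateaued after 6·10⁴), 2·10⁴
production sweeps sampled every 500, 4 independent replicas seeded
seed, seed+1, ….  The publication-scale protocol (N = 1000, 10 replicas)
is a parameter change.

Observables: A–B bond graph (multiple bonds per patch are allowed,
counted, and stay below a few percent), connected-component clusters
labelled by smallest member index, n(s) with replica-scatter standard
errors floored by the multinomial counting error (a handful of replicas
estimates its own scatter with ~40 % relative error), per-size R_g and
Debye structure factors over unwrapped molecule centers of mass, and
S_sim^eff(q) = ⟨|Σ_beads e^{iq·r}|²⟩/(81·N·P₁(q)) evaluated on
reciprocal-lattice shells q = (2π/L)·n (directions subsampled to ≤48 per
shell, deterministically).  A minimum-image Debye sum was rejected for
this observable: its sharp r = L/2 truncation produces O(1) ringing even
for an ideal gas.

The simulated n(s) is compared against hyperbranched theory *at the bond
probability measured in the same ensemble*: the theory-vs-simulation
claim is that the patchy model follows hyperbranched statistics, and the
measured p differs by a few percent from the Wertheim p because the
bonding volume here is a calibration rather than the original
(unpublished) patch-geometry integral.

Pair excluded volume: MC integration of the overlap indicator over
uniform relative positions in the bounding sphere and independent uniform
orientations (Shoemake quaternions).  For the 9-bead Y it gives
≈127 σ³, ~1.2× the CS-equivalent sphere value (4π/3)(2.95 σ)³ — the
effective-sphere mapping is a free-energy match, not an excluded-volume
identity, so order-unity agreement is the expected outcome.

## Data reduction and synthetic fixtures

SLS: R(90) = [(I−I_s)/I_ref]·R_ref·(n/n_ref)², ⟨M_w⟩_app = R(90)/(K·C)
with K = 4π²n²(dn/dC)²/(N_A λ₀⁴), dn/dC = 0.192 L/g; no angular
correction (the clusters are far smaller than the inverse scattering
vector).  DLS microrheology: first-cumulant fit of ln(g₂−1) on the early
decay (down to 30 % of the initial amplitude by default), D = Γ/q²,
η_r = D_solvent/D_sample.  SAXS merging: pinhole intensities interpolated
linearly in (q, log I) onto the reference grid; one multiplicative factor
minimizes the squared log-intensity difference over the overlap window
q > 0.04 Å⁻¹; extrapolation is forbidden.
S^eff(q) = [I(q)/c]/[I_ff(q)/c_ff] pointwise, masking non-positive
form-factor values.

The synthetic generator emulates the measured concentration series with
the forward model itself: per concentration, p from the calibrated
Wertheim stage, I(q)/c from the fjc pipeline on the experimental q-range
(0.00626–0.45 Å⁻¹), an arbitrary pinhole scale factor (default 3.7)
recovered by the merge step from a dilute companion curve (c_ff =
3.8 mg/mL), SLS records carrying exactly ⟨N_app⟩_w, and
single-exponential tracer correlograms encoding η_r.  Noise is
multiplicative log-normal with a seeded generator.  What passing the
closed loop shows: the reduction formulas invert the forward model
exactly (10⁻¹² at zero noise) and degrade gracefully with noise.  What it
does not show: robustness to instrument resolution, background
subtraction errors, incoherent polydispersity contributions, or any
feature of real detectors — none of which are modelled.

## Known limitations

* The bonding volume is calibrated, not derived from the patch geometry;
  absolute temperatures map onto bond probabilities only up to that
  calibration.
* One-bond-per-patch is exact in the theory but only approximate in the
  simulation (multi-bond fraction is monitored).
* Ring formation is excluded by construction in the theory; the
  simulation can form rings, a small systematic at large s.
* The sticky-sphere stage treats the (broad) cluster distribution as
  monodisperse; S^eff(0) is slightly underestimated at high c.
* The fc model is meaningless for s ≲ 15 and excluded from default
  averages.
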