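# Methods

## Model

A planar lipid monolayer sits at x = 0 with an aqueous half-space x > 0
(dielectric constant ε_w = 80, T = 298 K, Bjerrum length
l_B = e²/(4πε_wε₀k_BT) = 0.70 nm). A fraction β of the lipids is
"non-structured": a single in-plane point charge (default −1). The remaining
fraction 1−β carries a structured head group: an anchored charge q₀ in the
plane plus mobile charges q₁ (and q₂) on rigid segments. All in-plane charge
— q₀ of every lipid and the full charge of the non-structured component — is
smeared into a uniform surface density σ; the mobile segment charges enter
the volume charge density explicitly. The electrolyte is either the
neutralizing counterions alone or a 1:1 salt with bulk concentration c.

Internal units: lengths in nm, energies in k_BT, potential as ψ = eΨ/k_BT,
densities in nm⁻³. Conversions to volts, C m⁻², and mol dm⁻³ happen only at
the I/O boundary.

The free energy per unit area is the sum of the field energy
∫ψ′²/(8πl_B)dx, the head-group orientational entropy
(1−β)/a ∫W ln W, and the ideal ion free energy (two-component relative to
the bulk in salt mode; one-component with a de Broglie gauge constant v in
counterions-only mode). Stationarity under Gauss's law (with ψ as its
multiplier field) and ∫W = 1 (multiplier λ) gives Boltzmann ions and a
Boltzmann orientation density; Gauss's law closes the system.

### Orientation states and reference measures

W is a density in the *projected* coordinates with a uniform reference
measure. For a rigid segment pivoting isotropically in the half-space this
is exact (the Archimedes hat-box projection of the hemisphere is uniform),
so no solid-angle Jacobians appear:

* **Rigid rotor** — coordinate x ∈ [0, l₁] of the middle charge; the
  terminal charge is slaved to s = x(l₁+l₂)/l₁. W(x) ∝
  exp[−q₁ψ(x) − q₂ψ(s(x))].
* **Flexible** — coordinates (x, s) on Ω = {0 ≤ x ≤ l₁,
  max(0, x−l₂) ≤ s ≤ x+l₂}: the Archimedes shell of the free joint clipped
  by the wall. W(x,s) ∝ exp[−q₁ψ(x) − q₂ψ(s)]. Folded-back conformations
  touching the wall are allowed (point-charge model, no excluded volume).
* **Triangular** (equal arms l, apex angle α, in-plane rotation) — the
  coordinate is the centre-of-mass projection of the two apex charges on
  the support [l sin(α/2), l cos(α/2)]; within it the bisector elevation is
  θ = arcsin(x/(l cos α/2)) and the charges sit at heights l sin(θ ∓ α/2),
  which are non-negative on the whole support. Each x corresponds to two
  mirror orientations carrying half weight each. The support is adopted as
  the model definition; a strict midpoint-of-chord construction would give
  a marginally lower bound (l sin(α/2)cos(α/2), about 3% smaller at
  α = 30°), an ambiguity with no visible effect on profiles.
* **Zwitterionic** — the rotor with a single charged segment; also reached
  from the rotor by q₁ = 0 (verified as a property test).

### Sign conventions

A negative plane gives ψ(0) < 0 rising monotonically to the bulk value;
counterions are cations; E = −dψ/dx; ψ″ = −4πl_B ϱ/e; the surface boundary
condition is ψ′(0) = −4πl_B σ_e with σ_e in e/nm².

## Numerics

The domain splits at d₂ ≤ d₁ (rotor/flexible: d₂ = l₁, d₁ = l₁+l₂;
triangular: d₂ = d₁ = l, one region). On [0, d₁] a uniform step h is chosen
commensurate with both region lengths (adjusted downward via a rational
approximation of their ratio). The discrete equations are a conservative
flux-balance form of the second-order finite-difference scheme:

* half-cell flux balance at x = 0 carrying the σ boundary condition,
* central flux differences at interior nodes,
* the half-cell average of the (discontinuous) charge density at d₂,
* a half-cell closure at d₁ against the analytic tail slope.

Summing these equations telescopes *exactly* onto the trapezoidal
quadrature used for all normalization and charge integrals, so a converged
solution is electroneutral to the solver tolerance rather than to O(h²) —
measured residuals are ~10⁻¹³ relative. ψ and ψ′ are continuous across d₂
and d₁ by construction (single-valued fluxes); one-sided second-order
stencils are used for derivative reporting and the C¹ diagnostic. Observed
convergence order in ψ is ≈ 2.0.

Beyond d₁ the solution is closed-form: in salt mode the Gouy–Chapman decay
with matching slope ψ′(d₁) = −2κ sinh(ψ(d₁)/2); in counterions-only mode
the algebraic Gouy tail with ψ′(d₁)² = 8πl_B n(d₁). Either first integral
simultaneously enforces global electroneutrality. A closed-box mode
(hard wall with ψ′(x_max) = 0) is also provided; it matches the Monte Carlo
slab exactly and is used for the free-energy oracle.

**Unknowns.** Only the ψ nodes. Ion densities and W are eliminated
analytically through their Boltzmann stationarity, which keeps the Newton
system small and removes the positivity constraints. In counterions-only
mode the prefactor A of n = Ae^(−zψ) and the additive constant of ψ form a
gauge pair (the de Broglie constant v likewise shifts only λ); the solve
fixes A = 1 and the converged solution is re-gauged to ψ(d₁) = 0.
Comparisons against salt-mode runs are made on the gauge-free quantity
ψ − ψ(d₁).

**Charge assembly.** Head-group charges are deposited onto the grid by
mass-conserving cloud-in-cell spreading of quadrature-weighted orientation
masses (node values = cell masses / trapezoid weights). Totals per lipid are
then exact, density jumps at region boundaries automatically appear as their
half-cell averages, and the integrable inverse-square-root Jacobian
singularity of the triangular upper charge at full extension needs no
special-casing (the triangle uses a 6× oversampled deposition sub-grid).

**Nonlinear solve.** Damped Newton (max-norm Armijo backtracking) with a
forward-difference Jacobian, initialized from the matching Gouy–Chapman
profile; on failure, a homotopy in the interface charge (σ and head coupling
scaled up in steps) follows the solution branch. Defaults: h = 0.005 nm,
residual tolerance 10⁻⁸ (max-norm, flux units), 200 iterations. All study
conditions converge directly in ≤ 6 iterations. Non-convergence returns the
best iterate flagged `converged=False` with its residual norm; nothing is
raised silently.

**Reported maxima.** Orientation-density maxima are refined by parabolic
interpolation through the three nodes around the discrete maximum; at a
support edge the node is reported. For the flexible terminal marginal the
maximum sits at a kink (the Ω corner at s = l₂ + 0), which pins the peak at
s = l₁ independent of salt — both the mode and the mean of W_s are exposed,
since "interfacial thickness" statements depend on which statistic is meant.

## Monte Carlo validator

Canonical Metropolis sampling of the same models in a box periodic in the
two lateral directions: hard walls at x = 0 (carrying the smeared σ) and at
x = box_z (default 8 nm); lateral side sqrt(n_lipids·a). Mobile species are
counterions and the discrete segment charges anchored at uniform random
grafting sites. The counterions-only ensemble is sampled (a fixed-N salt box
would misrepresent a reservoir).

*Electrostatics* is the charged-sheet scheme: lateral minimum-image Coulomb
per pair plus an analytic correction replacing all further periodic images
of the partner by an infinite uniform sheet minus its central square at the
partner's height (closed form, verified against quadrature); the smeared σ
acts through the exact infinite-plane field. *Hard cores:* every charged
species carries radius 0.2 nm (the primitive model is undefined without
them — opposite point charges fuse); rigidly bonded intramolecular partners
are exempt and their constant-separation pair energy is dropped. Ion centres
range over the full [0, box_z], so the contact plane coincides with the
point-ion theory's x = 0.

Moves: 3D ion displacements, in-plane lipid translations, and segment
rotations by a random rotation vector (symmetric proposals); ~50% acceptance
targeted by step-size tuning during equilibration only. Energy bookkeeping
is verified against full recomputation (drift ~10⁻¹⁴). Profiles are
block-averaged (10 blocks) for per-bin standard errors; a first-half vs
second-half drift flag marks unequilibrated runs.

The desk-scale validation uses 50 lipids with 2 000 equilibration and
10 000 production attempted moves per particle at a = 6 nm² — the package's
standard reduced configuration — compared against the closed-box solver at
the same box height (bins where the theory density is below 1% of its
maximum are excluded: far-field bins with zero sampled variance make "2σ"
ill-defined).

What this comparison shows, quantitatively: at a = 6 nm² the electrostatic
coupling constant is Ξ = 2π z³ l_B² σ_e ≈ 0.5, and the particle-based
sampling resolves the leading correlation correction beyond mean field — a
reproducible counterion excess of ~2–3% of the peak density inside the
head-group region with a compensating mid-range deficit (present already at
β = 1, insensitive to box size, scaling away with coupling). Agreement is
therefore *figure-scale* at a = 6 (maximum deviation below 5% of the peak;
75–80% of bins within 2 block-SE), and *statistical* at weak coupling: at
a = 24 nm² (Ξ ≈ 0.13) over 90% of bins agree within 2 block-SE. Other
known, expected discrepancies: the MC triangle rotates in 3D while the
theory is two-dimensional, so the MC near-wall orientation histogram does
not vanish below l sin(α/2); at a = 0.6 nm² contact densities of ~12 nm⁻³
make the default 0.2 nm core a sizeable packing perturbation, so the
dense-regime cross-check uses a 0.1 nm core to track the point-ion theory.

## What the tests do and do not show

The synthetic study conditions are the model's own: no experimental data
enters. Passing tests demonstrate internal consistency (stationarity equals
free-energy minimization, electroneutrality, limit reductions to
Gouy–Chapman/zwitterionic/counterion cases, mean-field vs particle-based
agreement at weak coupling) — not that the point-charge, uniform-dielectric
model describes a laboratory monolayer. Finite ion size at high charge,
dielectric inhomogeneity, image charges, pH charge regulation, and membrane
fluctuations are all outside the model.

## Defaults that matter

| parameter | default | why |
|---|---|---|
| T, ε_w | 298 K, 80 | water at room temperature; l_B = 0.70 nm |
| a | 0.6 / 6 nm² | high/low charge regimes (σ ≈ 0.3 / 0.03 C m⁻²) |
| β | 0.5 | 1:1 structured/non-structured mixture of the study |
| q₀,q₁,q₂ | −1,+1,−1 | PS-like pattern (triangle: −1,−1,−1) |
| h | 0.005 nm | resolves supports as small as ~0.18 nm; O(h²) errors ≪ printed precision |
| tol | 10⁻⁸ | far below any physical scale; Newton typically lands at 10⁻¹³ |
| ion radius (MC) | 0.2 nm | small enough to track the point-ion theory, large enough to define the primitive model |
| v (de Broglie) | 1 | pure gauge; shifts λ only (verified) |

## Known limitations

Triangular head groups require equal arms (the general-arm geometry has no
single centre-of-mass convention and was not needed). The MC samples
counterions only. The charged-sheet electrostatics is approximate at short
lateral box sides; the β = 1 closed-form limit is its accuracy arbiter.
Incommensurate (irrational-ratio) segment lengths are rejected rather than
meshed non-uniformly.
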