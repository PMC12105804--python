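# Methods

This note records the models, numerical choices, and deliberate design
decisions behind `tbforge`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is quoted from
external sources.

## Scope and architecture

`tbforge` implements the complete route from first-principles atomic data to
a working third-order self-consistent-charge tight-binding (SCC-DFTB3)
parameter set, plus the molecular engine and validation tools needed to
qualify such a set:

1. `tbforge.atom` — all-electron radial Kohn-Sham solver (confined or free
   atoms, non- or scalar-relativistic) and the Hubbard-parameter machinery;
2. `tbforge.twocenter` / `tbforge.rotations` / `tbforge.skf` — Slater-Koster
   two-center tables, their rotation into the lab frame, and the standard
   `.skf` file format;
3. `tbforge.engine` — molecular SCC-DFTB3 total energies, Mulliken charges,
   numerical forces, quasi-Newton geometry optimization;
4. `tbforge.bands` / `tbforge.bandfit` — non-SCC band structures of
   elemental crystals and the derivative-free confinement fit against a
   reference band structure;
5. `tbforge.repulsive` — spline repulsive potentials fitted to
   reference-minus-electronic energy curves;
6. `tbforge.validation` / `tbforge.toyparams` / `tbforge.benchmark` —
   association/exchange energies, Kabsch RMSD, and the self-generating
   fixture pipeline the tests run on.

## The tight-binding model

The total energy is expanded around a reference density built from neutral
(pseudo)atoms:

    E = E_H0 + 1/2 Σ_ab Δq_a Δq_b γ_ab + 1/3 Σ_ab Δq_a² Δq_b Γ_ab + E_rep

with Δq_a the Mulliken charge fluctuation (excess electrons positive),
γ_ab the screened Coulomb kernel interpolating between the on-site chemical
hardness U_a and 1/r, and Γ_ab = (∂γ_ab/∂U_a)·U_a^d its charge derivative.
The variational Hamiltonian carries the corresponding shift

    H_μν = H⁰_μν + S_μν Σ_c Δq_c [ (γ_ac+γ_bc)/2
            + (Δq_a Γ_ac + Δq_b Γ_bc)/3 + Δq_c (Γ_ca+Γ_cb)/6 ].

Pairs involving hydrogen use the short-range damping
h = exp(−((U_a+U_b)/2)^ζ r²) with ζ = 4.0 (the value used throughout this
family of parameter sets); the damping multiplies the screening part of γ
and its U_a-dependence is included analytically in Γ. γ uses the standard
exponential-charge-cloud closed form with decay τ = 16U/5; near-equal τ
pairs (relative difference below 5%) are evaluated in 40-digit arithmetic
because the closed form cancels catastrophically toward the equal-τ limit.
The implementation of Γ is fully analytic; the test suite checks it against
high-order finite differences and checks γ against a direct numerical
Coulomb integral of the two exponential charge clouds.

## Radial atomic solver

The radial equation for u = rR is transformed to t = ln r with
v = u/√r, discretized with a symmetric 7-point stencil (O(h⁶)) on an
exponential grid (default r ∈ [1e-11, 50] bohr, 1000 points), and solved as
a symmetric banded eigenproblem: bisection for eigenvalues, shifted inverse
iteration with banded LU solves for eigenvectors. The inner Dirichlet wall
at r_min biases ns eigenvalues by ≈ 2Z³r_min/n³ hartree, which dictates the
very small r_min (at r_min = 1e-6 the bias would be ~0.13 hartree for the
1s of Z = 40).

SCF uses Pulay (DIIS) density mixing with adaptive history pruning and a
linear-mixing fallback; convergence is an integrated absolute density
change below 1e-9 electrons. Aufbau occupation of charged/fractional atoms
uses a tiny Fermi-Dirac smearing (1e-3 hartree) purely as a numerical
device: it makes the filling a continuous function of the eigenvalues so
that near-degenerate frontier shells (transition-metal d vs s) converge,
and its zero-width limit is exact aufbau with degenerate ties split
equally.

The scalar-relativistic mode solves the Koelling-Harmon equation (mass
function M = 1 + α²(ε−V)/2, spin-orbit dropped). The ε-dependence of M is
handled by freezing M per state and iterating; the first-derivative term is
removed by the substitution u = √(rM)·y so the banded symmetric machinery
is reused. For l = 0 the Koelling-Harmon equation is *exactly* the Dirac
j = 1/2 problem, which supplies a closed-form hydrogenic oracle for the
tests. Scalar relativity matters here: for the 4d-metal validation case the
5s/4d valence eigenvalues shift by −0.006/+0.013 hartree relative to the
non-relativistic solve, far beyond the reproduction tolerance, so
replication runs use `scalarrel=True`. Inside steep confinement walls
ε−V is hugely negative and M is floored at 0.1; the orbitals have decayed
to zero there, so the floor only prevents numerical overflow.

### Confinement

A power potential (r/r₀)^σ is added per subshell. Basis (wavefunction)
confinement applies per valence l-channel with its own (r₀, σ); the density
compression applies to every shell when constructing the superposed
reference density. The free atom supplies the on-site energies.

### Hubbard parameter and its charge derivative

Three schemes are implemented, because the literature value of "IP − EA"
hides a real operational ambiguity for transition metals whose spherical
spin-free anion is unbound:

- `kernel` (default): the frozen-orbital curvature
  U = ⟨n_homo | f_Hxc | n_homo⟩ of the self-consistent atom, evaluated by a
  symmetric finite difference of the Hartree+xc potential with a small
  admixture of the HOMO-shell density (step 0.02 e; halving the step moves
  U by ~1e-8). This is well defined for every charge state and is the
  quantity tabulated by the established parametrization tool chain — it
  reproduces the published Zr value to 0.01% and the familiar H/O values
  (0.4195 / 0.4954 hartree) of the organic/biological parameter family.
- `energy`: E(N−1) − 2E(N) + E(N+1) from self-consistent total energies
  with aufbau filling. When the anion cannot be converged the code logs a
  warning and falls back to the Janak derivative.
- `janak`: the relaxed eigenvalue derivative dε_HOMO/dN.

U^d is the central finite difference of U with respect to the charge
fluctuation (electron-count offsets ±0.05 on the HOMO shell); the sign
convention follows Δq = excess electrons, so atoms that soften upon
electron addition have U^d < 0.

## Two-center integrals

Hamiltonian/overlap channels (ssσ … ddδ) are integrated on a
prolate-spheroidal Gauss-Legendre mesh with the nuclei at the foci, with a
substitution concentrating ξ-points near the overlap region and adaptive
order refinement (relative tolerance 1e-8, order ×1.6 per round). The
kinetic energy acts analytically through T|φ_ν⟩ = (ε_ν − v_conf,ν)|φ_ν⟩,
so only smooth potential differences are quadratured; nuclear singular
parts cancel analytically. Convergence below ~0.8 bohr is slower (near
united-atom regime) but those rows lie far inside any physical geometry.

Both potential superposition (V_A + V_B of the density-compressed atoms)
and density superposition (V_KS[ρ_A+ρ_B]) are implemented. For the GGA
density superposition the gradient-correction divergence is expanded
analytically in the two-center coordinates (r_a, r_b), with the xc-kernel
derivatives obtained by vectorized finite differences.

Tables for both ordered pairs are produced in one pass; channels with
l₁ > l₂ follow from the midpoint-inversion parity rule
⟨B l₁|Ô|A l₂⟩ = (−1)^(l₁+l₂) ⟨A l₂|Ô|B l₁⟩. Lab-frame blocks are assembled
with real-spherical-harmonic rotation matrices (p: permuted Cartesian
rotation; d: quadratic-form transformation Q → RQRᵀ), which the tests
verify against an independent transcription of the classic direction-cosine
table.

## Band structures and the confinement fit

Elemental crystals use non-SCC Bloch sums H(k) = Σ_R e^{ikR} H⁰(R) over all
neighbor shells within the table cutoff; charge self-consistency is omitted
deliberately because all sites of an elemental crystal are equivalent and
the Mulliken fluctuations vanish by symmetry. The Fermi energy comes from
filling the valence electrons on a uniform zone mesh. Periodic *SCC* (Ewald
summation of γ) is out of scope and periodic SCC inputs are rejected
explicitly.

The confinement objective is a Boltzmann-weighted RMS band deviation,
w = exp(−|ε−E_F|/kT), after shifting both band sets to their own Fermi
level and matching bands index-by-index (ascending per k). As printed in
the source literature the weight exponent carries no absolute value and
would diverge below the Fermi energy; the absolute value implements the
stated intent (emphasis near E_F) with weights bounded by one. kT = 0.01 eV
is the replication value; the synthetic toy problems use a broader kT.

Minimization uses COBYLA with bounds as linear constraints, run as a short
sequence of restarts with shrinking initial trust region (the
linear-approximation steps stall once the simplex dwarfs the remaining
distance to the minimum). Failed pipeline evaluations return a large
finite penalty so the derivative-free search continues, and the best-so-far
parameters are returned (flagged) if the budget is exhausted. A caveat
probed by the tests: the radius and order of one subshell trade off along a
narrow *curved* valley of the objective, which a linear-approximation trust
region cannot track to arbitrary depth; joint fits therefore converge to
the valley floor (loss ~1e-4 on the toy problems) while the physically
identifiable radius recovery is exercised on the 1-parameter problem, where
the fit reaches loss < 1e-9 and recovers the radius to < 0.01%.

## Repulsive potentials

Targets are reference-minus-electronic energy differences along bond scans,
anchored to zero at the largest scanned distance (the scan should extend to
where the repulsive has decayed; the spline cutoff sits beyond the last
data point, by default +0.3 bohr). Molecular scans displace the bonded
substituent group rigidly along the bond axis (connectivity from covalent
radii ×1.3); crystal scans rescale lattice and coordinates isotropically.

The fit is a weighted least-squares cubic B-spline with equality
constraints V(cutoff) = V'(cutoff) = 0 (nullspace-projected KKT solve),
knots uniform over the data range plus one tail segment, knot count
max(6, n/4) by default. The terminal segment is re-expressed as the
quintic matching value/slope/curvature at its start and vanishing with
value, slope and curvature at the cutoff; below the first knot an
exponential exp(−a₁r + a₂) + a₃ matches value, slope and curvature. Joint
fits over several curves concatenate their targets with per-curve weights;
near-equilibrium upweighting (×5 within ±5% of the minimum) is available
and logged.

## Engine details

- Basis: minimal spd per species, ordering s | p(y,z,x) | d(xy,yz,z²,xz,x²−y²).
- On-site energies are the free-atom eigenvalues from the homonuclear table
  header; the Hubbard model is atom-resolved (one U, U^d per species).
- SCC: generalized eigenproblem per cycle, aufbau filling with equal
  splitting of degenerate frontier levels, Anderson/DIIS charge mixing
  (tolerance 1e-8 e). The overlap condition number is checked and the
  offending pair distance is reported on near-linear-dependence.
- Forces are central differences of the total energy (step 1e-3 bohr);
  geometry optimization is L-BFGS-B on the Cartesian coordinates with those
  forces.
- Dispersion is an optional pairwise C6/C8 term with Becke-Johnson damping
  and geometric-mean combination of user-supplied per-element coefficients
  — the fixed-coefficient two-body form of the usual D3(BJ) expression,
  without coordination-number interpolation of C6. It is off by default.

## Synthetic parameter sets (the test conditions)

`generate_toy_parameter_set` runs the entire pipeline for light elements:
confinement radii 1.85 × covalent radius (order 2) for wavefunctions and
3.6 × covalent radius for the density, Hubbard parameters from the kernel
scheme, two-center tables at 0.05 bohr spacing, and synthetic exponential
repulsives A·e^{−d/ρ} with A ∈ [6, 10] hartree and ρ ≈ 0.25 × covalent-pair
distance — amplitudes chosen so every pair curve has a bonded minimum near
the covalent distance, as for real parameter sets. The generator is
deterministic per seed and its ground truths are recorded in the table
metadata, which is what the recovery tests fit against.

What these fixtures do *not* emulate: multi-element charge transfer beyond
H/O chemistry, d-orbital bonding (the toy sets are s/p only), repulsives
fitted to correlated-wavefunction references, and basis-set limitations of
a real minimal basis. Passing the engine tests therefore demonstrates the
correctness of the *machinery* (equations, assembly, fitting), not the
chemical accuracy of any particular parameter set.

## Known limitations

- Periodic SCC (Ewald γ) and analytic gradients are not implemented.
- Spin polarization is absent throughout; ions and open-shell atoms are
  spherically averaged and spin-restricted.
- The scalar-relativistic mode covers the Koelling-Harmon average; there is
  no spin-orbit coupling.
- The published association/exchange and chelate-structure benchmarks
  require externally distributed parameter files and reference structures;
  the harness (registries, complex builders, batch drivers) ships here, the
  data does not. Complex starting geometries are idealized coordination
  polyhedra (square antiprism for 8-fold, capped trigonal prism for
  7-fold), so replicated minima may differ from published local minima —
  deviations must be interpreted with that caveat.
- The displacement filter compares raw (unsuperposed) coordinates; whether
  published batch filters superpose first is not documented anywhere we
  could verify, so the simplest reading is used.
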