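# tbforge

**tbforge** builds and runs third-order self-consistent-charge tight-binding
(SCC-DFTB3) models. It covers the complete parametrization pipeline that
practitioners normally stitch together from several tools — all-electron
confined atomic DFT, Slater-Koster two-center tables, band-structure-based
confinement fitting, spline repulsive fitting, the `.skf` exchange format —
plus a molecular DFTB3 engine and the validation machinery (ligand
association/exchange energies, Kabsch RMSD) used to qualify new parameter
sets. The package was built around the extension of the
organic/biological ("3OB"-style) DFTB3 parameter family to zirconium, whose
one-center electronic parameters it reproduces from scratch.

## The model

The DFTB3 total energy is an expansion of the DFT total energy around a
superposition of neutral atomic densities:

    E = Σ_i n_i ⟨ψ_i|Ĥ⁰|ψ_i⟩
        + ½ Σ_ab Δq_a Δq_b γ_ab
        + ⅓ Σ_ab Δq_a² Δq_b Γ_ab
        + ½ Σ_ab V_ab^rep(r_ab)

where ψ_i are molecular orbitals in a minimal basis of *confined*
pseudoatomic orbitals, Δq_a are self-consistent Mulliken charge
fluctuations, γ_ab(r) interpolates between the atomic chemical hardness
U_a and 1/r, Γ_ab = (∂γ_ab/∂U_a)·U_a^d carries the third-order charge
dependence, and V^rep is a fitted pairwise spline. Every ingredient —
ε_μ, U, U^d, the H⁰/S tables, V^rep — is produced by this package from
atomic DFT plus fitting; `docs/methods.md` documents the numerics.

## Worked example

Generate a self-consistent H/O parameter set end to end (confined atoms →
two-center tables → synthetic repulsive → `.skf` files) and compute the
DFTB3 energy of a water molecule:

```python
from tbforge import generate_toy_parameter_set, scc_solve
from tbforge.structure import from_angstrom

params = generate_toy_parameter_set(("H", "O"), seed=7)
water = from_angstrom(
    ["O", "H", "H"],
    [[0.0, 0.0, 0.0], [0.9572, 0.0, 0.0], [-0.2399, 0.9266, 0.0]],
)
res = scc_solve(water, params)
print(f"E_H0     = {res.e_h0:.6f} Ha")
print(f"E_gamma  = {res.e_gamma:.6f} Ha")
print(f"E_gamma3 = {res.e_gamma3:.6f} Ha")
print(f"E_rep    = {res.e_rep:.6f} Ha")
print(f"E_total  = {res.e_total:.6f} Ha")
print("Mulliken dq:", res.charges.round(4))
```

prints

```
E_H0     = -4.603743 Ha
E_gamma  = 0.006188 Ha
E_gamma3 = -0.002760 Ha
E_rep    = 0.264645 Ha
E_total  = -4.335670 Ha
Mulliken dq: [ 0.4441 -0.222  -0.222 ]
```

`E_H0` is the band-structure energy of the reference Hamiltonian, the two
γ terms are the second- and third-order charge-fluctuation corrections
(oxygen gains 0.44 electrons at hydrogen's expense), and `E_rep` is the
pairwise repulsive contribution; their sum is the total energy of this
model. The same functionality is exposed on the command line
(`tbforge skgen`, `tbforge energy`, `tbforge opt`, `tbforge bands`,
`tbforge bandfit`, `tbforge repfit`, `tbforge bench`, `tbforge rmsd`,
`tbforge atom solve|hubbard`).

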