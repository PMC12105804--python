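# Zirconium-ligand association reactions with their published MP2/cc-pVTZ
# reference energies (kcal/mol, 0 K, no ZPE).  Complexes are generated from
# idealized coordination polyhedra and relaxed before the energies are taken;
# running this registry requires the full 3OB parameter files plus the
# zirconium extension in data/external/zr3ob/ (not redistributable here).
#
# Coordination numbers of the "complex before association" rows follow the
# standard hydration/ammine series; where a printed subscript was ambiguous
# the chemically standard value is used.
reactions:
  - label: "[Zr(H2O)6]4+ + H2O"
    reference: -57.9
    reactants: [{metal: Zr, ligand: H2O, n: 6, charge: 4}, {ligand: H2O}]
    products: [{metal: Zr, ligand: H2O, n: 7, charge: 4}]
  - label: "[Zr(H2O)7]4+ + H2O"
    reference: -53.3
    reactants: [{metal: Zr, ligand: H2O, n: 7, charge: 4}, {ligand: H2O}]
    products: [{metal: Zr, ligand: H2O, n: 8, charge: 4}]
  - label: "[Zr(H2O)8]4+ + H2O"
    reference: -34.8
    reactants: [{metal: Zr, ligand: H2O, n: 8, charge: 4}, {ligand: H2O}]
    products: [{metal: Zr, ligand: H2O, n: 9, charge: 4}]
  - label: "[Zr(NH3)6]4+ + NH3"
    reference: -93.0
    reactants: [{metal: Zr, ligand: NH3, n: 6, charge: 4}, {ligand: NH3}]
    products: [{metal: Zr, ligand: NH3, n: 7, charge: 4}]
  - label: "[Zr(NH3)7]4+ + NH3"
    reference: -79.7
    reactants: [{metal: Zr, ligand: NH3, n: 7, charge: 4}, {ligand: NH3}]
    products: [{metal: Zr, ligand: NH3, n: 8, charge: 4}]
  - label: "[Zr(SH2)6]4+ + SH2"
    reference: -71.0
    reactants: [{metal: Zr, ligand: SH2, n: 6, charge: 4}, {ligand: SH2}]
    products: [{metal: Zr, ligand: SH2, n: 7, charge: 4}]
  - label: "[Zr(SH2)7]4+ + SH2"
    reference: -60.5
    reactants: [{metal: Zr, ligand: SH2, n: 7, charge: 4}, {ligand: SH2}]
    products: [{metal: Zr, ligand: SH2, n: 8, charge: 4}]
  - label: "[Zr(PH3)6]4+ + PH3"
    reference: -74.7
    reactants: [{metal: Zr, ligand: PH3, n: 6, charge: 4}, {ligand: PH3}]
    products: [{metal: Zr, ligand: PH3, n: 7, charge: 4}]
  - label: "[Zr(PH3)7]4+ + PH3"
    reference: -65.3
    reactants: [{metal: Zr, ligand: PH3, n: 7, charge: 4}, {ligand: PH3}]
    products: [{metal: Zr, ligand: PH3, n: 8, charge: 4}]
  - label: "ZrMg + Mg"
    reference: -7.8
    reactants: [{metal: Zr, ligand: Mg, n: 1, charge: 0}, {ligand: Mg}]
    products: [{metal: Zr, ligand: Mg, n: 2, charge: 0}]
  - label: "ZrCa + Ca"
    reference: -5.6
    reactants: [{metal: Zr, ligand: Ca, n: 1, charge: 0}, {ligand: Ca}]
    products: [{metal: Zr, ligand: Ca, n: 2, charge: 0}]
  - label: "ZrZn + Zn"
    reference: 0.1
    reactants: [{metal: Zr, ligand: Zn, n: 1, charge: 0}, {ligand: Zn}]
    products: [{metal: Zr, ligand: Zn, n: 2, charge: 0}]
  - label: "[ZrH3]- + H-"
    reference: -88.0
    reactants: [{metal: Zr, ligand: H, n: 3, charge: -1}, {ligand: H, charge: -1}]
    products: [{metal: Zr, ligand: H, n: 4, charge: -2}]
  - label: "[Zr(CH3)3]- + CH3-"
    reference: -82.7
    reactants: [{metal: Zr, ligand: CH3, n: 3, charge: -1}, {ligand: CH3, charge: -1}]
    products: [{metal: Zr, ligand: CH3, n: 4, charge: -2}]
  - label: "[ZrH3F] + F-"
    reference: -121.3
    reactants:
      - {metal: Zr, ligands: [{ligand: H, n: 3}, {ligand: F, n: 1}], charge: 0}
      - {ligand: F, charge: -1}
    products:
      - {metal: Zr, ligands: [{ligand: H, n: 3}, {ligand: F, n: 2}], charge: -1}
  - label: "[ZrH3Cl] + Cl-"
    reference: -73.4
    reactants:
      - {metal: Zr, ligands: [{ligand: H, n: 3}, {ligand: Cl, n: 1}], charge: 0}
      - {ligand: Cl, charge: -1}
    products:
      - {metal: Zr, ligands: [{ligand: H, n: 3}, {ligand: Cl, n: 2}], charge: -1}
  - label: "[ZrH3Br] + Br-"
    reference: -65.1
    reactants:
      - {metal: Zr, ligands: [{ligand: H, n: 3}, {ligand: Br, n: 1}], charge: 0}
      - {ligand: Br, charge: -1}
    products:
      - {metal: Zr, ligands: [{ligand: H, n: 3}, {ligand: Br, n: 2}], charge: -1}
  - label: "[ZrH3I] + I-"
    reference: -58.4
    reactants:
      - {metal: Zr, ligands: [{ligand: H, n: 3}, {ligand: I, n: 1}], charge: 0}
      - {ligand: I, charge: -1}
    products:
      - {metal: Zr, ligands: [{ligand: H, n: 3}, {ligand: I, n: 2}], charge: -1}
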