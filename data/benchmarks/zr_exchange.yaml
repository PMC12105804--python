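# Zirconium ligand-exchange reactions with published MP2 references
# (kcal/mol); same conventions as zr_association.yaml.
reactions:
  - label: "K + ZrHNa -> Na + ZrHK"
    reference: -1.8
    reactants:
      - {ligand: K}
      - {metal: Zr, ligands: [{ligand: H, n: 1}, {ligand: Na, n: 1}], charge: 0}
    products:
      - {ligand: Na}
      - {metal: Zr, ligands: [{ligand: H, n: 1}, {ligand: K, n: 1}], charge: 0}
  - label: "Ca + ZrMg -> Mg + ZrCa"
    reference: 4.0
    reactants:
      - {ligand: Ca}
      - {metal: Zr, ligand: Mg, n: 1, charge: 0}
    products:
      - {ligand: Mg}
      - {metal: Zr, ligand: Ca, n: 1, charge: 0}
  - label: "Cl- + [ZrH3F] -> F- + [ZrH3Cl]"
    reference: 50.9
    reactants:
      - {ligand: Cl, charge: -1}
      - {metal: Zr, ligands: [{ligand: H, n: 3}, {ligand: F, n: 1}], charge: 0}
    products:
      - {ligand: F, charge: -1}
      - {metal: Zr, ligands: [{ligand: H, n: 3}, {ligand: Cl, n: 1}], charge: 0}
  - label: "I- + [Zr(NH3)3Br]3+ -> Br- + [Zr(NH3)3I]3+"
    reference: 11.1
    reactants:
      - {ligand: I, charge: -1}
      - {metal: Zr, ligands: [{ligand: NH3, n: 3}, {ligand: Br, n: 1}], charge: 3}
    products:
      - {ligand: Br, charge: -1}
      - {metal: Zr, ligands: [{ligand: NH3, n: 3}, {ligand: I, n: 1}], charge: 3}
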