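# External reference data (not redistributable)

The published-benchmark tests look for the following here:

- `zr3ob/` — the 3OB base Slater-Koster set (dftb.org) together with the
  zirconium extension `.skf` files from the corresponding supplementary
  material (`Zr-Zr.skf`, `Zr-X.skf`, `X-Zr.skf` for X in the 3OB element
  list).
- `zr_dfo_b3lyp.xyz` — the B3LYP-optimized 3-cis zirconium-desferrioxamine
  structure from the original radiotracer study's supporting information.

Without these files the two external-benchmark tests fail with a message
pointing here; everything else in the test suite is self-contained.
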