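# Bundled 4-reaction stand-in myoglobin oxidation scheme.
#
# This is NOT a literature scheme: it is a minimal surrogate that reproduces
# the qualitative surface-color behaviour of refrigerated beef (surface
# redness holds near its bloomed value for about 10 days at 2 degC / 20% O2
# with threshold S = 2 and Ea = 32.5 kJ/mol, and high headspace O2 delays
# browning). Rate constants were tuned with scripts/tune_default_scheme.py
# (committed); re-run it after editing anything here. Users with a full
# literature scheme can drop in their own file in the same format.
#
# Units: myoglobin forms are dimensionless fractions summing to 1; dissolved
# O2 is mol m^-3. Rate-constant units are per reaction, noted below.
description: >-
  4-reaction stand-in: oxygenation, deoxygenation, autoxidation of
  oxymyoglobin to metmyoglobin, and a weak metmyoglobin reduction.
species:
  - {name: Mb, role: myoglobin-form, diffusive: false}
  - {name: MbO2, role: myoglobin-form, diffusive: false}
  - {name: MMb, role: myoglobin-form, diffusive: false}
  - {name: O2, role: dissolved-gas, diffusive: true}
reactions:
  - name: oxygenation
    reactants: {Mb: 1, O2: 1}
    products: {MbO2: 1}
    k_ref: 2.72e-3
    units: (mol m^-3)^-1 s^-1
  - name: deoxygenation
    reactants: {MbO2: 1}
    products: {Mb: 1, O2: 1}
    k_ref: 1.0e-4
    units: s^-1
  - name: autoxidation
    reactants: {MbO2: 1}
    products: {MMb: 1}
    k_ref: 7.1427e-7
    units: s^-1
  - name: mmb-reduction
    reactants: {MMb: 1}
    products: {Mb: 1}
    k_ref: 1.0e-8
    units: s^-1
T_ref_C: 20.0
D_O2_m2_s: 1.0e-9
Ea_kJ_mol: 32.5
o2_solubility_mol_m3_per_pct: 0.0135
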