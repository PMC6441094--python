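# Acid + alcohol -> ester written without the condensation water.
name: esterification
reactant_smarts:
  - "[C:1](=[O:2])[OX2:3][H]"
  - "[O:4]([H])[CX4:5]"
product_smarts:
  - "[C:1](=[O:2])[O:4][CX4:5]"
completion:
  side: products
  species: ["O"]
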