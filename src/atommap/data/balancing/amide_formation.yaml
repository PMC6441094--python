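# Acid + amine -> amide written without the condensation water.
name: amide-formation
reactant_smarts:
  - "[C:1](=[O:2])[OX2:3][H]"
  - "[NX3:4][H]"
product_smarts:
  - "[C:1](=[O:2])[N:4]"
completion:
  side: products
  species: ["O"]
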