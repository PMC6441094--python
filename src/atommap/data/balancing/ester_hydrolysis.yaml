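# Ester -> acid + alcohol written without the consumed water; the alcohol
# keeps the bridge oxygen (acyl-oxygen cleavage).
name: ester-hydrolysis
reactant_smarts:
  - "[C:1](=[O:2])[O:3][CX4:4]"
product_smarts:
  - "[C:1](=[O:2])[OX2][H]"
  - "[O:3]([H])[CX4:4]"
completion:
  side: reactants
  species: ["O"]
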