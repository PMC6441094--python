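# Keto-enol tautomerization.  A notational rather than chemical change, hence
# the negative score: choosing the other tautomer form should not penalize an
# otherwise correct mapping.
id: j
name: keto-enol-tautomerization
group: carbonyl
score: -1.5
pattern: "[O:1]=[C:2][C:3][H:4]"
edits:
  - [order, 1, 2, 1]
  - [order, 2, 3, 2]
  - [break, 3, 4]
  - [form, 1, 4, 1]
protect: []
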