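# [4+2] cycloaddition (Diels-Alder): diene + dienophile close a six-ring.
id: a
name: diels-alder-cycloaddition
group: pericyclic
score: 0.5
pattern: "[C:1]=[C:2]-[C:3]=[C:4].[C:5]=[C:6]"
edits:
  - [order, 1, 2, 1]
  - [order, 2, 3, 2]
  - [order, 3, 4, 1]
  - [order, 5, 6, 1]
  - [form, 1, 6, 1]
  - [form, 4, 5, 1]
protect:
  - [1, 6]
  - [4, 5]
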