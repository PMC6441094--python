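# [2+2] cycloaddition (ketene-type when position 1 is oxygen-bearing carbonyl).
id: d
name: two-plus-two-cycloaddition
group: pericyclic
score: 0.5
pattern: "[C,O:1]=[C:2].[C:3]=[C:4]"
edits:
  - [order, 1, 2, 1]
  - [order, 3, 4, 1]
  - [form, 1, 4, 1]
  - [form, 2, 3, 1]
protect:
  - [1, 4]
  - [2, 3]
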