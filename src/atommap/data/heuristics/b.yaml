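# [3,3]-sigmatropic shift (Cope; Claisen when position 3 or 4 is oxygen).
id: b
name: sigmatropic-3-3-shift
group: pericyclic
score: 0.5
pattern: "[C:1]=[C:2]-[C,O:3]-[C,O:4]-[C:5]=[C:6]"
edits:
  - [break, 3, 4]
  - [form, 1, 6, 1]
  - [order, 1, 2, 1]
  - [order, 2, 3, 2]
  - [order, 5, 6, 1]
  - [order, 4, 5, 2]
protect:
  - [1, 6]
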