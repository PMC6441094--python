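# Electrocyclic ring closure: hexatriene to cyclohexadiene.
id: c
name: electrocyclic-closure
group: pericyclic
score: 0.5
pattern: "[C:1]=[C:2]-[C:3]=[C:4]-[C:5]=[C:6]"
edits:
  - [order, 1, 2, 1]
  - [order, 2, 3, 2]
  - [order, 3, 4, 1]
  - [order, 4, 5, 2]
  - [order, 5, 6, 1]
  - [form, 1, 6, 1]
protect:
  - [1, 6]
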