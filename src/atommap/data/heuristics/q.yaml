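# Beckmann-type rearrangement: oxime to amide with migration of the carbon
# substituent anti to the leaving hydroxyl.
id: q
name: beckmann-rearrangement
group: rearrangement
score: 0.5
pattern: "[C:5][C:1]=[N:2][O:3][H:4]"
edits:
  - [break, 1, 5]
  - [form, 2, 5, 1]
  - [break, 2, 3]
  - [order, 1, 2, 1]
  - [form, 1, 3, 2]
  - [break, 3, 4]
  - [form, 2, 4, 1]
protect:
  - [2, 5]
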