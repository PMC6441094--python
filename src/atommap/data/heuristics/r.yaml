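# Allylic 1,3-hydrogen shift (alkene walk).  Scored zero: it relocates a
# notational double bond rather than encoding new chemistry.
id: r
name: allylic-hydrogen-shift
group: rearrangement
score: 0.0
pattern: "[C:1]=[C:2][CX4:3][H:4]"
edits:
  - [break, 3, 4]
  - [form, 1, 4, 1]
  - [order, 1, 2, 1]
  - [order, 2, 3, 2]
protect: []
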