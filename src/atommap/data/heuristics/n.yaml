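# Allylic 1,3-transposition of a heteroatom substituent (SN2'-type).
id: n
name: allylic-transposition
group: rearrangement
score: 0.5
pattern: "[C:1]=[C:2][CX4:3][O,N,F,Cl,Br,I:4]"
edits:
  - [break, 3, 4]
  - [form, 1, 4, 1]
  - [order, 1, 2, 1]
  - [order, 2, 3, 2]
protect: []
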