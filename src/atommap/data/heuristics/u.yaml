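# Retro-[4+2]: cyclohexene ring opens to diene plus dienophile.
id: u
name: retro-diels-alder
group: rearrangement
score: 0.5
pattern: "[C:1]1=[C:2][C:3][C:4][C:5][C:6]1"
edits:
  - [break, 3, 4]
  - [break, 5, 6]
  - [order, 1, 2, 1]
  - [order, 2, 3, 2]
  - [order, 4, 5, 2]
  - [order, 6, 1, 2]
protect: []
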