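# Meinwald rearrangement: epoxide to carbonyl with 1,2-hydride shift.
id: p
name: meinwald-epoxide-rearrangement
group: rearrangement
score: 0.5
pattern: "[C:1]([H:4])1[O:2][C:3]1"
edits:
  - [break, 2, 3]
  - [break, 1, 4]
  - [form, 3, 4, 1]
  - [order, 1, 2, 2]
protect: []
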