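# Pinacol rearrangement, hydride shift variant.
id: m
name: pinacol-hydride-shift
group: rearrangement
score: 0.5
pattern: "[O:1]([H:2])[C:3]([H:4])[C:5][O:6][H:7]"
edits:
  - [break, 3, 4]
  - [form, 5, 4, 1]
  - [break, 5, 6]
  - [break, 1, 2]
  - [form, 6, 2, 1]
  - [order, 1, 3, 2]
protect: []
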