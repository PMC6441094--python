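# Prins-pinacol cascade, hydride shift variant.
id: t
name: prins-pinacol-hydride-shift
group: rearrangement
score: 0.5
pattern: "[H:1][C:2]([O:3][H:4])[C:5]=[C:6].[C:7]=[O:8]"
edits:
  - [order, 5, 6, 1]
  - [form, 6, 7, 1]
  - [order, 7, 8, 1]
  - [break, 3, 4]
  - [form, 8, 4, 1]
  - [break, 2, 1]
  - [form, 5, 1, 1]
  - [order, 2, 3, 2]
protect:
  - [6, 7]
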