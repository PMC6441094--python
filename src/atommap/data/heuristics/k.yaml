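# Olefin metathesis: two C=C bonds are fully broken and the alkylidene halves
# recombined, compensating for the unwritten organometallic catalyst.
id: k
name: olefin-metathesis
group: missing-information
score: 0.5
pattern: "[C:1]=[C:2].[C:3]=[C:4]"
edits:
  - [break, 1, 2]
  - [break, 3, 4]
  - [form, 1, 3, 2]
  - [form, 2, 4, 2]
protect:
  - [1, 3]
  - [2, 4]
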