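# Addition of an O-H nucleophile across a carbonyl (hemiacetal, hydrate).
id: g
name: carbonyl-oh-addition
group: carbonyl
score: 0.5
pattern: "[C:1]=[O:2].[O:3][H:4]"
edits:
  - [order, 1, 2, 1]
  - [form, 1, 3, 1]
  - [break, 3, 4]
  - [form, 2, 4, 1]
protect:
  - [1, 3]
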