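# Aldol-type condensation: enolizable carbonyl + carbonyl partner give the
# unsaturated carbonyl with loss of a water molecule (expelled as a separate
# component; atom count is conserved).
id: h
name: aldol-condensation
group: carbonyl
score: 0.5
pattern: "[C:1](=[O:2])[C:3]([H:4])[H:5].[C:6]=[O:7]"
edits:
  - [break, 3, 4]
  - [break, 3, 5]
  - [break, 6, 7]
  - [form, 3, 6, 2]
  - [form, 7, 4, 1]
  - [form, 7, 5, 1]
protect:
  - [3, 6]
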