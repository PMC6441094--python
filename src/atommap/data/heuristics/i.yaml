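# Robinson annulation: Michael addition of a ketone alpha-carbon to an enone
# followed by intramolecular aldol condensation (water expelled).
id: i
name: robinson-annulation
group: carbonyl
score: 1.0
pattern: "[C:1]=[C:2][C:3](=[O:4])[C:5]([H:6])[H:7].[C:8]([H:9])[C:10]=[O:11]"
edits:
  - [form, 1, 8, 1]
  - [order, 1, 2, 1]
  - [break, 8, 9]
  - [form, 2, 9, 1]
  - [break, 5, 6]
  - [break, 5, 7]
  - [break, 10, 11]
  - [form, 5, 10, 2]
  - [form, 11, 6, 1]
  - [form, 11, 7, 1]
protect:
  - [1, 8]
  - [5, 10]
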