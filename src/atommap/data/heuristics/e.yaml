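# Anhydride + carboxylic acid exchange: the central oxygen of the new
# anhydride derives from the acid hydroxyl, not the old anhydride bridge.
id: e
name: anhydride-acid-exchange
group: symmetry-disambiguation
score: 0.5
pattern: "[C:1](=[O:2])[O:3][C:4]=[O:5].[O:6]([H:7])[C:8]=[O:9]"
edits:
  - [break, 3, 4]
  - [break, 6, 7]
  - [form, 4, 6, 1]
  - [form, 3, 7, 1]
protect:
  - [4, 6]
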