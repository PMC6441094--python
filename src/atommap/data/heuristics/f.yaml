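# Esterification / acyl substitution with acyl-oxygen cleavage: the ester
# bridge oxygen derives from the alcohol; the acid OH leaves in water.
id: f
name: acyl-oxygen-esterification
group: symmetry-disambiguation
score: 0.5
pattern: "[C:1](=[O:2])[O:3][H:4].[O:5]([H:6])[CX4:7]"
edits:
  - [break, 1, 3]
  - [break, 5, 6]
  - [form, 1, 5, 1]
  - [form, 3, 6, 1]
protect:
  - [1, 5]
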