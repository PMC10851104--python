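# Chemical-component id -> post-translational modification type.
# Editable: structures may carry further modified components; add rows with
# the same layout.  Components listed here are always treated as polymer
# amino acids during chain typing.
ALY: lysine-acetylation
KCR: lysine-crotonylation
M3L: lysine-trimethylation
MLY: lysine-dimethylation
MLZ: lysine-monomethylation
SEP: serine-phosphorylation
TPO: threonine-phosphorylation
PTR: tyrosine-phosphorylation
CIR: arginine-citrullination
AGM: arginine-methylation
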