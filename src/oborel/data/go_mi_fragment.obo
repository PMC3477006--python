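format-version: 1.2

[Term]
id: GO:FIX01
name: Developmental Process
property_value: oborel:kind process

[Term]
id: GO:FIX02
name: Cellular Process
property_value: oborel:kind process

[Term]
id: GO:FIX03
name: Cellular Developmental Process
property_value: oborel:kind process
is_a: GO:FIX01
is_a: GO:FIX02

[Term]
id: GO:FIX04
name: Cell Communication
property_value: oborel:kind process

[Term]
id: GO:FIX05
name: Signaling
property_value: oborel:kind process

[Term]
id: GO:FIX06
name: Cell-Cell Signaling
property_value: oborel:kind process
is_a: GO:FIX04
is_a: GO:FIX05

[Term]
id: GO:FIX07
name: Cell Fate Commitment
property_value: oborel:kind process

[Term]
id: GO:FIX08
name: Cell-Cell Signaling Involved in Cell Fate Commitment
property_value: oborel:kind process
is_a: GO:FIX06
relationship: part_of GO:FIX07
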