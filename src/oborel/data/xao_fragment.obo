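format-version: 1.2

[Term]
id: XAO:FIX01
name: Xenopus Developmental Stage
property_value: oborel:kind process

[Term]
id: XAO:FIX02
name: Unfertilized Egg
property_value: oborel:kind process
is_a: XAO:FIX01

[Term]
id: XAO:FIX03
name: Embryonic Stage
property_value: oborel:kind process
is_a: XAO:FIX01

[Term]
id: XAO:FIX04
name: Adult
property_value: oborel:kind process
is_a: XAO:FIX01

[Term]
id: XAO:FIX05
name: Death
property_value: oborel:kind process
is_a: XAO:FIX01

[Term]
id: XAO:FIX06
name: Blastula
property_value: oborel:kind process
is_a: XAO:FIX03

[Term]
id: XAO:FIX07
name: Neurula
property_value: oborel:kind process
is_a: XAO:FIX03

[Term]
id: XAO:FIX08
name: NF Stage 7
property_value: oborel:kind process
relationship: part_of XAO:FIX06

[Term]
id: XAO:FIX09
name: NF Stage 8
property_value: oborel:kind process
relationship: part_of XAO:FIX06
relationship: preceded_by XAO:FIX08

[Term]
id: XAO:FIX10
name: NF Stage 9
property_value: oborel:kind process
relationship: part_of XAO:FIX06
relationship: preceded_by XAO:FIX09
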