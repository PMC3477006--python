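format-version: 1.2

[Term]
id: PRO:FIX01
name: TGF-Beta
property_value: oborel:kind material

[Term]
id: PRO:FIX02
name: TGF-Beta 1
property_value: oborel:kind material
is_a: PRO:FIX01

[Term]
id: PRO:FIX03
name: Proteolytic Cleavage Product
property_value: oborel:kind material

[Term]
id: PRO:FIX04
name: TGF-Beta 1 Proteolytic Cleavage Product
property_value: oborel:kind material
is_a: PRO:FIX03
relationship: derives_from PRO:FIX02

[Term]
id: PRO:FIX05
name: TGF-Beta 1 Isoform 1
property_value: oborel:kind material
is_a: PRO:FIX02

[Term]
id: PRO:FIX06
name: TGF-Beta 1 Isoform 1 Cleaved 1
property_value: oborel:kind material
is_a: PRO:FIX04
relationship: derives_from PRO:FIX05
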