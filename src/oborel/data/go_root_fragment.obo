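format-version: 1.2

[Term]
id: GO:FIX01
name: Gene Ontology

[Term]
id: GO:FIX02
name: Biological Process
property_value: oborel:kind process
is_a: GO:FIX01

[Term]
id: GO:FIX03
name: Cellular Component
property_value: oborel:kind continuant
is_a: GO:FIX01

[Term]
id: GO:FIX04
name: Molecular Function
property_value: oborel:kind process
is_a: GO:FIX01
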