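# Structure-name standardization table.
# One rule per line: <synonym-prefix> <TAB> <canonical name>.
# Matching is case-insensitive on the name with punctuation, spaces and
# digits stripped; the longest matching prefix wins. Unmatched names map
# to "other". Edit or replace (Config.synonym_table) for local naming.
prostate	target
prost	target
ptv	target
ctv	target
gtv	target
bladder	bladder
blad	bladder
vessie	bladder
rectum	rectum
rect	rectum
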