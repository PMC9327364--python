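# Nuclear retention motifs scanned by default.
#
# The sequences below are transcribed from the primary motif literature, not
# from this package's own data; verify against source before relying on them
# for a production analysis.
#
# - 5SS: consensus 5' splice-site element reported to target transcripts to
#   nuclear speckles (verify against source: Lee et al., plasmid-backbone
#   5'SS motif). Exonic AG + intronic GTRAGT consensus, 8 nt.
# - BORG: AGCCC core of the nuclear-localization element found in the Borg
#   transcript (verify against source: Zhang et al.). The reported flanking
#   context (T/A at -8, G/C at -3) can be scanned instead by using the
#   pattern WNNNNSNNAGCCC.
# - SIRLOIN: 7-nt pyrimidine-rich sub-element of the SINE-derived SIRLOIN
#   element bound by hnRNPK (verify against source: Lubelsky & Ulitsky).
- name: 5SS
  pattern: AGGTAAGT
  provenance: real
  source_note: "5' splice-site consensus; verify against source"
- name: BORG
  pattern: AGCCC
  provenance: real
  source_note: "BORG nuclear-localization core element; verify against source"
- name: SIRLOIN
  pattern: CCCTCCC
  provenance: real
  source_note: "pyrimidine-rich SIRLOIN sub-element; verify against source"
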