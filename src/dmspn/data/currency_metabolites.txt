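# Common currency metabolites (KEGG compound IDs).
# Optional blacklist for enzyme-graph construction: edges mediated only
# by these ubiquitous carriers are suppressed when the list is enabled.
cpd:C00001	# H2O
cpd:C00002	# ATP
cpd:C00003	# NAD+
cpd:C00004	# NADH
cpd:C00005	# NADPH
cpd:C00006	# NADP+
cpd:C00007	# O2
cpd:C00008	# ADP
cpd:C00009	# orthophosphate
cpd:C00010	# CoA
cpd:C00011	# CO2
cpd:C00013	# diphosphate
cpd:C00014	# NH3
cpd:C00080	# H+
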