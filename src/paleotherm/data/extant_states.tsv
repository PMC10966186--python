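taxon	state
Salamandra_salamandra	ectothermy
Pelophylax_ridibundus	ectothermy
Trachemys_scripta	ectothermy
Varanus_exanthematicus	ectothermy
Podarcis_muralis	ectothermy
Zootoca_vivipara	ectothermy
Crocodylus_niloticus	ectothermy
Gallus_gallus	endothermy
Anas_platyrhynchos	endothermy
Columba_livia	endothermy
Mus_musculus	endothermy
Rattus_norvegicus	endothermy
Oryctolagus_cuniculus	endothermy
Capreolus_capreolus	endothermy
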