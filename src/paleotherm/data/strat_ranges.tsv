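taxon	fad_ma	lad_ma
Eusthenopteron	382.7	372.2
Acanthostega	366.8	359.3
Ichthyostega	366.8	359.3
Whatcheeria	346.7	330.9
Eryops	306.0	272.3
Acheloma	290.1	272.3
Trematops	290.1	272.3
Ecolsonia	290.1	279.3
Peltobatrachus	259.5	251.9
Dutuitosaurus	237.0	227.0
Seymouria	298.9	272.3
Cardiocephalus	290.1	272.3
Limnoscelis	303.7	295.0
Diadectes	306.0	272.3
Clepsydrops	313.0	303.7
Ophiacodon	303.7	272.3
Mycterosaurus	283.5	272.3
Edaphosaurus	303.7	280.0
Sphenacodon	303.7	280.0
Dimetrodon	295.0	272.3
Pareiasaurid_indet	265.1	251.9
Labidosaurus	283.5	272.3
Romeriid_indet	307.0	298.9
Dictybolos	285.0	272.3
Rutiodon	227.0	208.5
Salamandra_salamandra	0	0
Pelophylax_ridibundus	0	0
Trachemys_scripta	0	0
Varanus_exanthematicus	0	0
Podarcis_muralis	0	0
Zootoca_vivipara	0	0
Crocodylus_niloticus	0	0
Gallus_gallus	0	0
Anas_platyrhynchos	0	0
Columba_livia	0	0
Mus_musculus	0	0
Rattus_norvegicus	0	0
Oryctolagus_cuniculus	0	0
Capreolus_capreolus	0	0
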