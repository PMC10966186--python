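specimen_id	taxon	hmc_um	pend_printed	status_printed
MNHN-Histos-373	Acanthostega	29.171	8.35e-4	Ectothermy
MNHN-Histos-375	Acheloma	19.801	5.36e-2	Ectothermy
MNHN-Histos-1890	Cardiocephalus	20.158	4.60e-2	Ectothermy
MNHN-Histos-556a	Clepsydrops	16.400	2.07e-1	Ectothermy
MNHN-Histos-556b	Clepsydrops	16.888	1.74e-1	Ectothermy
MNHN-Histos-dRC-1	Diadectes	20.904	3.34e-2	Ectothermy
MNHN-Histos-dRC-2	Dictybolos	29.215	8.19e-4	Ectothermy
MNHN-Histos-2712	Dimetrodon	26.778	2.45e-3	Ectothermy
MNHN-Histos-2713	Dimetrodon	21.363	2.73e-2	Ectothermy
MNHN-Histos-384	Dutuitosaurus	28.417	1.17e-3	Ectothermy
MNHN-Histos-386	Dutuitosaurus	20.257	4.41e-2	Ectothermy
MNHN-Histos-3060	Dutuitosaurus	33.086	1.44e-4	Ectothermy
MNHN-Histos-3068	Dutuitosaurus	16.312	2.14e-1	Ectothermy
MNHN-Histos-376	Ecolsonia	33.224	2.12e-4	Ectothermy
MNHN-Histos-463	Edaphosaurus	20.060	4.8e-2	Ectothermy
MNHN-Histos-dRC-3	Eryops	25.667	4.03e-3	Ectothermy
MNHN-Histos-531	Eusthenopteron	20.157	4.60e-2	Ectothermy
MNHN-Histos-Ia	Ichthyostega	17.300	1.49e-1	Ectothermy
MNHN-Histos-Ib	Ichthyostega	13.559	4.85e-1	Ectothermy
MNHN-Histos-433	Labidosaurus	25.341	4.66e-3	Ectothermy
MNHN-Histos-dRC-4	Limnoscelis	25.806	3.79e-3	Ectothermy
MNHN-Histos-464	Mycterosaurus	18.211	1.04e-1	Ectothermy
MNHN-Histos-459	Ophiacodon	19.152	7.06e-2	Ectothermy
MNHN-Histos-dRC-5	Pareiasaurid_indet	24.920	5.64e-3	Ectothermy
MNHN-Histos-229	Peltobatrachus	12.136	6.41e-1	Endothermy
MNHN-Histos-437	Romeriid_indet	10.246	8.07e-1	Endothermy
MNHN-Histos-3028	Rutiodon	17.413	1.42e-1	Ectothermy
MNHN-Histos-2183	Seymouria	20.607	3.79e-2	Ectothermy
MNHN-Histos-2184	Seymouria	24.190	7.80e-3	Ectothermy
MNHN-Histos-462	Sphenacodon	23.140	1.25e-2	Ectothermy
MNHN-Histos-dRC-6	Trematops	20.293	4.34e-2	Ectothermy
FMNR-PR-5022	Whatcheeria	36.005	3.86e-5	Ectothermy
FMNR-PR-5021	Whatcheeria	36.552	3.02e-5	Ectothermy
FMNR-PR-5023	Whatcheeria	31.221	3.32e-4	Ectothermy
FMNR-PR-1962	Whatcheeria	51.183	4.17e-8	Ectothermy
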