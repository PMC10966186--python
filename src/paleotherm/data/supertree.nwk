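(Eusthenopteron,(Acanthostega,(Ichthyostega,(Whatcheeria,((Eryops,(((Acheloma,Trematops),Ecolsonia)Dissorophoidea,((Peltobatrachus,Dutuitosaurus)Stereospondyli,(Salamandra_salamandra,Pelophylax_ridibundus)Lissamphibia)))Temnospondyli,(Seymouria,(Cardiocephalus,(Limnoscelis,(Diadectes,((Clepsydrops,(Ophiacodon,(Mycterosaurus,(Edaphosaurus,(Sphenacodon,(Dimetrodon,(Capreolus_capreolus,(Oryctolagus_cuniculus,(Mus_musculus,Rattus_norvegicus)))Mammalia)))))))Synapsida,(Pareiasaurid_indet,(Labidosaurus,(Romeriid_indet,(Dictybolos,(Trachemys_scripta,((Varanus_exanthematicus,(Podarcis_muralis,Zootoca_vivipara))Squamata,(Rutiodon,(Crocodylus_niloticus,((Gallus_gallus,Anas_platyrhynchos),Columba_livia)Aves))Archosauromorpha)Diapsida)))))Sauropsida)Amniota)Cotylosauria)))Tetrapoda))))Tetrapodomorpha;
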