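# Bundled example dataset

Inputs for the headline analysis, all plain text:

- `table1_hmc.tsv` — published harmonic-mean vascular canal diameters (µm)
  for 35 femoral thin sections of 25 Paleozoic/Triassic tetrapod taxa,
  together with the published probabilities of endothermy and statuses
  they imply (columns `pend_printed`, `status_printed`, kept at printed
  precision for regression testing). Specimen ids follow the source
  collections (MNHN hard-tissue collection, Paris; Field Museum, Chicago);
  sections without a printed number carry a short disambiguating suffix.
- `supertree.nwk` — a composite cladogram of those 25 fossil taxa plus 14
  extant calibration tetrapods, assembled from standard phylogenetic
  placements. Internal nodes of interest are labeled (`Amniota`, `Aves`,
  `Mammalia`, `Stereospondyli`, ...). The original analysis used a
  supplementary supertree that is not redistributable here; this file is a
  reconstruction of it, so ensemble results are approximate, not exact.
- `strat_ranges.tsv` — first/last appearance data (Ma) per taxon, rounded
  from Paleobiology Database stage boundaries; extant taxa have 0/0.
- `extant_states.tsv` — known thermophysiology of the extant tips.

The extant species list of the original calibration set is likewise not
redistributable; the 14 species here are a representative stand-in
(3 birds, 4 mammals, 7 ectotherms) occupying the same clades.
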