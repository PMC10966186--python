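# paleotherm

Inference of thermophysiology (endothermy vs ectothermy) in extinct
tetrapods from bone histology, end to end:

1. **histology** — read per-canal diameter tables and compute the harmonic
   mean canal diameter (HMC, µm) per thin section.
2. **logistic** — convert HMC to a probability of endothermy
   (`p_end = expit(c·HMC + i)`, defaults `c = −0.45`, `i = 6.04`) and
   classify against a cut-off (`p_end ≥ 0.59` ⇒ endothermic).
3. **tree_time** — parse a fossil cladogram (Newick), sample tip ages
   uniformly within stratigraphic ranges (FAD/LAD, Ma), and time-scale it
   with the `equal` (even respacing of undatable nodes, with a root
   buffer) or `mbl` (minimum branch length, 1 Myr) algorithm.
4. **mk_asr** — binary Mk model: closed-form transition probabilities,
   Felsenstein pruning likelihood, bounded ML rate fitting (ER/ARD, flat
   or stationary root prior), marginal ancestral-state reconstruction by
   one post-order + one pre-order pass (equivalent to rerooting), plus an
   exhaustive brute-force oracle for testing. Tips may also carry soft
   probability vectors instead of hard states.
5. **ensemble** — orchestrates the whole pipeline: 100 dated trees per
   algorithm (repetition *r* uses `seed + r`), per-tree rate refit and
   ASR, then per-node mean/median of the probability of ancestral
   endothermy (`p_asend`).
6. **synthetic_data** — birth–death trees with fossil tips, Mk-evolved
   states, state-conditional lognormal canal diameters and bracketing
   stratigraphic ranges, so everything is testable without downloads.

A small example dataset ships with the package
(`src/paleotherm/data/`, see its README for provenance): 35 published
per-specimen HMC values for 25 Paleozoic/Triassic taxa, a reconstructed
composite supertree with labeled nodes (`Amniota`, `Aves`, `Mammalia`,
`Stereospondyli`), stratigraphic ranges, and extant calibration states.

## CLI

```sh
# Table-style classification of thin sections
paleotherm classify --measurements measurements.tsv

# 100 dated trees per algorithm
paleotherm timescale --tree tree.nwk --ranges ranges.tsv \
    --method mbl --reps 100 --seed 1 --out trees/

# single-tree marginal ASR on a dated Newick
paleotherm asr --tree trees/mbl_rep_001.nwk --states states.tsv

# full pipeline (writes summary_{equal,mbl}_{mean,median}.tsv,
# per-repetition Newicks and a JSON manifest)
paleotherm run --measurements measurements.tsv --extant-states extant.tsv \
    --tree tree.nwk --ranges ranges.tsv --reps 100 --seed 1 --out out/

# synthetic dataset
paleotherm simulate --seed 7 --out sim/
```

Configuration (YAML, all optional): `logistic.coefficient`,
`logistic.intercept`, `logistic.threshold`, `root_buffer`, `min_len`,
`mk_model` (`ER`/`ARD`), `root_prior` (`flat`/`stationary`), `reps`,
`seed`.

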