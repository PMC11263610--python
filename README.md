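# mixshift

Micropollutant dissipation and non-additive mixture effects on prokaryotic
communities at the sediment–water interface.

Pesticides and pharmaceuticals reach rivers as mixtures. At the
sediment–water interface they partition, dissipate (abiotically and
through biodegradation), and put selective pressure on the prokaryotic
communities living there. `mixshift` is an analysis pipeline for microcosm
experiments probing both sides of that interaction — built around three
model compounds spiked singly (ONE) or together (MIX): metformin (MFN, a
hydrophilic antidiabetic), metolachlor (MET, an agricultural herbicide)
and terbutryn (TER, a sediment-bound biocide) — together with a
synthetic-data generator with planted ground truth so the whole chain is
testable without any sequencing download.

## What it computes

**Kinetics** — first-order dissipation C_t = C_0·e^(−kt) fitted on pooled
replicates (log-linear OLS), DT50 ranges ln2/(k±SE), CI95 of k, percent
dissipation with 1σ error propagation, and the biodegradation fraction

    B,t % = D_biotic,t % − D_abiotic,t %

**Community statistics** — replicate-prevalence filtering of ASV tables,
taxonomic aggregation with `unclassified <lineage>` grouping, alpha
diversity (observed/Chao1/ACE, Shannon, Simpson, Pielou/Camargo/Simpson
evenness, Good's coverage), rarefaction, Bray–Curtis distances,
mean-distance UPGMA dendrograms, and PERMANOVA with sequential sums of
squares supporting strata-restricted and exhaustive permutations.

**Mixture-effect classification** — the core statistic chain, per taxon
and stratum (matrix × timepoint), on relative abundances:

    FC  = (mean_sample + 0.001) / (mean_CTRL + 0.001)
    IC  = FC − 1
    IC_ADD = max(−1, IC_MFN + IC_MET + IC_TER)

IC_MIX is compared with IC_ADD under conservative ±64 % relative
uncertainty bands: overlap → **additive**; disjoint bands of opposite
sign → **antagonism (opposing)**; otherwise **synergism** when
|IC_MIX| > |IC_ADD|, else **antagonism (repressing)**. Contributor
ranking then asks which single compound best explains the mixture
response. See `docs/methods.md` for the full model account.

## Worked example

Generate a synthetic experiment, fit its kinetics, and classify mixture
effects (the numbered scripts under `analysis/` run the same steps with
narration; outputs land in `results/`):

```
$ python analysis/01_simulate.py 1
$ python analysis/02_kinetics.py
fitted first-order rates (simulated data, system phase):
compound condition_type  k_biotic  k_abiotic  b_pct  b_sd
     MET            ONE     0.044      0.060   -3.0   1.0
     MFN            ONE     0.059      0.019   24.0   2.0
     TER            ONE     0.004      0.006   -8.0  10.0
...
MFN biotic vs abiotic CI95 disjoint: True (significant biodegradation)
```

Reading this: only MFN dissipates faster with biology present (k 0.059 vs
0.019 per day; ~24 % of its day-70 loss attributed to biodegradation);
MET's dissipation is mostly abiotic (b_pct ≈ 0 or negative), and TER
barely dissipates at all (k ≈ 0.005/day, DT50 beyond 100 days).

```
$ python analysis/04_interactions.py
confusion (planted taxa, expected vs called):
called                 additive  antagonism_opposing  antagonism_repressing  synergism
expected_category
additive                     40                    0                      0          0
antagonism_opposing           0                   40                      0          0
antagonism_repressing        0                    0                     40          0
synergism                     0                    2                      0         38

recovery of planted synergism/opposing: 97.5% (n=80); false non-additive
on planted-additive: 0.0% (n=40)
```

Reading this: on a community with 10 taxa planted per interaction
category, the FC→IC→classification chain recovers nearly every planted
non-additive taxon and never miscalls a planted-additive one; the two
misses are synergistic taxa whose near-zero additive expectation flipped
sign under count noise.

The same steps are scriptable via the CLI
(`mixshift simulate|kinetics|diversity|permanova|interactions|run|validate`),
e.g.:

```
mixshift simulate --seed 1 --benchmark --out sim/
mixshift permanova --counts sim/counts.tsv --taxonomy sim/taxonomy.tsv \
    --metadata sim/metadata.tsv --terms matrix,timepoint,condition \
    --strata matrix --permutations 9999 --seed 1 --out permanova.tsv
```

## Layout

```
src/mixshift/        library (synth, kinetics, community, interactions,
                     pipeline, experiments, refdata, cli)
analysis/            numbered narrative drivers writing results/
tests/               pytest suite (unit, property, acceptance)
scripts/acceptance.py  headline-quantity recomputation
docs/methods.md      model and design notes
```

File formats are plain TSV (UTF-8, tab-separated, '#'-prefixed header
lines carrying the config hash and seed), Newick for trees, JSON for
configuration and manifests. Identical config + seed reruns are
byte-identical.
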