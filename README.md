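# tnselect

Tn-Seq selection profiling for phage-resistance screens.

When a dense pooled transposon mutant library of a bacterium is challenged
with a lytic phage at high multiplicity of infection, the mutants that
survive are concentrated in genes whose disruption blocks infection —
receptor synthesis, envelope modification, and their supporting pathways.
`tnselect` turns the sequencing readout of such a screen (per-site
transposon insertion counts for challenged and untreated samples) into a
ranked table of candidate resistance loci, and supplies everything needed
to validate and stress-test that inference: a synthetic
library-under-selection generator with planted ground truth, phenotypic
profile clustering, and the phage adsorption / infection-center statistics
used to follow up hits.

It is written for microbial functional genomicists running or re-analysing
pooled selection screens (phage, antibiotic, or other killing selections)
who want a small, fully tested, scriptable pipeline rather than a web
platform.

## The statistic at the core

For each phage-challenged replicate with paired untreated control:

1. **Normalization.** Challenged site counts are scaled by
   `control_total / challenged_total`, so challenged and control totals
   match.
2. **Per-gene fold change.** For gene *g* with normalized challenged total
   *c̃_g* and control total *k_g*,
   `log2FC_g = log2((c̃_g + 1) / (k_g + 1))` (pseudocount 1, configurable).
3. **Mann–Whitney U.** Per-site counts within the gene (challenged vs
   control, over the union of observed sites) are compared with a
   two-sided U test — exact by enumeration for ≤ 8 sites per group
   (ties handled exactly), tie-corrected normal approximation above.
4. **Hit call.** A gene is a hit when `log2FC > 2` **and** the challenged
   sample has **more than one** unique insertion site, in **every**
   replicate. A second display tier (`strong_hit`) marks `log2FC > 5`
   everywhere. Genes shorter than 400 bp that fail only the
   unique-insertion filter are flagged for manual review, never
   auto-called. Depleted genes are reported but never interpreted.

Benjamini–Hochberg q-values and replicate reproducibility (Pearson r of
per-gene log2FC, and of the normalized insertion profiles) are emitted for
transparency; neither gates hit calling.

## Worked example

```python
from tnselect import SelectionModel, simulate_experiment, TnSeqScreenModel
from tnselect.pipeline import score_against_truth

# a two-replicate screen: 2,000 genes, 1e5 mutants, 10 resistance and
# 5 costly-resistance genes planted, escape baseline 1e-3
exp = simulate_experiment(SelectionModel(seed=1))
results = TnSeqScreenModel.from_experiment(exp).fit()
print(results.summary())
print(score_against_truth(results.hits, exp.truth))
```

prints (abridged):

```
               Tn-Seq phage-selection screen
============================================================
genes analysed:            2000
replicates:                2
fc threshold (log2):       > 2.0
...
hits:                      15
strong hits:               15
small-gene review flags:   0
depleted genes (not hits): 1882
replicate log2fc Pearson r: 0.499
replicate profile Pearson r: 0.982
============================================================
ScreenScore(sensitivity=1.0, false_positives=0, precision=1.0,
            n_planted=15, n_called=15)
```

All 15 planted resistance genes are recovered with no false positives.
The insertion profiles of the two challenges are nearly identical
(r = 0.98); the per-gene log2FC correlation is lower because rare
phage-escape survivors inject large, replicate-independent fold-change
spikes into otherwise fully depleted genes (see `docs/methods.md`).

The same analysis runs from the shell:

```bash
tnselect simulate --seed 1 --out sim/
tnselect enrich --sample-sheet sim/samples.tsv --counts sim/counts.tsv \
    --gff sim/genome.gff3 --out screen/
tnselect score --hits screen/hits.tsv --truth sim/truth.tsv
tnselect cluster --matrix profiles.tsv --r-threshold 0.9 --out clusters/
tnselect kinetics adsorption --data adsorption.tsv --cell-density 1e8
```

## Layout

- `tnselect.genome` — annotation/count-table types, GFF3/TSV/track I/O,
  site→gene assignment
- `tnselect.simulate` — the generative model of a library under selection
- `tnselect.enrichment` — normalization, fold change, U test, hit calling;
  `TnSeqScreenModel.fit() -> TnSeqScreenResults`
- `tnselect.profiling` — correlation-threshold clustering of phenotypic
  profiles
- `tnselect.kinetics` — adsorption fractions/rates, ECOI, t tests
- `tnselect.pipeline`, `tnselect.cli` — config, orchestration, CLI
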