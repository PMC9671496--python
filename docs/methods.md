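# Methods

## The screen and its inference

A pooled transposon mutant library is challenged with a lytic phage at
high multiplicity of infection; survivors are plated, pooled, and the
abundance of each insertion mutant is read out by sequencing insertion
junctions. Untreated aliquots of the same library are carried alongside as
paired controls. Because the selection kills essentially every
phage-sensitive cell, the analytical signal is extreme: genes whose
disruption confers resistance retain or gain read share, everything else
collapses toward zero.

The per-gene inference is deliberately simple and mirrors how such screens
are analysed in practice:

- challenged counts are normalized by total library size to the paired
  control (`scale = control_total / challenged_total`), so a gene's
  normalized challenged total and control total are directly comparable;
- the per-gene effect is `log2((challenged_norm + c) / (control + c))`
  with pseudocount `c = 1` (most genes have zero surviving reads, so a
  pseudocount is required for finiteness; `c` is configurable and echoed
  in run metadata);
- a two-sided Mann–Whitney U test compares per-site counts within the
  gene between the normalized challenged sample and the control, over the
  union of sites observed in either (absent sites count as zero). With
  ≤ 8 sites per group the test is exact by enumerating all relabelings of
  the observed values, which handles the heavy ties in count data without
  approximation; above that it uses the tie-corrected normal
  approximation with continuity correction. Genes with no observed sites,
  or all-tied values, carry no evidence and are flagged degenerate with
  p = 1;
- a gene is called a **hit** when `log2FC > 2` *and* the challenged
  sample shows more than one unique insertion site, in every replicate; a
  **strong** display tier additionally requires `log2FC > 5` everywhere.
  The unique-insertion filter is what suppresses single-clone artifacts
  (one jackpot survivor does not implicate a gene); requiring both
  criteria in both replicates is the strict reading of the calling rule,
  with `require_all_replicates=False` available for exploratory use.

Two deliberate non-gates: p-values (and their Benjamini–Hochberg
q-values, computed via `scipy.stats.false_discovery_control` on the
worst-replicate p per gene) are reported but never decide hits, and
depleted genes (negative fold change) are reported but never interpreted —
after a killing selection, depletion mostly reflects the enormous loss of
library complexity, not biology.

**Small-gene review flag.** Genes shorter than 400 bp can fail the
unique-insertion filter simply because they present a small mutational
target. Genes that clear the fold-change bar in every replicate but fail
only the insertion filter, and are shorter than the configurable length,
are emitted in a separate review list with `small_gene_flag=true`. They
are never auto-promoted; the flag exists because such calls need a human
looking at the insertion profile (e.g. short porin genes in an operon).

**Site model.** Coordinates are 1-based inclusive (GFF3 convention); a
site belongs to a gene when `start ≤ p ≤ end`, insertion orientation is
collapsed by default (a transposon disrupts either way; a flag preserves
strands), sites in overlapping genes count for each gene, intergenic
sites are kept in their own bucket, and no terminal fraction of a gene is
trimmed by default (`edge_trim` exposes the common 5–10 % exclusion for
users who want it). Insertion sites are arbitrary genomic positions
(Tn5-style chemistry); nothing restricts them to TA dinucleotides, so
mariner-style data simply present fewer distinct sites.

## The generative model (what the simulator emulates)

`tnselect.simulate` exists so that every pipeline stage, and the caller's
operating characteristics, can be exercised with known ground truth and no
external data. Per mutant:

1. **Site placement** — uniform over non-essential gene bodies and
   intergenic space. Essential genes are insertion voids (their mutants
   never exist).
2. **Library growth** — abundance ~ Gamma(shape 1) × *w*(gene), where the
   relative fitness *w* is 1 for neutral and resistance genes, 0.1 for
   "costly" classes (mutants that survive phage but grow poorly — the
   mycolic-acid-pathway phenotype), 0 for essential.
3. **Phage challenge** — each mutant survives as a unit with probability
   *s*(gene) = 0.9 for resistance classes, otherwise the escape baseline
   ε = 1e-3 (lysogeny / phenotypic escape of sensitive mutants). Survival
   is modelled per mutant, not per cell, because survivors are recovered
   as colony units.
4. **Plating bottleneck** — when surviving mutants exceed the plate
   capacity, mutants are subsampled without replacement, weighted by
   abundance (Gumbel top-k); otherwise plating is the identity. The
   untreated control arm skips killing and passes through a 100× larger
   capacity, mirroring the protocol's asymmetric dilution.
5. **Sequencing** — Dirichlet-multinomial counts at fixed depth: per-site
   concentration `dispersion × n_sites × q_i`, so `dispersion → ∞`
   recovers plain multinomial and the default (10) gives mild (~2×)
   variance inflation typical of library prep. Totals equal the requested
   depth exactly. The challenged arm is sequenced at 1/100 the control
   depth, mirroring 1:100 pooling of low-complexity challenged libraries.

Defaults describe the scaled-down study conditions: 2,000 genes (5 %
essential, 10 resistance, 5 costly-resistance), 1e5 mutants, two
replicates, control depth 1e6. One shared library (frozen aliquots) feeds
both replicates; selection, plating, and sequencing take independent child
seeds per replicate, spawned from the master seed in a fixed documented
order (genome, library, then four children per replicate), so every stage
is independently reproducible and byte-identical across runs.

Gene lengths are Gamma(shape 4) around a 900 bp mean with a 150 bp floor
and fixed 100 bp intergenic gaps — round numbers for a typical compact
bacterial genome. Two resistance genes are deliberately drawn short
(< 400 bp) so the small-gene review path faces realistic input.

**What the simulator does not emulate.** Chromosomal insertion bias and
replication-origin coverage gradients; positional effects within genes
(domain-sparing insertions); polar effects on operons; phage host-range
evolution during the challenge; per-cell escape dynamics within a mutant
lineage; sequence-level reads (counts only). Passing tests therefore
demonstrate that the caller recovers planted signal under realistic count
noise and selection structure — not that it is robust to every artifact of
real libraries.

### A known, structural property of the escape model

With per-mutant escape at ε = 1e-3, each challenge is survived by ~100
random sensitive mutants alongside the ~700 planted-resistance mutants.
Each escapee then carries ~1/800 of the challenged read mass, which after
normalization is large against its gene's control total: ~90 random genes
per replicate get a log2FC near +1.5 instead of the depleted baseline near
−9. These spikes are independent between replicates, so the Pearson
correlation of per-gene log2FC between replicates plateaus around 0.5 even
though the insertion *profiles* (normalized per-gene challenged read
totals) correlate at ~0.98 and the caller is unaffected (escapee genes
fail the two-replicate criteria almost surely: the chance a given gene
hosts ≥ 2 escapees in *both* replicates is ~1e-6). Both reproducibility
numbers are reported on the results object (`replicate_correlation`,
`count_correlation`); the profile correlation is the one comparable to the
replicate reproducibility quoted for real screens of this design.

## Kinetics

Adsorption is measured as depletion of free phage: `fraction unadsorbed =
free_titer(t) / input_titer`, with the mock-infected input as denominator;
values above 1 are allowed (titering noise) but warned about. The
first-order model `ln(P_t/P_0) = −k·B·t` is fitted by least squares on
log-fractions to report a rate constant `k` (mL/min) with R²; nonpositive
titers are excluded from the log fit with a warning. ECOI is
`(centers/input)` normalized to the reference (wild-type) host, exactly 1
for the reference against itself. Group comparisons use the two-tailed
Welch t test (Student's pooled variant by flag) with the tiers
`* p<0.05`, `** p<0.005`, `*** p<0.001` — including the unusual 0.005
second tier. Technical titer duplicates should be averaged in pfu space
before constructing series. Significance is assessed on fractions, not raw
titers.

## Profile clustering

Phenotypic fingerprints (one row per gene, one column per stress
condition, values log2FC) are compared by Pearson correlation with
pairwise deletion of missing values and a minimum of 3 shared conditions;
fewer shared conditions or zero variance yields an explicitly missing
similarity. Clusters are connected components of the graph with an edge
when r > 0.9 — the minimal reading of "similar means correlated above
threshold" — with a greedy complete-linkage alternative by flag. Because
Pearson r is affine-invariant, clustering is unchanged by rescaling any
single profile, and raising the threshold only splits clusters. Cluster
labels are the lexicographically smallest member gene id (deterministic,
row-order independent), and an average-linkage leaf ordering on
correlation distance is emitted for heatmap display.

## Numerical and design choices

- Exact U enumeration bound at group size 8: `C(16,8) = 12,870`
  relabelings is instant per gene; above that the normal approximation is
  accurate for count data of this sparsity.
- Largest-remainder apportionment assigns gene-class counts from
  fractions deterministically (ties broken by class name).
- Normalization is by genome-wide totals of the paired control — not
  median-of-ratios — because a killing selection violates the
  "most features unchanged" assumption that ratio-based methods require.
- The Mann–Whitney comparison unit (per-site counts within the gene) is a
  documented choice; the test is reported per replicate and never gates
  calls, so alternative units change annotations, not hits.
- All probabilities and thresholds surface as keyword arguments with the
  defaults above; every run writes its thresholds, pseudocount, and seed
  into `run_metadata.txt`.

## Problem sizes

The test suite and the reproduction script run the simulator at the
default scale (2,000 genes, 1e5 mutants, 1e6 control reads, two
replicates), which fits comfortably in memory and completes in seconds;
smaller configurations used in unit tests (100–300 genes) exercise the
same code paths.

## Limitations

- The caller implements one published-style decision rule; it does not
  estimate per-gene fitness, call essentiality, or correct insertion
  bias.
- The escape baseline is a single global constant; real phenotypic escape
  varies by phage and physiology.
- The exact U test enumerates relabelings, so its cost grows
  combinatorially; the group-size-8 cap keeps it bounded.
- Raw-read processing (trimming, alignment, junction extraction) is out
  of scope; the pipeline starts from per-site counts.
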