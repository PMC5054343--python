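# hepatlas

Cell-type-resolved proteome analysis for parenchymal organs, modeled on the
liver: hepatocytes (HC, the parenchymal cells) plus the three nonparenchymal
types — hepatic stellate cells (HSC), Kupffer cells (KC) and liver sinusoidal
endothelial cells (LSEC). The package turns per-cell-type abundance tables
into the statistics that characterize a division of labor between cell
types, and into a hierarchical crosstalk network explaining how the
nonparenchymal compartment maintains hepatocyte identity.

It is written for proteomics/systems-biology analysts who have label-free
quantification output (peptide intensities or gene-level iBAQ/FOT/FPKM
tables) plus standard resource tables (GMT gene sets, ligand-receptor pairs,
KEGG-style pathway graphs, CellNet-style TF→target tables) and want a
tested, scriptable re-implementation of this analysis rather than a one-off
notebook.

## What it computes

**Quantification.** iBAQ from peptide intensities and an in-silico tryptic
digest (cleave after K/R, not before P; observable window 6–30 residues):
iBAQ = Σ(peptide intensities) / #(theoretical peptides). FOT normalization
divides each sample column by its total so columns sum to 1.

**Proteome features.** Functional-category Shannon entropy of a gene set *S*
over annotation categories,

    H(S) = − Σᵢ Fᵢ log Fᵢ,   Fᵢ = Tᵢ / Σᵢ Tᵢ,

with Tᵢ the number of genes of *S* in category *i* (natural log; a sampling
null from random sets of equal size gives mean ± sd error bars); CV and
dynamic range; Spearman replicate correlations on log₁₀(FOT + 10⁻⁸);
average-linkage clustering on 1 − ρ distances; gene-complexity
over-representation (long genes > 28,256 bp, ≥ 5 cis-regulatory modules,
proteins > 512 aa, > 2 repeated domains); proteome/transcriptome Venn
partitions at FPKM > 1.

**Differential calls.** A protein is *cell-enhanced* when its abundance in
one cell type is at least 2× the average over all four cell types. A TF is
*cell-specific* when its level is at least 10× the geometric mean of the
other cell types. Enrichment uses the upper-tail hypergeometric p with
Bonferroni (FWER) correction; two-group comparisons use the Mann-Whitney U
test (exact by enumeration up to combined n = 12 without ties, otherwise a
tie- and continuity-corrected normal approximation).

**Crosstalk network.** Ligands enhanced in (or secreted by) a sender cell
are paired with receptors detected in the receiver; pathways are *active*
when their constituent proteins are enriched in enhanced proteins
(hypergeometric p < 0.05) and every node is detected in the proteome or
transcriptome; the network is simplified to ligand→receptor, receptor→TF
(annotated with the originating pathway and the shortest directed path
length in edges) and TF→target edges. Path lengths of edges ending at
receiver-specific TFs are compared against all TFs with a Mann-Whitney U
test.

**Synthetic cohorts.** `hepatlas.synthetic_data` generates complete, seeded
inputs — FOT proteome (4 cell types × 3 replicates, log₁₀ noise sd 0.2),
FPKM transcriptome, annotation GMT, ligand-receptor pairs, layered pathway
DAGs, TF→target tables, secretomes, and a drifting cultured-hepatocyte time
course — together with a machine-readable record of every planted feature
(`SyntheticTruth`). Every generation run re-derives the planted truth from
the noiseless expectation through the real calling pipeline and fails loudly
on any mismatch.

## Worked example

```python
from hepatlas.synthetic_data import GeneratorConfig, generate_cohort
from hepatlas.differential import call_enhanced, call_specific_tf
from hepatlas.crosstalk import (select_candidates, call_active_pathways,
                                build_network, compare_path_lengths)

cohort = generate_cohort(GeneratorConfig(seed=1))
m = cohort.proteome

enhanced = {c: call_enhanced(m, c) for c in cohort.config.cell_types}
specific = call_specific_tf(m, cohort.tf_list, "HC").genes

cands = select_candidates(cohort.lr_db, m, cohort.secretomes,
                          cohort.config.senders, "HC", enhanced)
detected = m.detected()
union = set().union(*(e.genes for e in enhanced.values()))
calls = call_active_pathways(cohort.pathways, union, detected, detected)
net = build_network(cands, calls, cohort.pathways, specific,
                    cohort.tf_targets, receiver_detected=m.detected("HC"))
comp = compare_path_lengths(net, specific, mode="all")
print(f"mean shortest path: specific TFs {comp.mean_specific:.2f} vs all TFs "
      f"{comp.mean_reference:.2f} (Mann-Whitney U p = {comp.mwu.p:.2e})")
```

prints

```
mean shortest path: specific TFs 3.97 vs all TFs 4.92 (Mann-Whitney U p = 4.41e-04)
```

The run recovers 29–106 enhanced proteins per cell type and all 8 planted
HC-specific TFs; 16 of 20 pathways are called active (the 4 planted-inactive
ones are vetoed by their undetected nodes), and the 64 receptor→TF edges
ending at specific TFs are on average about one edge shorter than the
network-wide average — the signature of a fast, direct crosstalk route into
the receiver's identity-defining TFs.

The same steps are available from the shell:

```sh
hepatlas simulate --out sim/ --seed 1
hepatlas enhanced --matrix sim/proteome_fot.tsv --cell HC --fold 2 --out enh.tsv
hepatlas crosstalk --matrix sim/proteome_fot.tsv --pairs sim/ligand_receptor_pairs.tsv \
    --pathways sim/pathways --tf-targets sim/tf_targets.tsv --tfs tfs.txt \
    --sender HSC,KC,LSEC --receiver HC --out-edges edges.tsv --out-summary summary.tsv
```

## Layout

```
src/hepatlas/
  io_formats.py      validated containers + TSV/GMT/edge-list readers & writers
  quantification.py  tryptic digest, iBAQ, FOT
  profile_stats.py   entropy, CV/dynamic range, correlation, clustering, overlap
  differential.py    enhanced proteins, specific TFs, enrichment, Mann-Whitney U
  crosstalk.py       candidate selection, active pathways, network, path lengths
  synthetic_data.py  seeded cohorts with planted ground truth
  cli.py             click command-line interface
docs/methods.md      model assumptions, parameter choices, limitations
```
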