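# Methods

This note records the models and procedures implemented in `hepatlas`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the package's known
limitations.

## Quantification

iBAQ divides the summed peptide intensity of a protein by the number of its
theoretically observable tryptic peptides. The digest rule is the
conventional one — cleave C-terminal of K or R unless the next residue is P —
with 0 missed cleavages and an observable window of 6–30 residues for the
denominator. All three choices are exposed on `DigestParams`; they are the
standard iBAQ conventions, made explicit because label-free pipelines rarely
print them. Proteins with no observable theoretical peptide have an undefined
iBAQ and are dropped with a warning rather than reported as 0 (which would be
a claim about abundance). Peptides shared between proteins are used as given:
protein inference belongs to the upstream search engine, not here.

FOT (fraction of total) divides each sample column by its sum, making
samples comparable regardless of input load; every FOT column sums to 1
within 1e-9 and the container enforces this. FOT is stored as a raw
fraction; parts-per-million scaling is offered only at the CLI for display.
The FOT divisor is the sum over all rows of the matrix. FOT is idempotent
and invariant to global rescaling by construction; these contracts are
tested on randomized inputs.

One consequence of FOT worth stating explicitly: a sample that expresses
fewer genes concentrates its total on the remaining ones, so cross-sample
abundance ratios are not invariant to differences in proteome breadth. The
synthetic generator is designed around this (see below).

## Proteome feature statistics

**Entropy.** The functional-category entropy of a gene set S is
−Σ Fᵢ log Fᵢ with Fᵢ = Tᵢ/ΣTᵢ, where Tᵢ counts the members of S in category
i and the sum runs over categories with Tᵢ > 0. Natural log is the default —
the base only rescales and all comparisons stay within one base — and is
configurable. A gene in several categories counts once per category (the
formula sums over categories, not genes), so ΣTᵢ may exceed |S|. A set with
no annotated member raises a dedicated error: "unannotatable" must not be
confused with the legitimate entropy-0 case of a single-category set. The
sampling null draws subsets of the universe without replacement (default 100
draws) and reports mean ± sd; it is seeded and reproducible. Entropy for
different ontologies (GO biological process vs KEGG-style pathways) should
be computed per ontology, not jointly — category granularity differs and a
joint index would mix scales.

**Correlation and clustering.** All correlation-based steps share one
transform: Spearman rank correlation on log₁₀(x + 1e-8). Rank correlation is
robust to the multi-decade dynamic range of FOT values, and the pseudocount
pins "not detected" (encoded as 0) at the bottom of the scale. Replicate
correlations are computed over genes detected in both columns; pairs sharing
fewer than 3 genes are reported as undefined. Clustering uses average
linkage on 1 − ρ with columns pre-sorted by label (making the tree invariant
to input column order) and scipy's optimal leaf ordering, which minimizes
the sum of adjacent-leaf distances. Optimal ordering is what makes a
gradient — such as a culture time course — come out with its leaves in
gradient order; the default id-based ordering cannot express that property
even when the distance structure supports it.

**CV.** Coefficients of variation use the population (n) standard deviation
over per-cell-type means; with four cell types the n−1 convention would
inflate every CV by the same √(4/3) factor, so the choice only shifts the
scale, but it is documented and configurable at the call site by passing
already-aggregated matrices.

**Complexity classes and omics overlap.** The four gene-complexity
predicates (gene length > 28,256 bp; ≥ 5 cis-regulatory modules; protein
length > 512 aa; > 2 domains in repeat-containing proteins) are taken as
user-supplied per-gene attribute tables; the package computes fold
over-representation (cell fraction / universe fraction) and a hypergeometric
p per class. The proteome-vs-transcriptome comparison is operationalized as
a Venn partition at FPKM > 1 (strict), each piece of which is a valid
enrichment query; merging a secretome into the proteome side reproduces the
observation that secreted-but-not-resident proteins explain part of the
extracellular-space bias between the two omics layers.

## Differential calls

**Cell-enhanced proteins.** ratio = (focal cell-type mean) / (arithmetic
mean over all cell types, focal included), called at ratio ≥ 2. "Average of
all four types" is read as the plain arithmetic mean including the focal
cell — the specific-TF rule names the geometric mean explicitly when it
means it — and an exclude-focal mode is provided. Replicates are averaged in
linear space first. With k cell types the ratio is bounded above by k, so
under the include-focal rule a fourfold-over-others profile scores 16/7 ≈
2.29 while a focal-exclusive profile scores the maximum 4.

**Cell-specific TFs.** ratio = (focal mean) / (geometric mean of the other
cell types), called at ratio ≥ 10, zeros replaced by a pseudocount (half the
smallest positive matrix value unless supplied). The geometric mean keeps a
single permissive cell type from masking specificity.

**Enrichment.** Upper-tail hypergeometric p = P(X ≥ k) for overlap k between
a query of size q and a category of size m in a universe of size N, with
fold = (k/q)/(m/N). The Bonferroni factor counts only categories that
intersect the universe — correcting for untestable categories costs power
and buys nothing. Bonferroni controls the family-wise error rate; output
columns say `p_bonferroni` and the documentation calls it FWER control.

**Mann-Whitney U.** Midrank ties; exact two-sided p by full null enumeration
when the combined sample size is ≤ 12 and the data are untied (C(12,6) = 924
labelings is instantaneous), otherwise a normal approximation with tie and
continuity corrections. Two identical groups return p = 1, not an error. The
exact branch is validated against an independent labeling-enumeration oracle
for every untied configuration up to combined n = 10, and the approximate
branch against permutation sampling.

## Crosstalk network

The model connects nonparenchymal *sender* cell types to one parenchymal
*receiver*:

1. **Candidates.** A ligand-receptor pair becomes a candidate for a sender
   when the ligand is called enhanced in that sender *or* appears in the
   sender's secretome, and the receptor is detected in the receiver (any
   replicate > 0, or FPKM > 1 when a transcriptome is supplied — detection
   accepts either omics layer, for receptors exactly as for pathway nodes).
2. **Active pathways.** A pathway is active when its node set is enriched in
   the union of enhanced proteins (hypergeometric, raw p < 0.05) AND every
   node is detected. The activity rule deliberately uses the raw p — it is a
   per-pathway gate, not a discovery list — and a `bonferroni` flag exists
   for stricter use.
3. **Simplification.** For each candidate receptor and every TF reachable
   from it inside an active pathway graph, one receptor→TF edge is recorded
   with the shortest directed path length in edges and the originating
   pathway; ties across pathways break on pathway name and the retained
   witness path is the lexicographically smallest node sequence, so output
   is reproducible. TF→target edges come from the TF-target table,
   restricted to genes detected in the receiver. Candidates whose receptor
   reaches no TF are dropped; an empty network is valid output.
4. **Path-length comparison.** Lengths of edges ending at receiver-specific
   TFs versus all TFs (overlapping groups, as the headline comparison is
   phrased) or versus nonspecific TFs only (disjoint mode), tested with the
   Mann-Whitney U above. Lengths are counted receptor→TF; starting at the
   ligand would add a constant 1 to both groups.

Orthology (e.g. mouse→human for TF-target resources) is applied to the
TF-target table only, before network construction; unmapped identifiers are
dropped with a logged count and many-to-one collisions union their target
sets. Pathway graphs are gene-level; protein complexes are not modeled.

## Synthetic-data generator

The generator emulates the study design the pipeline targets: four cell
types (receiver HC + senders HSC/KC/LSEC), three biological replicates,
log-normal baseline abundance (log₁₀ mean −4, sd 1 before FOT — a
multi-decade dynamic range), multiplicative replicate noise of sd 0.2 in
log₁₀, an FPKM transcriptome whose log-abundance tracks the proteome with
extra noise chosen so the mRNA–protein Spearman correlation lands near 0.6,
and a cultured-receiver time course at days 0/1/3/6/10.

Planted features and the reasoning behind their shapes:

* **Enhanced proteins** are planted as detected *only* in their focal cell
  type, at `enhanced_fold` (4×) the local baseline. Under the include-focal
  average, a fourfold-over-nonzero-others profile would score only 2.29
  against the 2.0 threshold — a margin smaller than the replicate noise, so
  such genes would not be recoverable at the stated noise level. Exclusive
  expression scores the maximum ratio (4 = number of cell types),
  which makes the planted margin 2× the threshold and matches how strongly
  cell-enhanced proteins (pathway triggers in particular) actually present:
  not detected in the other cell types.
* **Specific TFs** are planted at 20× over nonzero baselines in the other
  cells; their geometric-mean ratio is ≈ 20 against the 10 threshold. A
  20:1:1:1 profile also clears the 2-fold enhanced rule, so planted specific
  TFs are part of the enhanced truth — the two callers are deliberately
  consistent on them.
* **Crosstalk chains** ligand→receptor→intermediates→TF are planted inside
  layered pathway DAGs: 8 "specific" pathways end at receiver-specific TFs
  with receptor→TF lengths drawn from 3–5, 8 "nonspecific" pathways end at
  flat TFs with lengths 5–7 (a planted gap of 2 edges; 32 paths per group),
  and 4 inactive pathways carry one never-detected node per chain, which
  vetoes the all-nodes-detected rule deterministically. Ligands cycle
  through senders and evidence classes (enhanced / secreted / both).
* **The receiver's distinct program** combines silencing of 25% of genes
  (drawn from the mid-abundance band of unplanted genes) with bimodal
  ±0.24 log₁₀ shifts; each sender additionally carries ±0.26 shifts on 270
  dedicated genes. These magnitudes are chosen jointly with the ±0.04
  per-gene cell effects so that, after FOT renormalization, the worst-case
  ratio any unplanted gene can reach in the noiseless expectation stays
  below the 2× calling threshold (observed worst case ≈ 1.8 across hundreds
  of seeds) while the correlation structure still separates: within-type
  replicate correlations exceed every between-type correlation, and the
  receiver is the clustering outgroup.
* **Mass discipline.** FOT couples every gene to every other through column
  sums. Exclusive genes and specific TFs therefore draw their baselines from
  a clipped, narrower distribution a decade below the bulk, and the
  top-10%-mass genes carry no per-cell factors at all — otherwise a single
  large gene with a cell-biased factor skews whole columns and silently
  breaks recovery guarantees.
* **Time course.** Day-0 expectation equals the receiver's noiseless mean;
  targets of receiver-specific TFs plus 150 extra genes drift down and 150
  trigger-like genes drift up at 0.12 log₁₀/day, with replicate noise on
  every column. The rate is set so day-to-day distances dominate noise and
  the dendrogram leaves come out in day order, while the downregulated set
  remains strongly enriched in the receiver-specific TF target groups.

Every `generate_cohort` call (unless disabled) verifies itself: the
noiseless expectation is run through the real calling pipeline — enhanced,
specific TFs, candidates, active pathways, network construction — and
compared against the planted truth; any discrepancy raises an error at
generation time rather than surfacing as a silent test artifact.

**What passing on synthetic data does not show.** The generator works at the
gene-abundance level: it does not simulate spectra, peptide-level
identification, missing-value mechanisms of MS (censoring at the detection
limit, peptide sharing), compositional artifacts beyond FOT itself, or
correlated biological variation between replicates. Planted effects are
cleanly separable by construction; recovery rates here are upper bounds on
what equally-sized effects would yield in real data, and the planted
path-length gap makes the network comparison a calibration of machinery,
not a biological claim.

## Numerical choices and degenerate inputs

* Gene identifiers are opaque, case-sensitive strings; no symbol
  normalization is attempted. Missing abundance values are rejected; "not
  detected" must be written as 0.
* FOT sum tolerance 1e-9; round-trips through TSV preserve values to 1e-12.
* Column header grammar is fixed as `CELL_rep[_dDAY]`.
* All-zero columns are hard errors for FOT; rank-constant columns are hard
  errors for clustering (the correlation is undefined); a pathway with no
  node in the universe is reported inactive with p = 1 rather than an error.
* Shortest-path ties: length recorded once; the witness is the
  lexicographically smallest node sequence.
* Seeds: every stochastic routine takes an explicit seed or rng; cohorts are
  byte-identical across runs at the same seed.
* Problem sizes in tests and the acceptance script (1,500-gene cohorts, 100
  seeded replicates for rate estimates, 25-cohort batches inside the
  acceptance script) are chosen so the full suite completes in well under a
  minute of compute per property while keeping Monte-Carlo error far from
  the asserted margins.

## Known limitations

* No FDR alternatives to Bonferroni (by design — the implemented correction
  is the one the analysis model specifies); no moderated or count-based
  differential statistics.
* Flat annotation sets: no GO graph propagation.
* The crosstalk model is structural; it does not model signaling dynamics,
  ligand diffusion, dosage, or spatial arrangement.
* The exact Mann-Whitney branch requires untied data; tied small samples
  fall back to the corrected normal approximation, which is conservative at
  very small n.
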