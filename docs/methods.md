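# Methods

This note documents the models, rules and numerical choices behind
vdjflow, what the synthetic-data generator does and does not emulate,
and the design decisions taken where several readings were defensible.

## Multi-J resolution

A blastn-style hit table gives, per contig, candidate J-segment
alignments with an e-value (`j_support`, smaller = stronger), an
optional bit score, and 1-based inclusive coordinates on the contig.
Hits are first filtered at an e-value cutoff — 10⁻⁴ for J and 10⁻³ for
D segments by default, tightening the aligner's own permissive
threshold. Selection is greedy: take the best-supported hit, then
repeatedly take the best-supported remaining hit whose closed interval
intersects none of the selected intervals (sharing a single base counts
as overlap), until the list is exhausted. "Best-supported" is ascending
e-value; because e-values can tie (especially after float formatting),
ties break by larger bit score, longer span, smaller start, then gene
name, making the selection a total order and the output deterministic.
A `rank_by="bit_score"` toggle inverts the first two keys; with
realistic hit tables the two orderings almost always coincide.

A contig with ≥ 2 selected hits is *multi-J*. For contigs without a V
gene annotation, `j_call` is overwritten with the selected gene of
smallest start coordinate — the 5′-leftmost gene, which is the exon
that would remain in the mature mRNA after splicing. Contigs that carry
a V gene keep their upstream annotation: the V-gene aligner already
handles unrearranged downstream J genes, and overruling it would
discard information the hit table lacks. `j_call_multimappers` records
all selected genes in 5′→3′ order in both cases.

Per-group summaries (sample × locus × V-presence) report the contig
count and multi-J proportion; groups under 10 contigs are flagged
rather than dropped, so the caller decides about display thresholds.

## The multi-J logistic model

The probability p_i that contig i shows multi-J mapping is modelled as

    logit(p_i) = β_cell,c(i) + β_J,j(i) + β_V·x_V,i + β_cyclo·x_V,i·x_treat,i

with c(i) the cell type, j(i) the 5′-end J gene, x_V the V-presence
indicator and x_treat a translation-inhibitor (cycloheximide) treatment
indicator. The treatment enters *only* through its interaction with V
presence: inhibiting translation can only rescue multi-J transcripts
that would otherwise be translated and degraded by nonsense-mediated
decay (NMD); V-less transcripts are never translated, so treatment
cannot act on them. A main-effect variant is deliberately not the
default.

Coding: the cell-type block carries one indicator per level and absorbs
the intercept; the J-gene block drops its most frequent level as
reference (the most frequent level keeps the iteratively reweighted
least squares fit well conditioned when rare genes are present). The
fit is maximum likelihood via statsmodels' binomial GLM; Wald two-tailed
p-values are BH-adjusted across all reported coefficients. Rank-deficient
designs are rejected before fitting with the offending term named, and
suspected separation (non-finite standard errors or |β̂| > 30) raises
rather than returning garbage.

## Cell-level QC

Contigs outside the library's expected loci are removed first
(tr-ab → {TRA, TRB, TRD}, tr-gd → {TRG, TRD}, ig → {IGH, IGK, IGL});
TRD is admitted in αβ libraries because TRB and TRD rearrange
concurrently and genuine TRD contigs survive in αβ data. A contig whose
non-empty V/D/J/C calls do not all share the locus prefix is flagged
inconsistent and excluded from pairing (but kept in the table).

Within a cell, contigs are ordered productive-first, then by descending
UMI count, then lexicographically by id; the top contig per chain class
(VDJ = TRB/TRD/IGH, VJ = TRA/TRG/IGK/IGL) is the primary. Status rules,
applied to productive contigs:

* **ambiguous** — TR-class and IG-class contigs in one cell (a
  biologically irreconcilable mixture); reserved for TR+IG, so e.g.
  productive TRA+TRG is *extra*, not ambiguous;
* **extra_pair** — more than one productive chain on a side, after two
  exceptions: exactly IgM+IgD (and no other isotype detected in the
  cell, including on nonproductive contigs) count as one heavy chain,
  and TRB+TRD may co-occur. The VJ side has no exceptions: two
  productive light-type chains of any loci are extra;
* **single_pair / orphan_VDJ / orphan_VJ / none** as the names say.

`check_contigs` only annotates; nonproductive contigs are never removed
except by the library/barcode restriction. `filter_contigs` keeps, per
cell, all productive chains of a non-extra side (so the IgM/IgD and
TRB/TRD groups survive intact), or a lone VDJ chain; ambiguous,
VJ-orphan-only and extra-pair cells are dropped whole by default. The
alternative reading — keep the top-UMI primaries of an extra-pair cell —
is available as `keep_top=True`; dropping the cell was chosen as the
default because surplus productive chains usually indicate doublets.
The complete rule table over all locus/productivity combinations is
committed as a fixture (`tests/data/qc_status_fixture.tsv`) and the
implementation is tested against it exhaustively.

## Clonotypes, networks, diversity

Cells are grouped by (V gene, J gene, junction amino-acid length) of
both chains, then partitioned within groups by junction similarity:
TCRs require 100% junction-nucleotide identity on both chains; BCRs
link pairs with ≥ 85% amino-acid Hamming similarity on both chains and
take single-linkage connected components (complete linkage is available;
single linkage matches the "grouped into clones" reading of a
threshold graph). Orphan single-chain cells form clones from the
available chain alone when `require_both_chains` is false — the default
for TCR (mirroring the retention of orphan VDJ chains in filtering) but
not for BCR. Clone ids are deterministic: sorted group keys ×
component index.

Within a clone, each cell is represented by the concatenation of its
primary VDJ and VJ amino-acid alignments joined with `|` (a character
outside the amino-acid alphabet, so chain boundaries cannot blur).
Pairwise Levenshtein distances (computed with edlib) define a weighted
graph; a minimum spanning forest is built over the *positive-distance*
edges with Kruskal's algorithm (ties broken by weight, then sorted node
ids — deterministic), and afterwards every pair at distance zero is
connected. The zero-distance recovery step exists because an adjacency
matrix built from distances cannot represent a zero-weight edge —
identical cells would look unconnected — so identical-receptor cells
are explicitly re-linked; the union of forest and zero edges is always
connected within a clone.

Diversity per group is the population Gini coefficient
G = Σᵢⱼ|xᵢ−xⱼ| / (2n²·x̄) (defined 0 when x̄ = 0, computed via the
O(n log n) sorted form) of (a) the clone-size distribution and (b) node
centralities. Degree centrality is the headline number; closeness is
also computed since either reading of "centrality" is defensible.

## The pseudobulk V(D)J feature space

Cells are assigned to pseudobulks either by unique combinations of
metadata columns (a partition; combinations under 10 cells dropped) or
by partially overlapping neighborhoods: sampled index cells plus their
k Euclidean nearest neighbors in a supplied embedding. For each
(locus, segment) block, a cell contributes one binary indicator for the
gene of its primary contig at that locus (productive ranked first, then
highest UMI; first gene of a multi-gene call, allele stripped).
Indicators are summed per pseudobulk and each (pseudobulk, locus,
segment) block row is divided by its sum; blocks with zero sum stay
zero rather than dropping the pseudobulk, keeping the matrix
rectangular across loci. Features are ordered by locus, segment, then
natural gene order.

Differential usage tests each feature per group-vs-rest with the
two-sided Wilcoxon rank-sum test, BH-adjusted within group. With ≤ 12
pseudobulks the exact permutation enumeration is used — it remains
exact under the heavy ties of usage fractions — otherwise the
tie-corrected normal approximation with continuity correction.

### Baseline trajectory engine

External trajectory engines are supported through import/export of
assignment matrices and per-pseudobulk value tables; the built-in
engine exists so the pipeline is exercisable self-contained. It runs
PCA (5 components by default), builds a symmetric k-NN graph with
Euclidean edge weights, and unions it with the Euclidean minimum
spanning tree so sparse feature spaces cannot fragment into islands
unreachable from the root. Pseudotime is the shortest-path distance
from the root pseudobulk, min–max normalised to [0, 1] (the root is a
caller input, anchored by biological identity). Branch probabilities
come from a uniform random walk with the terminal pseudobulks
absorbing, solving (I−Q)B = R; on a path graph this reduces to the
classical gambler's-ruin closed form, which the tests exploit.

Per-pseudobulk values are projected back to cells as the average over a
cell's containing pseudobulks weighted by inverse pseudobulk size;
cells in no pseudobulk are omitted with a count. For trajectory
fidelity, genes of a segment are encoded by their 1-based 5′→3′ genomic
order (the caller supplies the ordered list), averaged per pseudobulk
over member cells, and correlated with pseudotime over sliding windows
of 30 consecutive pseudobulks (stride 1; zero-variance windows recorded
as missing).

## Statistical primitives

* **BH adjustment**: step-up, capped at 1, order-preserving. Note the
  step-up map is *not* idempotent — re-adjusting adjusted values changes
  them — so the tests assert monotonicity and agreement with the
  statsmodels reference rather than idempotence.
* **Wilcoxon rank-sum**: statistic is the rank sum of the first sample
  with midranks. Exact mode enumerates all assignments of pooled
  observations (feasible for ≤ ~12 observations; exact under ties);
  two-sided p doubles the smaller tail, capped at 1. Normal mode uses
  the tie-corrected variance and a 0.5 continuity correction; it agrees
  with scipy's asymptotic implementation to machine precision. At n=12
  the exact and normal p can differ by up to ~0.015 for central values —
  inherent discreteness, documented rather than hidden.
* **Chatterjee's ξ**: rows are sorted by x with seeded random tie
  order; ξ = 1 − n·Σ|r_{i+1}−r_i| / (2·Σ l_i(n−l_i)) with y-ranks r and
  l the tie-corrected form (reducing to 1 − 3Σ|Δr|/(n²−1) without
  ties, hence ξ = 1 − 3/(n+1) for strictly monotone data). The p-value
  uses the asymptotic null √n·ξ → N(0, 2/5), right-tailed for screening
  ("is there any functional dependence?"), doubled on request; under
  heavy y-ties it is approximate. The trend screen drops genes detected
  in fewer than 50 cells or with constant expression, BH-adjusts across
  tested genes, and flags genes with adjusted p < 0.05 *and* ξ > 0.1;
  an optional output bins pseudotime into 100 equal bins of mean
  expression for display.

## The synthetic generator

The generator emulates the statistical structure the analyses assume,
with defaults chosen once as realistic study conditions:

* gene pools of human scale (50 TRAV, 61 TRAJ, 48 TRBV, 13 TRBJ, 2
  TRBD; analogous IG pools);
* a latent maturation time t ~ U(0,1) per cell; *processive* TRA usage:
  the V/J index is drawn from a truncated-Gaussian window (σ = 4 genes)
  whose centre moves linearly with t from one end of the pool to the
  other — the direction of processive rearrangement is biological, the
  linear-Gaussian form is a modelling choice;
* nonproductive contigs at rate 0.15 with cause mix 50% missing V,
  25% premature stop, 20% frameshift, 5% missing junction; junctions
  are random in-frame codon strings with canonical anchors (C…F/W),
  and each defect is realised consistently in the sequence (a stop
  codon inserted, a frameshifting base appended, the junction removed);
* multi-J truth drawn from the same logistic model the stats module
  fits, with default β_V = −1.2 (NMD depletes translatable V-containing
  multi-J transcripts) and β_cyclo = +0.8 (treatment relaxes the
  depletion); hit tables carry 2–4 neighboring J genes in
  non-overlapping ~50 nt blocks with the intended gene 5′-leftmost,
  plus overlapping decoy hits strictly weaker than all true hits and
  noise hits above the e-value cutoff;
* an invariant MAIT-like cell type pinned to TRAV2/TRAJ33, clonal
  expansion (a new cell joins an existing clone with probability 0.2),
  and UMI counts 1 + Poisson(3);
* a branching variant: branch label assigned past t* = 0.5, a smooth
  2-D embedding (e₀ ≈ t, e₁ ≈ ±(t−t*)) with σ = 0.02 noise so k-NN
  neighborhoods are contiguous in t, and a branch-specific TRBV usage
  shift of ±12 genes.

All randomness flows from one seed through independent named streams
(SeedSequence spawn keys), so outputs are byte-identical across runs
and adding a feature does not perturb other draws.

What the generator does **not** emulate: germline sequence content
(junctions are random codons, alignments use pseudo-germline prefixes),
somatic hypermutation, isotype switching, allelic variation, doublets
and ambient contamination, sequencing error, and realistic per-gene
usage biases beyond the planted structure. Passing tests therefore
demonstrate algorithmic correctness and statistical calibration under
the planted model, not robustness to every artefact of real 10X data.

## Validation studies and problem sizes

The acceptance script and test suite use desk-scale problem sizes
chosen to give stable statistics: 1,000 random hit tables for the
greedy-selection oracle; 200 cells for brute-force clonotype
comparison; clones of ≤ 7 cells for exhaustive spanning-tree
enumeration; 3 seeds × 3,000 cells for trajectory recovery (observed
|Spearman| ≈ 0.998 against the latent time, threshold 0.8); 5,000
contigs × 20 response redraws for β_V recovery and 200 redraws for null
interaction calibration. The logistic recovery study uses a balanced
design (40% V-less contigs, all from missing-V nonproductives, base
rate ≈ 18%, treatment on half the cells) so that the standard error of
β̂_V (≈ 0.07) is well inside the ±0.2 recovery band; with the default
7.5% V-less fraction the coefficient is identifiable but noisier.

## Known limitations

* The Chatterjee p-value under y-ties uses the tie-free asymptotic
  variance; for heavily tied expression data the screen's ξ > 0.1
  requirement dominates in practice.
* `filter_contigs` cannot distinguish a genuine dual-TCR cell from a
  doublet; both are dropped (or trimmed with `keep_top`).
* The baseline trajectory engine is intentionally simple (shortest
  paths, uniform walk); it is a stand-in for dedicated engines, not a
  replacement, and is anchored by a caller-supplied root and terminals.
* BCR-specific refinements — somatic hypermutation distance, light
  chain editing and coherence — are out of scope.
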