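# Methods

## The problem

Comparative genomics datasets of single-copy orthologs usually contain far
more *nonubiquitous* genes — genes absent from one or more of the sampled
species — than ubiquitous ones, yet selection-regime analyses (dN/dS, ω)
are typically restricted to the ubiquitous subset because per-gene handling
of incomplete taxon sets is tedious. This package automates the two steps
that make nonubiquitous genes usable: per-gene pruning of the species tree
before model fitting, and species-set–based identification of "the same"
branch or clade across gene trees whose taxon content differs.

## The analyze stage

Per gene, the workflow:

1. reads the in-frame codon alignment (FASTA) and screens every sequence
   for stop codons at codon boundaries. A gene with any stop codon in any
   sequence is excluded (internal or terminal — downstream codon-model
   software rejects both). Gap codons (`---`) are skipped and codons
   containing `N` are treated as ambiguous, never as stops, to avoid false
   exclusions. The genetic code is an NCBI translation table (default 1);
2. prunes the species tree to the gene's taxon set (fixed-tree mode) or
   loads a per-gene tree (gene-tree mode). Unifurcations created by
   pruning are suppressed with their branch lengths summed, preserving
   leaf-to-leaf path lengths for the likelihood fits;
3. re-derives foreground labels on the pruned tree from the surviving
   species of each user definition (`#k` = stem branch of the MRCA, `$k` =
   whole clade including the stem, CodeML semantics). A definition whose
   surviving species are not monophyletic in a given tree is labeled at
   the MRCA and flagged in a report rather than silently altered;
4. fits the *general* and the nested *alternative* model, each replicated
   with random ω starting values drawn uniformly from [0.05, 2.0] (bounded
   away from 0 to avoid boundary starts); per model the replicate with the
   best log-likelihood is retained, ties broken by the lowest replicate
   index for reproducibility;
5. computes the LRT statistic 2(lnL_general − lnL_alternative) against
   chi-square with df = Δnp. Note the deliberate terminology: *general* is
   the parameter-rich model, *alternative* the restricted one nested
   within it. A negative raw statistic is clamped to zero and flagged,
   never silently rerun;
6. adjusts p values across the gene batch with Benjamini–Hochberg FDR and
   selects the general model for a gene only when q < α (default 0.05,
   strict inequality at the boundary).

Every failure (unparseable file, stop codon, too few taxa, failed fit) is
logged per gene with a reason; the batch never aborts on a single gene.
Genes with fewer than `min_taxa` (default 4) species are skipped, since a
smaller tree has no informative internal branch.

## The extract stage

Branch identity is the descendant species set, never a node number; node
numbers are reproduced only transiently while parsing CodeML output (the
numbering convention — leaves 1..N in appearance order, internal nodes
N+1.. in preorder — is validated against the tree echoed inside each
output file when present). Matching of a definition against a gene with
taxon set G uses P = species(defn) ∩ G:

* mode A: P must equal the full definition and be the exact leaf set of
  an edge of the gene tree;
* mode B: |P| must reach a threshold — `ceil(threshold·|defn|)` when the
  threshold is a proportion (< 1; "at least" semantics motivate the
  ceiling), or the threshold itself when it is an absolute count (≥ 1) —
  and P must again be an exact edge.

The boundary value 1 is therefore an absolute count of one; a proportion
of 100% is expressed as mode A (or as the absolute count |defn|, which is
equivalent — this equivalence is property-tested). Monophyly of P in the
gene tree is required in both modes: attributing metrics to a branch that
does not exist in that gene would be meaningless. A clade (`$`) definition
reduced to a single surviving species is reported unmatched (no clade
exists); a branch (`#`) definition still matches the terminal branch. Mode
B imposes no constraint on missing species *outside* the clade.

For a matched branch definition the output row is the stem branch's
(dN/dS, dN, dS); for a clade definition every branch inside the clade plus
the stem is reported, plus an unweighted-mean row explicitly marked
`derived` (no aggregation is standard in the field, so the per-branch rows
are always kept). Genes whose best-fit output lacks a branch table (site
models) are reported as `metrics-missing`, and every unmatched gene
appears in the coverage report with its reason.

## Gene-tree discordance

When per-gene trees are used alongside a species tree, the package reports
the Robinson–Foulds distance of each gene tree to the correspondingly
pruned species tree. RF is computed on unrooted nontrivial split sets and
normalized by the total number of nontrivial splits in both trees — a
choice that handles multifurcating trees gracefully (a star tree
contributes no splits; two stars are at distance 0). Root placement in the
input newick is not assumed meaningful.

## The built-in codon-model engine

The engine exists so the whole pipeline runs and is testable without an
external CodeML binary, and so the statistical behavior of the LRT chain
can be verified by simulation. It implements the Goldman–Yang codon model
on the 61 sense codons of the standard genetic code:

    q_ij = π_j · κ^[transition] · ω^[nonsynonymous]   (0 if >1 position differs)

scaled to one expected substitution per codon per unit branch length.
Likelihoods use Felsenstein pruning over unique site patterns with
per-node rescaling; transition matrices come from an eigendecomposition of
the generator in the π-symmetrized basis (stable and fast at 61 states).
Gap- or N-containing codons enter as missing data (all-ones conditional
vectors). dN and dS in emulated output are derived from the branch length,
the class ω, κ and the model's synonymous/nonsynonymous flux proportions,
which makes per-branch dN/dS equal the class ω by construction.

Deliberate simplifications, documented loudly: equal codon frequencies
(1/61) by default (F3x4 estimation out of scope); standard genetic code
only (other tables are supported in screening but not in the likelihood);
branch lengths fixed at their input values and never re-optimized, so
np = 1 + number of ω classes (M0: κ and one ω). Site and branch-site
likelihoods are not computed by the engine, though LRT handling and output
parsing work at the lnL/np level for any nested pair. The optimizer is
L-BFGS-B on log-parameters with box constraints κ ∈ [0.01, 50],
ω ∈ [1e-4, 20] and ftol 1e-10, with one fallback restart from (κ=2,
ω=0.5) if the starting likelihood is non-finite.

## What the simulator emulates — and what it does not

The fixture generator produces datasets shaped like real ortholog
batches: a random species tree with realistic branch lengths (0.02–0.3
substitutions/codon), per-gene alignments simulated under the engine's own
model (default ω = 0.2, κ = 2 — strong purifying selection typical of
conserved single-copy orthologs), and a fraction of nonubiquitous genes
(default 30%, each missing 1–2 species). It does not emulate alignment
error, recombination, codon-usage bias, rate heterogeneity across sites,
or gene-tree/species-tree discordance; tests passing on these fixtures
therefore validate the machinery (screening, pruning, labeling, fitting,
testing, matching, table assembly) and the statistical calibration of the
LRT under the model — not robustness to real-data pathologies.

## Simulation-based checks and their problem sizes

* Likelihood correctness: exhaustive enumeration over internal-node codon
  states (3 taxa × 3 codons, 61² terms per site), agreement to 1e-8.
* Parameter recovery: 50 alignments of 500 codons on an 8-taxon tree at
  ω = 0.2, κ = 2; the mean M0 estimate must fall within 2 SE of the truth.
* LRT calibration: 200 null replicates (M0 truth; M0 vs a 2-class branch
  model) on a 6-taxon tree with a 500-codon alignment; rejection at
  nominal α = 0.05 must lie in the binomial 95% envelope [0.02, 0.09].
  The alignment length matters here: the chi-square reference for the LRT
  is an asymptotic result, and with very short alignments (≈200 codons) a
  short foreground branch carries only a handful of substitutions
  informative about its ω class, which visibly fattens the upper tail of
  the null statistic beyond χ²₁. 500 codons is within the typical range
  of real coding genes and is enough for the asymptotics to hold on this
  tree; the small-sample behavior is a property of the LRT itself, not of
  the implementation.
* Clade-matching: exact agreement with a brute-force edge-enumeration
  oracle over 200 random trees (5–10 leaves) × all taxon subsets × both
  modes (≈10⁵ comparisons).

## Numerical and design choices

* Ties in replicate likelihoods: lowest replicate index wins.
* Pattern likelihoods are rescaled per internal node; a zero conditional
  likelihood yields −inf rather than an exception.
* `prune(prune(T,S1),S2) = prune(T,S2)` for S2 ⊆ S1 (property-tested on
  topology and path lengths).
* All randomness flows from one user seed through per-gene seeds derived
  with CRC-32 of the gene id (stable across runs, independent of batch
  order); engine-backend runs are byte-reproducible.
* The boundary-mixture null for branch-site LRTs (50:50 mixture of χ²) is
  out of scope; plain chi-square only.

## Known limitations

* The engine is a compact verification backend, not a CodeML replacement:
  no codon-frequency estimation, no site models, no branch-length
  re-optimization.
* Tree inference (e.g. RAxML) is an external, optional step; this package
  expects input trees with branch lengths.
* Non-monophyletic label definitions are honored at the MRCA with a flag;
  users analyzing heavily discordant gene trees should inspect the
  labeling report and the RF table before interpreting foreground ω.
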