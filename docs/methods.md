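# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `marinerscan`, in the order the pipeline runs them.

## Translated mining

Candidate transposase loci are found by searching a protein query against
all six reading frames of the genome. Exact amino-acid k-mer seeds
(default word length 4) nominate candidate windows; each window is scored
by Smith–Waterman local alignment under BLOSUM62 with gap open −11 /
extend −1, and kept at score ≥ 80. These defaults mirror common
translated-search (tblastn-style) practice; no E-value statistics are
computed — score and identity thresholds stand in, which is adequate at
the genome sizes the package targets. After the best alignment in a
window is taken, the window is split left and right of it and re-searched,
so several copies sharing one seed cluster are all reported. Hits on the
same contig/strand/frame within 50 nt are merged keeping the best-scoring
envelope; ties break to the leftmost coordinate, then '+' before '−', so
output is deterministic. On small genomes the seeded search is
score-equivalent to exhaustive Smith–Waterman over all six frames (tested).

Hits are extracted with up to 2 kb of flank on each side (clipped at
contig edges). Minus-strand copies are reverse-complemented into
transposase-sense orientation with flanks swapped.

## Boundary resolution and annotation

A mined hit covers only the transposase-homologous core. The element
boundaries are resolved inside the extracted window by enumerating
TA-anchored candidate termini (the TSD abuts the TIR) and scoring the
terminal inverted repeat between each candidate pair: ungapped alignment,
match +1 / mismatch −2, N never matches. The pair with the best TIR
alignment wins, subject to a minimum TIR length (default 20 bp) and a
maximum mismatch fraction (default 0.1). Copies without a qualifying pair
(typically truncated copies) keep their mined coordinates.

`find_tirs` applies the same scoring to the element's first and last 150
nt (the window must exceed the longest TIRs seen in this superfamily,
> 126 bp), anchored within 5 nt of each terminus, and reports the
maximal-scoring prefix — so a perfect repeat is not extended into
unrelated interior sequence. The mismatch penalty of −2 means an internal
mismatch is retained only when flanked by enough matches, which matches
how a curator would delimit a decayed repeat. The 0.1 mismatch bound is a
detectability policy, not an estimate; it is exposed in the configuration.

The ORF is the longest ATG-to-stop reading frame over all six frames
(ties: leftmost start, '+' before '−'). Single-ORF elements make a
gene-finder unnecessary. The catalytic triad is located by transferring
annotated D/D/E(D) columns from the best-scoring member of a bundled
reference panel (global alignment, BLOSUM62, gap open −10 / extend −1);
the triad is accepted only if all three transferred positions carry
D/D/(D or E) in the query, and the family label is spelled from the
observed spacing ("DD" + spacer + third residue). The bundled references
are synthetic transposases generated deterministically from a common
scaffold (see `references.py`); they are labelled synthetic and carry the
family architectures needed for spacing-based classification (DD34E,
DD34D, DD37E). The GRPR box is matched with the pattern G-R-[PK]-R.

Status classification is total and mutually exclusive, with precedence
intact → MITE → full_length → truncated: intact requires two TIRs plus a
≥ 300 aa ORF with a detected triad; MITE requires two TIRs, total length
below the full-length minimum (default 1000 bp) and no ORF reaching 300
aa; full_length requires two TIRs; everything else is truncated. The
1000–1500 bp full-length window and the 300 aa thresholds bracket the
intact elements (~1.2 kb, 335–382 aa transposases) and the truncated
235 aa products seen in decayed copies of this superfamily.

## Consensus, copy number, divergence

Copies are multiple-aligned progressively: shared-8-mer distances feed a
UPGMA guide tree (the k-mer distance is the standard fast proxy for
pairwise identity at this stage and keeps the guide phase O(n²) cheap);
merges are profile–profile Needleman–Wunsch with match +1 / mismatch −1 /
linear gap −2, occupancy-weighted gap costs, and a fixed diagonal-first
tie-break, so the alignment is deterministic for a fixed input order.

The consensus deletes majority-gap columns (a `--consensus-gap-rule any`
variant deletes every gapped column instead; full removal would erase most
of a ragged alignment, hence the majority default) and emits the plurality
base per remaining column, ties resolved to the base of the first row
holding a tied base; N never votes. Consensus building is used for
families with ≥ 10 copies; below that the best-scoring genomic hit is the
species representative.

Copy number is the count of genomic loci matching the consensus by seeded
(exact 11-mer) local nucleotide alignment on both strands, at alignment
span strictly greater than 1000 bp and identity strictly greater than 90%
(identity over aligned columns, N excluded; the strict reading of the
thresholds is a deliberate choice). Overlapping hits are resolved
best-score-first, discarding hits overlapping a kept one by more than 50%.

Per-copy divergence from the consensus is the mean of K2P distances of
each copy globally aligned to the consensus, reported as percent with
SE = sample SD / √n; saturated copies are skipped with a warning and the
summary is undefined for fewer than two usable copies (mirroring
low-copy-number families whose divergence cannot be determined).

## Distances, trees, clusters

K2P uses the closed form and Kimura's delta-method variance
(a = 1/(1−2P−Q), b = (a + 1/(1−2Q))/2, V = [a²P + b²Q − (aP+bQ)²]/n);
a non-positive log argument flags the pair saturated, and saturated
entries propagate as flagged (NaN) values, never as 0. Note that K2P
collapses to Jukes–Cantor when transitions are one third of differences
(Q = 2P), which the tests exercise.

The composite-likelihood matrix fits TN93 with empirical base frequencies:
the two rate ratios (purine and pyrimidine transitions vs transversions)
are shared across all pairs and estimated by Nelder–Mead on the composite
log-likelihood, with each pair's branch length profiled out by bounded 1-D
maximization; distances are reported in substitutions/site (rate matrix
normalized to unit mean rate). For a single pair this coincides with the
per-pair TN93 estimate (tested against an independent moment estimator
and against `ape::dist.dna`), and under equal rates it collapses to
Jukes–Cantor within Monte-Carlo error. Gamma rate variation is not
modelled; rates are uniform across sites.

Neighbor joining follows Saitou–Nei with two determinism/sanity policies:
Q-criterion ties break to the smallest node-index pair, and a negative
branch length is clamped to zero with its deficit moved to the sibling so
the pair sum is preserved. Additive matrices are reproduced exactly
(tested up to 8 taxa, cross-checked against dendropy's NJ). Optional
rooting places the root at the midpoint of the outgroup's branch.

Cluster assignment treats the tree as rooted as given: for each
unanchored leaf the ancestors are walked tipward-to-root and the first
ancestor whose clade contains anchors decides — one anchor label assigns
it, mixed labels leave the leaf `unassigned`. Non-monophyletic anchor
sets produce a warning, not an error.

## Horizontal-transfer inference

`ht_compare` pairs the taxa shared by the element and host matrices —
either all pairs or only within declared groups (two groups of 4 and 20
species give 6 + 190 = 196 comparisons) — and counts pairs with
`d_element < d_host` (strict; ties count against transfer). Summaries are
mean, sample SD, min, max per side. Pairs with an undefined distance on
either side are dropped with a warning. No significance test is applied:
the detector is exactly the distance inequality, and its operating
characteristics are established by simulation instead (below).

## Synthetic data

The generator's defaults are the study conditions, not tuning knobs:

* **Blueprint** — 1225 bp total, 29 bp TIRs, TA TSD, 346 aa ORF, triad
  spacer 36 with terminal E (DD36E). The master is assembled from TIR +
  5' spacer + ORF + 3' spacer + reverse-complemented TIR; the protein is
  built on the same synthetic scaffold as the reference panel so triad
  transfer works, and the construction is validated (and re-drawn if
  needed) until the annotation stage reports exactly the blueprint's TIR
  length with zero mismatches, the exact ORF length and the intended
  family label — rejecting chance inverted-repeat extensions or spurious
  upstream ATGs.
* **Planting** — copies are inserted at uniform positions (≥ 400 bp
  apart) with a duplicated TA, on a random strand, in a uniform-composition
  background (host base composition varies in reality, but composition is
  irrelevant to the contracts tested). Divergence is applied as a per-site
  K2P process at fixed branch length t = mean divergence (kappa default 2),
  with no indels except the explicit truncation/MITE deletions, keeping
  the truth table exact. Copies whose intended status requires a hallmark
  have disruptive substitutions repaired: intact copies keep an
  uninterrupted ORF, start codon and triad (the purifying selection that
  defines "intact" in real genomes), and TIR-bearing statuses keep the
  terminal repeat within the detectability bound; full-length copies are
  guaranteed a premature stop so they are never accidentally intact.
  Truncated copies lose one terminus at a uniform breakpoint; MITEs get an
  internal deletion to 810 bp preserving both TIRs.
* **Scenario** — a host gene (1 kb) and an element (1225 bp) evolve along
  the same ultrametric species tree under K2P; the element evolves at
  `te_rate_multiplier` (default 1.5) times the host rate, encoding
  "neutral, at least as fast as a purifying-selected ortholog" without
  overstating it. A transfer event (donor, recipient, time fraction from
  root to present) regrafts the recipient's element lineage onto the
  donor's lineage at the transfer age; truth flags mark exactly the pairs
  whose element common origin postdates the species split. Multiple
  transfers are applied sequentially, each replacing the recipient's whole
  element lineage; node ages are taken from root-to-tip depths, so the
  scenario tree should be ultrametric.

What the simulations do not emulate: insertions/deletions during decay,
nested insertions, selection on the host gene beyond a rate scalar,
base-composition heterogeneity, and assembly artifacts. Passing the
synthetic round-trips therefore demonstrates the correctness of the
algorithms under the stated generative model, not annotation performance
on real, indel-rich genomes.

## Problem sizes and numerical choices

The self-contained checks run at desk scale by design: genomes of
40–300 kb with up to 52 planted copies, 20–200 copies for consensus and
divergence recovery, 24-taxon two-cluster scenarios for the within-group
comparison (196 pairs), and 100 replicates of an 8-taxon ladder tree of
depth 0.2 substitutions/site for the transfer detector's error rates.
Optimizer bounds: pair branch lengths are profiled on log t ∈ [−14, 3]
(a fit at the upper bound is reported saturated); the Nelder–Mead outer
fit tolerates xatol 1e-4 and errors out, reporting the last parameter
set, if it exhausts its iteration budget.

## Known limitations

* Boundary resolution assumes TA-flanked insertions; elements with eroded
  TSDs fall back to hit-span coordinates and are typically classified
  truncated.
* Family classification is transfer-based and requires the query to be
  alignable to a reference scaffold; wholly novel transposase folds would
  need their own annotated references.
* The composite-likelihood fit shares rate ratios across all pairs; data
  mixing strongly heterogeneous compositions are better served by per-pair
  models.
* Maximum-likelihood tree inference, model selection, bootstrap support
  and divergence-time estimation are out of scope; the NJ tree is a
  topology/branch-length workhorse, not a substitute for ML analyses.
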