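# Methods

This note documents the models, conventions and numerical choices behind
`gatescan`, what the synthetic-data generator does and does not emulate,
and the known limitations of each stage.

## Coordinates and conventions

Residue positions are 1-based closed intervals throughout, matching the
way cleavage sites are reported in the literature (e.g. "the isoleucine
at position 118").  Genomic coordinates are 1-based inclusive nucleotide
positions; strands are `+`/`-`.  Newick supports are read from internal
node labels; a missing support is `None`, never 0.  Missing branch
lengths default to 0 with a logged warning, because patristic arithmetic
needs numbers.

## Profile search

Profiles are per-column log-odds matrices in bits:
`s(j,a) = log2(((c_ja + τ·b_a) / (n_j + τ)) / b_a)` with pseudocount
τ = 1 and a uniform background `b_a = 1/20` by default (synthetic
proteomes are composition-controlled; the background is overridable).
Columns with more than 50% gaps are dropped and logged; cell scores are
floored at −10 bits to keep arithmetic finite.  These are profiles, not
profile HMMs: `best-window` mode slides the ungapped profile (no
insert/delete states) and is the pipeline default; `glocal` mode aligns
the full profile to the protein with affine gaps (open 11, extend 1),
free protein flanks, for queries with internal insertions.  A hit must
span the profile (proteins shorter than `min_coverage = 0.9` of the
profile length return no hit).

Significance comes from a shuffled null: `n ≥ 200` i.i.d. sequences
drawn from the null composition (the profile's consensus composition by
default, matching the shuffled-background genes of synthetic cohorts)
are scanned in best-window mode and the resulting maxima are fitted with
a Gumbel distribution by the method of moments (`β = s·√6/π`,
`μ = m − γ·β` with Euler's γ).  E-values follow the classic exponential
form `E = N·e^{-(S-μ)/β}`, clipped to `[0, N]`.  Note the distributional
consequence: for null scores the Gumbel-CDF transform is uniform, while
`E/N` itself is approximately Exp(1)-distributed (the e-value of the
median null score is `N·ln 2 ≈ 0.69N`); the calibration sanity test
checks the former.  The pipeline's default hit threshold is `E ≤ 10⁻³`.

## Neighborhood classification

A candidate locus is the set of genes within min(±10 genes, ±10 kb) of a
nuclease hit on the same contig.  A fusion is called when a
protease-family hit starts within the N-terminal margin — min(40% of the
protein, 200 residues) — and a non-overlapping partner-family hit lies
C-terminal to it; overlapping hits are resolved by bit score.  The
classification rules are the locus grammar of the known systems: a
trypsin fusion with HamA (or a HamB helicase context) ⇒ Hachiman; with a
STAND ATPase ⇒ AVAST; with LmuA (or LmuB context) ⇒ Lamassu; with a
reverse transcriptase ⇒ DRT; a standalone caspase gene upstream of the
nuclease ⇒ *canu*; no rule fired ⇒ unknown.  When several rules fire,
the label with the highest total marker bit score wins and the
competitors are recorded.  Co-occurrence is strand-agnostic and
"upstream" is evaluated relative to the partner gene's reading direction;
the nuclease-upstream expectation is logged as a boolean, never
enforced, because natural loci vary.  The defense-island score counts
distinct additional defense/transposase marker families within an
extended 20 kb window, excluding the locus's own genes; it is monotone
in the window size by construction.

Catalytic-motif checks (e.g. the HamA D-GEXK motif, lost in
protease-HamA fusions) use degenerate patterns where letters match
exactly and `X`/`-` match any residue, restricted to a designated region
of the protein.

## Coevolution statistics

Distances are Poisson-corrected amino-acid distances `d = −ln(1−p)` over
columns where both sequences have residues; pairs with `p ≥ 0.95` are
flagged saturated and capped at `−ln 0.05` so matrices stay finite.
Neighbor joining follows the Saitou–Nei Q-criterion with a deterministic
tie-break (lexicographically smallest cluster-representative pair);
negative branch lengths are clamped to 0 with the total deficit logged.
On additive matrices the implementation is exact (verified against
patristic matrices of random trees).

Congruence of a nuclease tree and a protease tree is measured on ≥ 4
same-locus leaf pairings: the Mantel statistic is the Pearson
correlation of the two patristic distance matrices, and the null
permutes the locus pairing of one matrix;
`p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm)` with 999 permutations by
default and a mandatory recorded seed.  Degenerate (constant-distance)
inputs are flagged and given p = 1.  Robinson–Foulds distances are
symmetric differences of non-trivial bipartitions, normalized by the
attainable maximum (2(n−3) for binary trees).

The transfer statistic is Fitch label parsimony: the minimum number of
defense-system label changes on the (arbitrarily rooted, polytomies
arbitrarily resolved) nuclease gene tree, compared with the vertical
minimum of `#labels − 1`.  The excess counts candidate cross-system
transfers; a label-permutation null indicates whether labels remain
clustered.  This deliberately replaces formal
duplication-transfer-loss reconciliation: the parsimony excess captures
the testable signal (repeated independent acquisition) at a fraction of
the machinery, and tree pairs can be exported for external
reconciliation tools.  Patristic computations are intended to follow
support filtering (collapse of branches with support < 60, the
conventional display threshold); contraction treats the unsupported
branch as length 0.

## Gate detection

The candidate nuclease is globally aligned to the ungated reference with
affine gaps (BLOSUM62; open 11, extend 1; a length-k gap costs
`11 + k`).  The dynamic program is vectorized per row, and trace-back
ties are resolved deterministically: match > insert-in-query >
insert-in-reference.  Agreement with a brute-force enumeration of all
alignment paths is exhaustively tested on short sequences.

Insertions are maximal runs of reference-row gaps, merged when separated
by fewer than `merge_gap = 3` aligned columns, and reported as 1-based
closed intervals in query coordinates when at least `min_len = 10`
residues long.  Reference active-site columns are mapped through the
alignment (a column aligned to a query gap is "absent").  An insertion
contributes three unit-weight components to the gate score: length
≥ `min_len`, chain distance to the nearest mapped active-site position
≤ `prox_window = 30` residues, and presence of an expected cleavage
residue (Ile for trypsin-partner systems, Gly for *canu*, either for
unlabeled loci); a locus is *gated* when one insertion passes all three.
Proximity along the chain is a deliberate 1-D proxy for the structural
observation that the insertions occlude the catalytic pocket; it cannot
see loops that are sequence-distal but spatially close, which is the
main divergence from a structure-based reading.

Cleavage logos report per-column residue frequencies over non-gap
characters and information `log2 20 − H − e(n)` with the small-sample
correction `e(n) = 19/(2n·ln 2)` (clamped to `[0, log2 20]`); all-gap
columns are flagged with zero information.  Logos are emitted as TSV
frequency/information matrices.

## Synthetic data: what it emulates

Families evolve along pure-birth trees (scaled so the root-to-tip depth
equals `sub_rate` substitutions/site) under a 20-letter uniform
replacement model — chosen because it admits the closed-form Poisson
distance correction used in testing.  Leaf names are assigned in
randomized order so that the labels of independently simulated trees are
uncorrelated.  Horizontal co-transfer is a leaf SPR applied to a single
shared genealogy, so a nuclease/protease pair moves jointly by
construction.  `indel_rate` adds a per-branch, per-site deletion-to-gap
process (gaps inherited by descendants) to exercise gap handling;
insertion events are not simulated along trees because gating insertions
— the insertions whose ground truth matters — are implanted explicitly
by `make_gated_sequence`.

The default cohort is 50 single-contig genomes of 20 background genes
each (Fisher–Yates shuffles of seed-family sequences: composition
preserved, positional signal destroyed), with ten implanted loci (two
per architecture), ten ungated decoy nucleases, and one transposase gene
beside each implant as the defense-island cue.  The eight
trypsin-partnered loci co-evolve their nuclease and trypsin domains on
one joint genealogy (root-to-tip divergence 0.2, on average one
co-transfer event) so that tree congruence and transfer signal have
ground truth; partner domains and markers diverge independently at the
same rate.  Gating insertions (two per nuclease: 20 and 22 residues at
reference positions 100 and 200, cleavage residue mid-insertion) draw
their content from a disorder-promoting residue pool (A,E,G,K,P,Q,R,S
minus the cleavage residue), reflecting the disordered character of
natural gating loops and keeping insertion content compositionally
distinct from the folded reference.  Catalytic residues (the reference
nuclease's D/H/K triad, the HamA D-GEXK motif) are re-imposed after
neutral evolution in active family members — purifying selection — and
knocked out in protease-HamA fusion copies.  Seed alignments are eight
members per family at divergence 0.1.

What the generator does **not** emulate: nucleotide sequence, codon
structure and intergenic content; realistic substitution matrices and
rate heterogeneity; genuinely disordered-region evolution (elevated
indel rates); operon structure and strand correlation; paralogy within a
genome; and real database noise (partial genes, contaminant homologs).
Passing tests therefore demonstrate correctness of the machinery and
calibration under a controlled regime, not expected performance on real
genome databases, where search sensitivity and neighborhood noise
dominate.

## Discovery ranking

The candidate rank is the mean of min-max-normalized island score, gate
score, marker evidence count and (when a congruence block was
computable) the group Mantel r; NaN components are skipped and a
constant column normalizes to zero so it cannot reorder candidates.
This combined score is declared plumbing: a deterministic, monotone way
to order candidates for inspection, not a published statistic.  Runs are
deterministic end-to-end under a fixed master seed (child streams are
derived by stable hashing of component tags), and the report body is
byte-identical across repeated runs.

## Validation problem sizes

The validation battery (also run by `scripts/acceptance.py`) uses: 500
random short pairs for the alignment brute-force oracle; 100 random
trees (≤ 7 leaves, ≤ 4 labels) for exhaustive Fitch; 100 random additive
matrices (≤ 8 taxa) for NJ exactness; 500 independent-evolution
replicates (999 permutations each, 16 loci, 150-site families) for
Mantel type-I error and 100 joint-transfer replicates for power; 200
gated plus 200 ungated nucleases for gate recovery; and the default
50-genome cohort for classification and ranking.  These sizes give
stable estimates (e.g. a binomial 99% CI of ±0.025 around α = 0.05) at
about half a minute of total compute on one CPU.

## Known limitations

* Sequence-level gate calling inherits alignment ambiguity: at 20%
  divergence a called insertion boundary can shift by a few residues
  when insertion content happens to align favorably to the reference
  flank (~0.5% of insertions in the recovery study); cut sites at the
  extreme edge of an insertion are the most exposed.
* The Fitch count on multifurcating trees is an upper bound (exact for
  binary trees); polytomies are resolved arbitrarily but
  deterministically.
* E-value calibration assumes the null composition matches the scanned
  background; scanning proteomes whose composition differs markedly from
  the calibration null shifts e-values.
* Best-window scanning has no gap states; family members with large
  internal insertions relative to the seed alignment lose score
  linearly in the insertion length (the glocal mode exists for this
  case but is slower).
* The classifier only knows the five implemented architectures plus
  `unknown`; it does not discover novel system grammars.
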