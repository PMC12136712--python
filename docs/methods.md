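# Methods

This note documents the models, conventions and numerical choices
behind each phagekit module, what the synthetic-data generators do and
do not emulate, and the design decisions taken where more than one
defensible convention exists.

## Protein featurization

Each protein is described by 431 ordered descriptors: 20 amino-acid
composition fractions, 400 overlapping dipeptide fractions
(counts / (L−1)), and 11 scalars. Thirteen descriptor families expand
naturally to 430 dimensions; sequence length is included as the 431st
scalar, consistent with ProtParam-style pipelines, and the full order
is frozen in `phagekit.seq_features.FEATURE_NAMES` so feature matrices
are column-compatible across runs.

Conventions (all constants collected in `phagekit.constants`, and
exported as a sidecar JSON next to every feature matrix):

- **Molecular weight** — sum of average (not monoisotopic) Expasy
  residue masses plus one water (18.0153 Da).
- **Instability index** — Guruprasad dipeptide weights (DIWV):
  II = (10/L) Σ DIWV(sᵢ, sᵢ₊₁).
- **GRAVY** — mean Kyte–Doolittle hydropathy per residue.
- **Charge / pI** — Henderson–Hasselbalch over the two termini and the
  D, E, C, Y (acidic) and K, R, H (basic) side chains using the flat
  Bjellqvist pKa set (N-term 7.5, C-term 3.55, D 4.05, E 4.45, C 9.0,
  Y 10.0, H 5.98, K 10.0, R 12.0). We deliberately omit the
  residue-specific N-terminal pKa corrections of the full Bjellqvist
  method: the flat set keeps the charge model a pure function of
  residue counts, and the net charge is strictly decreasing in pH, so
  the pI exists and is unique. pI is found by bisection on [0, 14]
  (≤ 100 iterations, i.e. to machine precision).
- **Secondary-structure fractions** — the classic ProtParam propensity
  sets: helix {V,I,Y,F,W,L}, turn {N,P,G,S}, sheet {E,M,A,L}. The sets
  overlap by design (L is both helix- and sheet-forming). Newer
  Biopython releases use revised sets; we pin the classic convention
  because the overlap property is load-bearing for downstream feature
  semantics and tests.
- **Extinction coefficient** — 5500·nW + 1490·nY M⁻¹cm⁻¹, cysteines
  assumed reduced (no cystine term).

Sanitization uppercases, strips `*` and `-`, and removes ambiguity and
non-standard codes (B, Z, X, U, O) with a logged warning. Sequences
with fewer than 30 standard residues are rejected: dipeptide statistics
on shorter fragments are noise. The threshold is a parameter.

Every scalar descriptor is validated two ways: against a naive
loop-based oracle at 1e-9 relative tolerance on 1000 random sequences,
and (where the convention coincides) against Biopython's ProtParam.

## Family classification

A random forest with 1000 trees (scikit-learn, fixed `random_state`)
over the 431-dimensional vectors of tail-annotated proteins (product
contains the substring "tail", case-insensitive). No feature scaling is
applied — trees are scale-invariant. Evaluation is stratified 10-fold
cross-validation over proteins; if the rarest class has fewer members
than k, k is reduced with a warning. Proteins of one genome may land in
different folds; a `group_by_genome` mode (stratified group k-fold) is
available for users who consider that leakage, default off.

A genome-level family call aggregates per-protein predictions by
majority vote; ties break by highest mean predicted class probability,
then lexicographically — fully deterministic.

The default seed everywhere is 37; every CLI entry point takes
`--seed`.

## Genome comparison

- **Genome statistics** — GC% over the full sequence; coding density as
  |union of CDS intervals| / length × 100, merging overlapping genes so
  shared bases count once.
- **Hit filtering** — identity ≥ 50 %, query coverage ≥ 85 %,
  E-value ≤ 1e-9, all boundaries inclusive. E-values are consumed, not
  computed.
- **Module detection** — maximal runs of same-strand genes sharing a
  functional category with at most 2 intervening genes (parameter), the
  standard signature of a lysis cassette
  (endolysin–holin–spanin block).
- **Pairwise identity** — one global Needleman–Wunsch alignment with
  affine gaps (match +2, mismatch −1, gap open −4, extend −1;
  configurable), identity = matching columns / alignment columns × 100.
  Implemented on Biopython's PairwiseAligner.
- **Greedy clustering** — longest-first centroid-greedy search at a
  fractional identity threshold (default 0.5), deterministic given the
  input (length ties break by id).
- **Pan-genome** — a cluster is *core* if its members span all genomes,
  *unique* if they map to exactly one genome, *accessory* otherwise;
  the three counts always sum to the cluster count.
- **ANI** — both genomes are cut into consecutive 1020-bp fragments
  (sub-window tail discarded). A fragment pair is considered alignable
  only if it shares at least 8 exact 12-mers — an explicit seeding step
  standing in for the word-match stage of a BLAST-based orthologous
  fragment search. Per direction, the best-identity candidate (top 5 by
  seed count) defines the best hit; ANI is the mean identity over
  reciprocal best pairs at or above a 35 % identity floor. With no
  qualifying pair the ANI is *undefined* (returned as `None`), which is
  a result, not an error. The seeding step matters: a raw global
  alignment of two unrelated 1020-bp fragments lands near 50 % identity
  by chance, so a floor alone cannot distinguish "unrelated" from
  "divergent".
- **UPGMA** — average linkage with the size-weighted update
  d(k, i∪j) = (nᵢd(k,i) + nⱼd(k,j))/(nᵢ+nⱼ); a pair merges at height
  d/2, so leaf-to-root path lengths are equal (ultrametric) and the
  cophenetic distances reproduce scipy's average-linkage heights (the
  independent check used in the tests). Ties break by the
  lexicographically smaller pair of cluster representatives.

Coordinates are 1-based inclusive internally (GenBank convention);
converters to/from 0-based half-open are provided. Genomes are treated
as linear contigs; wrap-around features are out of scope.

## Phenotype statistics

- **EOP** = mean(target PFU)/mean(host PFU) × 100; by this definition
  the host against itself is exactly 100 %. The SD is the standard
  deviation of per-replicate ratios when counts pair one-to-one,
  otherwise first-order (delta-method) propagation of the two means.
- **Susceptibility** requires spot-test '+' *and* EOP > 0: a strain can
  show lytic clearing in a spot test (e.g. from lysis-from-without)
  while supporting no productive infection.
- **Fold reduction** = 10^(log₁₀N₀ − log₁₀N); below-detection
  points are carried as censored and produce flagged lower bounds.
  A helper rounds to 2 significant figures for reporting.
- **Growth-curve analysis** assumes a triphasic curve. The baseline is
  estimated iteratively from the first two points outward: a point
  joins while its titer stays ≤ rise_factor (default 2.0) × the running
  baseline mean. The latent period ends at the last baseline point, so
  it is resolved to one sampling interval. The plateau threshold is
  90 % of a robust peak — the median of the three largest titers —
  because with multiplicative noise the raw maximum is upward-biased
  and a single spike would otherwise truncate the plateau; the plateau
  is the mean of all points from the first threshold crossing after the
  rise. Burst size defaults to plateau/baseline (at low MOI with
  pre-sampling adsorption, infected centers ≈ initial free phage); the
  incremental form (plateau−baseline)/baseline is a flag. At burst
  sizes near 150 the two differ by under 1 %.

## Structure and conservation

Interface residues of chain group A against group B are those with any
heavy atom within 5.0 Å (inclusive) of any heavy atom of B, computed
with a k-d tree and reported with per-residue minimum distances;
hydrogens, waters and heteroatom groups are excluded at parse time
(flag to retain), only MODEL 1 of multi-model files is read, and for
alternate locations the highest-occupancy conformer is kept.
Contiguous interaction regions are maximal runs of consecutive author
numbers (same or empty insertion code) of length ≥ 6.

Alignment columns are profiled for occupancy (non-gap fraction),
conservation (modal-residue frequency among non-gap symbols; NaN for
all-gap columns) and information content IC = log₂20 − H bits; columns
below 50 % occupancy (parameter) are flagged low-alignment-ratio, since
conservation estimated from a few aligned sequences is unreliable.
Logo matrices report per-position residue frequencies among non-gap
symbols so gap-dominated positions render as blanks.

PCA is column-centered SVD; each component's sign is fixed so its
largest-magnitude loading is positive, making scores reproducible.

## Synthetic data: what it does and does not show

Every generator is a pure function of its arguments including an
explicit integer seed, and returns the ground truth it planted.

- **Proteomes** — family-specific residue frequencies drawn from
  Dirichlet priors concentrated on (typically disjoint) residue
  subsets; sequences are i.i.d. draws. This makes families separable by
  composition alone, which validates the learning machinery but is far
  easier than real tail-protein taxonomy, where families overlap in
  composition and signal lives in motifs and domain architecture. A
  high benchmark accuracy here shows the pipeline is sound, not that
  real-data accuracy will match.
- **Growth curves** — flat baseline, linear rise over a fixed duration,
  flat plateau, pointwise multiplicative lognormal noise (default CV
  5 %). Defaults are baseline 10⁵ PFU/mL, plateau 1.46 × 10⁷ (burst
  146), latent 20 min, 5-min sampling. Real curves have adsorption
  decay, ragged bursts and occasional second cycles — none emulated.
- **Genome pairs** — per-site i.i.d. substitutions at a given rate;
  no indels, no rearrangements, no repeat structure. ANI recovery of
  100·(1−rate) validates the fragment/reciprocal-best machinery under
  colinearity; real genome pairs diverge less uniformly.
- **Complexes** — single-atom residues on a widely spaced grid with
  planted cross-chain contacts strictly inside the cutoff and all other
  cross-chain distances beyond cutoff + margin (generator refuses a
  non-positive margin). This makes the expected interface exactly
  computable; real interfaces have packed, ambiguous boundary contacts.
- **Alignments** — per-column modal residue emitted with a prescribed
  probability, other residues uniform, gaps i.i.d. No phylogenetic
  correlation between sequences, so conservation estimates concentrate
  faster than on real alignments.

## Known limitations

- The classifier benchmark is intentionally separable; no claim is
  made about accuracy on public-database-scale phage data, which would
  require downloading those proteomes.
- ANI is undefined (not 0) below the alignability floor; comparing
  across genera should use the `None` signal, not a number.
- The greedy clusterer is O(n·k) pairwise global alignments and meant
  for phage-proteome scale, not metagenome scale.
- The internal aligner replaces external alignment/search binaries;
  scores are documented and configurable but E-values, where attached,
  are labelled approximate and not used for inference.
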