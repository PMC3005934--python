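# Methods

## The prediction problem

Given a protein chain, predict for every residue whether it contacts RNA in
the (usually unknown) complex. Ground truth comes from co-crystallized
protein–RNA structures: a residue is *RNA-binding* when the minimum
Euclidean distance between any of its heavy atoms and any heavy atom of an
RNA chain in the same structure is at most 5 Å. Binding residues are a
minority class (roughly one residue in five in ribosome-rich training data,
one in ten elsewhere), which shapes both the classifier design and the
evaluation protocol.

## Interface labeling and dataset construction

`structure_io` parses PDB/mmCIF with gemmi, classifies polymer chains by
residue-name majority (standard amino acids → protein; A/C/G/U → RNA),
drops hydrogens, and collapses alternate locations to the
highest-occupancy record (ties to file order). Labeling conventions that
the distance rule alone does not fix were resolved as follows:

- the 5 Å cutoff is **inclusive** (≤), matching the convention of the
  benchmark datasets this definition descends from;
- **any heavy atom** qualifies, backbone or side chain; hydrogens are
  excluded because most X-ray structures do not resolve them;
- the chain sequence is taken from **observed ATOM records**, not SEQRES:
  a residue without coordinates cannot be assigned a distance-based label;
- modified residues map to their standard parent letter where one exists,
  otherwise to `X`; both remain label-eligible.

Dataset filters follow the benchmark construction: resolution ≤ 3.5 Å
(inclusive; chains with no recorded resolution are dropped and logged) and
chain length strictly > 40. Redundancy reduction is a deterministic greedy
clustering — sequences visited by descending length (ties by id) join the
first representative with global-alignment identity (matches / alignment
columns; match = 1, mismatch = 0, gap = −1) above 30%, else found a new
cluster. This is a simple, reproducible stand-in for cluster-based
redundancy removal tools; on well-separated families it yields the same
partition as exhaustive all-pairs clustering (tested).

## Features

Per residue the evidence is its PSSM column (20 log-odds integers from an
iterative profile search, read from the blastpgp ASCII dialect) and three
predicted secondary-structure probabilities (PSIPRED `.ss2`, reordered
from the file's C/H/E columns to the internal H/E/C convention and used
**raw** — the upstream predictor's example probabilities do not sum to 1,
so renormalizing would change the data).

PSSM scores are squashed elementwise with the logistic sigmoid
`f(x) = 1/(1+e^{−x})`. The log-odds half of the PSSM file is used (a
signed quantity is what a sigmoid normalization presupposes); the squash is
a replaceable callable so min–max or clamping variants can be swapped in.

The window encoder concatenates the 24-value blocks of positions
*i−11 … i+11*: 20 normalized PSSM values, H, E, C, and a boundary flag.
Out-of-sequence positions contribute zeros with flag 1 — the flag exists
precisely to let the classifier distinguish "no evidence because off the
end" from "evidence ≈ 0". One flag per window position (23 per vector) is
forced by the 23 × 24 = 552 dimension arithmetic. The block order
(PSSM, H, E, C, flag) is an arbitrary but frozen convention; any
consistent order is equivalent for a kernel classifier.

## Classifier

An RBF-kernel SVM (scikit-learn's libsvm binding) with C = 2¹ and
γ = 2⁻⁵ — the tuned values for this feature encoding — and a decision
threshold fixed at 0 (the raw decision-function sign; no post-hoc cutoff
adjustment). No class reweighting is applied by default; a positive-class
weight is exposed in `ModelSpec` because heavier imbalance than the
training benchmark's may warrant it. `grid_select` re-tunes (C, γ) by
k-fold cross-validated MCC — MCC because it is the emphasized
imbalance-robust statistic here — with ties resolved toward the smaller C,
then the smaller γ (the less complex model). Training is deterministic
given data, spec and seed.

## Conservation mining

The conservation arm is a functional **stand-in** for discontinuous-pattern
miners of the WildSpan family, reproducing the interface contract
(conserved blocks linked by flexible gaps → residue calls) rather than any
specific published search algorithm. Stages:

1. **Homolog filtering**: keep hits with query identity in [0.30, 0.90],
   deduplicate exact sequences, cap at the 150 highest-identity hits
   (ties by id). The window excludes near-duplicates (no information) and
   remote homologs (alignment noise).
2. **Conservation vector**: each homolog is globally aligned to the query
   (match 1 / mismatch 0, gap open −10, extend −1); conservation at query
   position *i* is the fraction of homologs with the identical residue
   aligned there; gaps count as non-conserved.
3. **Block mining**: maximal runs with conservation ≥ `min_support`
   (default 0.8) of length ≥ `min_block_len` (default 3) become blocks;
   consecutive blocks at most `max_gap` (default 30) residues apart chain
   into one discontinuous pattern.
4. **Calls**: every position covered by a block is predicted binding.

Fewer than 3 usable homologs after filtering raises a documented
"no pattern" error — which includes the case where all homologs were too
similar and fell outside the identity window — and the pipeline falls back
to SVM-only predictions with a logged notice. The three mining parameters
are package defaults, deliberately configurable: under the null (random
30%-identity homologs) support 0.8 with block length 3 emits patterns in
under 5% of runs, while 95%-conserved planted blocks are recovered with
sensitivity ≥ 0.95 and false coverage ≤ 0.05 (both tested).

## Combination

A residue is binding if **either** predictor says so (call-level OR, with
per-position provenance recorded). The union direction is forced: combined
sensitivity ≥ SVM-only sensitivity and combined specificity ≤ SVM-only
specificity on any input. OR was chosen over AND/majority because the
benchmark count arithmetic of the combined predictor (TP larger than either
component's) is only consistent with a union; the conservation stage also
has no natural score, ruling out score-level fusion.

## Evaluation protocol

Counts are **micro-averaged**: TP/FP/TN/FN pooled across chains, folds or
RNA categories before computing sensitivity, specificity, precision,
accuracy, MCC and Fβ (β = 1, 0.5). Zero-denominator statistics return 0 and
are flagged; rounding happens only at display time.

Cross-validation is sequence-based by default — whole chains are randomly
assigned to k = 5 folds (sizes within one chain), repeated (default 20
times), with pooling across folds *within* a repeat and mean ± sample
(n−1) standard deviation across repeats. Window-based assignment is
implemented for contrast: adjacent residues share 22 of 23 window
positions, so splitting windows of one chain across folds leaks
near-duplicates into training and inflates the estimate. The package's
validation measures exactly this: on synthetic chains with contiguous
binding spans and a weak planted signal, the median window-based MCC
exceeds the sequence-based one.

## Synthetic data: what it emulates, what it does not

- `simulate_complex` plants an interface span geometrically: interface
  residues get one atom at a chosen distance < 5 Å from an RNA atom, all
  other atoms sit beyond the background distance > 5 Å, so the true labels
  are known exactly and the labeler can be checked against a brute-force
  all-pairs scan. The geometry is a point cloud, not a polymer.
- `simulate_family` makes point-mutated homologs: positions survive with
  probability `block_conservation` inside planted blocks and
  `background_identity` (default 0.3, the lower edge of the miner's
  identity window) elsewhere. No indels, no phylogenetic correlation
  between homologs.
- `simulate_profiles` draws integer PSSM scores from N(0, σ²) (σ = 2, a
  typical log-odds spread) and adds a mean shift `signal` on a fixed
  5-row subset at binding residues; secondary-structure probabilities are
  uniform noise. The 5-row subset concentrates the signal enough to
  survive dilution across the 552-dimensional window; real binding signals
  are of course not confined to fixed alphabet rows.

Consequently, passing tests demonstrate that the pipeline's machinery is
correct and sensitive to planted signal under controlled conditions — not
that the advertised benchmark performance would be reproduced on real
chains, which would require profile searches against external sequence
databases and structure downloads.

## Problem sizes and numerical choices

The validation experiments use sizes chosen to exercise every code path
with stable statistics: 50 random complexes (10–35 residues) for the
labeling oracle; 20 seeds of 60-homolog families (80-residue queries) for
block recovery; 20 chains × 50 residues per cross-validation run, with
signal levels {0, 2, 5} × 5 seeds for the signal response and 12 chains ×
20 seeds for the sequence- vs window-based comparison. Distance queries use
a k-d tree over RNA atoms; the brute-force all-pairs scan exists only as a
test oracle. Monotonicity of the sigmoid is asserted over the realistic
log-odds range |x| ≤ 16, beyond which float64 saturates.

## Known limitations

- The miner is an interface-compatible stand-in; its block/support/gap
  defaults are package choices, not values inherited from any published
  miner.
- Redundancy reduction is greedy single-linkage-like, not a reimplementation
  of BLAST-based clustering.
- No probability calibration, no ROC/AUC, no threshold optimization, no
  biological-assembly expansion, no DNA handling.
- External tools (profile search, secondary-structure prediction) are
  consumed via their output files only; the package never invokes them.
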