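# proterna

Sequence-based prediction of RNA-binding residues in proteins.

RNA-binding proteins recognize their RNA partners through a minority of
interface residues; knowing which residues those are guides site-directed
mutagenesis and the interpretation of protein–RNA complexes. `proterna`
implements a complete prediction framework for this problem:

- **Interface labeling** from co-crystallized protein–RNA complexes
  (PDB/mmCIF): a residue is RNA-binding when any of its heavy atoms lies
  within 5 Å (inclusive) of any RNA heavy atom, plus the dataset filters
  (resolution ≤ 3.5 Å, chain length > 40, redundancy reduction to ≤ 30%
  pairwise identity).
- **Evolutionary-profile window features**: each residue *i* is encoded by
  the profiles of residues *i−11 … i+11* (window size 23). A window
  position contributes 24 values — the 20 PSSM log-odds scores squashed
  through the logistic `f(x) = 1/(1+e^{−x})`, the three predicted
  secondary-structure probabilities (H, E, C), and a boundary flag for
  positions off the sequence ends — giving a 23 × 24 = 552-dimensional
  vector.
- **An RBF-kernel SVM** (C = 2¹, γ = 2⁻⁵, decision threshold 0) over those
  vectors.
- **Conserved-residue pattern mining** over homolog families (30–90%
  identity to the query, at most 150 sequences): maximal conserved runs
  chained through flexible gaps into discontinuous patterns whose covered
  positions become predicted binding residues.
- **A union combiner**: a residue is called binding when either predictor
  calls it, trading a little specificity for recovered sensitivity.
- **Imbalance-aware evaluation**: TP/FP/TN/FN micro-averaging and the seven
  statistics — sensitivity, specificity, precision, accuracy, the Matthews
  correlation coefficient

  MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

  and Fβ = (1+β²)·precision·sensitivity / (β²·precision + sensitivity) for
  β ∈ {1, 0.5} — with repeated **sequence-based** k-fold cross-validation
  (whole chains share folds, so overlapping windows of one chain never
  straddle the train/test split).

A seed-deterministic synthetic-data module generates toy complexes with
planted interfaces, homolog families with planted conserved blocks, and
profile matrices with a tunable binding signal, so the whole pipeline can be
exercised and validated without any external databases.

## Worked example

```python
import numpy as np
from proterna import (
    ModelSpec, combine_union, confusion, metrics, mine_patterns,
    pattern_calls, predict, train, encode_chain,
)
from proterna.conservation_miner import MinerConfig
from proterna.synthetic_data import (
    SimFamilyConfig, SimProfileConfig, simulate_family,
    simulate_labeled_chains, simulate_profiles,
)

# train the SVM on synthetic chains with a planted profile signal
dataset = simulate_labeled_chains(n_chains=8, chain_length=40, signal=4.0, seed=11)
model = train(
    np.vstack([X for _, X, _ in dataset]),
    np.concatenate([y for _, _, y in dataset]),
    ModelSpec(seed=0),
)

# a new chain: binding span at residues 16-27, homolog family conserved there
labels = np.array([int(15 <= i < 27) for i in range(50)])
profiles = simulate_profiles(SimProfileConfig(
    chain_length=50, binding_labels=tuple(labels), signal=4.0, seed=3))
family = simulate_family(SimFamilyConfig(
    query_length=50, n_homologs=40, planted_blocks=((16, 27),), seed=3))

svm = predict(model, encode_chain(profiles))
cons = pattern_calls(mine_patterns(family, MinerConfig(min_support=0.7)), 50)
combined = combine_union(svm, cons)
print(metrics(confusion(labels, combined.combined_calls)).summary())
```

prints

```
TP=12 FP=0 TN=38 FN=0
sensitivity 100.00%  specificity 100.00%
precision   100.00%  accuracy    100.00%
MCC 1.0000  F-score 1.0000  F0.5-score 1.0000
```

i.e. with this strong planted signal the union of the two predictors
recovers all 12 binding residues without over-calling any of the 38
non-binding ones. Weaker signals (see the acceptance experiments) yield the
intermediate MCC values where the statistic's sensitivity to both error
directions matters.

A CLI mirrors the stages (`proterna label | featurize | train | predict |
mine | evaluate | simulate`); run `proterna --help`.

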