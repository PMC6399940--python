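# antiangio

Sequence-based prediction of anti-angiogenic peptides.

Angiogenesis — the sprouting of new blood vessels from existing ones — is a
prerequisite for tumor growth and metastasis, and peptides that inhibit it are
an active lead class in cancer therapy. Screening candidate peptides in the
wet lab is slow, so a classifier that ranks sequences by their likelihood of
anti-angiogenic activity is a useful triage tool for peptide chemists and
computational biologists. `antiangio` provides that tool as a tested Python
library with a thin command-line interface: five sequence-derived feature
encoders, a near-zero-variance feature filter, and a configurable classifier
sweep from which three purpose-specific models are selected.

## The method

Each peptide of length *L* over the 20-letter amino-acid alphabet is encoded
by five feature families:

1. **Pseudo amino acid composition (type I, λ = 6, w = 0.05).** The 20
   residue frequencies *f*₁…*f*₂₀ are extended with λ sequence-order terms
   θ₁…θ_λ, where θ_k averages the mean squared difference of three
   standardized residue properties (hydrophobicity, hydrophilicity,
   side-chain mass) over all residue pairs k positions apart. Components
   x_u = f_u / (1 + w Σθ) for u ≤ 20 and x_{20+k} = w θ_k / (1 + w Σθ), so
   the 20 + λ = 26 components form a probability vector.
2. **k-mer composition (k = 2, 3, 4).** The fraction of each of the 20^k
   words among the L − k + 1 windows of the sequence.
3. **Reduced-alphabet k-mer composition (k = 2, 3, 4).** The same counts
   after mapping the 20 residues onto 8 physico-chemically derived classes
   {A,E} {I,L,F,M,V} {N,D,T,S} {G} {P} {R,K,Q,H} {Y,W} {C}, giving 8^k words.
4. **Physico-chemical profile.** For the 5 C-terminal positions (residues
   L−4…L) followed by the 5 N-terminal positions (residues 1…5), the value of
   every index in an AAIndex-style table; with a 191-index table this is a
   10 × 191 = 1910-dimensional block. Index tables are pruned to a
   non-redundant subset (no pair with |Pearson r| ≥ 0.8 over the 20 residues).
5. **Atomic profile.** The same 10 positions described by each residue's
   C, H, N, O, S atom counts (10 × 5 = 50 values).

Features with (almost) no variation across the sample are removed by the
near-zero-variance filter: a feature is dropped if it has a single unique
value, or if its percentage of unique values is ≤ 10 and the frequency ratio
of its two most common values is ≥ 19. A classifier registry — cost-sensitive
CART trees, pruned rule-list trees and regularized gradient boosting by
default, arbitrarily extensible — is then trained on the training partition
and scored on a held-out test partition (stratified 20% by default). Three
role models are selected from the leaderboard:

* **most_sensitive** — highest TP/(TP+FN): a broad candidate list that
  misses few true anti-angiogenic peptides;
* **most_specific** — highest TN/(TN+FP): a narrow, confident list;
* **most_accurate** — highest (TP+TN)/n overall.

## Worked example

Simulate a labeled dataset whose positives are enriched 8-fold in lysine and
arginine, encode it with the compact feature configuration (dipeptides only),
run the sweep, and predict:

```bash
printf 'encoder:\n  kmer_ks: [2]\n' > config.yaml
antiangio simulate --n-pos 100 --n-neg 100 --enrichment 8 --signal-residues KR \
    --seed 7 --out-fasta peptides.fasta --out-labels labels.tsv
antiangio encode --config config.yaml --fasta peptides.fasta --out features.tsv
antiangio sweep --config config.yaml --features features.tsv --labels labels.tsv \
    --seed 7 --out-bundle bundle --out-leaderboard leaderboard.tsv
```

The sweep prints the per-classifier leaderboard on the held-out 40-peptide
test partition and the chosen roles:

```
        name              family status error  tp  tn  fp  fn  sensitivity  specificity  accuracy
  tree_cost5 cost_sensitive_tree     ok        17  19   1   3         0.85         0.95      0.90
  tree_cost2 cost_sensitive_tree     ok        19  19   1   1         0.95         0.95      0.95
   tree_cart cost_sensitive_tree     ok        18  20   0   2         0.90         1.00      0.95
rules_pruned           rule_list     ok        18  20   0   2         0.90         1.00      0.95
      gboost            boosting     ok        18  20   0   2         0.90         1.00      0.95
  gboost_reg           boosting      ok        18  20   0   2         0.90         1.00      0.95
roles: {'most_sensitive': 'tree_cost2', 'most_specific': 'tree_cart', 'most_accurate': 'tree_cost2'}
```

Here the cost-weighted tree `tree_cost2` recovers 19 of the 20 positive test
peptides (sensitivity 0.95) at one false positive (specificity 0.95), and is
selected for both the sensitive and the accurate role. Scoring peptides with
the sensitive model:

```bash
antiangio predict --bundle bundle --features features.tsv --role most_sensitive --out predictions.tsv
antiangio evaluate --predictions predictions.tsv --labels labels.tsv
```

```
{
  "tp": 99, "tn": 99, "fp": 1, "fn": 1,
  "sensitivity": 0.99, "specificity": 0.99, "accuracy": 0.99
}
```

(The evaluation above includes the 160 training peptides, hence the optimistic
numbers; the leaderboard rows are the honest held-out estimates.)

The same pipeline is available programmatically via
`antiangio.pipeline.run_pipeline` and `run_synthetic_benchmark`.

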