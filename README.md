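# ppilearn

Protein–protein interaction (PPI) prediction from protein **domain** and
**GO-annotation** features, plus whole-proteome interaction-network
reconstruction. The pipeline:

1. **Ontology backtracking** — parse a Gene Ontology OBO 1.4 file, assign
   every term a level (shortest-path depth below a virtual root; the three
   namespace roots sit at level 1), and replace each protein's GO
   annotations by their ancestors at a fixed level *L*.
2. **Feature construction** — encode each protein as a binary vector over
   the ordered union of domain identifiers and level-*L* GO terms; encode a
   protein pair as the concatenation of the two vectors, emitted in both
   orders ("mirrored" vectors).
3. **Negative sampling** — draw random non-self, non-positive pairs until
   the classes are balanced (reproducible per seed).
4. **Classification** — soft-margin kernel SVM (RBF / linear / polynomial /
   sigmoid) with grid search over (C, γ), k-fold cross-validation, Platt
   probability calibration, and logistic-regression / random-forest
   baselines.
5. **Evaluation** — seven indicators: Acc, Sn, Spe, Pre, F1, AUC
   (rank-statistic, midranks for ties) and MCC. Undefined denominators are
   reported as undefined, never silently zero.
6. **Network reconstruction** — stream all candidate pairs of a proteome in
   batches, score each pair (mean of both orientations by default), keep
   edges with score > 0.5, bin scores cumulatively, and extract
   subnetworks around a protein subset.
7. **Synthetic data** — generate ontologies, annotated proteomes and
   rule-based ground-truth interactomes (interacting domain pairs and/or
   co-interacting level-*L* GO term pairs, optional label-flip noise) so
   every stage runs end-to-end with no downloads.

## Input formats

| Input | Format |
| --- | --- |
| Interactions | STRING `protein.links`-style table: `protein1 protein2 combined_score` (whitespace or tab separated, optional header). Scores are 0–1000 integers; a 0–1 scale is auto-detected and rescaled. The positive filter is strict (`score > threshold`); duplicate unordered pairs collapse to the max score. |
| GO annotations | Two-column TSV `protein<TAB>term`, or GAF 2.x (columns 2 and 5; `NOT`-qualified rows skipped). |
| Domains | Two-column TSV `protein<TAB>accession`, or a whitespace-delimited domain-scan report (`#` comments ignored; column indices configurable). Version suffixes (`PF00001.12`) are stripped. |
| Ontology | OBO 1.4 (`[Term]` stanzas; `is_a`, `part_of`, `regulates` edges; `positively_/negatively_regulates` folded into `regulates`; obsolete terms excluded from levels; `alt_id` resolved). |
| Edge lists (output) | TSV `protein_a protein_b score`, lexicographic pair order, six-decimal scores, lossless round-trip. |

## CLI

```bash
# generate a synthetic world (OBO + TSVs + ground truth)
ppilearn simulate --preset small --seed 3 --out world/

# backtrack GO annotations to level 4
ppilearn backtrack-go --obo go.obo --annotations go.tsv --level 4 --out go_l4.tsv

# build a balanced, mirrored, shuffled dataset (MatrixMarket + TSV sidecars)
ppilearn make-dataset --links links.tsv --obo go.obo --go go.tsv \
    --domains domains.tsv --level 4 --min-score 900 --neg-seed 1 --out ds/

# train (fixed kernel, a named profile, or --grid to search C and gamma)
ppilearn train --dataset ds/ --kernel rbf -C 8 --gamma 0.055 --out model.joblib
ppilearn crossval --dataset ds/ --profile crustacea --k 5 --seed 1

# score a saved dataset / reconstruct a proteome-wide network
ppilearn evaluate --model model.joblib --dataset ds/ --out report.json
ppilearn predict-network --model model.joblib --proteins proteins.txt \
    --domains domains.tsv --go go.tsv --obo go.obo --threshold 0.5 --out net/

# or run everything from a YAML config
ppilearn run --config run.yaml --out results/run1 --set go_level=2
```

Named kernel profiles: `bmori` (C=8, γ=0.05), `human` (C=36, γ=0.01),
`crustacea` (C=8, γ=0.055). Every `run` output directory contains the
exact config, a manifest of seeds and dataset sizes, per-fold metrics
(JSON + percentage table), the model archive, and optionally the edge
list, score-bin table and subnetwork.

## Notes on conventions

- GO levels: level(t) = 1 + min over parents, namespace roots at level 1;
  terms shallower than *L* are kept as themselves (`shallow=keep`, the
  default) or dropped.
- A score of exactly 0.5 is classified negative (strict `> 0.5`).
- `kfold` supports `row_level` (plain row shuffle; mirror twins may split
  across folds) and `pair_group` (keeps both orientations together —
  recommended to avoid twin leakage).
- Candidate generation includes self-pairs by default
  (n(n+1)/2 pairs for n proteins).
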