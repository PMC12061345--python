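# hemobleed

Identification of ISTH major postoperative bleeding events in Chinese
electronic-medical-record free text and semi-structured records, for
postoperative tumor-resection patients.

The package implements the full pipeline:

* **corpus_model** — data model for visits, course notes, hemoglobin series
  and transfusion records, with validated JSONL serialization
  (`src/hemobleed/data/visit.schema.json`) and a deterministic, stratified
  visit-level train/test split.
* **synthetic_notes** — a labeled synthetic Chinese EMR corpus generator
  (template bank of 31 clinical-register note templates, demographics,
  hemoglobin trajectories and transfusion records consistent with each
  visit's label), used because the source registry data is not public.
* **feature_extraction** — the 270-dimensional binary feature scheme:
  261 curated bleeding regexes (19 published key patterns plus a
  reconstructed lexicon), 8 frequency-selected segmentation tokens, and
  1 structured quantitative rule. The catalog ships as a versioned,
  user-replaceable TSV (`src/hemobleed/data/catalog_v1.tsv`). Includes text
  normalization, pluggable Chinese segmentation (built-in maximum-matching
  segmenter; jieba is used when importable), token-frequency selection, and
  quantity/unit extraction (transfusions, blood loss, drainage; both
  number-unit orders; Chinese numerals).
* **isth_rule** — quantitative adjudication of major bleeding: hemoglobin
  fall ≥ 2 g/dL, or ≥ 2 units of erythrocyte concentrate post-operatively
  (1 U = 200 mL by default), or critical-site bleeding text; with evidence
  provenance.
* **models** — three classifiers over the binary vectors, implemented in
  NumPy for exact reproducibility: logistic regression (single dense layer,
  sigmoid, sigmoid focal cross-entropy, Adam, 20% stratified validation
  split), exact brute-force KNN, and a 1-D CNN (conv + ReLU, local max
  pooling, single logistic output) with the same loss and optimizer.
* **evaluation** — confusion matrices, the six standard metrics (undefined
  metrics are `null`, never 0), ROC/AUC computed two ways (trapezoid and
  pairwise concordance, asserted equal), and `reconstruct_cm`, which inverts
  rounded published metric rows back to integer confusion matrices by
  exhaustive enumeration.
* **cli** — `hemobleed` command with subcommands
  `generate / adjudicate / extract / train / predict / evaluate / run`.

## CLI walkthrough

```bash
# 2000-visit labeled synthetic corpus at 4.31% prevalence
hemobleed generate --n 2000 --prevalence 0.0431 --seed 1 \
    --out corpus.jsonl --truth truth.csv

# rule-based adjudication only
hemobleed adjudicate --corpus corpus.jsonl --out decisions.csv

# features -> model -> predictions -> evaluation
hemobleed extract --corpus corpus.jsonl --out features.csv
hemobleed train --features features.csv --model lr --seed 1 --out model.json
hemobleed predict --model model.json --features features.csv --out preds.csv
hemobleed evaluate --model model.json --corpus corpus.jsonl \
    --report report.json --roc roc.csv

# or everything in one deterministic run directory (3 models + manifest)
hemobleed run --out runs/exp1 --seed 1
```

`hemobleed train` accepts a YAML config mirroring `ModelConfig`
(threshold, focal_alpha/gamma, epochs, batch_size, learning_rate, knn_k,
cnn_filters/kernel/pool, early stopping), with CLI flags taking precedence.

## Notes

* The corpus format is JSONL (UTF-8, one visit per line); all fixtures are
  generated programmatically, no binary data anywhere.
* The feature catalog's order is stable and versioned: it defines the 1-D
  axis the CNN convolves over, and trained models record the catalog version
  they were fitted against.
* Only the 20 key patterns of the published catalog are public; the
  remaining 241 category-1 entries here are a structurally faithful
  reconstruction (documented per entry in the TSV), not a replica of the
  unpublished lexicon.
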