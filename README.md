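# trialmine

Information extraction and outcome prediction for randomised-trial reports
of smoking cessation interventions, plus the evaluation harness to measure
both. Trial reports arrive as plain text with structured table objects;
the package

- tags entity mentions (a bundled 70-entity schema: presence/absence
  flags, numeric values, and complex sub-components) with BIO sequence
  labelling over sentences and table-derived pseudo-sentences;
- detects the number of study arms ("randomised into *n* groups"),
  clusters arm-name mentions with complete-link agglomeration, and
  associates each entity with the nearest arm mention inside a token
  window (falling back to the whole study);
- scores extraction with per-entity precision/recall/F1, human-benchmark
  comparison and Krippendorff's alpha;
- predicts per-arm cessation percentages from gold annotations with
  grand-mean and additive-linear baselines plus a stacked-LSTM regressor
  over node2vec-style co-occurrence-graph embeddings (optionally
  concatenated with skip-gram text embeddings), compared by five-fold
  cross-validated RMSE;
- generates synthetic gold-annotated corpora with known arms, entity
  values and a known linear outcome model, so everything above is
  testable offline.

## CLI

```bash
# synthetic corpus (documents + gold annotations)
trialmine simulate --seed 1 --n-docs 50 --out corpus.jsonl --gold gold.jsonl

# train a tagger (gazetteer or statistical) on gold BIO sequences
trialmine train-tagger --gold gold.jsonl --docs corpus.jsonl \
    --family statistical --seed 1 --out model.joblib

# tag documents, then cluster arms and associate entities
trialmine tag --model model.joblib --docs corpus.jsonl --out mentions.jsonl
trialmine resolve-arms --mentions mentions.jsonl --docs corpus.jsonl \
    --window 30 --out predicted.jsonl

# score extraction against gold (per-entity F1 table + arm accuracy)
trialmine evaluate --gold gold.jsonl --pred predicted.jsonl --out report.json

# cross-validated outcome-prediction comparison
trialmine predict --studies gold.jsonl \
    --models grand_mean,linear,entities_only,entities_plus_text \
    --k 5 --seed 1 --out rmse.json

# everything in one go
trialmine run-all --seed 1 --n-docs 50 --family gazetteer --outdir out/
```

All inter-stage data is JSON-lines; reports are JSON and embed the seeds
of every stochastic stage. The association window `t` (default 30 tokens)
is exposed via `--window`.

## Layout

| module | contents |
| --- | --- |
| `trialmine.schema` | entity schema, annotation model, value normalization, JSON-lines I/O |
| `trialmine.ingest` | sentence segmentation, table linearization, document assembly |
| `trialmine.tagging` | tokenizer, BIO encode/decode, gazetteer + statistical taggers |
| `trialmine.arms` | arm-count detection, complete-link clustering, entity-arm association |
| `trialmine.evaluate` | matching, P/R/F1, summaries, Krippendorff's alpha, CV folds |
| `trialmine.predict` | feature vectors, co-occurrence graph, embeddings, baselines, LSTM, RMSE |
| `trialmine.simulate` | synthetic corpus generator and annotation corruption |
| `trialmine.pipeline` / `trialmine.cli` | orchestration and the command-line interface |
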