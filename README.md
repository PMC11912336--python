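# toxgat

Graph-attention models for molecular toxicity prediction with
mechanism-oriented interpretability:

* **Model** (`gat_net`) — stacked graph-attention convolution layers
  (closed-neighborhood attention with self-loops, each followed by a linear
  transform and batch normalization), a global scaled-dot-product multihead
  attention block with a residual connection, concatenated global max/mean
  pooling, and a two-layer head (regression output or classification logit).
  All attention matrices can be captured during a forward pass.
  The network runs on a small NumPy reverse-mode autodiff engine
  (`autodiff`), so no deep-learning framework is required.
* **Transfer learning** (`train_eval`) — pretraining on a continuous
  lipophilicity-like target, fine-tuning as a binary toxicity classifier
  (head replaced, backbone trained at a smaller learning rate), scratch
  baselines, stratified k-fold splits, repeated 90/10 evaluation, RMSE and
  midrank ROC-AUC metrics, AdamW with decoupled weight decay, early stopping.
* **Attention correction** (`attn_correct`) — composes the per-layer local
  attention matrices into a composite contribution matrix `C`, corrects the
  head-averaged global attention as `M = mean(A_i) @ C + C` (residual
  consistent; every row of `M` sums to 2), derives per-atom scores, and
  selects candidate substructures (connected components of above-mean-score
  atoms).
* **Subgraph Shapley values** (`subgraph_shapley`) — a substructure is one
  player, the individual atoms reachable within `L` bonds (default 4) are the
  others, and everything else is zero-feature-masked in every evaluation.
  Exact enumeration up to a configurable cap, a seeded permutation-sampling
  estimator beyond it, and an unrestricted brute-force oracle for testing.
* **Alert discovery** (`alert_pipeline`) — substructures proposed by
  corrected attention are scored under both the toxicity and the
  lipophilicity model, grouped by canonical fragment, categorized by element
  content (nitrogen / sulfur / nitrogen-sulfur / halogen / other), and
  flagged as *specific-mode-of-action candidates* when they contribute
  positively to toxicity but negatively to lipophilicity.  Includes a KDE
  distribution-overlap statistic.
* **Synthetic benchmark** (`synthetic_bench`) — seeded generator of small
  valid molecules with an exactly additive per-atom surrogate property and a
  binary label partly driven by a planted thiourea-like alert whose atom
  weights are negative but whose label effect is strongly positive, so every
  stage (including attribution) is testable against known ground truth
  without any download.

## CLI

```bash
toxgat synth --kind pretrain --n 2000 --seed 7 --out pretrain.csv --truth truth.json
toxgat synth --kind task --n 250 --seed 7 --out task.csv
toxgat pretrain --data pretrain.csv --out lipo.ckpt --seed 7
toxgat finetune --init lipo.ckpt --data task.csv --out tox.ckpt --seed 7
toxgat evaluate --init lipo.ckpt --data task.csv --splits 10 --test-frac 0.1
toxgat explain --model tox.ckpt --smiles "NC(=S)Nc1ccccc1"
toxgat shapley --model tox.ckpt --smiles "NC(=S)Nc1ccccc1" --atoms 0,1,2,3 --l 4
toxgat alerts --tox tox.ckpt --lipo lipo.ckpt --data task.csv --out alerts.json
```

Data files are delimited text with columns `smiles,value` (regression) or
`smiles,label` (classification).  Substructures are exported as SMARTS.

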