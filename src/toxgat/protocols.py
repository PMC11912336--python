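"""Desk-scale benchmark protocols shared by the acceptance tests and the
acceptance report script.

One run of :func:`run_transfer_protocol` covers, for a single seed:

* pretraining on the synthetic additive surrogate (n=2000 by default),
* repeated stratified 90/10 splits of the task set (n=250) evaluating the
  pretrained-then-fine-tuned model against a scratch-trained twin,
* fine-tuning on the full task set and scoring the planted alert pattern
  under both models (toxicity Shapley vs lipophilicity Shapley).

Hyperparameters are scaled down from the full-size configuration (embedding
32, two convolution layers) so a run takes under a minute on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import alert_pipeline, gat_net, synthetic_bench, train_eval

__all__ = ["TransferRunResult", "run_transfer_protocol", "DESK_MODEL_CONFIG"]

DESK_MODEL_CONFIG = dict(embed_dim=32, n_conv_layers=2, n_global_heads=4)


@dataclass
class TransferRunResult:
    seed: int
    pretrain_val_rmse: float          # original target units
    noise_sd: float
    finetuned_aucs: list[float]
    scratch_aucs: list[float]
    alert_record: alert_pipeline.AlertRecord | None
    lipo_state: gat_net.ModelState = field(repr=False, default=None)
    tox_state: gat_net.ModelState = field(repr=False, default=None)


def run_transfer_protocol(
    seed: int,
    n_pretrain: int = 2000,
    n_task: int = 250,
    n_splits: int = 2,
    pretrain_epochs: int = 40,
    finetune_epochs: int = 30,
    alert_L: int = 3,
    keep_states: bool = False,
) -> TransferRunResult:
    """Full pretrain -> fine-tune -> evaluate -> alert-scoring pipeline."""
    synth_config = synthetic_bench.SyntheticConfig(seed=seed)
    pretrain_set = synthetic_bench.make_pretrain_set(n_pretrain, synth_config)
    task_set = synthetic_bench.make_task_set(n_task, synth_config)

    model_config = gat_net.ModelConfig(**DESK_MODEL_CONFIG)
    pre_cfg = train_eval.TrainConfig(
        seed=seed, max_epochs=pretrain_epochs, batch_size=128, learning_rate=1e-3
    )
    lipo_state, history = train_eval.pretrain(
        pre_cfg, pretrain_set.records, model_config, return_history=True
    )
    best_val = min(h["val_loss"] for h in history)
    val_rmse = float(np.sqrt(best_val) * lipo_state.target_sd)

    def finetuned_builder(train_records, split_seed):
        cfg = train_eval.TrainConfig(
            seed=split_seed, max_epochs=finetune_epochs, batch_size=32
        )
        return train_eval.finetune(lipo_state, train_records, cfg,
                                   learning_rate=5e-4)

    def scratch_builder(train_records, split_seed):
        cfg = train_eval.TrainConfig(
            seed=split_seed, max_epochs=finetune_epochs, batch_size=32,
            learning_rate=1e-3,
        )
        scratch_config = gat_net.ModelConfig(
            head_kind="binary-classification", **DESK_MODEL_CONFIG
        )
        return train_eval.train_scratch(train_records, cfg, scratch_config)

    ft_report = train_eval.repeated_split_eval(
        finetuned_builder, task_set.records, n_splits=n_splits, seed=seed
    )
    scratch_report = train_eval.repeated_split_eval(
        scratch_builder, task_set.records, n_splits=n_splits, seed=seed
    )

    # toxicity model for attribution: fine-tuned on the full task set
    ft_cfg = train_eval.TrainConfig(seed=seed, max_epochs=finetune_epochs,
                                    batch_size=32)
    tox_state = train_eval.finetune(lipo_state, task_set.records, ft_cfg,
                                    learning_rate=5e-4)
    alert_cfg = alert_pipeline.AlertConfig(
        L=alert_L, exact_cap=12, n_permutations=20, seed=seed,
        lipo_value_kind="regression-output",
    )
    record = alert_pipeline.score_pattern(
        task_set.records, tox_state, lipo_state,
        synthetic_bench.THIOUREA_SMARTS, alert_cfg, max_molecules=8,
    )
    return TransferRunResult(
        seed=seed,
        pretrain_val_rmse=val_rmse,
        noise_sd=synth_config.noise_sd,
        finetuned_aucs=list(ft_report.per_split),
        scratch_aucs=list(scratch_report.per_split),
        alert_record=record,
        lipo_state=lipo_state if keep_states else None,
        tox_state=tox_state if keep_states else None,
    )
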