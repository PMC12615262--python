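"""Model/Results facade over the training engine.

``SingleCellProfileModel`` bundles the data (coverage store, cell
embeddings, genome, gene models, splits) with the architecture choices
(geometry, backbone size, LoRA settings); ``fit()`` runs the training
engine and returns a ``ProfileFitResults`` carrying the selected
checkpoint, the training log, validation diagnostics and prediction
helpers, with a ``summary()`` table in the spirit of statsmodels results
objects.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .backbone import ModelGeometry, make_mini_backbone
from .coverage import TargetTransform
from .decoder import ProfileModel
from .layers import LoRAConfig, adapter_parameters, inject_lora, merge_lora
from .training import (LossWeights, TrainingConfig, TrainResult,
                       observed_gene_counts, predicted_gene_counts, train,
                       validation_metric)

__all__ = ["SingleCellProfileModel", "ProfileFitResults",
           "save_checkpoint", "load_checkpoint"]


class SingleCellProfileModel:
    """Sequence-to-single-cell-profile model bound to a dataset.

    Parameters
    ----------
    store : CoverageStore
        Per-cell RNA/ATAC archive providing training targets.
    embeddings : (n_cells, D) array
        Cell-state embeddings, aligned with ``store.cells``.
    genome : dict or SyntheticGenome
        chrom -> sequence mapping (or an object exposing ``sequences``).
    gene_models : dict
        gene_id -> GeneModel, for validation and count evaluation.
    splits : SplitDefinition
        Disjoint train/validation/test windows.
    labels : array of str, optional
        Per-cell cell-type labels (enables the validation metric).
    geometry, channels, n_transformer, hypernet_hidden, lora, seed :
        Architecture settings; ``lora=None`` trains the backbone fully
        instead of adapter-only.
    """

    def __init__(self, store, embeddings, genome, gene_models, splits,
                 labels=None, geometry: ModelGeometry | None = None,
                 channels: int = 32, n_transformer: int = 1,
                 hypernet_hidden: int = 48,
                 lora: LoRAConfig | None = LoRAConfig(),
                 assays: tuple = ("rna", "atac"),
                 transform: TargetTransform | None = None, seed: int = 0):
        self.store = store
        self.embeddings = np.asarray(embeddings, dtype=np.float64)
        if self.embeddings.shape[0] != store.n_cells:
            raise ValueError("embeddings rows must match store cells")
        self.genome = genome
        self.gene_models = gene_models
        self.splits = splits
        self.labels = None if labels is None else np.asarray(labels)
        self.geometry = geometry or ModelGeometry(
            input_length=4096, bin_width=32, output_bins=64,
            embedding_width=32)
        self.transform = transform or TargetTransform()
        self.lora = lora
        self.seed = seed
        backbone = make_mini_backbone(self.geometry, channels=channels,
                                      n_layers=n_transformer, seed=seed)
        if lora is not None:
            inject_lora(backbone, lora, seed=seed + 1)
        self.profile_model = ProfileModel(
            backbone, embedding_dim=self.embeddings.shape[1],
            hypernet_hidden=hypernet_hidden, assays=assays, seed=seed + 2)

    @property
    def sequences(self) -> dict:
        return (self.genome.sequences if hasattr(self.genome, "sequences")
                else self.genome)

    def fit(self, config: TrainingConfig | None = None,
            loss_weights: LossWeights | None = None,
            progress: bool = False) -> "ProfileFitResults":
        from .training import tiny_training_config

        config = config or tiny_training_config(seed=self.seed)
        result = train(self.profile_model, self.store, self.sequences,
                       self.embeddings, self.splits, config,
                       gene_models=self.gene_models, labels=self.labels,
                       loss_weights=loss_weights, transform=self.transform,
                       progress=progress)
        self.profile_model.load_state_dict(result.best_state)
        self.profile_model.bump_weight_version()
        return ProfileFitResults(self, result)


class ProfileFitResults:
    """Fitted-model results: checkpoint, log, diagnostics, predictions."""

    def __init__(self, model: SingleCellProfileModel, result: TrainResult):
        self.model = model
        self.profile_model = model.profile_model
        self.result = result

    @property
    def log(self) -> pd.DataFrame:
        return pd.DataFrame(self.result.log)

    @property
    def best_validation_metric(self) -> float:
        return self.result.best_metric

    def validation_history(self) -> pd.Series:
        df = self.log
        if "validation_metric" not in df.columns:
            return pd.Series(dtype=float)
        return df.set_index("epoch")["validation_metric"]

    def predicted_counts(self, gene_ids, cells=None,
                         rc_average: bool = True) -> pd.DataFrame:
        emb = (self.model.embeddings if cells is None
               else self.model.embeddings[cells])
        return predicted_gene_counts(self.profile_model, self.model.genome,
                                     self.model.gene_models, gene_ids, emb,
                                     self.model.transform,
                                     rc_average=rc_average)

    def observed_counts(self, gene_ids, cells=None) -> pd.DataFrame:
        return observed_gene_counts(self.model.store,
                                    self.model.gene_models, gene_ids,
                                    self.model.geometry, cells=cells)

    def validation_metric(self) -> float:
        return validation_metric(self.profile_model, self.model.store,
                                 self.model.sequences, self.model.splits,
                                 self.model.labels, self.model.gene_models,
                                 self.model.embeddings,
                                 self.model.transform)

    def merged_backbone(self):
        """Fold adapters into the base weights (no inference overhead)."""
        return merge_lora(self.profile_model.backbone)

    def summary(self) -> str:
        m = self.model
        pm = self.profile_model
        n_total = pm.n_parameters()
        n_adapter = sum(p.size for _, p in
                        adapter_parameters(pm.backbone))
        n_trainable = sum(p.size for p in pm.parameters()
                          if p.requires_grad)
        lines = [
            "Single-cell sequence-to-profile model",
            "=" * 54,
            f"input window          {m.geometry.input_length:>10} bp",
            f"bin width             {m.geometry.bin_width:>10} bp",
            f"output bins           {m.geometry.output_bins:>10}",
            f"embedding width       {m.geometry.embedding_width:>10}",
            f"cells                 {m.store.n_cells:>10}",
            f"cell-embedding dim    {m.embeddings.shape[1]:>10}",
            f"parameters (total)    {n_total:>10}",
            f"parameters (adapter)  {n_adapter:>10}",
            f"parameters (trainable){n_trainable:>10}",
            "-" * 54,
        ]
        if self.result.log:
            last = self.result.log[-1]
            lines.append(f"epochs run            {len(self.result.log):>10}")
            lines.append(f"final train loss      {last['train_loss']:>10.4f}")
            if "validation_metric" in last:
                lines.append(
                    f"best validation r     {self.result.best_metric:>10.4f}")
        return "\n".join(lines)


def save_checkpoint(model: SingleCellProfileModel, path: str):
    """Single-file archive: geometry + architecture config + weights."""
    pm = model.profile_model
    meta = {
        "geometry": {
            "input_length": model.geometry.input_length,
            "bin_width": model.geometry.bin_width,
            "output_bins": model.geometry.output_bins,
            "embedding_width": model.geometry.embedding_width,
        },
        "channels": pm.backbone.channels,
        "n_transformer": len(pm.backbone.blocks),
        "embedding_dim": pm.embedding_dim,
        "hypernet_hidden": pm.hypernet_rna.fc1.out_features
        if pm.hypernet_rna else pm.hypernet_atac.fc1.out_features,
        "assays": list(pm.assays),
        "lora_rank": model.lora.rank if model.lora else None,
        "lora_alpha": model.lora.alpha if model.lora else None,
        "lora_kinds": list(model.lora.target_kinds) if model.lora else None,
        "seed": model.seed,
    }
    state = pm.state_dict()
    np.savez(path, __meta__=json.dumps(meta),
             **{k: v for k, v in state.items()})


def load_checkpoint(path: str, store, embeddings, genome, gene_models,
                    splits, labels=None) -> SingleCellProfileModel:
    """Rebuild a model around a dataset from a saved checkpoint."""
    archive = np.load(path, allow_pickle=False)
    meta = json.loads(str(archive["__meta__"]))
    lora = None
    if meta["lora_rank"] is not None:
        lora = LoRAConfig(rank=meta["lora_rank"], alpha=meta["lora_alpha"],
                          target_kinds=tuple(meta["lora_kinds"]))
    model = SingleCellProfileModel(
        store, embeddings, genome, gene_models, splits, labels=labels,
        geometry=ModelGeometry(**meta["geometry"]),
        channels=meta["channels"], n_transformer=meta["n_transformer"],
        hypernet_hidden=meta["hypernet_hidden"], lora=lora,
        assays=tuple(meta["assays"]), seed=meta["seed"])
    state = {k: archive[k] for k in archive.files if k != "__meta__"}
    model.profile_model.load_state_dict(state)
    model.profile_model.bump_weight_version()
    return model
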