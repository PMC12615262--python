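"""Training engine: loss, sampling, optimization, validation selection.

Profiles are trained on the squashed scale with a combined
Poisson + multinomial objective: the Poisson term matches total counts
over the window, the multinomial term the positional distribution
(Poisson weight 0.2, multinomial 1.0 by default).  Only the LoRA
adapters, the hypernetworks and the from-scratch projection layer are
trainable; base backbone weights stay frozen.  Optimization is AdamW
(decoupled weight decay) with two learning-rate groups — 4e-4 for the
hypernetwork decoder, 2e-4 for adapters and the projection layer —
linear warmup then linear decay, gradient-norm clipping at 1.0.

Sequences are augmented by +-3 bp shifts and reverse complementation
(targets position-flipped and RNA strands swapped).  The checkpoint with
the best validation metric — mean across cell types of the Pearson
correlation between log2(pseudobulk + 1) predicted and observed gene
counts — is retained.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .backbone import one_hot
from .coverage import GenomicInterval, TargetTransform, extract_binned
from .decoder import ProfileModel
from .evaluation import exon_bin_indices, get_sequence
from .minigrad import Tensor, concat

__all__ = [
    "TrainingConfig", "LossWeights", "poisson_multinomial_loss",
    "combined_loss", "AdamW", "lr_schedule", "sample_training_batch",
    "train", "validation_metric", "TrainResult", "tiny_training_config",
]


@dataclass
class TrainingConfig:
    """Hyperparameters; defaults are the full-scale recipe."""

    batch_sequences: int = 8
    cells_per_sequence: int = 64
    lr_decoder: float = 4e-4
    lr_adapters: float = 2e-4
    warmup_steps: int = 1000
    epochs: int = 40
    steps_per_epoch: int | None = None   # default: one pass over train windows
    grad_clip: float = 1.0
    weight_decay: float = 1e-6
    shift_max: int = 3
    rc_prob: float = 0.5
    window_jitter_bins: int = 0   # random window displacement, in bins
    average_top_k: int = 1        # weight-average the k best val epochs
    seed: int = 0

    def __post_init__(self):
        for name in ("batch_sequences", "cells_per_sequence", "lr_decoder",
                     "lr_adapters", "warmup_steps", "epochs", "grad_clip"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def tiny_training_config(epochs: int = 40, seed: int = 0) -> TrainingConfig:
    """Desk-scale preset: smaller batches, warmup scaled to the shorter run."""
    return TrainingConfig(batch_sequences=4, cells_per_sequence=32,
                          lr_decoder=4e-3, lr_adapters=2e-3,
                          warmup_steps=40, epochs=epochs, seed=seed)


@dataclass
class LossWeights:
    """Weighting of the loss terms (Poisson on totals vs multinomial on
    the positional distribution) and of the two assays."""

    poisson_weight: float = 0.2
    multinomial_weight: float = 1.0
    rna_weight: float = 1.0
    atac_weight: float = 1.0

    def __post_init__(self):
        if min(self.poisson_weight, self.multinomial_weight,
               self.rna_weight, self.atac_weight) < 0:
            raise ValueError("loss weights must be nonnegative")


def poisson_multinomial_loss(pred: Tensor, target: np.ndarray,
                             weights: LossWeights | None = None) -> Tensor:
    """Mean over tracks of w_p * PoissonNLL(totals) + w_m * MultinomialNLL.

    ``pred`` has positive entries with positions on the last axis; all
    leading axes index tracks (sequence, cell, strand).  The Poisson term
    is ``sum(pred) - sum(target) * log(sum(pred))`` per track (constants
    dropped); the multinomial term is the cross-entropy of the target
    counts against the predicted positional distribution.
    """
    weights = weights or LossWeights()
    if isinstance(pred, np.ndarray):
        pred = Tensor(pred)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    if np.any(pred.data <= 0):
        raise ValueError("loss requires strictly positive predictions")
    total_p = pred.sum(axis=-1)
    total_t = target.sum(axis=-1)
    poisson = total_p - Tensor(total_t) * total_p.log()
    log_density = pred.log() - total_p.log().reshape(*total_p.shape, 1)
    multinomial = -(Tensor(target) * log_density).sum(axis=-1)
    per_track = (weights.poisson_weight * poisson
                 + weights.multinomial_weight * multinomial)
    return per_track.mean()


def combined_loss(preds: dict, targets: dict,
                  weights: LossWeights | None = None) -> Tensor:
    """Assay-weighted mean of the per-assay losses."""
    weights = weights or LossWeights()
    total, denom = None, 0.0
    for assay, w in (("rna", weights.rna_weight),
                     ("atac", weights.atac_weight)):
        if assay not in preds or preds[assay] is None or w == 0:
            continue
        term = poisson_multinomial_loss(preds[assay], targets[assay], weights) * w
        total = term if total is None else total + term
        denom += w
    if total is None:
        raise ValueError("no assay present in predictions")
    return total * (1.0 / denom)


class AdamW:
    """Adam with decoupled weight decay and global gradient-norm clipping."""

    def __init__(self, param_groups, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-6, grad_clip: float | None = 1.0):
        self.groups = []
        for g in param_groups:
            params = [p for p in g["params"] if p.requires_grad]
            self.groups.append({
                "params": params, "lr": g["lr"],
                "m": [np.zeros_like(p.data) for p in params],
                "v": [np.zeros_like(p.data) for p in params],
            })
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.grad_clip = grad_clip
        self.t = 0

    def clip_gradients(self) -> float:
        sq = 0.0
        for g in self.groups:
            for p in g["params"]:
                if p.grad is not None:
                    sq += float((p.grad ** 2).sum())
        norm = np.sqrt(sq)
        if self.grad_clip is not None and norm > self.grad_clip and norm > 0:
            scale = self.grad_clip / norm
            for g in self.groups:
                for p in g["params"]:
                    if p.grad is not None:
                        p.grad *= scale
        return norm

    def step(self, lr_scale: float = 1.0):
        self.t += 1
        norm = self.clip_gradients()
        for g in self.groups:
            lr = g["lr"] * lr_scale
            for p, m, v in zip(g["params"], g["m"], g["v"]):
                if p.grad is None:
                    continue
                m *= self.b1
                m += (1 - self.b1) * p.grad
                v *= self.b2
                v += (1 - self.b2) * p.grad ** 2
                mhat = m / (1 - self.b1 ** self.t)
                vhat = v / (1 - self.b2 ** self.t)
                p.data -= lr * (mhat / (np.sqrt(vhat) + self.eps)
                                + self.weight_decay * p.data)
        return norm

    def zero_grad(self):
        for g in self.groups:
            for p in g["params"]:
                p.grad = None


def lr_schedule(step: int, warmup_steps: int, total_steps: int) -> float:
    """Linear warmup to 1.0 over ``warmup_steps``, then linear decay to 0."""
    if step < warmup_steps:
        return step / warmup_steps
    if total_steps <= warmup_steps:
        return 1.0
    return max(0.0, (total_steps - step) / (total_steps - warmup_steps))


@dataclass
class TrainingBatch:
    onehot: np.ndarray        # (B, 4, L)
    cell_indices: np.ndarray  # (B, n_cells)
    targets: dict             # assay -> (B, n_cells, S, bins), squashed scale
    windows: list
    shifts: list
    rcs: list


def _output_window(window: GenomicInterval, geometry) -> GenomicInterval:
    lead = geometry.crop_bins * geometry.bin_width
    return GenomicInterval(window.chrom, window.start + lead,
                           window.start + lead + geometry.output_length)


def sample_training_batch(store, genome, embeddings: np.ndarray, split,
                          config: TrainingConfig, rng: np.random.Generator,
                          geometry, transform: TargetTransform | None = None,
                          ) -> TrainingBatch:
    """Draw one augmented batch of sequences, cells and squashed targets.

    Cells are sampled without replacement per sequence; on reverse
    complementation the target profiles are position-flipped and the RNA
    strand channels swapped.
    """
    transform = transform or TargetTransform()
    n_cells_total = embeddings.shape[0]
    onehots, cell_idx, windows, shifts, rcs = [], [], [], [], []
    tg = {"rna": [], "atac": []}
    for _ in range(config.batch_sequences):
        while True:
            window = split.train[int(rng.integers(len(split.train)))]
            if config.window_jitter_bins:
                j = geometry.bin_width * int(rng.integers(
                    -config.window_jitter_bins,
                    config.window_jitter_bins + 1))
                size = store.chrom_sizes[window.chrom]
                start = min(max(window.start + j, 0), size - len(window))
                window = GenomicInterval(window.chrom, start,
                                         start + len(window), window.strand)
            if (window.start >= 0 and
                    window.end <= store.chrom_sizes[window.chrom]):
                break
        shift = int(rng.integers(-config.shift_max, config.shift_max + 1))
        rc = bool(rng.random() < config.rc_prob)
        seq = get_sequence(genome, window)
        onehots.append(one_hot(seq, shift=shift, rc=rc).matrix)
        cells = rng.choice(n_cells_total, size=config.cells_per_sequence,
                           replace=False)
        cell_idx.append(cells)
        out_win = _output_window(window, geometry)
        for assay in ("rna", "atac"):
            track = extract_binned(store, out_win, cells=cells,
                                   bin_width=geometry.bin_width, assay=assay)
            vals = transform.forward(track.values, assay)
            if rc:
                vals = vals[:, :, ::-1]
                if assay == "rna":
                    vals = vals[:, ::-1, :]
            tg[assay].append(vals)
        windows.append(window)
        shifts.append(shift)
        rcs.append(rc)
    return TrainingBatch(
        onehot=np.stack(onehots),
        cell_indices=np.stack(cell_idx),
        targets={a: np.stack(v) for a, v in tg.items()},
        windows=windows, shifts=shifts, rcs=rcs)


@dataclass
class TrainResult:
    best_state: dict
    best_metric: float
    log: list = field(default_factory=list)
    config: TrainingConfig | None = None


def trainable_parameter_groups(model: ProfileModel, config: TrainingConfig):
    """Two groups: hypernetworks (decoder lr) vs adapters + projection layer.

    The projection layer is re-enabled after LoRA injection (it is trained
    from scratch); everything else in the backbone stays frozen.
    """
    proj = model.backbone.project
    for p in (proj.weight, proj.bias):
        if p is not None:
            p.requires_grad = True
    decoder_params = []
    for hn in (model.hypernet_rna, model.hypernet_atac):
        if hn is not None:
            decoder_params.extend(hn.parameters())
    adapter_params = [p for name, p in model.backbone.named_parameters()
                      if name.endswith("lora_A") or name.endswith("lora_B")]
    if adapter_params:
        adapter_params += [p for p in (proj.weight, proj.bias)
                           if p is not None]
    else:
        # no adapters injected: the backbone is trained from scratch
        for p in model.backbone.parameters():
            p.requires_grad = True
        adapter_params = list(model.backbone.parameters())
    return [
        {"params": decoder_params, "lr": config.lr_decoder},
        {"params": adapter_params, "lr": config.lr_adapters},
    ]


def train(model: ProfileModel, store, genome, embeddings: np.ndarray, split,
          config: TrainingConfig, *, gene_models: dict | None = None,
          labels: np.ndarray | None = None,
          loss_weights: LossWeights | None = None,
          transform: TargetTransform | None = None,
          log_path: str | None = None,
          progress: bool = False) -> TrainResult:
    """Fit adapters, hypernetworks and the projection layer.

    Checkpoint selection uses the validation metric when gene models and
    cell-type labels are provided, otherwise the (negated) training loss.
    A NaN loss aborts with the offending step's state attached.
    """
    rng = np.random.default_rng(config.seed)
    transform = transform or TargetTransform()
    loss_weights = loss_weights or LossWeights()
    geometry = model.backbone.geometry
    groups = trainable_parameter_groups(model, config)
    opt = AdamW(groups, weight_decay=config.weight_decay,
                grad_clip=config.grad_clip)
    steps_per_epoch = config.steps_per_epoch or max(
        1, len(split.train) // config.batch_sequences)
    total_steps = steps_per_epoch * config.epochs
    # stabilize the very first step: frozen norm statistics, no dropout
    model.backbone.freeze_norm()
    model.backbone.set_dropout_enabled(False)
    model.train()
    # checkpoint pool for top-k weight averaging (k=1: plain best-epoch)
    top_states: list = []  # (metric, epoch, state)
    log: list = []
    step = 0
    epoch_losses: list = []
    for epoch in range(config.epochs):
        epoch_losses = []
        for _ in range(steps_per_epoch):
            batch = sample_training_batch(store, genome, embeddings, split,
                                          config, rng, geometry, transform)
            cells = embeddings[batch.cell_indices.ravel()]
            # forward on all sequences at once; cells differ per sequence,
            # so decode per sequence against its own cell subset
            preds = model.forward_training(batch.onehot, cells)
            B = batch.onehot.shape[0]
            n = config.cells_per_sequence
            loss_terms = {}
            for assay, out in preds.items():
                # out: (B, B*n, S, bins); take each sequence's own cells
                sel = [out[b, b * n:(b + 1) * n] for b in range(B)]
                stacked = concat([s.reshape(1, *s.shape) for s in sel], axis=0)
                loss_terms[assay] = stacked
            loss = combined_loss(loss_terms, batch.targets, loss_weights)
            if not np.isfinite(loss.data):
                dump = {"step": step, "epoch": epoch}
                err = RuntimeError(f"training diverged (NaN loss) at step "
                                   f"{step}")
                err.state = model.state_dict()
                err.info = dump
                raise err
            model.zero_grad()
            loss.backward()
            scale = lr_schedule(step, config.warmup_steps, total_steps)
            norm = opt.step(lr_scale=scale)
            model.bump_weight_version()
            epoch_losses.append(float(loss.data))
            if step == 0:
                model.backbone.unfreeze_norm()
                model.backbone.set_dropout_enabled(True)
            step += 1
        entry = {"epoch": epoch, "step": step,
                 "train_loss": float(np.mean(epoch_losses)),
                 "lr_scale": lr_schedule(step, config.warmup_steps,
                                         total_steps)}
        if gene_models is not None and labels is not None:
            metric = validation_metric(model, store, genome, split, labels,
                                       gene_models, embeddings, transform)
            entry["validation_metric"] = metric
        else:
            metric = -entry["train_loss"]
        top_states.append((metric, epoch, model.state_dict()))
        top_states.sort(key=lambda t: (-t[0], t[1]))
        del top_states[max(config.average_top_k, 1):]
        log.append(entry)
        if progress:
            print(f"epoch {epoch}: " + " ".join(
                f"{k}={v:.4g}" for k, v in entry.items() if k != "epoch"))
        if log_path:
            import json
            with open(log_path, "a") as fh:
                fh.write(json.dumps(entry) + "\n")
    model.eval()
    # average the retained checkpoints (stochastic weight averaging over
    # the best validation epochs); k=1 reduces to the single best epoch
    best_metric = top_states[0][0]
    best_state = {
        key: np.mean([s[key] for _, _, s in top_states], axis=0)
        for key in top_states[0][2]
    }
    return TrainResult(best_state=best_state, best_metric=best_metric,
                       log=log, config=config)


def _genes_in_windows(gene_models: dict, windows) -> list:
    out = []
    for gid in sorted(gene_models):
        g = gene_models[gid]
        if any(g.body.overlaps(w) for w in windows):
            out.append(gid)
    return out


def observed_gene_counts(store, gene_models: dict, gene_ids, geometry,
                         cells=None) -> pd.DataFrame:
    """Observed per-cell exon-bin coverage sums, matching the prediction
    convention (strand-matched track, full bins on >=1 bp overlap)."""
    cols = {}
    for gid in gene_ids:
        g = gene_models[gid]
        win = g.body.resize(geometry.output_length,
                            store.chrom_sizes[g.chrom])
        track = extract_binned(store, win, cells=cells,
                               bin_width=geometry.bin_width, assay="rna")
        bins, _ = exon_bin_indices(g, win, geometry.bin_width)
        ch = 0 if g.strand == "+" else 1
        cols[gid] = track.values[:, ch, :][:, bins].sum(axis=1)
    names = list(store.cells) if cells is None else [
        store.cells[i] if not isinstance(i, str) else i for i in cells]
    return pd.DataFrame(cols, index=names)


def predicted_gene_counts(model: ProfileModel, genome, gene_models: dict,
                          gene_ids, embeddings: np.ndarray,
                          transform: TargetTransform | None = None,
                          rc_average: bool = False) -> pd.DataFrame:
    """Predicted per-cell natural-scale exon counts, window centered on the
    gene body."""
    from .evaluation import gene_counts as _gene_counts
    from .evaluation import predict_rc_averaged

    transform = transform or TargetTransform()
    geometry = model.backbone.geometry
    chrom_sizes = (genome.chrom_sizes if hasattr(genome, "chrom_sizes")
                   else {c: len(s) for c, s in genome.items()})
    seqs = genome.sequences if hasattr(genome, "sequences") else genome
    cols = {}
    for gid in gene_ids:
        g = gene_models[gid]
        win = g.body.resize(geometry.input_length, chrom_sizes[g.chrom])
        if rc_average:
            pred = predict_rc_averaged(model, win, embeddings, seqs,
                                       transform, seq_key=gid)
        else:
            seq = get_sequence(seqs, win)
            raw = model.cached_predict(one_hot(seq), embeddings, seq_key=gid)
            pred = type(raw)(rna=transform.inverse(raw.rna, "rna"),
                             atac=(transform.inverse(raw.atac, "atac")
                                   if raw.atac is not None else None),
                             transformed=False)
        out_win = _output_window(win, geometry)
        cols[gid] = _gene_counts(pred, g, geometry, out_win)
    return pd.DataFrame(cols)


def validation_metric(model: ProfileModel, store, genome, split,
                      labels: np.ndarray, gene_models: dict,
                      embeddings: np.ndarray,
                      transform: TargetTransform | None = None) -> float:
    """Mean across cell types of Pearson(log2(pseudobulk pred + 1),
    log2(pseudobulk obs + 1)) over validation genes."""
    gene_ids = _genes_in_windows(gene_models, split.validation)
    if not gene_ids:
        raise ValueError("no gene overlaps the validation regions")
    geometry = model.backbone.geometry
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        obs = observed_gene_counts(store, gene_models, gene_ids, geometry)
        pred = predicted_gene_counts(model, genome, gene_models, gene_ids,
                                     embeddings, transform)
    labels = np.asarray(labels)
    vals = []
    for ct in np.unique(labels):
        sel = labels == ct
        po = np.log2(pred.values[sel].sum(axis=0) + 1)
        oo = np.log2(obs.values[sel].sum(axis=0) + 1)
        if np.std(po) == 0 or np.std(oo) == 0:
            warnings.warn(f"validation_metric: zero variance for cell type "
                          f"{ct!r}; skipped")
            continue
        vals.append(float(np.corrcoef(po, oo)[0, 1]))
    return float(np.mean(vals)) if vals else np.nan
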