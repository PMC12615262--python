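"""Desk-scale presets: the tiny fixture plus a matched model and recipe.

``fit_tiny_model`` wires the synthetic multiome fixture to a mini
backbone and runs the full training pipeline at a scale that completes in
minutes on one CPU.  Both the test suite and the reproduction script use
this entry point, so the configuration lives in exactly one place.

The backbone's first convolutional layer is seeded with the fixture's PWM
set plus the splice-site and core-promoter elements — standing in for the
motif vocabulary that a pretrained sequence encoder brings along — while
everything downstream (which motifs matter, for which gene, in which cell
state, at what magnitude) is learned from the reads.
"""

from __future__ import annotations

import numpy as np

from .backbone import ModelGeometry, make_mini_backbone
from .decoder import ProfileModel
from .motifs import PWM
from .simulate import (ACCEPTOR_SITE, DONOR_SITE, TATA_BOX, TinyDataset,
                       make_splits, make_tiny_dataset)
from .training import LossWeights, TrainingConfig, train

__all__ = ["TINY_GEOMETRY", "tiny_fixture", "build_tiny_model",
           "tiny_run_config", "fit_tiny_model"]

TINY_GEOMETRY = ModelGeometry(input_length=4096, bin_width=32,
                              output_bins=64, embedding_width=32)


def _element_pwm(consensus: str, name: str,
                 consensus_prob: float = 0.94) -> PWM:
    m = np.full((len(consensus), 4), (1 - consensus_prob) / 3)
    for i, b in enumerate(consensus):
        m[i, "ACGT".index(b)] = consensus_prob
    return PWM(name, m)


def tiny_fixture(seed: int = 0) -> TinyDataset:
    """The tiny study conditions: 24 contigs x 12 genes, 240 cells,
    3 groups; the last four contigs are held out (2 validation, 2 test).

    The 240 training genes are what makes the shared motif->expression
    rule cheaper for the model to learn than per-window memorization.
    """
    ds = make_tiny_dataset(seed=seed, n_contigs=24, contig_length=32_768,
                           genes_per_contig=12,
                           input_length=TINY_GEOMETRY.input_length)
    ds.splits = make_splits(ds.genome, TINY_GEOMETRY.input_length,
                            n_val_contigs=2, n_test_contigs=2)
    return ds


def build_tiny_model(ds: TinyDataset, seed: int = 0,
                     channels: int = 24) -> ProfileModel:
    pwm_init = list(ds.pwms.values()) + [
        _element_pwm(DONOR_SITE, "donor"),
        _element_pwm(ACCEPTOR_SITE, "acceptor"),
        _element_pwm(TATA_BOX, "tata"),
    ]
    backbone = make_mini_backbone(TINY_GEOMETRY, channels=channels,
                                  n_layers=1, seed=seed + 7,
                                  pwm_init=pwm_init)
    return ProfileModel(backbone, embedding_dim=14, hypernet_hidden=48,
                        seed=seed + 9)


def tiny_run_config(seed: int = 0, epochs: int = 240) -> TrainingConfig:
    return TrainingConfig(batch_sequences=4, cells_per_sequence=64,
                          lr_decoder=5e-3, lr_adapters=5e-3,
                          warmup_steps=100, epochs=epochs,
                          steps_per_epoch=16, average_top_k=5,
                          seed=seed + 10)


def tiny_loss_weights() -> LossWeights:
    # totals and positions weighted equally at this scale: with hundreds
    # (not millions) of training windows the count-level signal needs the
    # same pressure as the positional term
    return LossWeights(poisson_weight=1.0, multinomial_weight=1.0)


def fit_tiny_model(seed: int = 0, epochs: int = 240, progress: bool = False):
    """Generate the fixture, train the mini model, return everything.

    Returns (dataset, model, train_result); the model carries the
    best-validation checkpoint.
    """
    ds = tiny_fixture(seed)
    model = build_tiny_model(ds, seed=seed)
    cfg = tiny_run_config(seed=seed, epochs=epochs)
    result = train(model, ds.store, ds.genome.sequences,
                   ds.population.embeddings, ds.splits, cfg,
                   gene_models=ds.genome.genes,
                   labels=ds.population.labels,
                   loss_weights=tiny_loss_weights(), progress=progress)
    model.load_state_dict(result.best_state)
    model.eval()
    model.bump_weight_version()
    return ds, model, result
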