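"""Model interpretation: motif effects, variant effects, deconvolution.

TF motif effect scoring mutates all matched binding sites of a factor in
silico (random replacement, several replicates) and measures the mean
log2 fold change of the predicted readout, mutated versus reference,
per cell — negative values therefore indicate activators, positive
repressors.  Variant (eQTL) effect prediction substitutes a single
nucleotide, centers the model window on the variant and reports per-group
log2 fold changes of exon-summed expression (pseudocount 1) and of
locus-wide accessibility.  Cell-type deconvolution ranks cell types by
predicted |effect| and is benchmarked against expression- and
accessibility-based baselines.  Gradient-weighted PWMs visualize the
sequence features driving a readout around a position.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .backbone import one_hot
from .coverage import GenomicInterval, TargetTransform
from .decoder import CellProfilePrediction, ProfileModel
from .evaluation import (exon_bin_indices, gene_counts, get_sequence,
                         locus_accessibility, predict_rc_averaged)
from .minigrad import Tensor
from .motifs import MutationConfig, mutate_hits, scan_pwm
from .training import _output_window

__all__ = [
    "read_variants", "differential_expression", "tf_motif_effect",
    "target_gene_effects", "variant_effect", "variant_effect_table",
    "classify_negligible", "rank_cell_types", "rank_by_expression",
    "rank_by_accessibility", "precision_at_k", "select_variable_eqtls",
    "sign_concordance_by_distance", "gradient_pwm", "cluster_effects",
]


# --------------------------------------------------------------------------
# inputs
# --------------------------------------------------------------------------

_VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "gene"]


def read_variants(path: str) -> pd.DataFrame:
    """Read a VCF-like TSV of single-nucleotide variants.

    Required columns: chrom, pos (1-based), ref, alt, gene; optional
    columns (observed effect, PIP, fine-mapping flags, TSS distance) are
    passed through.  Non-single-nucleotide rows are dropped with a
    warning, mirroring the fine-mapped-eQTL filtering convention.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table lacks columns {missing}")
    snv = (df.ref.str.len() == 1) & (df.alt.str.len() == 1)
    if not snv.all():
        warnings.warn(f"dropping {(~snv).sum()} non-SNV rows")
        df = df[snv].reset_index(drop=True)
    return df


def differential_expression(counts: pd.DataFrame, labels,
                            alpha: float = 0.05) -> pd.DataFrame:
    """Wilcoxon rank-sum one-vs-rest with Benjamini-Hochberg correction.

    ``counts``: cells x genes (natural scale); returns a table of
    (group, gene, log2_fold_change, p_value, q_value, significant).
    Routine selection statistics — pipelines may equally take externally
    supplied gene lists.
    """
    from scipy.stats import ranksums
    from statsmodels.stats.multitest import multipletests

    labels = np.asarray(labels)
    rows = []
    X = np.log2(counts.values + 1.0)
    for group in np.unique(labels):
        sel = labels == group
        for j, gene in enumerate(counts.columns):
            a, b = X[sel, j], X[~sel, j]
            if np.all(a == a[0]) and np.all(b == a[0]):
                stat, p = 0.0, 1.0
            else:
                stat, p = ranksums(a, b)
            rows.append({"group": group, "gene": gene,
                         "log2_fold_change": float(a.mean() - b.mean()),
                         "p_value": float(p)})
    df = pd.DataFrame(rows)
    df["q_value"] = multipletests(df.p_value, method="fdr_bh")[1]
    df["significant"] = df.q_value <= alpha
    return df


# --------------------------------------------------------------------------
# TF motif effect scoring
# --------------------------------------------------------------------------

def _natural(pred, transform: TargetTransform) -> CellProfilePrediction:
    return CellProfilePrediction(
        rna=transform.inverse(pred.rna, "rna") if pred.rna is not None else None,
        atac=(transform.inverse(pred.atac, "atac")
              if pred.atac is not None else None),
        transformed=False)


def _readout(pred: CellProfilePrediction, modality: str, gene, geometry,
             out_win) -> np.ndarray:
    if modality == "expression":
        return gene_counts(pred, gene, geometry, out_win)
    if modality == "accessibility":
        return locus_accessibility(pred)
    raise ValueError("modality must be 'expression' or 'accessibility'")


def tf_motif_effect(model: ProfileModel, genome, gene_models: dict,
                    gene_ids, pwm, cell_vectors: np.ndarray,
                    modality: str = "expression",
                    config: MutationConfig | None = None,
                    transform: TargetTransform | None = None,
                    rc_average: bool = True):
    """Per-cell motif mutation effect score for one TF.

    For every gene window (centered on the gene body) all PWM hits are
    replaced with random sequence, ``n_replicates`` times; replicate
    predictions are averaged.  Each cell's readout is divided by its
    reference size factor (the cell's total reference readout over the
    window) and rescaled by the median size factor across cells.  The
    score per cell is the mean over genes of log2(mutated / reference) —
    negative for activators.

    Returns (scores, per_gene) where ``scores`` is (n_cells,) and
    ``per_gene`` a genes x cells DataFrame of per-gene log2 fold changes
    (zero, with a warning, for genes without hits).
    """
    config = config or MutationConfig()
    transform = transform or TargetTransform()
    geometry = model.backbone.geometry
    rng = np.random.default_rng(config.seed)
    chrom_sizes = (genome.chrom_sizes if hasattr(genome, "chrom_sizes")
                   else {c: len(s) for c, s in genome.items()})
    seqs = genome.sequences if hasattr(genome, "sequences") else genome
    n_cells = cell_vectors.shape[0]
    per_gene = {}
    for gid in gene_ids:
        gene = gene_models[gid]
        win = gene.body.resize(geometry.input_length, chrom_sizes[gene.chrom])
        out_win = _output_window(win, geometry)
        seq = get_sequence(seqs, win)
        hits = scan_pwm(seq, pwm, threshold=config.p_value_threshold)
        ref_pred = _predict(model, win, seq, cell_vectors, transform,
                            rc_average, seq_key=("ref", gid))
        ref = _readout(ref_pred, modality, gene, geometry, out_win)
        size = (ref_pred.rna.sum(axis=(1, 2)) if modality == "expression"
                else ref_pred.atac.sum(axis=(1, 2)))
        if not hits:
            warnings.warn(f"gene {gid}: no {pwm.name} hit in window; "
                          f"effect 0")
            per_gene[gid] = np.zeros(n_cells)
            continue
        alts = mutate_hits(seq, hits, config, rng)
        alt_readout = np.zeros(n_cells)
        for k, alt_seq in enumerate(alts):
            alt_pred = _predict(model, win, alt_seq, cell_vectors, transform,
                                rc_average, seq_key=None)
            alt_readout += _readout(alt_pred, modality, gene, geometry,
                                    out_win)
        alt_readout /= len(alts)
        sf = size / np.median(size)
        ref_n = ref / sf
        alt_n = alt_readout / sf
        per_gene[gid] = np.log2(alt_n / ref_n)
    per_gene_df = pd.DataFrame(per_gene).T
    scores = per_gene_df.values.mean(axis=0)
    return scores, per_gene_df


def _predict(model, win, seq, cell_vectors, transform, rc_average, seq_key):
    if rc_average:
        fwd = model.cached_predict(one_hot(seq), cell_vectors,
                                   seq_key=seq_key)
        rev = model.cached_predict(one_hot(seq, rc=True), cell_vectors,
                                   seq_key=seq_key)
        rna = atac = None
        if fwd.rna is not None:
            rna = 0.5 * (fwd.rna + rev.rna[:, ::-1, ::-1])
        if fwd.atac is not None:
            atac = 0.5 * (fwd.atac + rev.atac[:, :, ::-1])
        pred = CellProfilePrediction(rna=rna, atac=atac, transformed=True)
    else:
        pred = model.cached_predict(one_hot(seq), cell_vectors,
                                    seq_key=seq_key)
    return _natural(pred, transform)


def target_gene_effects(per_gene_effects: pd.DataFrame | pd.Series,
                        threshold: float = 0.1) -> pd.DataFrame:
    """Putative target genes: |effect| above threshold, with direction.

    ``per_gene_effects``: per-gene effect sizes (a Series, or a genes x
    cells/cell-types frame that is averaged over its columns for the
    designated population).
    """
    if isinstance(per_gene_effects, pd.DataFrame):
        eff = per_gene_effects.mean(axis=1)
    else:
        eff = per_gene_effects
    keep = eff[eff.abs() > threshold]
    return pd.DataFrame({
        "effect": keep,
        "direction": np.where(keep < 0, "repressed_by_mutation",
                              "enhanced_by_mutation"),
    })


# --------------------------------------------------------------------------
# variant effects
# --------------------------------------------------------------------------

def variant_effect(model: ProfileModel, genome, variant, gene_models: dict,
                   cell_groups: dict, cell_vectors: np.ndarray,
                   transform: TargetTransform | None = None,
                   pseudocount: float = 1.0) -> pd.Series:
    """Per-cell-group log2 fold change (alt vs ref) for one variant.

    The model window is centered on the variant; reference and alternative
    predictions are reverse-complement averaged and inverted to the
    natural scale.  Expression effects are exon-summed counts of the
    target gene summed over each group's cells; accessibility effects sum
    the ATAC track over the whole window.  The overall effect is the mean
    over groups.
    """
    transform = transform or TargetTransform()
    geometry = model.backbone.geometry
    chrom_sizes = (genome.chrom_sizes if hasattr(genome, "chrom_sizes")
                   else {c: len(s) for c, s in genome.items()})
    seqs = genome.sequences if hasattr(genome, "sequences") else genome
    chrom = variant["chrom"]
    pos0 = int(variant["pos"]) - 1
    ref, alt = variant["ref"], variant["alt"]
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("only single-nucleotide variants are supported")
    gene = gene_models[variant["gene"]]
    center = GenomicInterval(chrom, pos0, pos0 + 1)
    win = center.resize(geometry.input_length, chrom_sizes[chrom])
    seq = get_sequence(seqs, win)
    offset = pos0 - win.start
    if seq[offset].upper() != ref.upper():
        raise ValueError(
            f"reference mismatch at {chrom}:{pos0 + 1}: genome has "
            f"{seq[offset]!r}, variant table says {ref!r}")
    alt_seq = seq[:offset] + alt + seq[offset + 1:]
    out_win = _output_window(win, geometry)
    preds = {}
    for name, s in (("ref", seq), ("alt", alt_seq)):
        preds[name] = _predict(model, win, s, cell_vectors, transform,
                               rc_average=True, seq_key=None)
    expr = {n: gene_counts(p, gene, geometry, out_win)
            for n, p in preds.items()}
    acc = {n: locus_accessibility(p) for n, p in preds.items()}
    out = {}
    for gname, idx in cell_groups.items():
        idx = np.asarray(idx)
        out[f"expression:{gname}"] = float(np.log2(
            (expr["alt"][idx].sum() + pseudocount)
            / (expr["ref"][idx].sum() + pseudocount)))
        out[f"accessibility:{gname}"] = float(np.log2(
            (acc["alt"][idx].sum() + pseudocount)
            / (acc["ref"][idx].sum() + pseudocount)))
    expr_vals = [v for k, v in out.items() if k.startswith("expression:")]
    acc_vals = [v for k, v in out.items() if k.startswith("accessibility:")]
    out["expression:mean"] = float(np.mean(expr_vals))
    out["accessibility:mean"] = float(np.mean(acc_vals))
    return pd.Series(out, name=f"{chrom}:{variant['pos']}{ref}>{alt}")


def variant_effect_table(model: ProfileModel, genome,
                         variants: pd.DataFrame, gene_models: dict,
                         cell_groups: dict, cell_vectors: np.ndarray,
                         transform: TargetTransform | None = None,
                         modality: str = "expression") -> pd.DataFrame:
    """Variants x cell-groups effect table (one modality)."""
    rows = {}
    for i, var in variants.iterrows():
        s = variant_effect(model, genome, var, gene_models, cell_groups,
                           cell_vectors, transform)
        rows[s.name] = {k.split(":", 1)[1]: v for k, v in s.items()
                        if k.startswith(modality + ":")
                        and not k.endswith(":mean")}
    return pd.DataFrame(rows).T


def classify_negligible(effects, tau: float = 0.05):
    """Mask of negligible predictions: |log2 effect| < tau (boundary
    excluded).  Returns (mask, percent_fold_change) where the percentage
    is the equivalent fold change, (2**tau - 1) * 100 (3.5% at tau=0.05).
    """
    effects = np.asarray(effects, dtype=np.float64)
    pct = round(float((2.0 ** tau - 1.0) * 100.0), 1)
    return np.abs(effects) < tau, pct


# --------------------------------------------------------------------------
# cell-type deconvolution
# --------------------------------------------------------------------------

def _ranked(series: pd.Series) -> list:
    df = pd.DataFrame({"v": series})
    df["name"] = df.index.astype(str)
    df = df.sort_values(["v", "name"], ascending=[False, True])
    return list(df.index)


def rank_cell_types(effect_row: pd.Series) -> list:
    """Cell types in descending order of |predicted effect|; deterministic
    lexicographic tie-break."""
    return _ranked(effect_row.abs())


def rank_by_expression(pseudobulk_expression: pd.Series) -> list:
    """Baseline: rank cell types by pseudobulk expression of the eGene."""
    return _ranked(pseudobulk_expression)


def rank_by_accessibility(peaks: pd.DataFrame, variant,
                          cell_type_columns=None) -> list | None:
    """Baseline: rank by accessibility of the variant's overlapping or
    nearest peak.

    ``peaks``: columns chrom, start, end plus one (size-factor-normalized)
    accessibility column per cell type. Returns None, with a warning, when
    no peak lies on the variant's chromosome.
    """
    chrom = variant["chrom"]
    pos0 = int(variant["pos"]) - 1
    sub = peaks[peaks.chrom == chrom]
    if sub.empty:
        warnings.warn(f"no peak on chromosome {chrom!r}; variant skipped")
        return None
    inside = sub[(sub.start <= pos0) & (pos0 < sub.end)]
    if not inside.empty:
        row = inside.iloc[0]
    else:
        dist = np.minimum(np.abs(sub.start - pos0), np.abs(sub.end - 1 - pos0))
        row = sub.loc[dist.idxmin()]
    cols = cell_type_columns or [c for c in peaks.columns
                                 if c not in ("chrom", "start", "end")]
    return _ranked(row[cols])


def precision_at_k(ranking: list, positives, k: int = 1) -> float:
    top = ranking[:k]
    return sum(1 for ct in top if ct in set(positives)) / float(k)


def select_variable_eqtls(effects: pd.DataFrame,
                          mean_threshold: float = 0.05,
                          variance_quantile: float = 0.85) -> pd.DataFrame:
    """Two-stage filter for cell-type-specific eQTLs.

    Keeps variants whose mean |log2 effect| across cell types exceeds
    ``mean_threshold``, then of those the top (1 - quantile) fraction by
    across-cell-type variance (top 15% by default).
    """
    mean_ok = effects.abs().mean(axis=1) > mean_threshold
    sub = effects[mean_ok]
    if sub.empty:
        return sub
    var = sub.var(axis=1, ddof=0)
    cut = var.quantile(variance_quantile)
    return sub[var > cut] if (var > cut).any() else sub[var >= cut]


def sign_concordance_by_distance(pred_effects, observed_signs,
                                 tss_distances, bins,
                                 tau: float = 0.05) -> pd.DataFrame:
    """Fraction of sign-concordant predictions per TSS-distance bin.

    Computed both over all variants and after discarding negligible
    predictions (|effect| < tau). Empty bins yield NaN with count 0.
    """
    pred = np.asarray(pred_effects, dtype=np.float64)
    obs = np.sign(np.asarray(observed_signs, dtype=np.float64))
    dist = np.asarray(tss_distances, dtype=np.float64)
    edges = np.asarray(bins, dtype=np.float64)
    which = np.digitize(dist, edges) - 1
    neg_mask, _ = classify_negligible(pred, tau)
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        row = {"bin_lo": edges[b], "bin_hi": edges[b + 1],
               "n_all": int(sel.sum()),
               "n_filtered": int((sel & ~neg_mask).sum())}
        row["concordance_all"] = (
            float((np.sign(pred[sel]) == obs[sel]).mean())
            if sel.any() else np.nan)
        fsel = sel & ~neg_mask
        row["concordance_filtered"] = (
            float((np.sign(pred[fsel]) == obs[fsel]).mean())
            if fsel.any() else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def cluster_effects(effects: pd.DataFrame, metric: str = "seuclidean",
                    method: str = "ward", n_clusters: int | None = None):
    """Thin utility: hierarchical clustering of an effect table.

    Returns (linkage_matrix, row_order[, cluster_labels]); plotting is the
    caller's concern (the linkage feeds directly into seaborn.clustermap).
    """
    from scipy.cluster.hierarchy import dendrogram, fcluster, linkage
    from scipy.spatial.distance import pdist

    d = pdist(effects.values, metric=metric)
    z = linkage(d, method=method)
    order = dendrogram(z, no_plot=True)["leaves"]
    if n_clusters is not None:
        labels = fcluster(z, criterion="maxclust", t=n_clusters)
        return z, order, labels
    return z, order


# --------------------------------------------------------------------------
# gradient attribution
# --------------------------------------------------------------------------

def gradient_pwm(model: ProfileModel, sequence: str, center: int,
                 cell_vectors: np.ndarray, gene=None, window: int = 10,
                 assay: str = "rna"):
    """Gradient-weighted PWM over ``window`` positions centered on
    ``center``.

    The readout is the predicted (transformed-scale) coverage summed over
    the chosen cells — restricted to the gene's exon bins and strand when
    a gene model is given, the whole window otherwise.  Per position the
    nucleotide weights are 2**gradient, sum-normalized.
    """
    from .motifs import PWM

    geometry = model.backbone.geometry
    if len(sequence) != geometry.input_length:
        raise ValueError("sequence must match the model input length")
    half = window // 2
    if center - half < 0 or center + window - half > len(sequence):
        raise ValueError("attribution window exceeds the sequence")
    oh = one_hot(sequence)
    x = Tensor(oh.matrix[None], requires_grad=True)
    was_training = model.training
    model.eval()
    try:
        emb = model.backbone(x)  # (1, bins, E)
        hn = model.hypernet_rna if assay == "rna" else model.hypernet_atac
        par = hn(Tensor(np.asarray(cell_vectors, dtype=np.float64)))
        E = geometry.embedding_width
        w, b = par[:, :E, :], par[:, E:, :]
        pre = emb.reshape(1, 1, emb.shape[1], emb.shape[2]) @ w + b
        out = pre.softplus()  # (1, N, bins, S)
        if gene is not None:
            lead = geometry.crop_bins * geometry.bin_width
            # exon bins relative to a window starting at coordinate 0 of
            # this sequence: caller passes gene coords relative to sequence
            win = GenomicInterval("seq", lead, lead + geometry.output_length)
            bins, _ = exon_bin_indices(gene, win, geometry.bin_width)
            ch = 0 if gene.strand == "+" else 1
            readout = out[:, :, bins, ch].sum()
        else:
            readout = out.sum()
        readout.backward()
    finally:
        model.train(was_training)
    grad = x.grad[0]  # (4, L)
    sub = grad[:, center - half:center - half + window].T  # (window, 4)
    weights = 2.0 ** sub
    weights = weights / weights.sum(axis=1, keepdims=True)
    return PWM(f"grad@{center}", weights)
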