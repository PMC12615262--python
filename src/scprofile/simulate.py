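"""Self-contained synthetic multiome generator with known ground truth.

Emulates the structure of 10x multiome data at desk scale: a random
genome with compact multi-exon genes, transcription-factor motifs planted
in promoters, a multi-group cell population with group-informative
embeddings, RNA reads sampled along mature transcripts (split across exon
junctions, optional 3' positional bias), ATAC fragments concentrated at
accessible promoters, and single-nucleotide variants that destroy planted
motifs (plus matched null variants in neutral sequence).

Every stage records its generative truth (planted instances, per-group
rates, expected count matrix, variant effect signs), which downstream
tests use as the acceptance surface.  Generation is bit-reproducible per
seed.

Default scales (the tiny preset): 6 contigs of 65,536 bp with 8 genes
each, 3 cell groups, 240 cells, 14-dimensional embeddings.  Planted
activator motifs multiply a gene's expression rate by 3 (ubiquitous
motif) or by 6 in the responsive group only (group-specific motif) —
effect sizes in the range of strong marker genes; promoter accessibility
scales analogously (x2 / x4).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage import GenomicInterval, ReadRecord
from .evaluation import GeneModel
from .motifs import PWM

__all__ = [
    "SyntheticGenome", "SyntheticTruth", "SyntheticCellPopulation",
    "PlantedMotif", "default_pwms", "make_genome", "plant_motifs",
    "make_population", "simulate_reads", "make_variants", "make_splits",
    "make_tiny_dataset", "TinyDataset",
]

_BASES = "ACGT"

# fixed, mutually distinct consensus 8-mers for the toy motif set
_CONSENSI = ["GATAACGC", "CCGGTATG", "TGCATCGA", "ACGTGGTC", "GTTACCAG",
             "CAGTGTCA"]

# tiny-preset generative rates
BASE_EXPRESSION = 2.0        # reads / cell / gene without any motif
BASE_ACCESSIBILITY = 1.0     # fragments / cell / promoter
UBIQ_EXPR_MULT = 3.0
GROUP_EXPR_MULT = 6.0
UBIQ_ACC_MULT = 2.0
GROUP_ACC_MULT = 4.0
READ_LENGTH = 80
PROMOTER_LENGTH = 180

# sequence signatures marking gene structure, emulating the signals real
# models learn exon placement from (splice sites, exonic GC elevation,
# core promoter elements)
EXON_GC = 0.58
DONOR_SITE = "GTAAGT"        # written at intron starts (sense strand)
ACCEPTOR_SITE = "TTTCAG"     # written at intron ends (sense strand)
TATA_BOX = "TATAAAAG"        # written 28 bp upstream of the TSS


def default_pwms(n_groups: int = 3, consensus_prob: float = 0.94) -> dict:
    """Toy PWM set: one ubiquitous activator plus one per cell group."""
    names = ["UBIQ"] + [f"GRP{g}" for g in range(n_groups)]
    out = {}
    for name, cons in zip(names, _CONSENSI):
        m = np.full((len(cons), 4), (1.0 - consensus_prob) / 3.0)
        for i, b in enumerate(cons):
            m[i, _BASES.index(b)] = consensus_prob
        out[name] = PWM(name, m)
    return out


@dataclass
class SyntheticGenome:
    sequences: dict                  # contig -> str
    genes: dict                      # gene_id -> GeneModel
    seed: int

    @property
    def chrom_sizes(self) -> dict:
        return {c: len(s) for c, s in self.sequences.items()}

    def write_fasta(self, path: str):
        with open(path, "w") as fh:
            for chrom in sorted(self.sequences):
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")

    def write_gtf(self, path: str):
        with open(path, "w") as fh:
            for gid in sorted(self.genes):
                g = self.genes[gid]
                body = g.body
                attrs = (f'gene_id "{gid}"; gene_name "{gid}"; '
                         f'transcript_id "{gid}.t1";')
                fh.write(f"{g.chrom}\tsynthetic\tgene\t{body.start + 1}\t"
                         f"{body.end}\t.\t{g.strand}\t.\t{attrs}\n")
                fh.write(f"{g.chrom}\tsynthetic\ttranscript\t{body.start + 1}"
                         f"\t{body.end}\t.\t{g.strand}\t.\t{attrs}\n")
                for ex in g.exons:
                    fh.write(f"{g.chrom}\tsynthetic\texon\t{ex.start + 1}\t"
                             f"{ex.end}\t.\t{g.strand}\t.\t{attrs}\n")


@dataclass
class PlantedMotif:
    pwm_name: str
    interval: GenomicInterval
    gene_id: str
    responsive_groups: tuple         # () means "all groups"
    sign: int = 1                    # +1 activator, -1 repressor
    expr_multiplier: float = 1.0
    acc_multiplier: float = 1.0

    def affects(self, group: int) -> bool:
        return not self.responsive_groups or group in self.responsive_groups


@dataclass
class SyntheticTruth:
    """Generative ground truth for every pipeline stage."""

    motifs: list                     # PlantedMotif
    promoters: dict                  # gene_id -> GenomicInterval
    base_expression: float
    base_accessibility: float
    n_groups: int
    seed: int
    variants: pd.DataFrame | None = None

    def __post_init__(self):
        for m in self.motifs:
            if m.expr_multiplier <= 0 or m.acc_multiplier <= 0:
                raise ValueError("effect multipliers must be > 0")

    def gene_motifs(self, gene_id: str) -> list:
        return [m for m in self.motifs if m.gene_id == gene_id]

    def _unique_gene_elements(self, gene_id: str) -> list:
        """One representative per (gene, motif type): a regulatory element
        may be planted as several copies but its effect applies once."""
        seen, out = set(), []
        for m in self.gene_motifs(gene_id):
            if m.pwm_name not in seen:
                seen.add(m.pwm_name)
                out.append(m)
        return out

    def expression_rate(self, gene_id: str, group: int) -> float:
        rate = self.base_expression
        for m in self._unique_gene_elements(gene_id):
            if m.affects(group):
                rate *= m.expr_multiplier ** m.sign
        return rate

    def accessibility_rate(self, gene_id: str, group: int) -> float:
        rate = self.base_accessibility
        for m in self._unique_gene_elements(gene_id):
            if m.affects(group):
                rate *= m.acc_multiplier ** m.sign
        return rate

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "n_groups": self.n_groups,
            "base_expression": self.base_expression,
            "base_accessibility": self.base_accessibility,
            "motifs": [
                {"pwm": m.pwm_name, "chrom": m.interval.chrom,
                 "start": m.interval.start, "end": m.interval.end,
                 "gene": m.gene_id, "groups": list(m.responsive_groups),
                 "sign": m.sign, "expr_multiplier": m.expr_multiplier,
                 "acc_multiplier": m.acc_multiplier}
                for m in self.motifs],
            "promoters": {g: [iv.chrom, iv.start, iv.end]
                          for g, iv in self.promoters.items()},
        }
        return json.dumps(payload, indent=2)


@dataclass
class SyntheticCellPopulation:
    barcodes: list
    group_labels: np.ndarray         # (n_cells,) int
    embeddings: np.ndarray           # (n_cells, D)
    depth_factors: np.ndarray        # (n_cells,) log-normal
    group_names: list = field(default_factory=list)

    def __post_init__(self):
        if not self.group_names:
            self.group_names = [f"group{g}" for g in
                                range(int(self.group_labels.max()) + 1)]

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def labels(self) -> np.ndarray:
        return np.array([self.group_names[g] for g in self.group_labels])

    def separation_margin(self) -> float:
        """Smallest centroid-gap margin of the embeddings (> 0 means the
        groups are linearly separable by nearest-centroid)."""
        groups = np.unique(self.group_labels)
        cents = np.stack([self.embeddings[self.group_labels == g].mean(axis=0)
                          for g in groups])
        d_own = np.linalg.norm(
            self.embeddings - cents[self.group_labels], axis=1)
        margin = np.inf
        for i, g in enumerate(groups):
            others = [j for j in range(len(groups)) if j != i]
            d_other = np.min(np.linalg.norm(
                self.embeddings[self.group_labels == g][:, None, :]
                - cents[others][None], axis=2), axis=1)
            margin = min(margin,
                         float((d_other - d_own[self.group_labels == g]).min()))
        return margin


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[i] for i in rng.choice(4, size=length, p=p))


_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _write_gene_signature(seq: list, gene: GeneModel,
                          rng: np.random.Generator):
    """Imprint learnable gene structure onto the contig sequence.

    Exons are redrawn GC-rich, intron boundaries receive splice-site
    consensus (strand-aware), and a TATA-like element marks the core
    promoter — the sequence features a profile model uses to place
    coverage, which pure random sequence lacks.
    """
    for ex in gene.exons:
        seq[ex.start:ex.end] = list(
            _random_sequence(rng, len(ex), EXON_GC))
    for left, right in zip(gene.exons[:-1], gene.exons[1:]):
        i_start, i_end = left.end, right.start  # the intron between them
        if gene.strand == "+":
            seq[i_start:i_start + len(DONOR_SITE)] = list(DONOR_SITE)
            seq[i_end - len(ACCEPTOR_SITE):i_end] = list(ACCEPTOR_SITE)
        else:
            seq[i_end - len(DONOR_SITE):i_end] = list(_revcomp(DONOR_SITE))
            seq[i_start:i_start + len(ACCEPTOR_SITE)] = list(
                _revcomp(ACCEPTOR_SITE))
    if gene.strand == "+":
        t0 = gene.body.start - 28 - len(TATA_BOX)
        seq[t0:t0 + len(TATA_BOX)] = list(TATA_BOX)
    else:
        t0 = gene.body.end + 28
        seq[t0:t0 + len(TATA_BOX)] = list(_revcomp(TATA_BOX))


def make_genome(n_contigs: int = 6, length: int = 65_536, gc: float = 0.41,
                seed: int = 0, genes_per_contig: int = 8,
                out_dir: str | None = None) -> SyntheticGenome:
    """Random contigs with compact toy genes (2-4 exons, both strands).

    Gene bodies are short (roughly 0.5-1 kb) so that a desk-scale model
    window centered on a gene or on a promoter variant covers the exons.
    """
    rng = np.random.default_rng(seed)
    sequences = {}
    genes: dict = {}
    for c in range(n_contigs):
        chrom = f"contig{c}"
        seq = list(_random_sequence(rng, length, gc))
        for j in range(genes_per_contig):
            anchor = (j + 1) * length // (genes_per_contig + 1)
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 5))
            exon_lens = rng.integers(120, 181, size=n_exons)
            intron_lens = rng.integers(70, 111, size=n_exons - 1)
            gid = f"gene_c{c}_{j}"
            pos = anchor
            exons = []
            for k in range(n_exons):
                exons.append(GenomicInterval(chrom, pos,
                                             pos + int(exon_lens[k]), strand))
                pos += int(exon_lens[k])
                if k < n_exons - 1:
                    pos += int(intron_lens[k])
            gene = GeneModel(gene_id=gid, chrom=chrom, strand=strand,
                             exons=exons, name=gid)
            genes[gid] = gene
            _write_gene_signature(seq, gene, rng)
        sequences[chrom] = "".join(seq)
    genome = SyntheticGenome(sequences=sequences, genes=genes, seed=seed)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        genome.write_fasta(os.path.join(out_dir, "genome.fa"))
        genome.write_gtf(os.path.join(out_dir, "genes.gtf"))
    return genome


def _promoter(gene: GeneModel) -> GenomicInterval:
    if gene.strand == "+":
        start = gene.body.start - PROMOTER_LENGTH
        return GenomicInterval(gene.chrom, start, gene.body.start)
    return GenomicInterval(gene.chrom, gene.body.end,
                           gene.body.end + PROMOTER_LENGTH)


def plant_motifs(genome: SyntheticGenome, pwms: dict | None = None,
                 n_groups: int = 3, seed: int = 0,
                 p_ubiquitous: float = 0.5,
                 p_group_specific: float = 0.75) -> SyntheticTruth:
    """Write consensus motif sites into promoters; record the truth table.

    Each gene receives the ubiquitous activator with probability
    ``p_ubiquitous`` and one group-specific activator (group uniform) with
    probability ``p_group_specific``.  A chosen element is planted as
    several copies — a promoter-proximal slot plus one slot per intron —
    mimicking the repeated occurrences of a factor's sites around a
    regulated gene and keeping every exon within local sequence reach of
    at least one copy.  The effect multiplier applies once per element
    (not per copy).  Sequences are edited in place; planted copies never
    overlap each other or the splice/promoter signature elements.
    """
    rng = np.random.default_rng(seed)
    pwms = pwms or default_pwms(n_groups)
    motifs: list = []
    promoters: dict = {}
    seqs = {c: list(s) for c, s in genome.sequences.items()}
    for gid in sorted(genome.genes):
        gene = genome.genes[gid]
        prom = _promoter(gene)
        promoters[gid] = prom
        # two promoter-proximal slots upstream of the TSS (clear of the
        # TATA element at -28) and two slots inside each intron (clear of
        # the 6-bp splice sites; introns are >= 70 bp)
        if gene.strand == "+":
            prom_slots = [gene.body.start - 73, gene.body.start - 90]
        else:
            prom_slots = [gene.body.end + 65, gene.body.end + 82]
        introns = [(left.end, right.start) for left, right in
                   zip(gene.exons[:-1], gene.exons[1:])]
        chosen = []
        if rng.random() < p_ubiquitous:
            chosen.append(("UBIQ", (), UBIQ_EXPR_MULT, UBIQ_ACC_MULT))
        if rng.random() < p_group_specific:
            g = int(rng.integers(n_groups))
            chosen.append((f"GRP{g}", (g,), GROUP_EXPR_MULT, GROUP_ACC_MULT))
        for k, (name, groups, em, am) in enumerate(chosen):
            slots = [prom_slots[k]]
            for i_start, i_end in introns:
                slots.append(i_start + 8 if k == 0 else i_end - 16)
            for slot in slots:
                cons = pwms[name].consensus
                iv = GenomicInterval(prom.chrom, slot, slot + len(cons))
                seqs[prom.chrom][slot:slot + len(cons)] = list(cons)
                motifs.append(PlantedMotif(pwm_name=name, interval=iv,
                                           gene_id=gid,
                                           responsive_groups=tuple(groups),
                                           sign=1, expr_multiplier=em,
                                           acc_multiplier=am))
    genome.sequences = {c: "".join(s) for c, s in seqs.items()}
    return SyntheticTruth(motifs=motifs, promoters=promoters,
                          base_expression=BASE_EXPRESSION,
                          base_accessibility=BASE_ACCESSIBILITY,
                          n_groups=n_groups, seed=seed)


def make_population(n_cells: int = 240, n_groups: int = 3, dim: int = 14,
                    seed: int = 0,
                    depth_sigma: float = 0.3) -> SyntheticCellPopulation:
    """Cell population with group-informative embeddings.

    The first ``n_groups`` embedding dimensions carry 2x the group one-hot
    plus mild noise, the remainder pure noise, so groups are linearly
    separable with a margin while the space stays mostly unstructured —
    loosely emulating a low-dimensional multiomic latent space.
    """
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(n_groups), int(np.ceil(n_cells / n_groups)))
    labels = labels[:n_cells]
    emb = rng.normal(0.0, 0.5, size=(n_cells, dim))
    emb[:, :n_groups] = rng.normal(0.0, 0.3, size=(n_cells, n_groups))
    emb[np.arange(n_cells), labels] += 2.0
    depth = np.exp(rng.normal(0.0, depth_sigma, size=n_cells))
    barcodes = [f"CELL{i:04d}" for i in range(n_cells)]
    return SyntheticCellPopulation(barcodes=barcodes, group_labels=labels,
                                   embeddings=emb, depth_factors=depth)


def _genomic_segments(gene: GeneModel, t_start: int, t_len: int) -> tuple:
    """Map a transcript-coordinate interval to genomic (start, length) segments."""
    # exon order follows transcription direction
    exons = gene.exons if gene.strand == "+" else list(reversed(gene.exons))
    segments = []
    offset = 0
    for ex in exons:
        ex_len = len(ex)
        lo = max(t_start, offset)
        hi = min(t_start + t_len, offset + ex_len)
        if lo < hi:
            if gene.strand == "+":
                g0 = ex.start + (lo - offset)
                segments.append((g0, hi - lo))
            else:
                g_end = ex.end - (lo - offset)
                segments.append((g_end - (hi - lo), hi - lo))
        offset += ex_len
    return tuple(sorted(segments))


def simulate_reads(truth: SyntheticTruth, genome: SyntheticGenome,
                   population: SyntheticCellPopulation, depth: float = 1.0,
                   seed: int = 0, split_read_fraction: float = 0.5,
                   three_prime_bias: float = 0.0,
                   background_fragments: float = 0.3):
    """Sample RNA reads and ATAC fragments from the generative truth.

    RNA reads per (cell, gene) are Poisson with rate
    ``base x group multipliers x depth factor x depth``; a
    ``split_read_fraction`` of reads is placed in transcript coordinates
    (splitting across junctions), the rest within single exons.
    ``three_prime_bias`` > 0 weights read starts toward the 3' end with an
    exponential profile. ATAC fragments concentrate at promoters with
    group-modulated rates plus uniform background.

    Returns (rna_records, atac_records, expected_counts) where
    ``expected_counts`` is the exact generative rate matrix
    (cells x genes, reads per cell).
    """
    rng = np.random.default_rng(seed)
    gene_ids = sorted(genome.genes)
    n_cells = population.n_cells
    expected = np.zeros((n_cells, len(gene_ids)))
    rna: list = []
    atac: list = []
    for gj, gid in enumerate(gene_ids):
        gene = genome.genes[gid]
        t_len = gene.transcript_length
        max_start = max(t_len - READ_LENGTH, 0)
        if three_prime_bias > 0 and max_start > 0:
            w = np.exp(three_prime_bias *
                       np.arange(max_start + 1) / max(max_start, 1))
            w = w / w.sum()
        else:
            w = None
        rate_by_group = np.array([truth.expression_rate(gid, g)
                                  for g in range(truth.n_groups)])
        acc_by_group = np.array([truth.accessibility_rate(gid, g)
                                 for g in range(truth.n_groups)])
        prom = truth.promoters[gid]
        for ci in range(n_cells):
            g = population.group_labels[ci]
            lam = rate_by_group[g] * population.depth_factors[ci] * depth
            expected[ci, gj] = lam
            n_reads = rng.poisson(lam)
            for r in range(n_reads):
                rlen = min(READ_LENGTH, t_len)
                if rng.random() < split_read_fraction:
                    t0 = (int(rng.choice(max_start + 1, p=w)) if w is not None
                          else int(rng.integers(0, max_start + 1)))
                    segs = _genomic_segments(gene, t0, rlen)
                else:
                    ex = gene.exons[rng.integers(len(gene.exons))]
                    elen = min(rlen, len(ex))
                    s0 = ex.start + int(rng.integers(0, len(ex) - elen + 1))
                    segs = ((s0, elen),)
                rna.append(ReadRecord(
                    barcode=population.barcodes[ci], chrom=gene.chrom,
                    segments=segs, assay="rna", strand=gene.strand,
                    umi=f"{gid}:{ci}:{r}"))
            lam_acc = acc_by_group[g] * population.depth_factors[ci] * depth
            for _ in range(rng.poisson(lam_acc)):
                center = int(rng.normal(prom.center, 50))
                flen = int(rng.integers(60, 141))
                start = max(center - flen // 2, 0)
                size = genome.chrom_sizes[prom.chrom]
                start = min(start, size - flen - 1)
                atac.append(ReadRecord(
                    barcode=population.barcodes[ci], chrom=prom.chrom,
                    segments=((start, flen),), assay="atac"))
    # uniform background fragments
    for chrom, size in genome.chrom_sizes.items():
        for ci in range(n_cells):
            lam = background_fragments * depth
            for _ in range(rng.poisson(lam)):
                flen = int(rng.integers(60, 141))
                start = int(rng.integers(0, size - flen))
                atac.append(ReadRecord(barcode=population.barcodes[ci],
                                       chrom=chrom, segments=((start, flen),),
                                       assay="atac"))
    expected_df = pd.DataFrame(expected, index=population.barcodes,
                               columns=gene_ids)
    return rna, atac, expected_df


def make_variants(truth: SyntheticTruth, genome: SyntheticGenome,
                  pwms: dict | None = None, n_null: int = 12,
                  seed: int = 0) -> pd.DataFrame:
    """Variant table: motif-destroying substitutions plus matched nulls.

    For each group-specific planted site, the consensus base with the
    largest log-odds drop is substituted by the PWM's least likely base at
    that position (maximally score-reducing). Null variants are placed in
    neutral intergenic sequence >= 100 bp from any planted site, with the
    nearest gene as target and expected sign 0.
    """
    rng = np.random.default_rng(seed)
    pwms = pwms or default_pwms(truth.n_groups)
    rows = []
    # one variant per (gene, group-specific element); when an element is
    # planted as several copies, target the first intronic copy
    chosen: dict = {}
    for m in truth.motifs:
        if not m.responsive_groups:
            continue
        key = (m.gene_id, m.pwm_name)
        gene = genome.genes[m.gene_id]
        intronic = gene.body.start <= m.interval.start < gene.body.end
        if key not in chosen or (intronic and not chosen[key][1]):
            chosen[key] = (m, intronic)
    for m, _ in chosen.values():
        pwm = pwms[m.pwm_name]
        lo = pwm.log_odds
        cons_idx = pwm.matrix.argmax(axis=1)
        worst_idx = pwm.matrix.argmin(axis=1)
        drops = lo[np.arange(len(pwm)), cons_idx] - lo[np.arange(len(pwm)),
                                                       worst_idx]
        j = int(drops.argmax())
        pos = m.interval.start + j
        ref = genome.sequences[m.interval.chrom][pos]
        alt = _BASES[int(worst_idx[j])]
        if alt == ref:  # consensus not planted? fall back to any other base
            alt = next(b for b in _BASES if b != ref)
        rows.append({"chrom": m.interval.chrom, "pos": pos + 1, "ref": ref,
                     "alt": alt, "gene": m.gene_id, "kind": "planted",
                     "pwm": m.pwm_name,
                     "responsive_group": m.responsive_groups[0],
                     "expected_sign": -m.sign})
    planted_pos = [(m.interval.chrom, m.interval.start, m.interval.end)
                   for m in truth.motifs]
    gene_list = sorted(genome.genes)
    occupied = []
    for gid in gene_list:
        g = genome.genes[gid]
        occupied.append((g.chrom, g.body.start - PROMOTER_LENGTH - 50,
                         g.body.end + PROMOTER_LENGTH + 50))
    n_placed = 0
    attempts = 0
    chroms = sorted(genome.sequences)
    while n_placed < n_null and attempts < 10_000:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(200, genome.chrom_sizes[chrom] - 200))
        if any(c == chrom and s - 100 <= pos < e + 100
               for c, s, e in planted_pos):
            continue
        if any(c == chrom and s <= pos < e for c, s, e in occupied):
            continue
        near = min((g for g in gene_list if genome.genes[g].chrom == chrom),
                   key=lambda g: abs(genome.genes[g].body.center - pos))
        ref = genome.sequences[chrom][pos]
        alt = _BASES[int(rng.choice([i for i in range(4)
                                     if _BASES[i] != ref]))]
        rows.append({"chrom": chrom, "pos": pos + 1, "ref": ref, "alt": alt,
                     "gene": near, "kind": "null", "pwm": "",
                     "responsive_group": -1, "expected_sign": 0})
        n_placed += 1
    df = pd.DataFrame(rows)
    truth.variants = df
    return df


@dataclass
class SplitDefinition:
    """Disjoint train/validation/test genomic windows."""

    train: list
    validation: list
    test: list

    def __post_init__(self):
        all_sets = [("train", self.train), ("validation", self.validation),
                    ("test", self.test)]
        for i in range(len(all_sets)):
            for j in range(i + 1, len(all_sets)):
                for iv1 in all_sets[i][1]:
                    for iv2 in all_sets[j][1]:
                        if iv1.overlaps(iv2):
                            raise ValueError(
                                f"{all_sets[i][0]} and {all_sets[j][0]} "
                                f"regions overlap: {iv1} / {iv2}")


def make_splits(genome: SyntheticGenome, input_length: int,
                n_val_contigs: int = 1, n_test_contigs: int = 1) -> SplitDefinition:
    """Contig-level split: windows centered on gene bodies, the last
    contigs held out for validation and test (leakage-free by contig)."""
    contigs = sorted(genome.sequences)
    test_c = set(contigs[-n_test_contigs:])
    val_c = set(contigs[-(n_test_contigs + n_val_contigs):-n_test_contigs])
    train, val, test = [], [], []
    for gid in sorted(genome.genes):
        g = genome.genes[gid]
        win = g.body.resize(input_length, genome.chrom_sizes[g.chrom])
        if g.chrom in test_c:
            test.append(win)
        elif g.chrom in val_c:
            val.append(win)
        else:
            train.append(win)
    return SplitDefinition(train=train, validation=val, test=test)


@dataclass
class TinyDataset:
    """Everything the full pipeline needs, generated from one seed."""

    genome: SyntheticGenome
    truth: SyntheticTruth
    population: SyntheticCellPopulation
    pwms: dict
    store: "object"
    expected_counts: pd.DataFrame
    variants: pd.DataFrame
    splits: SplitDefinition


def make_tiny_dataset(seed: int = 0, input_length: int = 4096,
                      n_contigs: int = 6, contig_length: int = 65_536,
                      genes_per_contig: int = 8, n_cells: int = 240,
                      n_groups: int = 3,
                      three_prime_bias: float = 0.0) -> TinyDataset:
    """One-call tiny fixture: genome, truth, reads, store, variants, splits."""
    from .coverage import build_store, fragments_to_insertions

    ss = np.random.SeedSequence(seed)
    s_genome, s_plant, s_pop, s_reads, s_var = [
        int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(5)]
    genome = make_genome(n_contigs=n_contigs, length=contig_length,
                         genes_per_contig=genes_per_contig, seed=s_genome)
    pwms = default_pwms(n_groups)
    truth = plant_motifs(genome, pwms, n_groups=n_groups, seed=s_plant)
    population = make_population(n_cells=n_cells, n_groups=n_groups,
                                 seed=s_pop)
    rna, atac, expected = simulate_reads(truth, genome, population,
                                         seed=s_reads,
                                         three_prime_bias=three_prime_bias)
    insertions = fragments_to_insertions(atac)
    store = build_store(rna_records=rna, atac_insertions=insertions,
                        whitelist=population.barcodes,
                        chrom_sizes=genome.chrom_sizes,
                        genome_id=f"synthetic-{seed}")
    variants = make_variants(truth, genome, pwms, seed=s_var)
    splits = make_splits(genome, input_length)
    return TinyDataset(genome=genome, truth=truth, population=population,
                       pwms=pwms, store=store, expected_counts=expected,
                       variants=variants, splits=splits)
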