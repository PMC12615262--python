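"""Per-cell read-coverage archive and model-ready binned target tracks.

Single-cell alignments (RNA BAM, split reads stored as one entry per
aligned segment) and ATAC fragment files are converted into a compact
per-chromosome archive of (cell, start, length) segments — stranded for
RNA — and (cell, position) Tn5 insertion events for ATAC (two per
fragment, at the first and last covered base).  The archive supports
ranged extraction of 32-bp-binned per-cell tracks, the squashed-scale
target transform, pseudobulk bigWig export, and the leakage/prevalence
feature filter used before cell-embedding construction.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomicInterval", "ReadRecord", "InsertionRecord", "CoverageStore",
    "TargetTransform", "BinnedTrack", "parse_alignments",
    "read_fragment_file", "fragments_to_insertions", "build_store",
    "extract_binned", "apply_transform", "invert_transform",
    "export_pseudobulk_bigwig", "filter_leaky_features",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self):
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom and self.start < other.end
                and other.start < self.end)

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def resize(self, length: int, chrom_size: int | None = None) -> "GenomicInterval":
        """Center-expand/shrink to `length`, optionally clamped to the chromosome."""
        start = self.center - length // 2
        if chrom_size is not None:
            start = min(max(start, 0), max(chrom_size - length, 0))
        return GenomicInterval(self.chrom, start, start + length, self.strand)


@dataclass
class ReadRecord:
    """One deduplicated sequencing record.

    RNA records may carry several (start, length) segments (split reads);
    ATAC records carry exactly one segment — the fragment.
    """

    barcode: str
    chrom: str
    segments: tuple
    assay: str  # "rna" | "atac"
    strand: str = "."
    umi: str | None = None

    def __post_init__(self):
        if self.assay not in ("rna", "atac"):
            raise ValueError("assay must be 'rna' or 'atac'")
        if self.assay == "atac" and len(self.segments) != 1:
            raise ValueError("ATAC records carry exactly one segment")
        prev_end = -1
        for start, length in self.segments:
            if length < 1:
                raise ValueError("segment length must be >= 1")
            if start < prev_end:
                raise ValueError("segments must be sorted and non-overlapping")
            prev_end = start + length

    @property
    def total_bases(self) -> int:
        return sum(length for _, length in self.segments)


@dataclass(frozen=True)
class InsertionRecord:
    """A single Tn5 transposition event."""

    barcode: str
    chrom: str
    pos: int


@dataclass
class TargetTransform:
    """Squashed-scale transform for training targets.

    Coverage values are power-compressed (``v ** squash_exponent``) and then
    soft-clipped above ``clip_soft``: ``v -> clip_soft + sqrt(v - clip_soft)``.
    ATAC values are pre-multiplied by ``atac_scale`` (0.05) so both assays
    share a scale; inversion rescales by 1/atac_scale (= 20 at defaults).
    """

    clip_soft: float = 5.0
    atac_scale: float = 0.05
    squash_exponent: float = 0.75

    def forward(self, values: np.ndarray, assay: str) -> np.ndarray:
        v = np.asarray(values, dtype=np.float64)
        if np.any(v < 0):
            raise ValueError("squash transform requires nonnegative input")
        if assay == "atac":
            v = v * self.atac_scale
        v = v ** self.squash_exponent
        over = v > self.clip_soft
        v = np.where(over, self.clip_soft + np.sqrt(
            np.maximum(v - self.clip_soft, 0.0)), v)
        return v

    def inverse(self, values: np.ndarray, assay: str,
                unscale: bool = True) -> np.ndarray:
        v = np.asarray(values, dtype=np.float64)
        over = v > self.clip_soft
        v = np.where(over, self.clip_soft + (v - self.clip_soft) ** 2, v)
        v = np.maximum(v, 0.0) ** (1.0 / self.squash_exponent)
        if assay == "atac" and unscale:
            v = v / self.atac_scale
        return v


@dataclass
class BinnedTrack:
    """Per-cell binned coverage over an interval.

    values: (n_cells, n_strands, n_bins); RNA has two strand channels
    (plus, minus), ATAC one.
    """

    interval: GenomicInterval
    bin_width: int
    values: np.ndarray
    assay: str
    cells: list
    transformed: bool = False

    @property
    def n_bins(self) -> int:
        return self.values.shape[-1]


# --------------------------------------------------------------------------
# parsing
# --------------------------------------------------------------------------

def _segments_from_cigar(aln) -> tuple:
    """Aligned reference segments of a pysam-style record.

    Match/mismatch and deletion operations extend the current segment;
    reference skips (introns, CIGAR N) split it; soft clips and insertions
    are dropped.
    """
    cig = aln.cigartuples
    if cig is None:
        raise ValueError(f"malformed CIGAR for record {aln.query_name!r}")
    segments = []
    pos = aln.reference_start
    cur_start, cur_len = pos, 0
    for op, length in cig:
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference
            cur_len += length
            pos += length
        elif op == 3:  # N: splice gap
            if cur_len > 0:
                segments.append((cur_start, cur_len))
            pos += length
            cur_start, cur_len = pos, 0
        elif op in (1, 4, 5, 6):  # I, S, H, P: no reference advance
            continue
        else:
            raise ValueError(
                f"malformed CIGAR op {op} in record {aln.query_name!r}")
    if cur_len > 0:
        segments.append((cur_start, cur_len))
    if not segments:
        raise ValueError(f"record {aln.query_name!r} has no aligned segment")
    return tuple(segments)


def parse_alignments(alignment_stream, assay: str, barcode_tag: str = "CB",
                     umi_tag: str = "UB",
                     require_valid_flag: bool = False) -> list:
    """Convert a stream of alignment records into deduplicated ReadRecords.

    ``alignment_stream`` is an iterable of pysam ``AlignedSegment``-like
    objects (e.g. a ``pysam.AlignmentFile``).  RNA split alignments yield
    one record with one segment per aligned block.  When
    ``require_valid_flag`` is set, only reads carrying the pipeline
    validity tag ``xf:i:25`` are kept.  Duplicates collapse by
    (barcode, umi, chrom, first-segment start) for RNA — falling back to
    (barcode, chrom, segments) when no UMI is present — and by
    (barcode, chrom, segment) for ATAC.
    """
    if assay not in ("rna", "atac"):
        raise ValueError("assay must be 'rna' or 'atac'")
    records: dict = {}
    n_missing_barcode = 0
    for aln in alignment_stream:
        if getattr(aln, "is_unmapped", False):
            continue
        if assay == "atac" and getattr(aln, "is_paired", False):
            # keep only the leftmost mate of a proper pair; the fragment
            # spans from its start over the template length
            if not getattr(aln, "is_proper_pair", False):
                continue
            if aln.template_length <= 0:
                continue
        if getattr(aln, "is_secondary", False) or getattr(
                aln, "is_supplementary", False):
            continue
        if require_valid_flag:
            if not aln.has_tag("xf") or aln.get_tag("xf") != 25:
                continue
        if not aln.has_tag(barcode_tag):
            n_missing_barcode += 1
            continue
        barcode = aln.get_tag(barcode_tag)
        umi = aln.get_tag(umi_tag) if (umi_tag and aln.has_tag(umi_tag)) else None
        chrom = aln.reference_name
        if assay == "atac":
            if getattr(aln, "is_paired", False):
                start = aln.reference_start
                segments = ((start, abs(aln.template_length)),)
            else:
                segs = _segments_from_cigar(aln)
                start = segs[0][0]
                end = segs[-1][0] + segs[-1][1]
                segments = ((start, end - start),)
            key = (barcode, chrom, segments[0])
            rec = ReadRecord(barcode=barcode, chrom=chrom, segments=segments,
                             assay="atac")
        else:
            segments = _segments_from_cigar(aln)
            strand = "-" if getattr(aln, "is_reverse", False) else "+"
            if umi is not None:
                key = (barcode, umi, chrom, segments[0][0])
            else:
                key = (barcode, chrom, segments)
            rec = ReadRecord(barcode=barcode, chrom=chrom, segments=segments,
                             assay="rna", strand=strand, umi=umi)
        records.setdefault(key, rec)
    if n_missing_barcode:
        warnings.warn(
            f"parse_alignments: skipped {n_missing_barcode} records with "
            f"missing {barcode_tag} tag")
    return list(records.values())


def read_fragment_file(path: str) -> list:
    """Read a (possibly gzip/bgzip-compressed) BED-like fragment TSV.

    Columns: chrom, start, end, barcode[, count]. Returns ATAC ReadRecords
    (already-deduplicated fragment files yield one record per line).
    """
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    out = []
    with opener(path, "rt") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end, barcode = parts[0], int(parts[1]), int(parts[2]), parts[3]
            out.append(ReadRecord(barcode=barcode, chrom=chrom,
                                  segments=((start, end - start),),
                                  assay="atac"))
    return out


def fragments_to_insertions(records) -> list:
    """Each ATAC fragment yields two insertions: at its start and at its
    last covered base (end - 1). A length-1 fragment yields two events at
    the same position."""
    out = []
    for rec in records:
        if rec.assay != "atac":
            raise ValueError("fragments_to_insertions expects ATAC records")
        start, length = rec.segments[0]
        out.append(InsertionRecord(rec.barcode, rec.chrom, start))
        out.append(InsertionRecord(rec.barcode, rec.chrom, start + length - 1))
    return out


# --------------------------------------------------------------------------
# the store
# --------------------------------------------------------------------------

class CoverageStore:
    """Compact per-cell archive of RNA segments and ATAC insertions.

    RNA segments are stored per chromosome and strand as parallel arrays
    (cell index, start, length) sorted by start; ATAC insertions as
    (cell index, position) sorted by position.  Extraction results are
    independent of input record order.
    """

    def __init__(self, cells, chrom_sizes: dict, genome_id: str = ""):
        self.cells = list(cells)
        self.cell_index = {c: i for i, c in enumerate(self.cells)}
        self.chrom_sizes = dict(chrom_sizes)
        self.genome_id = genome_id
        # chrom -> strand -> dict(cell=…, start=…, length=…)
        self.rna: dict = {}
        # chrom -> dict(cell=…, pos=…)
        self.atac: dict = {}

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def rna_totals(self) -> np.ndarray:
        """Total aligned bases per cell."""
        tot = np.zeros(self.n_cells)
        for chrom in self.rna:
            for strand in self.rna[chrom]:
                d = self.rna[chrom][strand]
                np.add.at(tot, d["cell"], d["length"])
        return tot

    def atac_totals(self) -> np.ndarray:
        """Number of insertion events per cell."""
        tot = np.zeros(self.n_cells)
        for chrom in self.atac:
            np.add.at(tot, self.atac[chrom]["cell"], 1)
        return tot

    # -- persistence (HDF5, h5ad-style obs/uns naming) ------------------------
    def save(self, path: str):
        import h5py

        with h5py.File(path, "w") as f:
            obs = f.create_group("obs")
            obs.create_dataset("barcodes",
                               data=np.array(self.cells, dtype="S"))
            uns = f.create_group("uns")
            uns.attrs["genome_id"] = self.genome_id
            cs = uns.create_group("chrom_sizes")
            for chrom, size in self.chrom_sizes.items():
                cs.attrs[chrom] = int(size)
            rna = f.create_group("rna")
            for chrom, strands in self.rna.items():
                for strand, d in strands.items():
                    g = rna.create_group(f"{chrom}/{'plus' if strand == '+' else 'minus'}")
                    for k, v in d.items():
                        g.create_dataset(k, data=v)
            atac = f.create_group("atac")
            for chrom, d in self.atac.items():
                g = atac.create_group(chrom)
                for k, v in d.items():
                    g.create_dataset(k, data=v)

    @classmethod
    def load(cls, path: str) -> "CoverageStore":
        import h5py

        with h5py.File(path, "r") as f:
            cells = [b.decode() for b in f["obs/barcodes"][:]]
            chrom_sizes = {k: int(v) for k, v in
                           f["uns/chrom_sizes"].attrs.items()}
            store = cls(cells, chrom_sizes,
                        genome_id=f["uns"].attrs.get("genome_id", ""))
            for chrom in f["rna"]:
                store.rna[chrom] = {}
                for sname in f[f"rna/{chrom}"]:
                    strand = "+" if sname == "plus" else "-"
                    g = f[f"rna/{chrom}/{sname}"]
                    store.rna[chrom][strand] = {k: g[k][:] for k in g}
            for chrom in f["atac"]:
                g = f[f"atac/{chrom}"]
                store.atac[chrom] = {k: g[k][:] for k in g}
        return store


def build_store(rna_records=None, atac_insertions=None, whitelist=None,
                chrom_sizes: dict | None = None,
                genome_id: str = "") -> CoverageStore:
    """Assemble a CoverageStore from ReadRecords and InsertionRecords.

    Only whitelisted barcodes are retained; per-cell totals are preserved
    for retained cells. Unknown chromosomes raise; an empty result warns
    but yields a valid empty store.
    """
    if whitelist is None or len(whitelist) == 0:
        raise ValueError("whitelist must be non-empty")
    if chrom_sizes is None:
        raise ValueError("chrom_sizes is required")
    store = CoverageStore(whitelist, chrom_sizes, genome_id=genome_id)
    by_key: dict = {}
    n_kept = 0
    for rec in (rna_records or []):
        if rec.assay != "rna":
            raise ValueError("rna_records must contain RNA ReadRecords")
        if rec.chrom not in chrom_sizes:
            raise ValueError(f"unknown chromosome {rec.chrom!r}")
        ci = store.cell_index.get(rec.barcode)
        if ci is None:
            continue
        n_kept += 1
        strand = rec.strand if rec.strand in ("+", "-") else "+"
        key = (rec.chrom, strand)
        lst = by_key.setdefault(key, ([], [], []))
        for start, length in rec.segments:
            lst[0].append(ci)
            lst[1].append(start)
            lst[2].append(length)
    for (chrom, strand), (ci, st, ln) in by_key.items():
        st = np.asarray(st, dtype=np.int64)
        order = np.argsort(st, kind="stable")
        store.rna.setdefault(chrom, {})[strand] = {
            "cell": np.asarray(ci, dtype=np.int64)[order],
            "start": st[order],
            "length": np.asarray(ln, dtype=np.int64)[order],
        }
    by_chrom: dict = {}
    for ins in (atac_insertions or []):
        if ins.chrom not in chrom_sizes:
            raise ValueError(f"unknown chromosome {ins.chrom!r}")
        ci = store.cell_index.get(ins.barcode)
        if ci is None:
            continue
        n_kept += 1
        lst = by_chrom.setdefault(ins.chrom, ([], []))
        lst[0].append(ci)
        lst[1].append(ins.pos)
    for chrom, (ci, pos) in by_chrom.items():
        pos = np.asarray(pos, dtype=np.int64)
        order = np.argsort(pos, kind="stable")
        store.atac[chrom] = {
            "cell": np.asarray(ci, dtype=np.int64)[order],
            "pos": pos[order],
        }
    if n_kept == 0:
        warnings.warn("build_store: no record matched the whitelist; "
                      "store is empty")
    return store


# --------------------------------------------------------------------------
# extraction and transforms
# --------------------------------------------------------------------------

def _cell_subset(store: CoverageStore, cells) -> tuple[np.ndarray, list]:
    if cells is None:
        return np.arange(store.n_cells), list(store.cells)
    idx = np.array([store.cell_index[c] if isinstance(c, str) else int(c)
                    for c in cells], dtype=np.int64)
    names = [store.cells[i] for i in idx]
    return idx, names


def extract_binned(store: CoverageStore, interval: GenomicInterval,
                   cells=None, bin_width: int = 32,
                   assay: str = "rna") -> BinnedTrack:
    """Binned per-cell track over `interval`.

    RNA: per-base coverage (sum of segment-overlap lengths) accumulated
    into bins, one channel per strand. ATAC: insertion-event counts per
    bin. Data outside the interval is ignored.
    """
    if len(interval) % bin_width != 0:
        raise ValueError(
            f"interval length {len(interval)} not divisible by bin width "
            f"{bin_width}")
    idx, names = _cell_subset(store, cells)
    remap = -np.ones(store.n_cells, dtype=np.int64)
    remap[idx] = np.arange(len(idx))
    n_bins = len(interval) // bin_width
    a, b = interval.start, interval.end
    if assay == "rna":
        cov = np.zeros((len(idx), 2, len(interval)))
        for si, strand in enumerate(("+", "-")):
            d = store.rna.get(interval.chrom, {}).get(strand)
            if d is None:
                continue
            starts, lengths, cellv = d["start"], d["length"], d["cell"]
            hi = np.searchsorted(starts, b, side="left")
            sel = slice(0, hi)
            s, l, c = starts[sel], lengths[sel], cellv[sel]
            keep = (s + l > a) & (remap[c] >= 0)
            for sj, lj, cj in zip(s[keep], l[keep], remap[c[keep]]):
                cov[cj, si, max(sj - a, 0):min(sj + lj - a, b - a)] += 1.0
        values = cov.reshape(len(idx), 2, n_bins, bin_width).sum(axis=3)
    elif assay == "atac":
        values = np.zeros((len(idx), 1, n_bins))
        d = store.atac.get(interval.chrom)
        if d is not None:
            pos, cellv = d["pos"], d["cell"]
            lo = np.searchsorted(pos, a, side="left")
            hi = np.searchsorted(pos, b, side="left")
            p, c = pos[lo:hi], remap[cellv[lo:hi]]
            keep = c >= 0
            np.add.at(values, (c[keep], 0, (p[keep] - a) // bin_width), 1.0)
    else:
        raise ValueError("assay must be 'rna' or 'atac'")
    return BinnedTrack(interval=interval, bin_width=bin_width, values=values,
                       assay=assay, cells=names, transformed=False)


def apply_transform(track: BinnedTrack, transform: TargetTransform) -> BinnedTrack:
    if track.transformed:
        raise ValueError("track already transformed")
    values = transform.forward(track.values, track.assay)
    return BinnedTrack(track.interval, track.bin_width, values, track.assay,
                       track.cells, transformed=True)


def invert_transform(track: BinnedTrack, transform: TargetTransform,
                     unscale: bool = True) -> BinnedTrack:
    if not track.transformed:
        raise ValueError("track is not on the transformed scale")
    values = transform.inverse(track.values, track.assay, unscale=unscale)
    return BinnedTrack(track.interval, track.bin_width, values, track.assay,
                       track.cells, transformed=False)


# --------------------------------------------------------------------------
# pseudobulk export and feature filtering
# --------------------------------------------------------------------------

def export_pseudobulk_bigwig(store: CoverageStore, group_labels: dict,
                             out_dir: str) -> list:
    """Write one bigWig per group (per strand for RNA; one for ATAC).

    ``group_labels`` maps barcode -> group name and must cover all cells.
    Returns the list of written paths.
    """
    import pyBigWig

    missing = [c for c in store.cells if c not in group_labels]
    if missing:
        raise ValueError(f"group_labels missing {len(missing)} cells, e.g. "
                         f"{missing[:3]}")
    os.makedirs(out_dir, exist_ok=True)
    groups = sorted(set(group_labels.values()))
    group_of = np.array([groups.index(group_labels[c]) for c in store.cells])
    header = sorted(store.chrom_sizes.items())
    written = []

    def _write(path, per_chrom):
        bw = pyBigWig.open(path, "w")
        bw.addHeader(header)
        for chrom, _size in header:
            vals = per_chrom.get(chrom)
            if vals is None or not np.any(vals):
                continue
            bw.addEntries(chrom, 0, values=vals.astype(np.float64), span=1,
                          step=1)
        bw.close()
        written.append(path)

    for gi, group in enumerate(groups):
        member = group_of == gi
        if not member.any():
            warnings.warn(f"export_pseudobulk_bigwig: group {group!r} is empty")
        for strand, sname in (("+", "plus"), ("-", "minus")):
            per_chrom = {}
            for chrom, size in header:
                d = store.rna.get(chrom, {}).get(strand)
                if d is None:
                    continue
                cov = np.zeros(size)
                sel = member[d["cell"]]
                for sj, lj in zip(d["start"][sel], d["length"][sel]):
                    cov[sj:sj + lj] += 1.0
                per_chrom[chrom] = cov
            _write(os.path.join(out_dir, f"{group}_rna_{sname}.bw"), per_chrom)
        per_chrom = {}
        for chrom, size in header:
            d = store.atac.get(chrom)
            if d is None:
                continue
            cov = np.zeros(size)
            sel = member[d["cell"]]
            np.add.at(cov, d["pos"][sel], 1.0)
            per_chrom[chrom] = cov
        _write(os.path.join(out_dir, f"{group}_atac.bw"), per_chrom)
    return written


def filter_leaky_features(intervals, counts, heldout_regions,
                          min_prevalence: float = 0.01):
    """Leakage and prevalence filter applied before embedding construction.

    Removes features (genes/peaks) overlapping any held-out (validation or
    test) region, then features detected in fewer than ``min_prevalence``
    of all cells (default 1%).  ``counts`` is (n_features, n_cells); order
    is preserved. Returns (kept_intervals, kept_counts, mask).
    """
    counts = np.asarray(counts)
    if counts.shape[0] != len(intervals):
        raise ValueError("counts rows must match the number of intervals")
    mask = np.ones(len(intervals), dtype=bool)
    for i, iv in enumerate(intervals):
        for region in heldout_regions:
            if iv.overlaps(region):
                mask[i] = False
                break
    prevalence = (counts > 0).mean(axis=1)
    mask &= prevalence >= min_prevalence
    kept = [iv for i, iv in enumerate(intervals) if mask[i]]
    return kept, counts[mask], mask
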