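"""Position weight matrices: MEME reading, scanning, in silico mutation.

Scanning scores a window by the log-odds sum log(p_base / background) and
converts scores to p-values by exact dynamic programming over the PWM's
discretized score distribution under the background model (the approach
FIMO takes).  Hits on both strands at p <= 1e-4 (the conventional cutoff)
are candidate TF binding sites; ``mutate_hits`` replaces all of them
simultaneously with random sequence, several replicates per input, for
motif-deletion scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coverage import GenomicInterval

__all__ = ["PWM", "MotifHit", "MutationConfig", "read_meme", "scan_pwm",
           "mutate_hits", "merge_hit_spans"]

_ALPHABET = "ACGT"
_COMP = {0: 3, 1: 2, 2: 1, 3: 0}


@dataclass
class PWM:
    """Probability matrix (positions x ACGT) with background frequencies."""

    name: str
    matrix: np.ndarray
    background: np.ndarray | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (length, 4)")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=np.float64)
        rows = self.matrix.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-6):
            raise ValueError("PWM rows must sum to 1")
        if np.any(self.matrix < 0):
            raise ValueError("PWM probabilities must be nonnegative")

    def __len__(self):
        return self.matrix.shape[0]

    def smoothed(self, pseudocount: float = 1e-3) -> "PWM":
        m = self.matrix + pseudocount
        m = m / m.sum(axis=1, keepdims=True)
        return PWM(self.name, m, self.background)

    @property
    def log_odds(self) -> np.ndarray:
        return np.log(self.matrix) - np.log(self.background)

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.matrix[::-1, ::-1].copy(),
                   self.background[::-1].copy())


@dataclass
class MotifHit:
    interval: GenomicInterval
    score: float
    p_value: float

    def __post_init__(self):
        if not (0 < self.p_value <= 1):
            raise ValueError("p-value must lie in (0, 1]")


@dataclass
class MutationConfig:
    """Settings for in silico motif deletion."""

    n_replicates: int = 10
    p_value_threshold: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def read_meme(path: str, pseudocount: float = 1e-3) -> list:
    """Read MEME-format PWMs (via Bio.motifs), pseudocount-smoothed."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    out = []
    for m in parsed:
        mat = np.array([[m.pwm[b][i] for b in _ALPHABET]
                        for i in range(m.length)])
        bg = np.array([m.background[b] for b in _ALPHABET])
        if not np.any(bg > 0):
            bg = None
        out.append(PWM(m.name, mat / mat.sum(axis=1, keepdims=True),
                       bg).smoothed(pseudocount))
    return out


def score_distribution(pwm: PWM, granularity: float = 1e-3):
    """Exact null distribution of the discretized log-odds score.

    Per-position log-odds are quantized to integer multiples of
    ``granularity``; the DP convolves the per-position distributions under
    the background model.  Returns (q, offset, tail) where ``q`` holds the
    integer per-position scores, and ``tail[i] = Pr(S_int >= offset + i)``.
    Scoring windows with the same quantized values makes tie handling
    exact.
    """
    lo = pwm.log_odds
    q = np.round(lo / granularity).astype(np.int64)
    # DP over positions; arr[i] = Pr(sum == offset + i)
    arr = np.array([1.0])
    offset = 0
    for row in q:
        new = np.zeros(len(arr) + (row.max() - row.min()))
        for letter in range(4):
            shift = row[letter] - row.min()
            new[shift:shift + len(arr)] += arr * pwm.background[letter]
        arr, offset = new, offset + row.min()
    tail = np.cumsum(arr[::-1])[::-1]
    return q, offset, tail


def _pvalue_lookup(offset, tail, int_score: int) -> float:
    idx = int(int_score) - offset
    if idx >= len(tail):
        return float(max(tail[-1], np.finfo(float).tiny))
    if idx < 0:
        return 1.0
    return float(max(tail[idx], np.finfo(float).tiny))


def _encode(seq: str) -> np.ndarray:
    table = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(_ALPHABET):
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


def scan_pwm(sequence: str, pwm: PWM, threshold: float = 1e-4,
             chrom: str = "seq", offset: int = 0,
             granularity: float = 1e-3) -> list:
    """Scan both strands for motif hits with p-value <= threshold.

    Windows containing N are skipped. Hit intervals are reported in
    forward-strand coordinates (optionally shifted by ``offset`` into
    chromosome coordinates), sorted by position.
    """
    w = len(pwm)
    idx = _encode(sequence)
    if w > len(idx):
        return []
    q_fwd, grid_offset, tail = score_distribution(pwm, granularity)
    hits = []
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    valid = (windows >= 0).all(axis=1)
    for strand, p in (("+", pwm), ("-", pwm.reverse_complement())):
        lo = p.log_odds
        # the reverse-complement PWM has the same null distribution; score
        # windows with the identically quantized log-odds for exact ties
        q = (q_fwd if strand == "+" else q_fwd[::-1, ::-1])
        safe = np.where(windows >= 0, windows, 0)
        scores = lo[np.arange(w)[None, :], safe].sum(axis=1)
        int_scores = q[np.arange(w)[None, :], safe].sum(axis=1)
        for i in np.nonzero(valid)[0]:
            pv = _pvalue_lookup(grid_offset, tail, int_scores[i])
            if pv <= threshold:
                hits.append(MotifHit(
                    interval=GenomicInterval(chrom, offset + int(i),
                                             offset + int(i) + w, strand),
                    score=float(scores[i]), p_value=pv))
    hits.sort(key=lambda h: (h.interval.start, h.interval.strand))
    return hits


def merge_hit_spans(hits) -> list:
    """Merge overlapping hit intervals (across strands) into plain spans."""
    spans = sorted((h.interval.start, h.interval.end) for h in hits)
    merged = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def mutate_hits(sequence: str, hits, config: MutationConfig,
                rng: np.random.Generator | None = None) -> list:
    """Replace all hit spans with random sequence, ``n_replicates`` times.

    Overlapping hits are merged and each merged span replaced by i.i.d.
    uniform ACGT bases; sequence length is preserved.  Returns a list of
    ``n_replicates`` alternative sequences (copies of the input when there
    are no hits).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    spans = merge_hit_spans(hits)
    for s, e in spans:
        if s < 0 or e > len(sequence):
            raise ValueError(f"hit span ({s}, {e}) outside the sequence")
    out = []
    for _ in range(config.n_replicates):
        chars = list(sequence)
        for s, e in spans:
            repl = rng.integers(0, 4, size=e - s)
            chars[s:e] = [_ALPHABET[j] for j in repl]
        out.append("".join(chars))
    return out
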