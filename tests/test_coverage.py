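"""Coverage archive: parsing, deduplication, binning, transform, export."""

import numpy as np
import pysam
import pytest

from scprofile.coverage import (BinnedTrack, CoverageStore, GenomicInterval,
                                InsertionRecord, ReadRecord, TargetTransform,
                                apply_transform, build_store,
                                export_pseudobulk_bigwig, extract_binned,
                                filter_leaky_features, fragments_to_insertions,
                                invert_transform, parse_alignments)

CHROM_SIZES = {"chr1": 10_000, "chr2": 8_000}


def _write_sam(path, body_lines):
    header = ("@HD\tVN:1.6\tSO:coordinate\n"
              "@SQ\tSN:chr1\tLN:10000\n@SQ\tSN:chr2\tLN:8000\n")
    path.write_text(header + "".join(line + "\n" for line in body_lines))
    return str(path)


def _rna_line(name, pos, cigar, cb="AAAC", ub="U1", xf=True, flag=0,
              seqlen=100):
    tags = []
    if cb:
        tags.append(f"CB:Z:{cb}")
    if ub:
        tags.append(f"UB:Z:{ub}")
    if xf:
        tags.append("xf:i:25")
    return (f"{name}\t{flag}\tchr1\t{pos}\t60\t{cigar}\t*\t0\t0\t"
            f"{'A' * seqlen}\t*\t" + "\t".join(tags))


class TestParseAlignments:
    def test_split_read_yields_one_record_with_two_segments(self, tmp_path):
        sam = _write_sam(tmp_path / "a.sam",
                         [_rna_line("r1", 101, "50M400N50M")])
        with pysam.AlignmentFile(sam, check_sq=False) as af:
            recs = parse_alignments(af, "rna", require_valid_flag=True)
        assert len(recs) == 1
        assert recs[0].segments == ((100, 50), (550, 50))
        assert recs[0].strand == "+"

    def test_validity_flag_filter(self, tmp_path):
        sam = _write_sam(tmp_path / "a.sam", [
            _rna_line("r1", 101, "100M", xf=True),
            _rna_line("r2", 301, "100M", ub="U2", xf=False),
        ])
        with pysam.AlignmentFile(sam, check_sq=False) as af:
            kept = parse_alignments(af, "rna", require_valid_flag=True)
        assert [r.segments[0][0] for r in kept] == [100]

    def test_missing_barcode_skipped_with_warning(self, tmp_path):
        sam = _write_sam(tmp_path / "a.sam", [
            _rna_line("r1", 101, "100M", cb=None),
            _rna_line("r2", 301, "100M"),
        ])
        with pysam.AlignmentFile(sam, check_sq=False) as af:
            with pytest.warns(UserWarning, match="missing"):
                kept = parse_alignments(af, "rna")
        assert len(kept) == 1

    def test_rna_deduplication_matches_bruteforce_grouping(self, tmp_path):
        # 10-read toy stream with planted duplicates
        rng = np.random.default_rng(0)
        lines, keys = [], []
        for i in range(10):
            cb = f"BC{rng.integers(2)}"
            ub = f"U{rng.integers(3)}"
            pos = int(rng.choice([101, 201]))
            lines.append(_rna_line(f"r{i}", pos, "100M", cb=cb, ub=ub))
            keys.append((cb, ub, "chr1", pos - 1))
        sam = _write_sam(tmp_path / "a.sam", lines)
        with pysam.AlignmentFile(sam, check_sq=False) as af:
            recs = parse_alignments(af, "rna")
        assert len(recs) == len(set(keys))

    def test_atac_paired_fragment(self, tmp_path):
        # proper pair, leftmost mate at pos 101 (1-based), template 100
        lines = [
            "f1\t99\tchr1\t101\t60\t50M\t=\t151\t100\t" + "A" * 50 +
            "\t*\tCB:Z:AAAC",
            "f1\t147\tchr1\t151\t60\t50M\t=\t101\t-100\t" + "A" * 50 +
            "\t*\tCB:Z:AAAC",
        ]
        sam = _write_sam(tmp_path / "a.sam", lines)
        with pysam.AlignmentFile(sam, check_sq=False) as af:
            recs = parse_alignments(af, "atac")
        assert len(recs) == 1
        assert recs[0].segments == ((100, 100),)

    def test_malformed_cigar_raises(self):
        # htslib unmaps reads with absent CIGAR on parse, so the error path
        # is exercised with a duck-typed record carrying no cigartuples
        class Stub:
            query_name = "bad"
            reference_name = "chr1"
            reference_start = 100
            cigartuples = None
            is_unmapped = False
            is_paired = False
            is_secondary = False
            is_supplementary = False
            is_reverse = False

            def has_tag(self, tag):
                return tag in ("CB", "UB")

            def get_tag(self, tag):
                return "AAAC" if tag == "CB" else "U1"

        with pytest.raises(ValueError, match="bad"):
            parse_alignments([Stub()], "rna")


class TestInsertions:
    def test_two_insertions_per_fragment_at_ends(self):
        rec = ReadRecord("BC1", "chr1", ((100, 100),), "atac")
        ins = fragments_to_insertions([rec])
        assert [(i.pos) for i in ins] == [100, 199]

    def test_length_one_fragment_two_events_same_position(self):
        rec = ReadRecord("BC1", "chr1", ((50, 1),), "atac")
        ins = fragments_to_insertions([rec])
        assert [i.pos for i in ins] == [50, 50]

    def test_conservation_two_n_insertions(self, rng):
        recs = [ReadRecord(f"BC{i}", "chr1",
                           ((int(rng.integers(0, 900)), int(rng.integers(1, 100))),),
                           "atac") for i in range(25)]
        assert len(fragments_to_insertions(recs)) == 50

    def test_rna_record_rejected(self):
        rec = ReadRecord("BC1", "chr1", ((0, 10),), "rna")
        with pytest.raises(ValueError):
            fragments_to_insertions([rec])


def _random_records(rng, n, cells, chrom="chr1", split_prob=0.3):
    out = []
    for i in range(n):
        start = int(rng.integers(0, 8_000))
        if rng.random() < split_prob:
            l1, gap, l2 = (int(rng.integers(10, 60)),
                           int(rng.integers(50, 200)),
                           int(rng.integers(10, 60)))
            segs = ((start, l1), (start + l1 + gap, l2))
        else:
            segs = ((start, int(rng.integers(10, 120))),)
        out.append(ReadRecord(str(rng.choice(cells)), chrom, segs, "rna",
                              strand=str(rng.choice(["+", "-"])), umi=f"u{i}"))
    return out


class TestStore:
    def test_whitelist_filters_cells(self, rng):
        recs = [ReadRecord(bc, "chr1", ((10, 20),), "rna", strand="+",
                           umi=str(i))
                for i, bc in enumerate(["A", "B", "C"])]
        store = build_store(rna_records=recs, whitelist=["A", "B"],
                           chrom_sizes=CHROM_SIZES)
        assert store.n_cells == 2
        assert store.rna_totals().sum() == 40

    def test_unknown_chromosome_raises(self):
        rec = ReadRecord("A", "chrX", ((0, 5),), "rna")
        with pytest.raises(ValueError, match="chrX"):
            build_store(rna_records=[rec], whitelist=["A"],
                        chrom_sizes=CHROM_SIZES)

    def test_empty_store_warns_but_valid(self):
        with pytest.warns(UserWarning, match="empty"):
            store = build_store(rna_records=[], whitelist=["A"],
                                chrom_sizes=CHROM_SIZES)
        track = extract_binned(store, GenomicInterval("chr1", 0, 64))
        assert track.values.sum() == 0

    def test_totals_preserved_and_roundtrip(self, rng, tmp_path):
        cells = ["A", "B", "C"]
        recs = _random_records(rng, 40, cells)
        ins = fragments_to_insertions(
            [ReadRecord(str(rng.choice(cells)), "chr1",
                        ((int(rng.integers(0, 900)), 50),), "atac")
             for _ in range(15)])
        store = build_store(rna_records=recs, atac_insertions=ins,
                            whitelist=cells, chrom_sizes=CHROM_SIZES)
        exp_bases = sum(r.total_bases for r in recs)
        assert store.rna_totals().sum() == exp_bases
        assert store.atac_totals().sum() == 30
        path = tmp_path / "store.h5"
        store.save(str(path))
        loaded = CoverageStore.load(str(path))
        iv = GenomicInterval("chr1", 0, 9984)
        for assay in ("rna", "atac"):
            np.testing.assert_array_equal(
                extract_binned(store, iv, assay=assay).values,
                extract_binned(loaded, iv, assay=assay).values)

    def test_extraction_independent_of_record_order(self, rng):
        cells = ["A", "B"]
        recs = _random_records(rng, 30, cells)
        s1 = build_store(rna_records=recs, whitelist=cells,
                         chrom_sizes=CHROM_SIZES)
        s2 = build_store(rna_records=recs[::-1], whitelist=cells,
                         chrom_sizes=CHROM_SIZES)
        iv = GenomicInterval("chr1", 64, 8_256)
        np.testing.assert_array_equal(extract_binned(s1, iv).values,
                                      extract_binned(s2, iv).values)


class TestExtractBinned:
    def test_matches_per_base_bruteforce(self, rng):
        cells = ["A", "B", "C"]
        recs = _random_records(rng, 60, cells)
        store = build_store(rna_records=recs, whitelist=cells,
                            chrom_sizes=CHROM_SIZES)
        iv = GenomicInterval("chr1", 512, 4_608)
        track = extract_binned(store, iv, bin_width=32)
        # oracle: accumulate per-base coverage, then block-sum
        cov = np.zeros((3, 2, len(iv)))
        for r in recs:
            ci = cells.index(r.barcode)
            si = 0 if r.strand == "+" else 1
            for s, l in r.segments:
                a, b = max(s, iv.start), min(s + l, iv.end)
                if a < b:
                    cov[ci, si, a - iv.start:b - iv.start] += 1
        expected = cov.reshape(3, 2, len(iv) // 32, 32).sum(axis=3)
        np.testing.assert_array_equal(track.values, expected)

    def test_insertion_bin_boundary(self):
        ins = [InsertionRecord("A", "chr1", 31), InsertionRecord("A", "chr1", 32)]
        store = build_store(atac_insertions=ins, whitelist=["A"],
                            chrom_sizes=CHROM_SIZES)
        track = extract_binned(store, GenomicInterval("chr1", 0, 64),
                               assay="atac")
        np.testing.assert_array_equal(track.values[0, 0], [1, 1])

    def test_indivisible_interval_raises(self, rng):
        store = build_store(rna_records=[], whitelist=["A"],
                            chrom_sizes=CHROM_SIZES)
        with pytest.raises(ValueError, match="divisible"):
            extract_binned(store, GenomicInterval("chr1", 0, 33))

    def test_single_segment_two_bins(self):
        rec = ReadRecord("A", "chr1", ((0, 64),), "rna", strand="+", umi="u")
        store = build_store(rna_records=[rec], whitelist=["A"],
                            chrom_sizes=CHROM_SIZES)
        track = extract_binned(store, GenomicInterval("chr1", 0, 64))
        np.testing.assert_array_equal(track.values[0, 0], [32, 32])


class TestTransform:
    def test_roundtrip_identity_on_grid(self):
        tr = TargetTransform()
        grid = np.array([0.0, 0.1, 1.0, 5.0, 7.0, 8.55, 50.0, 5000.0])
        for assay in ("rna", "atac"):
            back = tr.inverse(tr.forward(grid, assay), assay)
            np.testing.assert_allclose(back, grid, rtol=1e-6, atol=1e-9)

    def test_atac_unscale_factor_is_twenty(self):
        tr = TargetTransform()
        raw = np.array([100.0])
        fwd = tr.forward(raw, "atac")
        assert tr.inverse(fwd, "atac") == pytest.approx(100.0)
        assert (tr.inverse(fwd, "atac")
                / tr.inverse(fwd, "atac", unscale=False)) == pytest.approx(20.0)

    def test_zero_maps_to_zero(self):
        tr = TargetTransform()
        assert tr.forward(np.zeros(3), "rna").sum() == 0
        assert tr.inverse(np.zeros(3), "rna").sum() == 0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            TargetTransform().forward(np.array([-1.0]), "rna")

    def test_track_transform_flags(self, rng):
        store = build_store(
            rna_records=_random_records(rng, 10, ["A"]), whitelist=["A"],
            chrom_sizes=CHROM_SIZES)
        track = extract_binned(store, GenomicInterval("chr1", 0, 8192))
        tr = TargetTransform()
        squashed = apply_transform(track, tr)
        assert squashed.transformed
        with pytest.raises(ValueError):
            apply_transform(squashed, tr)
        back = invert_transform(squashed, tr)
        np.testing.assert_allclose(back.values, track.values, rtol=1e-6)


class TestBigWigExport:
    def test_group_additivity(self, rng, tmp_path):
        import pyBigWig

        cells = ["A", "B", "C", "D"]
        recs = _random_records(rng, 40, cells)
        ins = fragments_to_insertions(
            [ReadRecord(str(rng.choice(cells)), "chr1", ((100, 50),), "atac")
             for _ in range(10)])
        store = build_store(rna_records=recs, atac_insertions=ins,
                            whitelist=cells, chrom_sizes=CHROM_SIZES)
        d1 = tmp_path / "split"
        d2 = tmp_path / "single"
        export_pseudobulk_bigwig(
            store, {"A": "g1", "B": "g1", "C": "g2", "D": "g2"}, str(d1))
        export_pseudobulk_bigwig(store, {c: "all" for c in cells}, str(d2))

        def values(path):
            with pyBigWig.open(str(path)) as bw:
                if "chr1" not in bw.chroms():
                    return np.zeros(10_000)
                v = np.nan_to_num(np.array(
                    bw.values("chr1", 0, 10_000), dtype=float))
            return v

        for suffix in ("rna_plus.bw", "rna_minus.bw", "atac.bw"):
            total = values(d2 / f"all_{suffix}")
            parts = (values(d1 / f"g1_{suffix}")
                     + values(d1 / f"g2_{suffix}"))
            np.testing.assert_allclose(parts, total)

    def test_labels_must_cover_cells(self, rng, tmp_path):
        store = build_store(rna_records=_random_records(rng, 5, ["A", "B"]),
                            whitelist=["A", "B"], chrom_sizes=CHROM_SIZES)
        with pytest.raises(ValueError, match="missing"):
            export_pseudobulk_bigwig(store, {"A": "g"}, str(tmp_path))


class TestLeakyFeatureFilter:
    def test_heldout_overlap_and_prevalence(self):
        ivs = [GenomicInterval("chr1", 0, 100),
               GenomicInterval("chr1", 500, 600),
               GenomicInterval("chr2", 0, 100)]
        counts = np.array([
            np.ones(200),                       # prevalent, overlaps held-out
            np.r_[np.ones(2), np.zeros(198)],   # 1% exactly -> kept
            np.r_[np.ones(1), np.zeros(199)],   # 0.5% -> dropped
        ])
        heldout = [GenomicInterval("chr1", 50, 60)]
        kept, kc, mask = filter_leaky_features(ivs, counts, heldout)
        assert mask.tolist() == [False, True, False]
        assert kept == [ivs[1]]

    def test_matches_bruteforce_overlap(self, rng):
        ivs = [GenomicInterval("chr1", int(s), int(s) + 50)
               for s in rng.integers(0, 5_000, size=10)]
        counts = np.ones((10, 100))
        regions = [GenomicInterval("chr1", 1_000, 1_500),
                   GenomicInterval("chr1", 3_000, 3_100)]
        _, _, mask = filter_leaky_features(ivs, counts, regions)
        expect = [not any(iv.start < r.end and r.start < iv.end
                          for r in regions) for iv in ivs]
        assert mask.tolist() == expect

    def test_order_preserved(self):
        ivs = [GenomicInterval("chr1", i * 100, i * 100 + 50)
               for i in range(5)]
        counts = np.ones((5, 10))
        kept, _, _ = filter_leaky_features(ivs, counts, [])
        assert kept == ivs
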