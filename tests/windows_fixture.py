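"""Hand-constructed 12-gene annotation and its hand-computed window table.

Covers: neighbour-midpoint truncation (with and without neighbours),
short-gene truncation of intronic bins, exon masking including exons of an
overlapping opposite-strand gene, - strand orientation, equidistant-base
dropping at an odd-length gap, a non-bin-aligned gene end, and chromosome
end clipping.  All expected kept intervals below were derived by hand from
the rules: bin k spans oriented distance [200k, 200k+200) along the
non-template strand (TSS: d=0 first transcribed base; END3: d=0 first base
past the transcript); intronic-side bins stay inside the gene; intergenic
bins keep a base only if strictly nearer to this gene than to the
neighbouring gene span; every exonic base of any gene is masked.
"""

from txsubst.regions import GeneModel

CHROM_LEN = 100_000

GENES = [
    GeneModel("g0", "chr1", 2000, 4000, "+", ((2000, 2100),)),
    GeneModel("gA", "chr1", 10000, 18000, "+",
              ((10000, 10150), (13000, 13200), (17800, 18000))),
    GeneModel("gB", "chr1", 20000, 30000, "+", ((20000, 20100),)),
    GeneModel("gC", "chr1", 32000, 37000, "-", ((32000, 32200), (36900, 37000))),
    GeneModel("gD", "chr1", 40000, 43000, "+", ((40000, 40060),)),
    GeneModel("gE", "chr1", 50000, 56000, "+", ((50000, 50100),)),
    GeneModel("gF", "chr1", 57000, 61000, "-", ((57000, 57100), (60900, 61000))),
    GeneModel("gG", "chr1", 70000, 76000, "+",
              ((70000, 70100), (73000, 73150), (75900, 76000))),
    GeneModel("gH", "chr1", 72000, 74000, "-", ((72000, 72100), (73900, 74000))),
    GeneModel("gI", "chr1", 80000, 82000, "+", ((80000, 80050),)),
    GeneModel("gJ", "chr1", 82601, 84000, "+", ((82601, 82650),)),
    GeneModel("gK", "chr1", 90000, 96000, "-", ((90000, 90100), (95900, 96000))),
]


def _plus(anchor_pos: int, k: int):
    return (anchor_pos + 200 * k, anchor_pos + 200 * (k + 1))


def _minus(anchor_pos: int, k: int):
    return (anchor_pos - 200 * (k + 1), anchor_pos - 200 * k)


def expected_windows() -> dict[tuple[str, str, int], tuple[tuple[int, int], ...]]:
    """(gene_id, anchor, bin) -> kept intervals; absent keys mean empty."""
    E: dict[tuple[str, str, int], tuple[tuple[int, int], ...]] = {}

    def full(gene, anchor, span_fn, a, ks):
        for k in ks:
            E[(gene, anchor, k)] = (span_fn(a, k),)

    # g0 [2000,4000)+, exon (2000,2100); no left neighbour, midpoint to gA 7000
    full("g0", "TSS", _plus, 2000, range(-10, 0))          # [0, 2000)
    E[("g0", "TSS", 0)] = ((2100, 2200),)
    full("g0", "TSS", _plus, 2000, range(1, 10))
    full("g0", "END3", _plus, 4000, range(0, 15))          # [4000, 7000)
    E[("g0", "END3", -10)] = ((2100, 2200),)
    full("g0", "END3", _plus, 4000, range(-9, 0))

    # gA [10000,18000)+, midpoints 7000 / 19000
    full("gA", "TSS", _plus, 10000, range(-15, 0))         # [7000, 10000)
    E[("gA", "TSS", 0)] = ((10150, 10200),)
    full("gA", "TSS", _plus, 10000, range(1, 15))
    # bin 15 fully exonic (13000,13200)
    full("gA", "TSS", _plus, 10000, range(16, 25))
    full("gA", "END3", _plus, 18000, range(0, 5))          # [18000, 19000)
    full("gA", "END3", _plus, 18000, range(-24, -1))       # bins -24..-2
    # bins -25 and -1 fully exonic

    # gB [20000,30000)+, midpoints 19000 / 31000
    full("gB", "TSS", _plus, 20000, range(-5, 0))
    E[("gB", "TSS", 0)] = ((20100, 20200),)
    full("gB", "TSS", _plus, 20000, range(1, 25))
    full("gB", "END3", _plus, 30000, range(0, 5))
    full("gB", "END3", _plus, 30000, range(-25, 0))

    # gC [32000,37000)-, exons (32000,32200),(36900,37000); midpoints 31000/38500
    E[("gC", "TSS", 0)] = ((36800, 36900),)
    full("gC", "TSS", _minus, 37000, range(1, 24))
    # bin 24 = [32000,32200) fully exonic
    full("gC", "TSS", _minus, 37000, range(-7, 0))         # [37000, 38400)
    E[("gC", "TSS", -8)] = ((38400, 38500),)
    full("gC", "END3", _minus, 32000, range(0, 5))         # [31000, 32000)
    # intronic: bin -1 = [32000,32200) fully exonic
    full("gC", "END3", _minus, 32000, range(-24, -1))
    E[("gC", "END3", -25)] = ((36800, 36900),)

    # gD [40000,43000)+ length 3000; midpoints 38500 / 46500
    E[("gD", "TSS", -8)] = ((38500, 38600),)
    full("gD", "TSS", _plus, 40000, range(-7, 0))
    E[("gD", "TSS", 0)] = ((40060, 40200),)
    full("gD", "TSS", _plus, 40000, range(1, 15))          # bins 15..24 truncated
    full("gD", "END3", _plus, 43000, range(0, 17))
    E[("gD", "END3", 17)] = ((46400, 46500),)
    E[("gD", "END3", -15)] = ((40060, 40200),)
    full("gD", "END3", _plus, 43000, range(-14, 0))

    # gE [50000,56000)+; midpoints 46500 / 56500
    E[("gE", "TSS", -18)] = ((46500, 46600),)
    full("gE", "TSS", _plus, 50000, range(-17, 0))
    E[("gE", "TSS", 0)] = ((50100, 50200),)
    full("gE", "TSS", _plus, 50000, range(1, 25))
    full("gE", "END3", _plus, 56000, range(0, 2))
    E[("gE", "END3", 2)] = ((56400, 56500),)
    full("gE", "END3", _plus, 56000, range(-25, 0))

    # gF [57000,61000)- length 4000; midpoints 56500 / 65500
    E[("gF", "TSS", 0)] = ((60800, 60900),)
    full("gF", "TSS", _minus, 61000, range(1, 19))
    E[("gF", "TSS", 19)] = ((57100, 57200),)
    full("gF", "TSS", _minus, 61000, range(-22, 0))        # [61000, 65400)
    E[("gF", "TSS", -23)] = ((65400, 65500),)
    full("gF", "END3", _minus, 57000, range(0, 2))         # [56600, 57000)
    E[("gF", "END3", 2)] = ((56500, 56600),)
    E[("gF", "END3", -1)] = ((57100, 57200),)
    full("gF", "END3", _minus, 57000, range(-19, -1))
    E[("gF", "END3", -20)] = ((60800, 60900),)

    # gG [70000,76000)+ with nested - strand gH [72000,74000)
    E[("gG", "TSS", -23)] = ((65500, 65600),)
    full("gG", "TSS", _plus, 70000, range(-22, 0))
    E[("gG", "TSS", 0)] = ((70100, 70200),)
    full("gG", "TSS", _plus, 70000, range(1, 10))
    E[("gG", "TSS", 10)] = ((72100, 72200),)
    full("gG", "TSS", _plus, 70000, range(11, 15))
    E[("gG", "TSS", 15)] = ((73150, 73200),)
    full("gG", "TSS", _plus, 70000, range(16, 19))
    E[("gG", "TSS", 19)] = ((73800, 73900),)
    full("gG", "TSS", _plus, 70000, range(20, 25))
    # gG END3 downstream: the nested gene lies wholly inside gG, so the
    # right flank runs to the midpoint with gI at 78000
    full("gG", "END3", _plus, 76000, range(0, 10))
    E[("gG", "END3", -1)] = ((75800, 75900),)
    full("gG", "END3", _plus, 76000, range(-10, -1))
    E[("gG", "END3", -11)] = ((73800, 73900),)
    full("gG", "END3", _plus, 76000, range(-14, -11))
    E[("gG", "END3", -15)] = ((73150, 73200),)
    full("gG", "END3", _plus, 76000, range(-19, -15))
    E[("gG", "END3", -20)] = ((72100, 72200),)
    full("gG", "END3", _plus, 76000, range(-25, -20))

    # gH [72000,74000)-: both flanks lie inside the containing gene gG and
    # are claimed by it (distance 0), so every intergenic bin is empty
    E[("gH", "TSS", 0)] = ((73800, 73900),)
    full("gH", "TSS", _minus, 74000, range(1, 4))
    E[("gH", "TSS", 4)] = ((73150, 73200),)
    full("gH", "TSS", _minus, 74000, range(5, 9))
    E[("gH", "TSS", 9)] = ((72100, 72200),)
    E[("gH", "END3", -1)] = ((72100, 72200),)
    full("gH", "END3", _minus, 72000, range(-5, -1))
    E[("gH", "END3", -6)] = ((73150, 73200),)
    full("gH", "END3", _minus, 72000, range(-9, -6))
    E[("gH", "END3", -10)] = ((73800, 73900),)

    # gI [80000,82000)+; midpoints 78000 / 82300 (odd gap to gJ: base 82300
    # is equidistant and dropped)
    full("gI", "TSS", _plus, 80000, range(-10, 0))
    E[("gI", "TSS", 0)] = ((80050, 80200),)
    full("gI", "TSS", _plus, 80000, range(1, 10))
    E[("gI", "END3", 0)] = ((82000, 82200),)
    E[("gI", "END3", 1)] = ((82200, 82300),)
    E[("gI", "END3", -10)] = ((80050, 80200),)
    full("gI", "END3", _plus, 82000, range(-9, 0))

    # gJ [82601,84000)+ (end not bin-aligned); midpoints 82301 / 87000
    E[("gJ", "TSS", -1)] = ((82401, 82601),)
    E[("gJ", "TSS", -2)] = ((82301, 82401),)
    E[("gJ", "TSS", 0)] = ((82650, 82801),)
    full("gJ", "TSS", _plus, 82601, range(1, 6))
    E[("gJ", "TSS", 6)] = ((83801, 84000),)
    full("gJ", "END3", _plus, 84000, range(0, 15))         # [84000, 87000)
    full("gJ", "END3", _plus, 84000, range(-6, 0))
    E[("gJ", "END3", -7)] = ((82650, 82800),)

    # gK [90000,96000)-; midpoint to gJ 87000; chromosome end at 100000
    E[("gK", "TSS", 0)] = ((95800, 95900),)
    full("gK", "TSS", _minus, 96000, range(1, 25))
    full("gK", "TSS", _minus, 96000, range(-20, 0))        # [96000, 100000)
    full("gK", "END3", _minus, 90000, range(0, 15))        # [87000, 90000)
    E[("gK", "END3", -1)] = ((90100, 90200),)
    full("gK", "END3", _minus, 90000, range(-25, -1))

    return E
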