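"""Gene annotation, CpG-island detection, and TSS/3'-end window construction.

Coordinates are 0-based half-open (BED convention) throughout.  The TSS is
the first transcribed base of the furthest 5' end among a gene's
transcripts; alternative TSSs are assumed already collapsed in the input
annotation.

Windows: around each gene's 5' end (TSS) and 3' end (END3) the flanking
and genic sequence is cut into ``bin_size`` (default 200 bp) non-overlapping
bins indexed by oriented distance along the non-template strand; bin k
covers oriented distance [bin_size*k, bin_size*(k+1)).  For the TSS anchor,
distance 0 is the first transcribed base; for the END3 anchor, distance 0 is
the first base past the transcript, so negative bins are intronic.  Bins
are truncated at the midpoint to the nearest neighbouring gene (equidistant
bases are dropped), intronic-side bins never extend past the gene's other
end, and every exonic base of any gene on either strand is masked out.
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_right
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqcodes import seq_to_codes

TSS = "TSS"
END3 = "END3"
ANCHORS = (TSS, END3)

CGI_CLASS = "CGI"
NONCGI_CLASS = "nonCGI"

# CpG-island thresholds (Gardiner-Garden-style definition)
CGI_MIN_LENGTH = 400
CGI_MIN_GC = 0.5
CGI_MIN_OBS_EXP = 0.6


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclasses.dataclass
class GeneModel:
    """A protein-coding gene span with its exons (half-open intervals)."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not self.start < self.end:
            raise ValueError(f"{self.id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"{self.id}: strand must be + or -")
        prev = self.start
        for s, e in self.exons:
            if s < prev or e > self.end or s >= e:
                raise ValueError(f"{self.id}: exons must be sorted, disjoint and within the gene")
            prev = e

    @property
    def tss(self) -> int:
        """Genomic position of the first transcribed base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def end3(self) -> int:
        """Genomic position of the last transcribed base."""
        return self.end - 1 if self.strand == "+" else self.start

    def mirror(self, chrom_len: int) -> "GeneModel":
        """The same gene on the reverse-complemented chromosome."""
        return GeneModel(
            id=self.id,
            chrom=self.chrom,
            start=chrom_len - self.end,
            end=chrom_len - self.start,
            strand="-" if self.strand == "+" else "+",
            exons=tuple(
                sorted((chrom_len - e, chrom_len - s) for s, e in self.exons)
            ),
        )


@dataclasses.dataclass
class CgiInterval:
    chrom: str
    start: int
    end: int
    gc_fraction: float
    obs_exp_cpg: float

    def __post_init__(self) -> None:
        if self.end - self.start < CGI_MIN_LENGTH:
            raise ValueError("CpG island shorter than the minimum length")
        if self.gc_fraction < CGI_MIN_GC or self.obs_exp_cpg < CGI_MIN_OBS_EXP:
            raise ValueError("CpG island below the GC or obs/exp threshold")


@dataclasses.dataclass
class WindowEntry:
    gene_id: str
    anchor: str
    bin_index: int
    chrom: str
    kept: tuple[tuple[int, int], ...]
    gene_class: str

    @property
    def kept_length(self) -> int:
        return sum(e - s for s, e in self.kept)


@dataclasses.dataclass
class WindowSet:
    bin_size: int
    entries: list[WindowEntry]

    def nonempty(self) -> Iterable[WindowEntry]:
        return (e for e in self.entries if e.kept)

    def kept_length(self, anchor: str, bin_index: int, gene_class: str | None = None) -> int:
        return sum(
            e.kept_length
            for e in self.entries
            if e.anchor == anchor
            and e.bin_index == bin_index
            and (gene_class is None or e.gene_class == gene_class)
        )


# --------------------------------------------------------------------------
# CpG island detection
# --------------------------------------------------------------------------


def _window_qualifies(nc: int, ng: int, ncg: int, length: int) -> bool:
    """Thresholds on exact integer counts (no float edge cases):
    GC >= 0.5 and obs/exp CpG = ncg*length/(nc*ng) >= 0.6."""
    if 2 * (nc + ng) < length:
        return False
    if nc == 0 or ng == 0:
        return False
    return 10 * ncg * length >= 6 * nc * ng


def detect_cgi(
    sequence: str,
    chrom: str = "",
    min_length: int = CGI_MIN_LENGTH,
) -> list[CgiInterval]:
    """Detect CpG islands: >=400 bp, GC >= 50%, observed/expected CpG >= 0.6.

    Sliding ``min_length`` windows at 1 bp steps; qualifying windows are
    unioned, and each merged interval is re-verified and symmetrically
    trimmed (one base off each end per step) until it qualifies or falls
    below the minimum length.  Windows containing N never qualify, so no N
    appears inside a reported island.
    """
    if not sequence:
        return []
    bad = set(sequence.upper()) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN symbols in sequence: {sorted(bad)}")
    codes = seq_to_codes(sequence)
    n = len(codes)
    L = min_length
    if n < L:
        return []
    is_c = codes == 1
    is_g = codes == 2
    is_n = codes > 3
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_n = np.concatenate([[0], np.cumsum(is_n)])
    cg = is_c[:-1] & is_g[1:]
    cum_cg = np.concatenate([[0], np.cumsum(cg)])

    starts = np.arange(0, n - L + 1)
    nc = cum_c[starts + L] - cum_c[starts]
    ng = cum_g[starts + L] - cum_g[starts]
    nn = cum_n[starts + L] - cum_n[starts]
    # CpG dinucleotides fully inside the window start in [i, i+L-1)
    ncg = cum_cg[starts + L - 1] - cum_cg[starts]
    ok = (
        (nn == 0)
        & (2 * (nc + ng) >= L)
        & (nc > 0)
        & (ng > 0)
        & (10 * ncg * L >= 6 * nc * ng)
    )
    idx = starts[ok]
    if idx.size == 0:
        return []

    # union of qualifying windows (all length L): merge starts within L
    merged: list[tuple[int, int]] = []
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i <= prev + L:
            prev = i
        else:
            merged.append((int(run_start), int(prev + L)))
            run_start = i
            prev = i
    merged.append((int(run_start), int(prev + L)))

    islands: list[CgiInterval] = []
    for s, e in merged:
        while e - s >= L:
            nc_i = int(cum_c[e] - cum_c[s])
            ng_i = int(cum_g[e] - cum_g[s])
            ncg_i = int(cum_cg[e - 1] - cum_cg[s])
            if _window_qualifies(nc_i, ng_i, ncg_i, e - s):
                islands.append(
                    CgiInterval(
                        chrom=chrom,
                        start=s,
                        end=e,
                        gc_fraction=(nc_i + ng_i) / (e - s),
                        obs_exp_cpg=ncg_i * (e - s) / (nc_i * ng_i),
                    )
                )
                break
            s += 1
            e -= 1
    return islands


# --------------------------------------------------------------------------
# Gene classification
# --------------------------------------------------------------------------


def classify_genes(
    genes: Sequence[GeneModel], cgis: Sequence[CgiInterval]
) -> dict[str, str]:
    """CGI-gene iff the single 5'-end base lies inside an island (half-open)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for isl in cgis:
        by_chrom.setdefault(isl.chrom, []).append((isl.start, isl.end))
    for iv in by_chrom.values():
        iv.sort()
    out: dict[str, str] = {}
    for g in genes:
        tss = g.tss
        cls = NONCGI_CLASS
        ivs = by_chrom.get(g.chrom, [])
        j = bisect_right(ivs, (tss, np.inf)) - 1
        if j >= 0 and ivs[j][0] <= tss < ivs[j][1]:
            cls = CGI_CLASS
        out[g.id] = cls
    return out


# --------------------------------------------------------------------------
# Window construction
# --------------------------------------------------------------------------


def _subtract_sorted(
    lo: int, hi: int, starts: np.ndarray, ends: np.ndarray
) -> list[tuple[int, int]]:
    """[lo, hi) minus the merged sorted intervals (starts, ends)."""
    if hi <= lo:
        return []
    out = []
    i = int(np.searchsorted(ends, lo, side="right"))
    cur = lo
    while i < len(starts) and starts[i] < hi:
        if starts[i] > cur:
            out.append((cur, int(starts[i])))
        cur = max(cur, int(ends[i]))
        if cur >= hi:
            break
        i += 1
    if cur < hi:
        out.append((cur, hi))
    return out


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    ivs = sorted((s, e) for s, e in ivs if e > s)
    starts: list[int] = []
    ends: list[int] = []
    for s, e in ivs:
        if starts and s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def build_windows(
    genes: Sequence[GeneModel],
    chrom_lengths: Mapping[str, int],
    *,
    bin_size: int = 200,
    extent: int = 5000,
    anchors: Sequence[str] = ANCHORS,
    bin_range: tuple[int, int] | None = None,
    gene_classes: Mapping[str, str] | None = None,
) -> WindowSet:
    """Construct the distance-indexed, truncated, exon-masked window set.

    ``bin_range`` (lo, hi) restricts bin indices to [lo, hi); the default is
    the full [-extent/bin_size, extent/bin_size).
    """
    if extent % bin_size != 0:
        raise ValueError("bin_size must divide extent")
    nb = extent // bin_size
    lo_bin, hi_bin = bin_range if bin_range is not None else (-nb, nb)
    if lo_bin < -nb or hi_bin > nb:
        raise ValueError("bin_range outside the configured extent")

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        if g.chrom not in chrom_lengths:
            raise ValueError(f"{g.id}: unknown chromosome {g.chrom}")
        clen = chrom_lengths[g.chrom]
        if g.start < 0 or g.end > clen:
            raise ValueError(f"{g.id}: outside chromosome bounds")
        by_chrom.setdefault(g.chrom, []).append(g)

    entries: list[WindowEntry] = []
    for chrom, cgenes in by_chrom.items():
        cgenes = sorted(cgenes, key=lambda g: (g.start, g.end))
        clen = chrom_lengths[chrom]
        ex_starts, ex_ends = _merge_intervals(
            (s, e) for g in cgenes for s, e in g.exons
        )
        n = len(cgenes)
        g_starts = [g.start for g in cgenes]
        g_ends = np.array([g.end for g in cgenes], dtype=np.int64)
        prefmax = np.maximum.accumulate(g_ends)  # max end among genes [0..i]

        for i, g in enumerate(cgenes):
            # keep a flanking base iff strictly nearer to this gene's span
            # than to any other gene's span; equidistant bases are dropped.
            # A gene whose span reaches past this gene's boundary claims the
            # whole flank (distance 0 or a tie at the boundary).
            li = bisect_right(g_starts, g.start - 1)  # first start >= g.start
            m_left = int(prefmax[li - 1]) if li > 0 else -1
            same_start_blocker = bisect_right(g_starts, g.start) - li > 1
            if m_left > g.start or same_start_blocker:
                left_keep = g.start  # flank claimed by an overlapping gene
            elif li > 0:
                left_keep = (g.start + m_left - 1) // 2 + 1  # first kept base
            else:
                left_keep = 0
            ri = bisect_right(g_starts, g.end - 1)  # first start >= g.end
            m_right = max(
                int(prefmax[i - 1]) if i > 0 else -1,
                int(g_ends[i + 1 : ri].max()) if ri > i + 1 else -1,
            )
            if m_right >= g.end:
                right_keep = g.end  # flank claimed (or tied) by another span
            elif ri < n:
                ns = g_starts[ri]
                right_keep = (ns + g.end - 2) // 2 + 1  # exclusive end
            else:
                right_keep = clen
            cls = gene_classes.get(g.id, "all") if gene_classes else "all"
            for anchor in anchors:
                for k in range(lo_bin, hi_bin):
                    span = _bin_genomic_span(g, anchor, k, bin_size)
                    blo, bhi = span
                    # intronic side stays inside the gene; intergenic side is
                    # clipped at the neighbour midpoint (and chromosome ends)
                    intronic = (anchor == TSS) == (k >= 0)
                    if intronic:
                        blo, bhi = max(blo, g.start), min(bhi, g.end)
                    else:
                        upstream_of_gene = (anchor == TSS) == (g.strand == "+")
                        if upstream_of_gene:
                            blo, bhi = max(blo, left_keep), min(bhi, g.start)
                        else:
                            blo, bhi = max(blo, g.end), min(bhi, right_keep)
                        blo = max(blo, 0)
                        bhi = min(bhi, clen)
                    kept = _subtract_sorted(blo, bhi, ex_starts, ex_ends)
                    entries.append(
                        WindowEntry(
                            gene_id=g.id,
                            anchor=anchor,
                            bin_index=k,
                            chrom=chrom,
                            kept=tuple(kept),
                            gene_class=cls,
                        )
                    )
    return WindowSet(bin_size=bin_size, entries=entries)


def _bin_genomic_span(
    g: GeneModel, anchor: str, k: int, bs: int
) -> tuple[int, int]:
    """Genomic half-open span of oriented-distance bin k for one gene.

    Oriented distance runs along the non-template strand; for the TSS anchor
    d=0 is the first transcribed base, for END3 d=0 is the first base past
    the transcript.
    """
    if g.strand == "+":
        a = g.start if anchor == TSS else g.end
        return a + bs * k, a + bs * (k + 1)
    a = g.end if anchor == TSS else g.start
    return a - bs * (k + 1), a - bs * k


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------


def write_genes_bed12(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            offs = ",".join(str(s - g.start) for s, e in g.exons) + ","
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes}\t{offs}\n"
            )


def read_genes_bed12(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",") if x]
            offs = [int(x) for x in f[11].rstrip(",").split(",") if x]
            exons = tuple((start + o, start + o + s) for o, s in zip(offs, sizes))
            genes.append(GeneModel(name, chrom, start, end, strand, exons))
    return genes


def write_cgi_bed(cgis: Sequence[CgiInterval], path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        for i, isl in enumerate(cgis):
            fh.write(
                f"{isl.chrom}\t{isl.start}\t{isl.end}\tCGI_{i}\t"
                f"{isl.gc_fraction:.6f}\t{isl.obs_exp_cpg:.6f}\n"
            )


def read_cgi_bed(path) -> list[CgiInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                CgiInterval(f[0], int(f[1]), int(f[2]), float(f[4]), float(f[5]))
            )
    return out


def write_windowset_tsv(ws: WindowSet, path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("gene_id\tanchor\tbin\tchrom\tkept\tclass\n")
        for e in ws.entries:
            kept = ",".join(f"{s}-{t}" for s, t in e.kept) or "."
            fh.write(
                f"{e.gene_id}\t{e.anchor}\t{e.bin_index}\t{e.chrom}\t{kept}\t"
                f"{e.gene_class}\n"
            )


def read_windowset_tsv(path, bin_size: int = 200) -> WindowSet:
    entries = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            gid, anchor, k, chrom, kept_s, cls = line.rstrip("\n").split("\t")
            kept = (
                tuple(
                    (int(a), int(b))
                    for a, b in (p.split("-") for p in kept_s.split(","))
                )
                if kept_s != "."
                else ()
            )
            entries.append(WindowEntry(gid, anchor, int(k), chrom, kept, cls))
    return WindowSet(bin_size=bin_size, entries=entries)
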