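"""Aligned trinucleotide column extraction and genome-wide pooling.

From MAF alignment blocks, every reference position whose centered triplet
(p-1, p, p+1) is covered by gap-free, unambiguous columns in all species
yields one trinucleotide column.  Columns are restricted to the kept
subintervals of the window set, oriented to the owning gene's non-template
strand (reverse-complemented, flanks swapped, for - strand genes), and
pooled genome-wide per (anchor, distance bin, gene class).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import AlignIO

from .regions import WindowSet
from .seqcodes import BASE_TO_CODE, TRIPLET_REVCOMP, triplet_str

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# MAF input
# --------------------------------------------------------------------------


@dataclasses.dataclass
class MafRow:
    species: str
    chrom: str
    start: int  # 0-based on the source + strand after normalization
    size: int
    strand: str
    src_size: int
    text: str


@dataclasses.dataclass
class MafBlock:
    rows: dict[str, MafRow]

    def normalized(self, ref_species: str) -> "MafBlock":
        """Reference row on the + strand (MAF convention: - strand rows give
        coordinates on the reverse complement)."""
        ref = self.rows[ref_species]
        if ref.strand == "+":
            return self
        comp = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")
        rows = {}
        for sp, r in self.rows.items():
            rows[sp] = MafRow(
                species=sp,
                chrom=r.chrom,
                start=r.src_size - r.start - r.size,
                size=r.size,
                strand="+" if r.strand == "-" else "-",
                src_size=r.src_size,
                text=r.text.translate(comp)[::-1],
            )
        return MafBlock(rows=rows)


def read_maf(path) -> Iterator[MafBlock]:
    """Iterate alignment blocks (species names split from 'species.chrom')."""
    try:
        for aln in AlignIO.parse(path, "maf"):
            rows = {}
            for rec in aln:
                sp, _, chrom = rec.id.partition(".")
                ann = rec.annotations
                rows[sp] = MafRow(
                    species=sp,
                    chrom=chrom,
                    start=int(ann["start"]),
                    size=int(ann["size"]),
                    strand="+" if ann["strand"] in (1, "+") else "-",
                    src_size=int(ann["srcSize"]),
                    text=str(rec.seq),
                )
            yield MafBlock(rows=rows)
    except ValueError as exc:
        raise ValueError(f"malformed MAF {path}: {exc}") from exc


# --------------------------------------------------------------------------
# Triplet extraction
# --------------------------------------------------------------------------


def _block_arrays(block: MafBlock, species: Sequence[str], ref_species: str):
    """Per-species code arrays over alignment columns + ref positions."""
    texts = [block.rows[sp].text for sp in species]
    n = len(texts[0])
    codes = np.empty((len(species), n), dtype=np.uint8)
    for i, t in enumerate(texts):
        codes[i] = BASE_TO_CODE[np.frombuffer(t.encode("ascii"), dtype=np.uint8)]
    ref = block.rows[ref_species]
    ref_codes = codes[species.index(ref_species)]
    ungapped = np.frombuffer(ref.text.encode("ascii"), dtype=np.uint8) != ord("-")
    pos = np.cumsum(ungapped) - 1 + ref.start  # ref position per column
    return codes, pos, ungapped


def extract_triplets(
    block: MafBlock,
    window_subintervals: Sequence[tuple[int, int, int]],
    gene_strand: str,
    species: Sequence[str],
    ref_species: str,
) -> tuple[np.ndarray, np.ndarray]:
    """(bin indices, combined pattern codes) for qualifying sites.

    ``window_subintervals`` is a list of (bin_index, start, end) in
    reference genomic coordinates; intervals may partially overlap the
    block and are clipped.  A site qualifies only if the three alignment
    columns centered on it are gap-free ACGT in every species.  For
    - strand genes each species' triplet is reverse-complemented (flanks
    swapped).  The combined code is sum_i triplet_i * 64**i over the given
    species order.
    """
    block = block.normalized(ref_species)
    missing = [sp for sp in species if sp not in block.rows]
    if missing:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    codes, pos, ungapped = _block_arrays(block, list(species), ref_species)
    n = codes.shape[1]
    if n < 3:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    valid = (codes < 4).all(axis=0)
    okc = valid[:-2] & valid[1:-1] & valid[2:]  # center at column j+1
    tri = (
        codes[:, :-2].astype(np.int64) * 16
        + codes[:, 1:-1].astype(np.int64) * 4
        + codes[:, 2:].astype(np.int64)
    )
    if gene_strand == "-":
        tri = TRIPLET_REVCOMP[tri]
    mult = 64 ** np.arange(len(species), dtype=np.int64)
    combined = (tri * mult[:, None]).sum(axis=0)
    center_pos = pos[1:-1]
    bins_out = []
    codes_out = []
    for bin_index, s, e in window_subintervals:
        sel = okc & (center_pos >= s) & (center_pos < e)
        if sel.any():
            c = combined[sel]
            bins_out.append(np.full(c.shape[0], bin_index, dtype=np.int64))
            codes_out.append(c)
    if not bins_out:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    return np.concatenate(bins_out), np.concatenate(codes_out)


# --------------------------------------------------------------------------
# Pooling
# --------------------------------------------------------------------------


@dataclasses.dataclass
class PatternCounts:
    """Pooled trinucleotide-column counts for one (anchor, bin, class)."""

    anchor: str
    bin_index: int
    gene_class: str
    species: tuple[str, ...]
    codes: np.ndarray  # combined pattern codes, sorted
    counts: np.ndarray

    @property
    def total_sites(self) -> int:
        return int(self.counts.sum())

    def pattern_matrix(self, species: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """(npat, nspecies) per-species triplet codes in the requested order."""
        pats = np.empty((len(self.codes), len(species)), dtype=np.int64)
        for j, sp in enumerate(species):
            i = self.species.index(sp)
            pats[:, j] = (self.codes // 64**i) % 64
        return pats, self.counts.astype(float)

    def ref_triplets(self, ref_species: str) -> np.ndarray:
        i = self.species.index(ref_species)
        return (self.codes // 64**i) % 64

    def composition(self, ref_species: str):
        """Current composition of the reference species over scored sites:
        mononucleotides from the central base, dinucleotides from the
        (central, right-flank) pair (so dinuc[C,G] is the CpG density)."""
        from .model import Composition

        tri = self.ref_triplets(ref_species)
        mid = (tri >> 2) & 3
        right = tri & 3
        mono = np.bincount(mid, weights=self.counts, minlength=4).astype(float)
        mono /= mono.sum()
        dinuc = np.zeros((4, 4))
        np.add.at(dinuc, (mid, right), self.counts)
        dinuc /= dinuc.sum()
        return Composition(mono=mono, dinuc=dinuc)

    def revcomp(self) -> "PatternCounts":
        """Counts as seen from the opposite strand (exact closure)."""
        mult = 64 ** np.arange(len(self.species), dtype=np.int64)
        pats = np.stack([(self.codes // m) % 64 for m in mult])
        rc = (TRIPLET_REVCOMP[pats] * mult[:, None]).sum(axis=0)
        order = np.argsort(rc)
        return dataclasses.replace(
            self, codes=rc[order], counts=self.counts[order].copy()
        )


def pool_counts(
    stream: Iterable[tuple[str, int, str, np.ndarray]],
    species: Sequence[str],
    max_sites_per_key: int | None = None,
) -> list[PatternCounts]:
    """Exact multiset union per (anchor, bin, class), order-invariant.

    ``stream`` yields (anchor, bin_index, gene_class, combined codes array).
    With ``max_sites_per_key``, pooling for a key stops once the cap is
    reached (sites are taken in stream order).
    """
    acc: dict[tuple[str, int, str], dict[int, int]] = {}
    sizes: dict[tuple[str, int, str], int] = {}
    for anchor, bin_index, cls, arr in stream:
        key = (anchor, int(bin_index), cls)
        if max_sites_per_key is not None:
            have = sizes.get(key, 0)
            if have >= max_sites_per_key:
                continue
            arr = arr[: max_sites_per_key - have]
        d = acc.setdefault(key, {})
        uniq, cnt = np.unique(arr, return_counts=True)
        for u, c in zip(uniq.tolist(), cnt.tolist()):
            d[u] = d.get(u, 0) + c
        sizes[key] = sizes.get(key, 0) + int(arr.shape[0])
    out = []
    for (anchor, bin_index, cls), d in sorted(acc.items()):
        codes = np.array(sorted(d), dtype=np.int64)
        counts = np.array([d[c] for c in codes], dtype=np.int64)
        out.append(
            PatternCounts(
                anchor=anchor,
                bin_index=bin_index,
                gene_class=cls,
                species=tuple(species),
                codes=codes,
                counts=counts,
            )
        )
    return out


def count_patterns(
    maf_path,
    windows: WindowSet,
    genes_by_id: Mapping[str, "object"],
    species: Sequence[str],
    ref_species: str,
    max_sites_per_bin: int | None = None,
) -> list[PatternCounts]:
    """Stream MAF blocks against a WindowSet and pool pattern counts."""
    species = sorted(species)
    # flatten kept subintervals, sorted by genomic start for block lookup
    flat = []  # (start, end, bin, anchor, class, strand)
    for e in windows.entries:
        g = genes_by_id[e.gene_id]
        for s, t in e.kept:
            flat.append((s, t, e.bin_index, e.anchor, e.gene_class, g.strand))
    flat.sort(key=lambda x: x[0])
    starts = np.array([f[0] for f in flat], dtype=np.int64)
    ends = np.array([f[1] for f in flat], dtype=np.int64)
    max_len = int((ends - starts).max()) if len(flat) else 0

    def stream():
        skipped = 0
        for block in read_maf(maf_path):
            if ref_species not in block.rows:
                continue
            block = block.normalized(ref_species)
            ref = block.rows[ref_species]
            blo, bhi = ref.start, ref.start + ref.size
            if any(sp not in block.rows for sp in species):
                skipped += 1
                continue
            lo = int(np.searchsorted(starts, blo - max_len))
            hi = int(np.searchsorted(starts, bhi))
            by_strand: dict[str, dict[tuple[str, str], list]] = {}
            for s, t, bin_index, anchor, cls, strand in flat[lo:hi]:
                if t <= blo or s >= bhi:
                    continue
                by_strand.setdefault(strand, {}).setdefault((anchor, cls), []).append(
                    (bin_index, max(s, blo), min(t, bhi))
                )
            for strand, groups in by_strand.items():
                for (anchor, cls), subs in groups.items():
                    bins, combined = extract_triplets(
                        block, subs, strand, species, ref_species
                    )
                    if bins.size == 0:
                        continue
                    for b in np.unique(bins):
                        yield anchor, int(b), cls, combined[bins == b]
        if skipped:
            logger.info("count_patterns: %d blocks skipped (missing species)", skipped)

    return pool_counts(stream(), species, max_sites_per_key=max_sites_per_bin)


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------


def write_patterncounts_tsv(pcs: Sequence[PatternCounts], path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        if pcs:
            fh.write("# species: " + ",".join(pcs[0].species) + "\n")
        fh.write("anchor\tbin\tclass\tpattern\tcount\n")
        for pc in pcs:
            for code, cnt in zip(pc.codes.tolist(), pc.counts.tolist()):
                tris = [
                    triplet_str((code // 64**i) % 64) for i in range(len(pc.species))
                ]
                fh.write(
                    f"{pc.anchor}\t{pc.bin_index}\t{pc.gene_class}\t"
                    f"{'|'.join(tris)}\t{cnt}\n"
                )


def read_patterncounts_tsv(path) -> list[PatternCounts]:
    species: tuple[str, ...] = ()
    acc: dict[tuple[str, int, str], dict[int, int]] = {}
    from .seqcodes import triplet_code

    with open(path) as fh:
        for line in fh:
            if line.startswith("# species:"):
                species = tuple(line.split(":", 1)[1].strip().split(","))
                continue
            if not line.strip() or line.startswith("#") or line.startswith("anchor\t"):
                continue
            anchor, b, cls, pattern, cnt = line.rstrip("\n").split("\t")
            tris = pattern.split("|")
            code = sum(triplet_code(t) * 64**i for i, t in enumerate(tris))
            d = acc.setdefault((anchor, int(b), cls), {})
            d[code] = d.get(code, 0) + int(cnt)
    out = []
    for (anchor, bin_index, cls), d in sorted(acc.items()):
        codes = np.array(sorted(d), dtype=np.int64)
        out.append(
            PatternCounts(
                anchor=anchor,
                bin_index=bin_index,
                gene_class=cls,
                species=species,
                codes=codes,
                counts=np.array([d[c] for c in codes], dtype=np.int64),
            )
        )
    return out
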