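"""Synthetic genomes, annotations and multi-species no-indel alignments.

Ground-truth data for the whole pipeline: a root genome with non-overlapping
genes (a configurable fraction carrying GC-rich, CpG-island-like promoter
segments) is evolved down a phylogeny under known per-branch RateSets by an
exact event-driven simulator.  Position-dependent rate modifiers — step
functions over oriented distance from a gene end, acting on the owning
gene's non-template strand — emulate transcription-associated local and
global substitution asymmetries around TSSs.

The simulator realizes the context-dependent continuous-time process
exactly by thinning: candidate events are drawn from a Poisson process with
a uniform bound on the per-site total rate and accepted with the current
(context- and position-dependent) rates, so a substitution that creates or
destroys a CpG immediately changes its neighbours' rates.  Since no indels
are modelled, leaf sequences align 1:1 positionally and are emitted as
single-block-per-chunk MAF.

Branch "length" is absorbed into the frequencies: each branch is simulated
over unit time with rate = frequency.  Context at the chromosome ends is
circular, avoiding edge special cases.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from typing import Mapping, Sequence

import numpy as np
import numba
import yaml

from . import model as _model
from .model import RateSet, Phylogeny, RC_PROCESS_PERM, N_PROC, SINGLE_INDEX
from .regions import GeneModel, TSS
from .seqcodes import codes_to_seq

CHROM = "chr1"


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclasses.dataclass
class Modifier:
    """Multiplicative factor on one process over an oriented distance range.

    The interval [start, end) is measured in bp of oriented distance from
    ``anchor`` (same convention as window bins: TSS d=0 is the first
    transcribed base); ``end=None`` extends to the gene's 3' end.  The
    process name refers to the owning gene's non-template strand.
    """

    anchor: str
    start: int
    end: int | None
    process: str
    factor: float
    gene_class: str | None = None  # None = all genes, else "CGI" / "nonCGI"

    def __post_init__(self) -> None:
        if self.factor < 0:
            raise ValueError("modifier factors must be >= 0")
        if self.process not in _model.PROCESS_NAMES:
            raise ValueError(f"unknown process {self.process}")


def _default_branch_rates() -> dict[str, float]:
    """Per-branch defaults: vertebrate-like transition/transversion spectrum
    with strong CpG methylation-deamination surcharges."""
    rates = {}
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    for x in "ACGT":
        for y in "ACGT":
            if x != y:
                rates[f"{x}>{y}"] = 0.08 if (x, y) in transitions else 0.03
    rates.update(
        {
            "CpG>TpG": 0.35,
            "CpG>CpA": 0.35,
            "CpG>ApG": 0.06,
            "CpG>CpT": 0.06,
            "CpG>CpC": 0.06,
            "CpG>GpG": 0.06,
        }
    )
    return rates


@dataclasses.dataclass
class SimConfig:
    """Synthetic-genome study conditions (defaults emulate the analyzed
    design: genes exceeding the 5 kb window extent, a majority CGI-gene
    class, a global [A>G] asymmetry along transcripts and a local [C>T]
    asymmetry in the first 2 kb downstream of the TSS)."""

    seed: int = 0
    n_genes: int = 2000
    gene_length: tuple[int, int] = (5100, 5500)
    intergenic_length: tuple[int, int] = (700, 900)
    first_exon_length: tuple[int, int] = (60, 140)
    exon_length: int = 150
    exon_spacing: int = 1200
    cgi_fraction: float = 0.6
    background_gc: float = 0.36
    promoter_gc: float = 0.70
    promoter_halfwidth: int = 300
    tree: str = "((sp1,sp2),sp3);"
    branch_rates: dict = dataclasses.field(default_factory=dict)
    modifiers: list = dataclasses.field(
        default_factory=lambda: [
            # global and local transcription-associated strand asymmetries
            Modifier(TSS, 0, None, "A>G", 1.3),
            Modifier(TSS, 0, 2000, "C>T", 1.4),
            # hypomethylation of CpG-island promoters: methylation-deamination
            # collapses near the TSS of CGI-genes, which also preserves the
            # islands' CpGs over the simulated divergence
            Modifier(TSS, -600, 600, "CpG>TpG", 0.05, gene_class="CGI"),
            Modifier(TSS, -600, 600, "CpG>CpA", 0.05, gene_class="CGI"),
            Modifier(TSS, -600, 600, "CpG>ApG", 0.5, gene_class="CGI"),
            Modifier(TSS, -600, 600, "CpG>CpT", 0.5, gene_class="CGI"),
            Modifier(TSS, -600, 600, "CpG>CpC", 0.5, gene_class="CGI"),
            Modifier(TSS, -600, 600, "CpG>GpG", 0.5, gene_class="CGI"),
        ]
    )

    def __post_init__(self) -> None:
        if self.n_genes < 0 or min(self.gene_length) <= 0 or min(self.intergenic_length) <= 0:
            raise ValueError("lengths and counts must be positive")
        self.modifiers = [
            m if isinstance(m, Modifier) else Modifier(**m) for m in self.modifiers
        ]
        if not self.branch_rates:
            phylo = Phylogeny(self.tree)
            self.branch_rates = {
                name: _default_branch_rates() for name in phylo.branch_names
            }

    def rate_sets(self) -> dict[str, RateSet]:
        out = {}
        for name, r in self.branch_rates.items():
            single = {k: v for k, v in r.items() if not k.startswith("CpG")}
            cpg = {k: v for k, v in r.items() if k.startswith("CpG")}
            out[name] = RateSet(single=single, cpg=cpg)
        return out

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("gene_length", "intergenic_length", "first_exon_length"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclasses.dataclass
class TruthRecord:
    """Realized truth for one branch: per-region effective rates and counts."""

    branch: str
    region_factors: np.ndarray  # (n_regions, 18) multiplicative factors
    event_counts: np.ndarray  # (n_regions, 18) accepted events
    base_rates: np.ndarray  # (18,)

    def effective_rates(self, region: int) -> np.ndarray:
        return self.base_rates * self.region_factors[region]


# --------------------------------------------------------------------------
# Genome construction
# --------------------------------------------------------------------------


@dataclasses.dataclass
class SyntheticGenome:
    seq: np.ndarray  # uint8 root sequence
    genes: list
    cgi_gene_ids: set
    chrom: str
    region_ids: np.ndarray  # (L,) per-position modifier-combination id
    region_factors: np.ndarray  # (n_regions, 18) factors on + strand processes

    @property
    def chrom_length(self) -> int:
        return int(self.seq.shape[0])


def _iid_fill(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _gene_exons(
    rng: np.random.Generator, start: int, end: int, strand: str, cfg: SimConfig
) -> tuple[tuple[int, int], ...]:
    """First exon at the TSS, internal exons at regular spacing, last exon
    at the transcript end; all in genomic coordinates."""
    length = end - start
    fe = int(rng.integers(cfg.first_exon_length[0], cfg.first_exon_length[1] + 1))
    fe = min(fe, length)
    exons = [(0, fe)]
    pos = fe + cfg.exon_spacing
    while pos + cfg.exon_length < length - cfg.exon_length:
        exons.append((pos, pos + cfg.exon_length))
        pos += cfg.exon_spacing + cfg.exon_length
    if length >= cfg.exon_length and exons[-1][1] <= length - cfg.exon_length:
        exons.append((length - cfg.exon_length, length))
    if strand == "+":
        out = [(start + s, start + e) for s, e in exons]
    else:
        out = sorted((end - e, end - s) for s, e in exons)
    return tuple(out)


def _oriented_to_genomic(
    g: GeneModel, anchor: str, d0: int, d1: int
) -> tuple[int, int]:
    """Genomic half-open span of oriented-distance interval [d0, d1)."""
    if g.strand == "+":
        a = g.start if anchor == TSS else g.end
        return a + d0, a + d1
    a = g.end if anchor == TSS else g.start
    return a - d1, a - d0


def _build_regions(
    genes: Sequence[GeneModel],
    chrom_length: int,
    modifiers: Sequence[Modifier],
    cgi_gene_ids: set | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position modifier-combination ids and their +strand factor table.

    Factors of overlapping modifier intervals multiply.  A modifier names a
    process on the owning gene's non-template strand; for - strand genes it
    acts on the complementary process of the + strand.
    """
    cgi_gene_ids = cgi_gene_ids or set()
    region = np.zeros(chrom_length, dtype=np.uint16)
    factors = [tuple([1.0] * N_PROC)]
    combo_id: dict[tuple, int] = {factors[0]: 0}
    for g in genes:
        gcls = "CGI" if g.id in cgi_gene_ids else "nonCGI"
        for m in modifiers:
            if m.gene_class is not None and m.gene_class != gcls:
                continue
            d1 = (g.end - g.start) if m.end is None else m.end
            lo, hi = _oriented_to_genomic(g, m.anchor, m.start, d1)
            lo, hi = max(lo, 0), min(hi, chrom_length)
            if hi <= lo:
                continue
            k = _model.PROCESS_NAMES.index(m.process)
            if g.strand == "-":
                k = int(np.nonzero(RC_PROCESS_PERM == k)[0][0])
            sl = region[lo:hi]
            orig = sl.copy()
            for old in np.unique(orig):
                f = list(factors[old])
                f[k] *= m.factor
                f = tuple(f)
                if f not in combo_id:
                    combo_id[f] = len(factors)
                    factors.append(f)
                sl[orig == old] = combo_id[f]
    return region, np.asarray(factors, dtype=float)


def make_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> SyntheticGenome:
    """Root genome, non-overlapping gene annotation, and CGI truth.

    Deterministic given the config seed.  CGI-gene promoters (oriented
    [-halfwidth, halfwidth) around the TSS) are drawn GC-rich so that
    island detection recovers at least the configured class fraction.
    """
    rng = rng or np.random.default_rng(config.seed)
    genes: list[GeneModel] = []
    spans: list[tuple[int, int, str]] = []
    pos = int(rng.integers(*_pair(config.intergenic_length)))
    for i in range(config.n_genes):
        glen = int(rng.integers(config.gene_length[0], config.gene_length[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        spans.append((pos, pos + glen, strand))
        pos += glen + int(rng.integers(*_pair(config.intergenic_length)))
    chrom_length = pos
    seq = _iid_fill(rng, chrom_length, config.background_gc)

    cgi_ids: set[str] = set()
    for i, (s, e, strand) in enumerate(spans):
        gid = f"g{i:05d}"
        exons = _gene_exons(rng, s, e, strand, config)
        g = GeneModel(gid, CHROM, s, e, strand, exons)
        genes.append(g)
        if rng.random() < config.cgi_fraction:
            cgi_ids.add(gid)
            lo, hi = _oriented_to_genomic(
                g, TSS, -config.promoter_halfwidth, config.promoter_halfwidth
            )
            lo, hi = max(lo, 0), min(hi, chrom_length)
            seq[lo:hi] = _iid_fill(rng, hi - lo, config.promoter_gc)
    region, factors = _build_regions(genes, chrom_length, config.modifiers, cgi_ids)
    return SyntheticGenome(
        seq=seq,
        genes=genes,
        cgi_gene_ids=cgi_ids,
        chrom=CHROM,
        region_ids=region,
        region_factors=factors,
    )


def _pair(t: tuple[int, int]) -> tuple[int, int]:
    return (t[0], t[1] + 1)


# --------------------------------------------------------------------------
# Exact event-driven simulation
# --------------------------------------------------------------------------


@numba.njit(cache=True)
def _thinning_kernel(
    seq, n_candidates, singles, cpg_c, cpg_g, region, ftab, sidx, cidx_c, cidx_g,
    rmax, seed, event_counts,
):  # pragma: no cover - exercised via simulate_branch
    np.random.seed(seed)
    L = seq.shape[0]
    for _ in range(n_candidates):
        p = np.random.randint(0, L)
        b = seq[p]
        left = seq[p - 1] if p > 0 else seq[L - 1]
        right = seq[p + 1] if p < L - 1 else seq[0]
        reg = region[p]
        u = np.random.random() * rmax
        acc = 0.0
        hit = False
        for y in range(4):
            if y == b:
                continue
            r = singles[b, y] * ftab[reg, sidx[b, y]]
            if acc + r > u:
                seq[p] = y
                event_counts[reg, sidx[b, y]] += 1
                hit = True
                break
            acc += r
            if b == 1 and right == 2:  # C of a CpG
                rc = cpg_c[y] * ftab[reg, cidx_c[y]]
                if acc + rc > u:
                    seq[p] = y
                    event_counts[reg, cidx_c[y]] += 1
                    hit = True
                    break
                acc += rc
            elif b == 2 and left == 1:  # G of a CpG
                rg = cpg_g[y] * ftab[reg, cidx_g[y]]
                if acc + rg > u:
                    seq[p] = y
                    event_counts[reg, cidx_g[y]] += 1
                    hit = True
                    break
                acc += rg
        # not hit: thinned (candidate rejected), sequence unchanged


_SIDX = np.zeros((4, 4), dtype=np.int64)
for (_x, _y), _k in SINGLE_INDEX.items():
    _SIDX[_x, _y] = _k
_CIDX_C = np.zeros(4, dtype=np.int64)
_CIDX_G = np.zeros(4, dtype=np.int64)
for _k, (_name, _side, _tgt) in enumerate(_model.CPG_DEFS):
    if _side == "C":
        _CIDX_C[_tgt] = 12 + _k
    else:
        _CIDX_G[_tgt] = 12 + _k


def simulate_branch(
    sequence: np.ndarray,
    rates: RateSet,
    rng: np.random.Generator,
    region_ids: np.ndarray | None = None,
    region_factors: np.ndarray | None = None,
    duration: float = 1.0,
    branch: str = "",
) -> tuple[np.ndarray, TruthRecord]:
    """Exact continuous-time simulation of one branch (default unit time).

    ``sequence`` is a uint8 code array (not modified).  Context is
    recomputed after every event; modifiers are applied per position via
    ``region_ids``/``region_factors``.
    """
    seq = np.ascontiguousarray(sequence, dtype=np.uint8).copy()
    L = seq.shape[0]
    if region_ids is None:
        region_ids = np.zeros(L, dtype=np.uint16)
        region_factors = np.ones((1, N_PROC))
    ftab = np.ascontiguousarray(region_factors, dtype=np.float64)
    singles = rates.single_matrix()
    cpg_c, cpg_g = rates.cpg_side_vectors()
    # uniform bound on the per-site total rate over all bases and regions
    base_tot = np.array(
        [
            (singles[b] * ftab[:, _SIDX[b]]).sum(axis=1)
            + (cpg_c * ftab[:, _CIDX_C]).sum(axis=1) * (b == 1)
            + (cpg_g * ftab[:, _CIDX_G]).sum(axis=1) * (b == 2)
            for b in range(4)
        ]
    )
    rmax = float(base_tot.max())
    event_counts = np.zeros((ftab.shape[0], N_PROC), dtype=np.int64)
    if rmax > 0 and L > 0:
        n_cand = int(rng.poisson(L * rmax * duration))
        seed = int(rng.integers(0, 2**31 - 1))
        _thinning_kernel(
            seq, n_cand, singles, cpg_c, cpg_g,
            np.ascontiguousarray(region_ids, dtype=np.uint16), ftab,
            _SIDX, _CIDX_C, _CIDX_G, rmax, seed, event_counts,
        )
    truth = TruthRecord(
        branch=branch,
        region_factors=ftab,
        event_counts=event_counts,
        base_rates=rates.to_vector(),
    )
    return seq, truth


def simulate_tree(
    root_sequence: np.ndarray,
    tree: str | Phylogeny,
    branch_rates: Mapping[str, RateSet],
    seed: int,
    region_ids: np.ndarray | None = None,
    region_factors: np.ndarray | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, TruthRecord]]:
    """Recursive branch simulation; leaves align positionally 1:1."""
    phylo = tree if isinstance(tree, Phylogeny) else Phylogeny(tree)
    node_seq: dict[int, np.ndarray] = {phylo.root: np.asarray(root_sequence, dtype=np.uint8)}
    truths: dict[str, TruthRecord] = {}
    leaves: dict[str, np.ndarray] = {}
    ss = np.random.SeedSequence(seed)
    children_seeds = ss.spawn(phylo.n_branches)
    for n in range(phylo.n_nodes - 1, -1, -1):  # parents before children
        if n == phylo.root:
            pass
        for c in phylo.children[n]:
            b = phylo.branch_of_node[c]
            name = phylo.branch_names[b]
            rng = np.random.default_rng(children_seeds[b])
            node_seq[c], truths[name] = simulate_branch(
                node_seq[n],
                branch_rates[name],
                rng,
                region_ids,
                region_factors,
                branch=name,
            )
        if not phylo.children[n]:
            leaves[phylo.node_names[n]] = node_seq[n]
    return leaves, truths


# --------------------------------------------------------------------------
# Output
# --------------------------------------------------------------------------


def write_fasta(path, seq: np.ndarray, chrom: str = CHROM, width: int = 80) -> None:
    s = codes_to_seq(seq)
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(s), width):
            fh.write(s[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def write_maf(
    path,
    leaf_seqs: Mapping[str, np.ndarray],
    chrom: str = CHROM,
    ref_species: str | None = None,
    block_size: int = 500_000,
) -> None:
    """No-indel alignment as MAF blocks (reference row first)."""
    species = sorted(leaf_seqs)
    if ref_species is None:
        ref_species = species[0]
    order = [ref_species] + [s for s in species if s != ref_species]
    L = len(next(iter(leaf_seqs.values())))
    with open(path, "w") as fh:
        fh.write("##maf version=1 scoring=none\n")
        fh.write("# no-indel synthetic alignment\n\n")
        for lo in range(0, L, block_size):
            hi = min(lo + block_size, L)
            fh.write("a score=0.0\n")
            for sp in order:
                seg = codes_to_seq(np.asarray(leaf_seqs[sp][lo:hi]))
                fh.write(f"s {sp}.{chrom} {lo} {hi - lo} + {L} {seg}\n")
            fh.write("\n")


def write_truth_tsv(path, truths: Mapping[str, TruthRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("branch\tregion\tprocess\tbase_rate\tfactor\teffective_rate\tevents\n")
        for name, tr in truths.items():
            for reg in range(tr.region_factors.shape[0]):
                for k, proc in enumerate(_model.PROCESS_NAMES):
                    fh.write(
                        f"{name}\t{reg}\t{proc}\t{tr.base_rates[k]:.6g}\t"
                        f"{tr.region_factors[reg, k]:.6g}\t"
                        f"{tr.base_rates[k] * tr.region_factors[reg, k]:.6g}\t"
                        f"{tr.event_counts[reg, k]}\n"
                    )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture(config: SimConfig, outdir) -> dict:
    """Generate and write the full fixture; returns the checksum manifest."""
    os.makedirs(outdir, exist_ok=True)
    genome = make_genome(config)
    leaves, truths = simulate_tree(
        genome.seq,
        config.tree,
        config.rate_sets(),
        seed=config.seed + 1,
        region_ids=genome.region_ids,
        region_factors=genome.region_factors,
    )
    phylo = Phylogeny(config.tree)
    ref = phylo.species[0]
    from .regions import write_genes_bed12  # local to avoid cycle at import

    paths = {
        "genome.fa": lambda p: write_fasta(p, leaves[ref], genome.chrom),
        "genes.bed": lambda p: write_genes_bed12(genome.genes, p),
        "alignment.maf": lambda p: write_maf(p, leaves, genome.chrom, ref),
        "tree.nwk": lambda p: open(p, "w").write(config.tree + "\n"),
        "truth.tsv": lambda p: write_truth_tsv(p, truths),
        "config.yaml": lambda p: config.to_yaml(p),
    }
    manifest = {}
    for name, writer in paths.items():
        full = os.path.join(outdir, name)
        writer(full)
        manifest[name] = _sha256(full)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
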