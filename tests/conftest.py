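import numpy as np
import pytest

from txsubst import Phylogeny, RateSet, SimConfig, make_genome, simulate_tree
from txsubst.simulate import write_maf, write_fasta
from txsubst.regions import write_genes_bed12

FOURTAXON = "(((sp1,sp2),sp3),sp4);"
THREETAXON = "((sp1,sp2),sp3);"


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20100618)


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A small synthetic dataset shared by IO-level tests: 30 genes,
    three species, single MAF block."""
    d = tmp_path_factory.mktemp("smallfix")
    cfg = SimConfig(
        seed=11,
        n_genes=30,
        gene_length=(2100, 2500),
        intergenic_length=(500, 800),
    )
    genome = make_genome(cfg)
    leaves, truths = simulate_tree(
        genome.seq, cfg.tree, cfg.rate_sets(), seed=12,
        region_ids=genome.region_ids, region_factors=genome.region_factors,
    )
    phylo = Phylogeny(cfg.tree)
    ref = phylo.species[0]
    write_fasta(d / "genome.fa", leaves[ref], genome.chrom)
    write_genes_bed12(genome.genes, d / "genes.bed")
    write_maf(d / "alignment.maf", leaves, genome.chrom, ref, block_size=10**9)
    (d / "tree.nwk").write_text(cfg.tree + "\n")
    return {
        "dir": d,
        "config": cfg,
        "genome": genome,
        "leaves": leaves,
        "truths": truths,
        "phylo": phylo,
        "ref": ref,
    }


def random_rateset(rng, lo=0.005, hi=0.05, cpg_ts=(0.2, 0.4), cpg_tv=(0.02, 0.08)):
    v = np.empty(18)
    v[:12] = rng.uniform(lo, hi, 12)
    v[12:14] = rng.uniform(*cpg_ts, size=2)
    v[14:] = rng.uniform(*cpg_tv, size=4)
    return RateSet.from_vector(v)
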