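# Methods

## The model

Sequence evolution is modeled as a continuous-time Markov process on
nucleotides that is neither stationary nor time-reversible.  Each branch of
a rooted species tree carries 18 free parameters: the twelve single-base
substitution frequencies [X→Y] plus six CpG-context processes
(CpG→TpG, CpG→CpA, CpG→ApG, CpG→CpT, CpG→CpC, CpG→GpG) modeled as additive
surcharges on the corresponding single-base process whenever the mutating
base forms a CpG with its neighbor.  Parameters are *frequencies* —
expected substitutions per site along the branch, with time absorbed — so
no molecular clock links branches, and the composition at the root is a
free (empirical) distribution rather than the equilibrium of the process.
All frequencies refer to the non-template (coding) strand of the gene a
window belongs to.

Because neighbors matter, the likelihood unit is the trinucleotide column:
every aligned site contributes the column of centered triplets across
species (overlapping sites share flanks — a composite likelihood).  The
generator on the 64 triplet states applies the CpG surcharge wherever both
CpG partners are visible in the window; branch transition matrices are
matrix exponentials, and column probabilities come from Felsenstein pruning
over the 64 states with the root distribution fixed to the pooled observed
leaf triplet distribution (a softmax-parameterized free root is available
behind `root_mode="free"`).

### Conditional composite likelihood

The default estimation objective is the *conditional* composite likelihood
log P(triplet columns) − log P(flank columns): the probability of the
central bases given the observed flanks.  The outermost positions of a
triplet can form CpGs with neighbors outside the window; modeling them with
visible-context-only rates biases the single-base frequencies upward (edge
G→A and C→T absorb unseen CpG context) and the CpG surcharges downward.
Conditioning on the flanks cancels this first-order edge misspecification
while preserving the context dependence of the central position, whose CpG
partners are always visible.  Parameter-recovery simulations directly
validate the choice (see Limitations for what remains).  For the joint
(non-conditional) objective, six additional per-branch "edge" nuisance
frequencies — effective CpG surcharges for the two invisible-partner edge
cases — are estimated alongside the 18 reported processes.

### Optimization

Bounded L-BFGS-B on all branch frequencies jointly (bounds [0, 0.75), the
sub-saturation cap), with analytic gradients: the generator is linear in
the frequencies, so each gradient needs the Fréchet derivatives of the
matrix exponential along fixed structure matrices.  These are computed by
the eigendecomposition (Daleckiǐ–Kreǐn) formula with a divided-difference
table, validated against scipy's Padé-based `expm_frechet` and falling back
to it when the eigenbasis is ill-conditioned or the result fails sanity
checks.  Likelihood and gradient accumulate over cache-sized chunks of
patterns.  A 1e-10 uniform mixture on each transition matrix keeps every
pattern probability strictly positive (with an exactly consistent
gradient), so the line search never encounters a clamped plateau.
Initialization is moment-based (half the observed mismatch fraction
between the closest leaf pair spanning each branch); `restarts` perturbed
starts (default 3) guard against local optima, and profile-stage fits warm
start from the neighboring bin with a single start.  Convergence is a
relative log-likelihood change below `ftol` (default 1e-9).  Branches
adjacent to the root are estimated jointly but flagged non-identifiable and
excluded from headline reports, matching the identifiability structure of a
free-root non-reversible model.

### Stationary composition

GC*, stationary skews and the stationary composition come from a
dinucleotide mean-field (pair-closure) fixed point: the 16 dinucleotide
frequencies evolve under the context-dependent dynamics with triplet
probabilities closed as P(abc) = f(ab)·f(bc)/m(b), integrated by explicit
Euler steps (dt = 0.25/max total rate) until the L1 change per unit time
falls below 1e-8.  Single-base frequencies are floored at 1e-12 inside this
computation only, guaranteeing irreducibility.  For CpG-free rate sets the
pair closure factorizes and agrees with the exact 4-state null-space solve
(`stationary_4state`, the cross-check oracle) to the iteration tolerance;
with CpG surcharges it agrees with the long-run composition of the exact
sequence simulator within Monte-Carlo error on 1e5-site sequences (tested).

## Windows and annotation

Coordinates are 0-based half-open throughout.  Around each gene's 5' end
(TSS = first transcribed base) and 3' end, 200 bp bins are indexed by
oriented distance along the non-template strand (bin k covers
[200k, 200(k+1)); for the 3' anchor d=0 is the first base past the
transcript).  Bins are truncated at the midpoint to the nearest neighboring
gene span on either strand — a flanking base is kept only if strictly
nearer to the owning gene's span than to any other gene's span, equidistant
bases are dropped, and a gene whose span reaches past the boundary claims
the whole flank (this makes the rule exactly mirror-symmetric, which the
strand-closure checks exploit).  Intronic-side bins never extend past the
gene's other end, so genes shorter than 5 kb contribute truncated intronic
coverage.  Every exonic base of any gene on either strand is masked.

CpG islands use the Gardiner–Garden-style definition (≥400 bp, GC ≥ 0.5,
observed/expected CpG ≥ 0.6 with obs/exp = N_CG·L/(N_C·N_G)): 400 bp
windows slide at 1 bp steps, qualifying windows are unioned, and each
merged interval is re-verified and symmetrically trimmed (one base off each
end per step) until it qualifies or drops below 400 bp.  All threshold
comparisons are exact integer arithmetic.  A gene is CGI-class iff its
single 5'-end base lies inside an island.

Per-site trinucleotide columns are taken from MAF blocks; a site qualifies
only if the three centered alignment columns are gap-free ACGT in every
species.  The current ("observed") composition of a bin is measured on the
reference species over exactly the scored sites: mononucleotides from the
central base, dinucleotides (including the CpG density) from the
(center, right-flank) pair.

## Derived statistics

Per (anchor, bin, class, branch): the five complementary ratios
[A→G]/[T→C], [C→T]/[G→A], [G→T]/[C→A], [C→G]/[G→C], [A→T]/[T→A]; the
weak→strong and strong→weak frequencies

    [W→S] = ([A]([A→C]+[A→G]) + [T]([T→C]+[T→G])) / ([A]+[T])
    [S→W] = ([C]([C→A]+[C→T]) + [G]([G→A]+[G→T])
             + [CpG]([CpG→TpG]+[CpG→CpA]+[CpG→ApG]+[CpG→CpT])) / ([C]+[G])

with the [CpG] term dropped in the non-CpG variant (the S→S processes
CpG→CpC and CpG→GpG never enter); TA and GC skews ([T]−[A])/([T]+[A]) and
([G]−[C])/([G]+[C])) of the current and stationary compositions; current GC
and GC*.  In the source study these two equations appear only as an
unrecoverable image; the form above is reconstructed from the surrounding
definitions and should be read with that caveat.  Zero denominators produce
NaN markers, never exceptions.  Uncertainty, when requested, is a
gene-level nonparametric bootstrap (resample genes with replacement,
re-pool, re-estimate; 2.5/97.5 percentiles), off by default because each
replicate costs a full count+estimate pass.

## Synthetic data

The generator writes the ground truth for every pipeline stage: an iid
background genome (GC 0.36 by default — vertebrate-like AT richness; real
genomes are additionally CpG-depleted, which the iid background is not),
non-overlapping genes with a first exon at the TSS, regularly spaced
internal exons and a terminal exon, and GC-rich (GC 0.70) promoter segments
over oriented [−300, 300) for a configurable CGI-class fraction (0.6 by
default).  Defaults are sized so genes exceed the 5 kb window extent
(5.1–5.5 kb genes, 0.7–0.9 kb intergenic, 2000 genes).

Evolution down the tree (default ((sp1,sp2),sp3)) is simulated *exactly* by
thinning: candidate events form a Poisson process bounded by the maximum
per-site rate and are accepted with the current context- and
position-dependent rates, so CpG creation/destruction feeds back
immediately.  Chromosome ends use circular context.  Branch defaults are
transitions 0.08, transversions 0.03, CpG→TpG/CpA 0.35 and CpG transversion
surcharges 0.06 per branch — a vertebrate-like spectrum sized so that
per-bin ratio estimates at the default pooling depth resolve the injected
asymmetries.  Position-dependent modifiers multiply a process's rate over
an oriented distance interval of the owning gene (on its non-template
strand; complemented for − genes).  The default modifier set encodes the
transcription-associated patterns under study: [A→G] ×1.3 along the whole
transcript (global asymmetry), [C→T] ×1.4 over the first 2 kb downstream of
the TSS (local asymmetry), and CpG-surcharge suppression (×0.05
transitions, ×0.5 transversions) within ±600 bp of CGI-class TSSs —
promoter hypomethylation, which is also what lets the islands survive the
simulated divergence, as in real genomes.  What the generator does *not*
emulate: indels (none are simulated, so alignments are trivial and MAF
blocks positional), isochore structure, CpG-depleted backgrounds,
recombination or selection; passing tests therefore validate the
machinery under the stated mutational model, not robustness to alignment
error or compositional heterogeneity of real data.

The realized truth (per-region effective rates and accepted event counts
per process) is written alongside the fixture with a checksum manifest;
regeneration from the same config is byte-identical.

## Pipeline

`simulate → regions → counts → estimate → profile`, all driven by one
config and one seed; every artifact carries a provenance header (version,
config hash, seed) and re-runs are bit-identical.  Relevant knobs:
`max_sites_per_bin` caps pooled sites per (anchor, bin, class) in stream
order (a variance/runtime control), `merge_classes` pools CGI and nonCGI
genes, `bin_min`/`bin_max` and `anchors` restrict the profile,
`warm_start` toggles bin-chained initialization.

## Problem sizes and numerical choices in the shipped checks

The test suite and the acceptance script scale the study down to sizes a
single CPU handles comfortably while keeping each check's statistical
margin: parameter recovery uses the four-taxon tree at 2×10⁵ pooled sites;
the end-to-end profile run uses the full 2000-gene genome with the TSS
anchor, merged classes and 200k pooled sites per bin in single precision
(per-bin log-ratio dispersion ≈2.7% once read from the pooled identifiable
branches, against asserted margins of ≥8%); the strand-closure run uses 60
genes, bins −1..1 at `ftol` 1e-12 with cold starts so the mirrored
optimizations follow near-identical paths, comparing identifiable branches
(root-adjacent parameters sit on flat likelihood directions and are not
determined to that precision); the acceptance script's profile run uses
300 genes and 60k sites per bin.  Mean-field/simulator cross-checks use
1e5-site sequences equilibrated for 150 unit-time branch applications with
block-estimated Monte-Carlo standard errors.

## Known limitations

- The closed-triplet composite likelihood is an approximation of the
  sequence process.  Conditioning on flanks removes the first-order edge
  bias, but the split between CpG transversion surcharges sharing an
  opportunity process (e.g. CpG→ApG vs CpG→GpG) remains weakly identified
  when CpG→TpG/CpA are large (ancestral CpG context decays before the
  transversion's order can be resolved): their sum is recovered well, the
  split carries several-fold the naive binomial error.  Single-base
  frequencies and the strong CpG transitions — everything entering the
  reported ratios, skews, W→S/S→W and GC* — are recovered tightly.
- The mean-field stationary composition is a pair closure, exact only in
  the CpG-free limit; against the exact simulator it agrees within
  Monte-Carlo error at 1e5 sites.
- Root-adjacent branches are structurally non-identifiable and reported
  only as flagged estimates.
- The bootstrap resamples genes, not alignment columns; within-gene
  autocorrelation beyond genes is not captured.
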