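"""Neighbor-dependent (CpG) substitution model over trinucleotide states.

The model follows a non-stationary, time-irreversible continuous-time Markov
description of single-nucleotide evolution in which each branch of a rooted
phylogeny carries its own set of 18 substitution frequencies: the 12 ordered
single-base processes [X->Y] plus 6 additional CpG-context processes
(CpG->TpG, CpG->CpA, CpG->ApG, CpG->CpT, CpG->CpC, CpG->GpG) that act as
additive surcharges on the corresponding single-base process whenever the
mutating position forms a CpG with a neighbor.  Branch "length" is absorbed
into the frequencies (expected substitutions per site along the branch), so
no molecular clock is assumed and the root composition is free rather than
stationary.

Likelihoods are computed over trinucleotide alignment columns (64 states per
species) by Felsenstein pruning; every aligned site contributes its own
centered triplet, giving a composite likelihood for neighbor-dependent
rates.  Estimation is bounded quasi-Newton (L-BFGS-B) with analytic
gradients obtained from Frechet derivatives of the matrix exponential.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg
from scipy.optimize import minimize

import dendropy

from .seqcodes import BASES, N_TRIPLETS, triplet_code

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# Process bookkeeping
# --------------------------------------------------------------------------

#: the 12 ordered single-base processes, (from, to) in A,C,G,T encoding
SINGLE_PAIRS: list[tuple[int, int]] = [
    (x, y) for x in range(4) for y in range(4) if x != y
]
SINGLE_INDEX = {pair: k for k, pair in enumerate(SINGLE_PAIRS)}
SINGLE_NAMES = [f"{BASES[x]}>{BASES[y]}" for x, y in SINGLE_PAIRS]

#: CpG-context processes: (name, side, target). side "C" means the C of the
#: CpG mutates (e.g. CpG->TpG is C->T); side "G" means the G mutates.
CPG_DEFS: list[tuple[str, str, int]] = [
    ("CpG>TpG", "C", 3),
    ("CpG>CpA", "G", 0),
    ("CpG>ApG", "C", 0),
    ("CpG>CpT", "G", 3),
    ("CpG>CpC", "G", 1),
    ("CpG>GpG", "C", 2),
]
CPG_NAMES = [name for name, _, _ in CPG_DEFS]
CPG_INDEX = {name: 12 + k for k, (name, _, _) in enumerate(CPG_DEFS)}

PROCESS_NAMES = SINGLE_NAMES + CPG_NAMES
N_PROC = 18

# CpG side lookup: for a mutating C followed by G, surcharge index per target
_CPG_C_SIDE = {tgt: 12 + k for k, (_, side, tgt) in enumerate(CPG_DEFS) if side == "C"}
_CPG_G_SIDE = {tgt: 12 + k for k, (_, side, tgt) in enumerate(CPG_DEFS) if side == "G"}

# complementary-process permutation: [X>Y] <-> [X'>Y']; C-side CpG process
# with target y <-> G-side process with target y'
RC_PROCESS_PERM = np.empty(N_PROC, dtype=np.int64)
for _k, (_x, _y) in enumerate(SINGLE_PAIRS):
    RC_PROCESS_PERM[_k] = SINGLE_INDEX[(3 - _x, 3 - _y)]
for _k, (_name, _side, _tgt) in enumerate(CPG_DEFS):
    _other = _CPG_G_SIDE if _side == "C" else _CPG_C_SIDE
    RC_PROCESS_PERM[12 + _k] = _other[3 - _tgt]


def _build_structure_tensor() -> np.ndarray:
    """S[k] is d(generator)/d(frequency k): one 64x64 matrix per process."""
    S = np.zeros((N_PROC, N_TRIPLETS, N_TRIPLETS))

    def add(k: int, i: int, j: int) -> None:
        S[k, i, j] += 1.0
        S[k, i, i] -= 1.0

    for a in range(4):
        for b in range(4):
            for c in range(4):
                t = 16 * a + 4 * b + c
                # position 0 (only a visible CpG partner is b to its right)
                for y in range(4):
                    if y == a:
                        continue
                    j = 16 * y + 4 * b + c
                    add(SINGLE_INDEX[(a, y)], t, j)
                    if a == 1 and b == 2:  # a is the C of a CpG
                        add(_CPG_C_SIDE[y], t, j)
                # position 1 (both neighbors visible)
                for y in range(4):
                    if y == b:
                        continue
                    j = 16 * a + 4 * y + c
                    add(SINGLE_INDEX[(b, y)], t, j)
                    if a == 1 and b == 2:  # b is the G of CpG "ab"
                        add(_CPG_G_SIDE[y], t, j)
                    elif b == 1 and c == 2:  # b is the C of CpG "bc"
                        add(_CPG_C_SIDE[y], t, j)
                # position 2
                for y in range(4):
                    if y == c:
                        continue
                    j = 16 * a + 4 * b + y
                    add(SINGLE_INDEX[(c, y)], t, j)
                    if b == 1 and c == 2:  # c is the G of CpG "bc"
                        add(_CPG_G_SIDE[y], t, j)
    return S


STRUCTURE_TENSOR = _build_structure_tensor()


def _build_edge_tensors() -> tuple[np.ndarray, np.ndarray]:
    """Structure tensors for CpG surcharges whose partner lies outside the
    triplet: position 0 as the G of a CpG with an invisible left C (weight
    pi_C), and position 2 as the C of a CpG with an invisible right G
    (weight pi_G)."""
    Eg = np.zeros((N_PROC, N_TRIPLETS, N_TRIPLETS))
    Ec = np.zeros((N_PROC, N_TRIPLETS, N_TRIPLETS))
    for a in range(4):
        for b in range(4):
            for c in range(4):
                t = 16 * a + 4 * b + c
                if a == 2:  # position 0 G, possible invisible left C
                    for y in range(4):
                        if y == a:
                            continue
                        j = 16 * y + 4 * b + c
                        k = _CPG_G_SIDE[y]
                        Eg[k, t, j] += 1.0
                        Eg[k, t, t] -= 1.0
                if c == 1:  # position 2 C, possible invisible right G
                    for y in range(4):
                        if y == c:
                            continue
                        j = 16 * a + 4 * b + y
                        k = _CPG_C_SIDE[y]
                        Ec[k, t, j] += 1.0
                        Ec[k, t, t] -= 1.0
    return Eg, Ec


EDGE_TENSOR_GLEFT, EDGE_TENSOR_CRIGHT = _build_edge_tensors()

#: Extended direction tensor for estimation: the 18 reported processes plus
#: 6 edge-context nuisance processes per branch.  A triplet's outermost
#: positions can form a CpG with a neighbour outside the window (position 0
#: as the G of a CpG whose C is invisible; position 2 as the C of a CpG
#: whose G is invisible); those positions receive their own freely-estimated
#: effective surcharges (the true surcharge times the unknown probability
#: that the invisible partner completes a CpG), so that edge dynamics cannot
#: bias the reported single-base and CpG frequencies.
_EDGE_G_PROCS = [12 + k for k, (_, side, _t) in enumerate(CPG_DEFS) if side == "G"]
_EDGE_C_PROCS = [12 + k for k, (_, side, _t) in enumerate(CPG_DEFS) if side == "C"]
EXTENDED_TENSOR = np.concatenate(
    [
        STRUCTURE_TENSOR,
        EDGE_TENSOR_GLEFT[_EDGE_G_PROCS],
        EDGE_TENSOR_CRIGHT[_EDGE_C_PROCS],
    ]
)
N_PROC_EXT = EXTENDED_TENSOR.shape[0]
EDGE_NUISANCE_NAMES = [
    "edge:" + CPG_NAMES[k - 12] for k in _EDGE_G_PROCS + _EDGE_C_PROCS
]

MAX_FREQUENCY = 0.75  # sub-saturation bound on any single frequency


# --------------------------------------------------------------------------
# RateSet
# --------------------------------------------------------------------------


@dataclasses.dataclass
class RateSet:
    """The 18 per-branch substitution frequencies (per bp, non-template strand).

    ``single`` maps the 12 ordered base pairs "X>Y" to frequencies;
    ``cpg`` maps the six CpG-context process names to additive surcharges.
    """

    single: dict[str, float]
    cpg: dict[str, float]

    def __post_init__(self) -> None:
        missing = [n for n in SINGLE_NAMES if n not in self.single]
        missing += [n for n in CPG_NAMES if n not in self.cpg]
        if missing:
            raise ValueError(f"missing processes: {missing}")
        for name, v in {**self.single, **self.cpg}.items():
            if v < 0:
                raise ValueError(f"negative frequency for {name}: {v}")
            if v >= MAX_FREQUENCY:
                raise ValueError(
                    f"frequency for {name} = {v} exceeds the sub-saturation "
                    f"bound {MAX_FREQUENCY}"
                )

    # -- conversions -------------------------------------------------------

    def to_vector(self) -> np.ndarray:
        v = np.empty(N_PROC)
        for k, name in enumerate(SINGLE_NAMES):
            v[k] = self.single[name]
        for k, name in enumerate(CPG_NAMES):
            v[12 + k] = self.cpg[name]
        return v

    @classmethod
    def from_vector(cls, v: Sequence[float]) -> "RateSet":
        v = np.asarray(v, dtype=float)
        if v.shape != (N_PROC,):
            raise ValueError("expected 18 frequencies")
        return cls(
            single={n: float(v[k]) for k, n in enumerate(SINGLE_NAMES)},
            cpg={n: float(v[12 + k]) for k, n in enumerate(CPG_NAMES)},
        )

    @classmethod
    def uniform(cls, single: float = 0.0, cpg: float = 0.0) -> "RateSet":
        v = np.concatenate([np.full(12, single), np.full(6, cpg)])
        return cls.from_vector(v)

    @classmethod
    def zero(cls) -> "RateSet":
        return cls.uniform()

    def revcomp(self) -> "RateSet":
        """RateSet seen from the opposite strand ([X>Y] <-> [X'>Y'])."""
        v = self.to_vector()
        out = np.empty_like(v)
        out[RC_PROCESS_PERM] = v
        return RateSet.from_vector(out)

    def is_strand_symmetric(self, tol: float = 0.0) -> bool:
        v = self.to_vector()
        return bool(np.all(np.abs(v - v[RC_PROCESS_PERM]) <= tol))

    def single_matrix(self) -> np.ndarray:
        """4x4 matrix of single-base frequencies (diagonal zero)."""
        m = np.zeros((4, 4))
        for k, (x, y) in enumerate(SINGLE_PAIRS):
            m[x, y] = self.single[SINGLE_NAMES[k]]
        return m

    def cpg_side_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """(C-side, G-side) surcharge per target base (length-4 vectors)."""
        c_side = np.zeros(4)
        g_side = np.zeros(4)
        for k, (name, side, tgt) in enumerate(CPG_DEFS):
            if side == "C":
                c_side[tgt] = self.cpg[name]
            else:
                g_side[tgt] = self.cpg[name]
        return c_side, g_side


# --------------------------------------------------------------------------
# Generator / transition matrix
# --------------------------------------------------------------------------


def build_generator(rates: RateSet | np.ndarray) -> np.ndarray:
    """64x64 generator over trinucleotide states for one branch.

    Off-diagonal entries are the frequency of the corresponding
    single-position change; the CpG surcharge applies whenever the mutating
    position forms a CpG with a neighbor visible inside the triplet.
    """
    if isinstance(rates, RateSet):
        theta = rates.to_vector()
    else:
        theta = np.asarray(rates, dtype=float)
        if np.any(theta < 0):
            raise ValueError("negative frequency")
    return np.tensordot(theta, STRUCTURE_TENSOR, axes=(0, 0))


def transition_matrix(generator: np.ndarray) -> np.ndarray:
    """exp(Q): the per-branch trinucleotide substitution probabilities."""
    P = scipy.linalg.expm(generator)
    # exp of a generator is stochastic up to roundoff
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def _expm_and_frechet(Q: np.ndarray, directions: np.ndarray):
    """exp(Q) and its Frechet derivatives along each direction.

    Uses the eigendecomposition (Daleckii-Krein) formula with a divided
    difference table; falls back to scipy's Pade-based expm_frechet when the
    eigenvector basis is ill-conditioned.
    """
    def _pade_fallback():
        P = scipy.linalg.expm(Q)
        F = np.stack(
            [scipy.linalg.expm_frechet(Q, E, compute_expm=False) for E in directions]
        )
        return P, F

    try:
        lam, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        cond = np.linalg.norm(V, 2) * np.linalg.norm(Vinv, 2)
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e8:
        return _pade_fallback()
    elam = np.exp(lam)
    P = np.real((V * elam) @ Vinv)
    d = lam[:, None] - lam[None, :]
    mid = np.exp((lam[:, None] + lam[None, :]) / 2.0)
    half = d / 2.0
    small = np.abs(half) < 1e-6
    half_safe = np.where(small, 1.0, half)
    sinch = np.where(small, 1.0 + half * half / 6.0, np.sinh(half_safe) / half_safe)
    phi = mid * sinch  # divided difference (e^li - e^lj)/(li - lj)
    G = Vinv @ directions @ V  # (k, 64, 64)
    F = np.real(V @ (G * phi) @ Vinv)
    # a near-defective eigenbasis can slip past the condition estimate and
    # produce silently wrong magnitudes; validate before trusting
    fmax = np.abs(directions).max() * 10.0 + 10.0
    if (
        not np.isfinite(P).all()
        or not np.isfinite(F).all()
        or np.abs(P.sum(axis=1) - 1.0).max() > 1e-8
        or np.abs(F).max() > fmax * cond
    ):
        return _pade_fallback()
    return P, F


# --------------------------------------------------------------------------
# Phylogeny
# --------------------------------------------------------------------------


class Phylogeny:
    """Rooted tree with per-branch RateSets and a root state distribution.

    Each non-root node owns the branch above it; branch names are the leaf
    label for terminal branches and "+"-joined sorted descendant leaves for
    internal branches.  Branches adjacent to the root are flagged
    non-identifiable: with a free root composition and independent
    frequencies per branch, only branches not directly connected to the root
    are reliably estimable.
    """

    def __init__(
        self,
        newick: str,
        rates: Mapping[str, RateSet] | None = None,
        root_distribution: np.ndarray | None = None,
    ):
        tree = dendropy.Tree.get(data=newick, schema="newick")
        self.newick = newick
        nodes = list(tree.postorder_node_iter())
        self._index = {id(nd): i for i, nd in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.root = self.n_nodes - 1
        self.children: list[list[int]] = []
        self.node_names: list[str] = []
        leaf_labels: list[str] = []
        for nd in nodes:
            ch = [self._index[id(c)] for c in nd.child_nodes()]
            self.children.append(ch)
            if not ch:
                label = nd.taxon.label.replace(" ", "_")
                leaf_labels.append(label)
                self.node_names.append(label)
            else:
                leaves_below = sorted(
                    lf for c in ch for lf in self.node_names[c].split("+")
                )
                self.node_names.append("+".join(leaves_below))
        self.species = sorted(leaf_labels)
        self.leaf_species_index = [
            self.species.index(self.node_names[i]) if not self.children[i] else -1
            for i in range(self.n_nodes)
        ]
        # branches = all non-root nodes, postorder
        self.branch_nodes = [i for i in range(self.n_nodes) if i != self.root]
        self.branch_names = [self.node_names[i] for i in self.branch_nodes]
        self.branch_of_node = {n: b for b, n in enumerate(self.branch_nodes)}
        root_children = set(self.children[self.root])
        self.root_adjacent = [n in root_children for n in self.branch_nodes]
        self.rates = dict(rates) if rates else {}
        self.root_distribution = (
            None if root_distribution is None else np.asarray(root_distribution, float)
        )
        if self.root_distribution is not None:
            s = self.root_distribution.sum()
            if not np.isclose(s, 1.0, atol=1e-8):
                raise ValueError("root_distribution must sum to 1")

    @property
    def n_branches(self) -> int:
        return len(self.branch_nodes)

    def theta_matrix(self) -> np.ndarray:
        """(n_branches, 18) frequency matrix in branch order."""
        th = np.empty((self.n_branches, N_PROC))
        for b, name in enumerate(self.branch_names):
            if name not in self.rates:
                raise KeyError(f"no RateSet for branch {name}")
            th[b] = self.rates[name].to_vector()
        return th


#: flank-pair code (left, right) of each triplet code, for middle-base
#: marginalization in the conditional likelihood
FLANK_OF_CODE = np.array([(t >> 4) * 4 + (t & 3) for t in range(N_TRIPLETS)])


def _pruning(
    phylo: Phylogeny,
    Ps: np.ndarray,
    root_dist: np.ndarray,
    leaf_codes: np.ndarray,
    leaf_Ps: np.ndarray | None = None,
) -> tuple[np.ndarray, list, list]:
    """Upward pass.  Returns (per-pattern likelihood, msgs, below).

    ``leaf_Ps`` optionally replaces the transition matrices used for the
    leaf-message gathers (e.g. middle-marginalized 64x16 matrices, with
    ``leaf_codes`` then holding flank codes)."""
    if leaf_Ps is None:
        leaf_Ps = Ps
    msgs: list = [None] * phylo.n_nodes  # message through branch above node
    below: list = [None] * phylo.n_nodes  # product of children messages / leaf codes
    for n in range(phylo.n_nodes):
        ch = phylo.children[n]
        if not ch:
            obs = leaf_codes[phylo.leaf_species_index[n]]
            below[n] = obs  # store codes for leaves
            if n != phylo.root:
                msgs[n] = leaf_Ps[phylo.branch_of_node[n]][:, obs]
        else:
            w = msgs[ch[0]].copy()
            for c in ch[1:]:
                w *= msgs[c]
            below[n] = w
            if n != phylo.root:
                msgs[n] = Ps[phylo.branch_of_node[n]] @ w
    L = root_dist @ below[phylo.root]
    return L, msgs, below


def loglik_patterns(
    phylo: Phylogeny,
    patterns: np.ndarray,
    root_dist: np.ndarray | None = None,
    theta: np.ndarray | None = None,
) -> np.ndarray:
    """Per-pattern log-likelihoods for (npat, nspecies) triplet codes."""
    if theta is None:
        theta = phylo.theta_matrix()
    if root_dist is None:
        root_dist = phylo.root_distribution
        if root_dist is None:
            raise ValueError("phylogeny has no root distribution")
    Ps = np.stack(
        [transition_matrix(build_generator(theta[b])) for b in range(phylo.n_branches)]
    )
    leaf_codes = np.asarray(patterns, dtype=np.int64).T.copy()
    L, _, _ = _pruning(phylo, Ps, root_dist, leaf_codes)
    with np.errstate(divide="ignore"):
        return np.log(L)


def column_loglik(phylo: Phylogeny, column: Sequence[str] | Sequence[int]) -> float:
    """Log-probability of one trinucleotide column (ordered by phylo.species).

    A zero-probability column under a degenerate root distribution yields
    ``-inf``.
    """
    codes = [triplet_code(c) if isinstance(c, str) else int(c) for c in column]
    if len(codes) != len(phylo.species):
        raise ValueError("column length must match the number of species")
    return float(loglik_patterns(phylo, np.asarray([codes]))[0])


# --------------------------------------------------------------------------
# Maximum-likelihood estimation
# --------------------------------------------------------------------------


@dataclasses.dataclass
class EstimateOptions:
    restarts: int = 3
    maxiter: int = 600
    ftol: float = 1e-9
    seed: int = 0
    root_mode: str = "empirical"  # or "free"
    objective: str = "conditional"  # or "joint"
    dtype: str = "float64"  # "float32" halves the per-pattern pass cost
    edge_context: str = "free"  # joint objective only: or "visible-only"
    polish: int = 0  # extra L-BFGS rounds restarted from the solution
    init_theta: np.ndarray | None = None
    lower: float = 0.0
    upper: float = MAX_FREQUENCY - 1e-6


@dataclasses.dataclass
class FitReport:
    loglik: float
    converged: bool
    nit: int
    nstarts: int
    message: str
    identifiable: dict[str, bool]
    total_sites: float
    edge_nuisance: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)


def _empirical_root_distribution(
    patterns: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Pooled observed leaf trinucleotide distribution."""
    dist = np.zeros(N_TRIPLETS)
    for s in range(patterns.shape[1]):
        np.add.at(dist, patterns[:, s], weights)
    dist /= dist.sum()
    return dist


def _leaf_pair_for_branch(phylo: Phylogeny, node: int) -> tuple[int, int]:
    """A representative (leaf inside, nearest leaf outside) species pair."""

    def leaves_below(n: int) -> list[int]:
        ch = phylo.children[n]
        if not ch:
            return [n]
        return [lf for c in ch for lf in leaves_below(c)]

    inside = leaves_below(node)
    all_leaves = leaves_below(phylo.root)
    outside = [lf for lf in all_leaves if lf not in inside]
    u = inside[0]
    w = outside[0] if outside else all_leaves[0]
    return phylo.leaf_species_index[u], phylo.leaf_species_index[w]


def _moment_init(
    phylo: Phylogeny, patterns: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Initial frequencies: half the observed mismatch fraction between the
    two most closely related leaves spanning each branch."""
    mid = (patterns >> 2) & 3
    left = patterns >> 4
    right = patterns & 3
    theta0 = np.empty((phylo.n_branches, N_PROC))
    for b, node in enumerate(phylo.branch_nodes):
        su, sw = _leaf_pair_for_branch(phylo, node)
        mu, mw = mid[:, su], mid[:, sw]
        for k, (x, y) in enumerate(SINGLE_PAIRS):
            denom = weights[mu == x].sum()
            num = weights[(mu == x) & (mw == y)].sum()
            frac = num / denom if denom > 0 else 0.0
            theta0[b, k] = np.clip(frac / 2.0, 1e-4, 0.3)
        for k, (name, side, tgt) in enumerate(CPG_DEFS):
            if side == "C":
                ctx = (mu == 1) & (right[:, su] == 2)
            else:
                ctx = (mu == 2) & (left[:, su] == 1)
            denom = weights[ctx].sum()
            num = weights[ctx & (mw == tgt)].sum()
            frac = num / denom if denom > 0 else 0.0
            theta0[b, 12 + k] = np.clip(frac / 2.0, 1e-3, 0.5)
    return theta0


_P_MIX = 1e-10
_CHUNK = 4096  # patterns per block; keeps the (64, chunk) work arrays in cache


def _chunk_ll_and_M(
    phylo: Phylogeny,
    Ps: np.ndarray,
    root_dist: np.ndarray,
    leaf_codes: np.ndarray,
    weights: np.ndarray,
    Ms: np.ndarray | None,
    root_grad: np.ndarray | None = None,
    marginalize_middle: bool = False,
    dtype=np.float64,
) -> float:
    """Log-likelihood; if ``Ms`` is given, accumulate per-branch dL/dP there.

    Processes patterns in cache-sized chunks.  ``Ms`` has shape
    (n_branches, 64, 64); the gradient wrt frequency k of branch b is then
    <Fs[b, k], Ms[b]> with Fs the Frechet derivatives of expm.

    With ``marginalize_middle`` the leaf observations are reduced to their
    flank pairs (the middle base is summed out), yielding the denominator
    of the conditional (middle-given-flanks) likelihood.

    With ``dtype`` float32 the per-pattern passes run in single precision
    (the log-likelihood and Ms still accumulate in double); any chunk whose
    smallest pattern probability underflows float32 is transparently redone
    in double precision, so boundary parameter values remain safe.
    """
    nb = phylo.n_branches
    npat = leaf_codes.shape[1]
    use32 = dtype == np.float32
    if use32:
        Ps_lo = Ps.astype(np.float32)
        root_lo = root_dist.astype(np.float32)
    else:
        Ps_lo, root_lo = Ps, root_dist
    if marginalize_middle:
        # 64x16 middle-marginalized leaf matrices; leaf_codes must already
        # hold flank codes (see _aggregate_flanks)
        leaf_Ps = np.stack(
            [
                np.add.reduceat(
                    Ps[b][:, np.argsort(FLANK_OF_CODE, kind="stable")],
                    np.arange(0, 64, 4),
                    axis=1,
                )
                for b in range(nb)
            ]
        )
        n_leaf_states = 16
        leaf_Ps_lo = leaf_Ps.astype(np.float32) if use32 else leaf_Ps
    else:
        leaf_Ps = leaf_Ps_lo = None
        n_leaf_states = N_TRIPLETS

    ll = 0.0
    for lo in range(0, npat, _CHUNK):
        hi = min(lo + _CHUNK, npat)
        lc = leaf_codes[:, lo:hi]
        w = weights[lo:hi]
        m = hi - lo
        P_c, r_c, lp_c = Ps_lo, root_lo, leaf_Ps_lo
        L, msgs, below = _pruning(phylo, P_c, r_c, lc, lp_c)
        if use32 and bool((L <= 0).any()):
            # a pattern probability underflowed single precision: redo the
            # chunk in double so objective and gradient stay consistent
            P_c, r_c, lp_c = Ps, root_dist, leaf_Ps
            L, msgs, below = _pruning(phylo, P_c, r_c, lc, lp_c)
        L = L.astype(np.float64)
        # zero-probability patterns are clamped; their gradient contribution
        # is dropped so that objective and gradient stay consistent for the
        # line search
        Lc = np.clip(L, 1e-290, None)
        ll += float(w @ np.log(Lc))
        coef = np.where(L > 1e-290, w / Lc, 0.0)
        if root_grad is not None:
            root_grad += below[phylo.root] @ coef
        if Ms is None:
            continue
        coef = coef.astype(P_c.dtype)
        f: list = [None] * phylo.n_nodes
        for n in range(phylo.n_nodes - 1, -1, -1):  # reverse postorder
            ch = phylo.children[n]
            if n == phylo.root:
                for c in ch:
                    fc = np.broadcast_to(r_c[:, None], (N_TRIPLETS, m))
                    for c2 in ch:
                        if c2 != c:
                            fc = fc * msgs[c2]
                    f[c] = np.ascontiguousarray(fc)
            elif ch:
                base = P_c[phylo.branch_of_node[n]].T @ f[n]
                for c in ch:
                    fc = base
                    for c2 in ch:
                        if c2 != c:
                            fc = fc * msgs[c2]
                    f[c] = np.ascontiguousarray(fc)
            if n != phylo.root:
                b = phylo.branch_of_node[n]
                fn = f[n] * coef
                if phylo.children[n]:
                    Ms[b] += fn @ below[n].T
                else:
                    obs = below[n]
                    Mleaf = np.empty((N_TRIPLETS, n_leaf_states))
                    for i in range(N_TRIPLETS):  # group columns by observed code
                        Mleaf[i] = np.bincount(
                            obs, weights=fn[i].astype(np.float64),
                            minlength=n_leaf_states,
                        )
                    if marginalize_middle:
                        Ms[b] += Mleaf[:, FLANK_OF_CODE]
                    else:
                        Ms[b] += Mleaf
    return ll


def _aggregate_flanks(
    leaf_codes: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Unique flank-pair patterns with summed weights (the conditional
    denominator has at most 16^nspecies distinct patterns)."""
    fl = FLANK_OF_CODE[leaf_codes]  # (nleaf, npat)
    key = np.zeros(fl.shape[1], dtype=np.int64)
    for row in fl:
        key = key * 16 + row
    uniq, inv = np.unique(key, return_inverse=True)
    w = np.bincount(inv, weights=weights)
    nleaf = fl.shape[0]
    out = np.empty((nleaf, len(uniq)), dtype=np.int64)
    rem = uniq.copy()
    for i in range(nleaf - 1, -1, -1):
        out[i] = rem % 16
        rem //= 16
    return out, w


def _nll_and_grad(
    theta_flat: np.ndarray,
    phylo: Phylogeny,
    leaf_codes: np.ndarray,
    weights: np.ndarray,
    root_dist: np.ndarray,
    directions: np.ndarray | None = None,
    conditional: bool = True,
    den: tuple[np.ndarray, np.ndarray] | None = None,
    dtype=np.float64,
) -> tuple[float, np.ndarray]:
    """Negative (conditional) composite log-likelihood and its gradient.

    With ``conditional`` (the default) the objective is the probability of
    the middle bases given the observed flank columns,
    log P(triplets) - log P(flanks): flank positions act as observed
    context, so their approximate edge dynamics cannot bias the estimates.
    """
    nb = phylo.n_branches
    if directions is None:
        directions = STRUCTURE_TENSOR
    npr = directions.shape[0]
    theta = theta_flat.reshape(nb, npr)
    Ps = np.empty((nb, N_TRIPLETS, N_TRIPLETS))
    Fs = np.empty((nb, npr, N_TRIPLETS, N_TRIPLETS))
    for b in range(nb):
        Q = np.tensordot(theta[b], directions, axes=(0, 0))
        Ps[b], Fs[b] = _expm_and_frechet(Q, directions)
    # tiny uniform mixture keeps every pattern probability strictly positive
    # (and the gradient exactly consistent), so the line search never meets
    # a flat clamped plateau
    Ps = (1.0 - _P_MIX) * Ps + _P_MIX / N_TRIPLETS
    Fs *= 1.0 - _P_MIX
    Ms = np.zeros((nb, N_TRIPLETS, N_TRIPLETS))
    ll = _chunk_ll_and_M(
        phylo, Ps, root_dist, leaf_codes, weights, Ms, dtype=dtype
    )
    if conditional:
        if den is None:
            den = _aggregate_flanks(leaf_codes, weights)
        Ms_den = np.zeros((nb, N_TRIPLETS, N_TRIPLETS))
        ll -= _chunk_ll_and_M(
            phylo, Ps, root_dist, den[0], den[1], Ms_den,
            marginalize_middle=True,
        )
        Ms -= Ms_den
    grad = np.einsum("bkij,bij->bk", Fs, Ms)
    return -ll, -grad.ravel()


def estimate_rates(
    counts,
    tree: str | Phylogeny,
    options: EstimateOptions | None = None,
) -> tuple[dict[str, RateSet], FitReport]:
    """Maximum composite-likelihood estimation of per-branch RateSets.

    ``counts`` is either a PatternCounts-like object exposing
    ``pattern_matrix(species)`` or a tuple ``(patterns, weights)`` with
    ``patterns`` an (npat, nspecies) array of triplet codes ordered by the
    phylogeny's sorted species list.

    Root-adjacent branches are estimated jointly but flagged
    non-identifiable in the report.
    """
    opts = options or EstimateOptions()
    phylo = tree if isinstance(tree, Phylogeny) else Phylogeny(tree)
    if hasattr(counts, "pattern_matrix"):
        patterns, weights = counts.pattern_matrix(phylo.species)
    else:
        patterns, weights = counts
    patterns = np.asarray(patterns, dtype=np.int64)
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("total_sites must be positive")

    root_dist = (
        phylo.root_distribution
        if phylo.root_distribution is not None and opts.root_mode == "fixed"
        else _empirical_root_distribution(patterns, weights)
    )
    conditional = opts.objective == "conditional"
    if conditional:
        # flanks are conditioned on; edge nuisance would be unidentified
        directions = STRUCTURE_TENSOR
    else:
        directions = (
            EXTENDED_TENSOR if opts.edge_context == "free" else STRUCTURE_TENSOR
        )
    npr = directions.shape[0]
    leaf_codes = patterns.T.copy()
    nb = phylo.n_branches
    bounds = [(opts.lower, opts.upper)] * (nb * npr)

    theta0 = (
        np.asarray(opts.init_theta, dtype=float)
        if opts.init_theta is not None
        else _moment_init(phylo, patterns, weights)
    )
    if theta0.shape[1] < npr:
        # edge-context nuisance starts at a small fraction of the surcharge
        extra = np.concatenate(
            [0.1 * theta0[:, [CPG_INDEX[n] for n in ("CpG>CpA", "CpG>CpT", "CpG>CpC")]],
             0.1 * theta0[:, [CPG_INDEX[n] for n in ("CpG>TpG", "CpG>ApG", "CpG>GpG")]]],
            axis=1,
        )
        theta0 = np.concatenate([theta0, extra], axis=1)
    theta0 = np.clip(theta0, opts.lower + 1e-8, opts.upper - 1e-8)
    den = _aggregate_flanks(leaf_codes, weights) if conditional else None

    if opts.root_mode == "free":
        return _estimate_free_root(
            phylo, leaf_codes, weights, root_dist, theta0, opts, directions,
            conditional, den,
        )

    rng = np.random.default_rng(opts.seed)
    best = None
    nstarts = max(1, opts.restarts)
    for s in range(nstarts):
        x0 = theta0.ravel().copy()
        if s > 0:
            x0 = np.clip(
                x0 * rng.lognormal(0.0, 0.5, size=x0.shape),
                opts.lower + 1e-8,
                opts.upper - 1e-8,
            )
        res = minimize(
            _nll_and_grad,
            x0,
            args=(
                phylo, leaf_codes, weights, root_dist, directions, conditional,
                den, np.float32 if opts.dtype == "float32" else np.float64,
            ),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": opts.maxiter, "ftol": opts.ftol, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
    for _ in range(opts.polish):
        # a fresh quasi-Newton state often escapes slow-progress plateaus,
        # tightening agreement between equivalent optimizations
        res = minimize(
            _nll_and_grad,
            best.x.copy(),
            args=(
                phylo, leaf_codes, weights, root_dist, directions, conditional,
                den, np.float32 if opts.dtype == "float32" else np.float64,
            ),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": opts.maxiter, "ftol": opts.ftol, "gtol": 1e-7},
        )
        if res.fun < best.fun:
            best = res
    theta_hat = best.x.reshape(nb, npr)
    rates = {
        phylo.branch_names[b]: RateSet.from_vector(theta_hat[b, :N_PROC])
        for b in range(nb)
    }
    edge = (
        {phylo.branch_names[b]: theta_hat[b, N_PROC:].copy() for b in range(nb)}
        if npr > N_PROC
        else {}
    )
    report = FitReport(
        loglik=-float(best.fun),
        converged=bool(best.success),
        nit=int(best.nit),
        nstarts=nstarts,
        message=str(best.message),
        identifiable={
            phylo.branch_names[b]: not phylo.root_adjacent[b] for b in range(nb)
        },
        total_sites=float(weights.sum()),
        edge_nuisance=edge,
    )
    if not best.success:
        logger.warning("estimate_rates did not converge: %s", best.message)
    return rates, report


def _estimate_free_root(
    phylo, leaf_codes, weights, root_dist0, theta0, opts, directions, conditional,
    den=None,
):
    """Joint estimation with a softmax-parameterized free root distribution."""
    nb = phylo.n_branches
    npr = directions.shape[0]
    nth = nb * npr

    def fun(x):
        theta_flat = x[:nth]
        logits = x[nth:]
        z = np.exp(logits - logits.max())
        pi = z / z.sum()
        theta = theta_flat.reshape(nb, npr)
        Ps = np.empty((nb, N_TRIPLETS, N_TRIPLETS))
        Fs = np.empty((nb, npr, N_TRIPLETS, N_TRIPLETS))
        for b in range(nb):
            Q = np.tensordot(theta[b], directions, axes=(0, 0))
            Ps[b], Fs[b] = _expm_and_frechet(Q, directions)
        Ps = (1.0 - _P_MIX) * Ps + _P_MIX / N_TRIPLETS
        Fs *= 1.0 - _P_MIX
        Ms = np.zeros((nb, N_TRIPLETS, N_TRIPLETS))
        dll_dpi = np.zeros(N_TRIPLETS)
        ll = _chunk_ll_and_M(phylo, Ps, pi, leaf_codes, weights, Ms, dll_dpi)
        if conditional:
            dcodes, dw = den if den is not None else _aggregate_flanks(
                leaf_codes, weights
            )
            Ms_den = np.zeros((nb, N_TRIPLETS, N_TRIPLETS))
            dpi_den = np.zeros(N_TRIPLETS)
            ll -= _chunk_ll_and_M(
                phylo, Ps, pi, dcodes, dw, Ms_den, dpi_den,
                marginalize_middle=True,
            )
            Ms -= Ms_den
            dll_dpi -= dpi_den
        gth = np.einsum("bkij,bij->bk", Fs, Ms).ravel()
        dll_dlogits = pi * (dll_dpi - pi @ dll_dpi)
        return -ll, np.concatenate([-gth, -dll_dlogits])

    x0 = np.concatenate(
        [theta0.ravel(), np.log(np.clip(root_dist0, 1e-8, None))]
    )
    bounds = [(opts.lower, opts.upper)] * nth + [(None, None)] * N_TRIPLETS
    res = minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": opts.maxiter, "ftol": opts.ftol, "gtol": 1e-7},
    )
    theta_hat = res.x[:nth].reshape(nb, npr)
    rates = {
        phylo.branch_names[b]: RateSet.from_vector(theta_hat[b, :N_PROC])
        for b in range(nb)
    }
    report = FitReport(
        loglik=-float(res.fun),
        converged=bool(res.success),
        nit=int(res.nit),
        nstarts=1,
        message=str(res.message),
        identifiable={
            phylo.branch_names[b]: not phylo.root_adjacent[b] for b in range(nb)
        },
        total_sites=float(weights.sum()),
        edge_nuisance=(
            {phylo.branch_names[b]: theta_hat[b, N_PROC:].copy() for b in range(nb)}
            if npr > N_PROC
            else {}
        ),
    )
    return rates, report


# --------------------------------------------------------------------------
# Stationary composition
# --------------------------------------------------------------------------


@dataclasses.dataclass
class Composition:
    """Mono- and dinucleotide frequencies of a (real or stationary) sequence."""

    mono: np.ndarray  # (4,) frequencies of A, C, G, T
    dinuc: np.ndarray  # (4,4) frequencies of ordered pairs; dinuc[C,G] is [CpG]

    def __post_init__(self) -> None:
        self.mono = np.asarray(self.mono, dtype=float)
        self.dinuc = np.asarray(self.dinuc, dtype=float)
        if not np.isclose(self.mono.sum(), 1.0, atol=1e-6):
            raise ValueError("mononucleotide frequencies must sum to 1")

    @property
    def gc(self) -> float:
        return float(self.mono[1] + self.mono[2])

    @property
    def cpg_density(self) -> float:
        return float(self.dinuc[1, 2])

    @classmethod
    def from_mono(cls, mono: np.ndarray) -> "Composition":
        mono = np.asarray(mono, dtype=float)
        return cls(mono=mono, dinuc=np.outer(mono, mono))


def context_rate_tensor(rates: RateSet, floor: float = 0.0) -> np.ndarray:
    """R[a, b, c, y]: rate of middle base b->y in left/right context (a, c)."""
    singles = np.maximum(rates.single_matrix(), floor)
    np.fill_diagonal(singles, 0.0)
    c_side, g_side = rates.cpg_side_vectors()
    R = np.broadcast_to(singles[None, :, None, :], (4, 4, 4, 4)).copy()
    R[1, 2, :, :] += g_side[None, :]  # left neighbor C, middle G
    R[:, 1, 2, :] += c_side[None, :]  # middle C, right neighbor G
    for b in range(4):
        R[:, b, :, b] = 0.0
    return R


def _check_irreducible(singles: np.ndarray) -> None:
    """Raise if the 4-state single-base dynamics is not irreducible."""
    reach = (singles > 0) | np.eye(4, dtype=bool)
    for _ in range(4):
        reach = reach | (reach @ reach)
    if not reach.all():
        bad = sorted(
            {BASES[y] for x in range(4) for y in range(4) if not reach[x, y]}
        )
        raise ValueError(f"reducible dynamics: unreachable states {bad}")


def stationary_composition(
    rates: RateSet,
    tol: float = 1e-8,
    floor: float = 1e-12,
    dt_safety: float = 0.25,
    max_iter: int = 5_000_000,
) -> Composition:
    """Stationary composition under the context-dependent dynamics.

    Fixed point of the dinucleotide mean-field (pair-closure) update: the
    16-dim dinucleotide frequency vector is evolved under the dynamics, with
    triplet probabilities closed as P(abc) = f(ab) f(bc) / m(b), until the
    L1 change per unit time drops below ``tol``.  Single-base frequencies
    are floored at ``floor`` to guarantee irreducibility.
    """
    R = context_rate_tensor(rates, floor=floor)
    if floor <= 0.0:
        _check_irreducible(np.maximum(rates.single_matrix(), 0.0))
    total = R.sum(axis=3)  # T[a, b, c]: total exit rate of middle b in (a, c)
    dt = dt_safety / max(total.max(), 1e-30)
    f = np.full((4, 4), 1.0 / 16.0)
    converged = False
    for _ in range(max_iter):
        m = f.sum(axis=1)
        m_safe = np.where(m > 1e-300, m, 1.0)
        # pair closure: P(w, u, z) = f(w,u) f(u,z) / m(u)
        P3 = f[:, :, None] * (f / m_safe[:, None])[None, :, :]
        # left member of pair (x, y) mutates: triplet (w, x', y)
        left_gain = np.einsum("wpy,wpyx->xy", P3, R)
        left_loss = np.einsum("wxy,wxy->xy", P3, total)
        # right member of pair (x, y) mutates: triplet (x, y', z)
        right_gain = np.einsum("xqz,xqzy->xy", P3, R)
        right_loss = np.einsum("xyz,xyz->xy", P3, total)
        df = left_gain - left_loss + right_gain - right_loss
        f = f + dt * df
        np.clip(f, 0.0, None, out=f)
        f /= f.sum()
        if np.abs(df).sum() < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "stationary_composition: mean-field iteration did not reach "
            "L1 change < %g within %d iterations", tol, max_iter
        )
    mono = (f.sum(axis=1) + f.sum(axis=0)) / 2.0
    mono /= mono.sum()
    return Composition(mono=mono, dinuc=f)


def stationary_4state(rates: RateSet) -> Composition:
    """Null-space stationary composition of the 4-state single-base generator.

    Cross-check oracle for CpG-free RateSets: with all surcharges zero the
    sites decouple and the stationary composition is the left null vector of
    the 4x4 generator.  Raises on CpG surcharges or reducible dynamics.
    """
    c_side, g_side = rates.cpg_side_vectors()
    if np.any(c_side > 0) or np.any(g_side > 0):
        raise ValueError("stationary_4state requires all CpG surcharges to be 0")
    singles = rates.single_matrix()
    _check_irreducible(singles)
    Q = singles.copy()
    np.fill_diagonal(Q, -singles.sum(axis=1))
    ns = scipy.linalg.null_space(Q.T)
    if ns.shape[1] != 1:  # pragma: no cover - guarded by irreducibility check
        raise ValueError("generator null space is not one-dimensional")
    pi = ns[:, 0]
    pi = pi / pi.sum()
    if np.any(pi < -1e-9):
        raise ValueError("negative stationary probabilities")
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    return Composition.from_mono(pi)
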