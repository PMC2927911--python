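"""Substitution model: generator construction, likelihoods, estimation,
stationary compositions."""

import numpy as np
import pytest

from txsubst import model as M
from txsubst.model import (
    EstimateOptions,
    Phylogeny,
    RateSet,
    build_generator,
    column_loglik,
    estimate_rates,
    stationary_4state,
    stationary_composition,
    transition_matrix,
)
from txsubst.seqcodes import triplet_code

from conftest import FOURTAXON, random_rateset


def vec(**kw):
    v = np.zeros(18)
    for name, val in kw.items():
        key = name.replace("_", ">")
        if key in M.CPG_INDEX:
            v[M.CPG_INDEX[key]] = val
        else:
            v[M.SINGLE_INDEX[(M.BASES.index(key[0]), M.BASES.index(key[2]))]] = val
    return v


class TestGenerator:
    def test_zero_rates_zero_matrix(self):
        assert np.all(build_generator(RateSet.zero()) == 0)

    @pytest.mark.parametrize(
        "rates, src, dst, expected",
        [
            (vec(A_G=0.1), "AAA", "AGA", 0.1),
            (vec(A_G=0.1), "AAA", "GAA", 0.1),
            (vec(A_G=0.1), "AAA", "AGG", 0.0),
            (vec(C_T=0.01, CpG_TpG=0.4), "ACG", "ATG", 0.41),
            (vec(C_T=0.01, CpG_TpG=0.4), "ACT", "ATT", 0.01),
            # G-side surcharge inside the triplet
            (vec(G_A=0.02, CpG_CpA=0.3), "CGA", "CAA", 0.32),
            (vec(G_A=0.02, CpG_CpA=0.3), "TGA", "TAA", 0.02),
        ],
    )
    def test_entries(self, rates, src, dst, expected):
        Q = build_generator(rates)
        assert Q[triplet_code(src), triplet_code(dst)] == pytest.approx(expected)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            build_generator(-0.1 * np.ones(18))
        with pytest.raises(ValueError):
            RateSet.uniform(single=-0.01)

    def test_sub_saturation_bound(self):
        with pytest.raises(ValueError):
            RateSet.uniform(single=0.8)

    def test_diagonal_is_negative_row_sum(self, rng):
        Q = build_generator(random_rateset(rng))
        assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)
        off = Q - np.diag(np.diag(Q))
        assert np.all(off >= 0)


class TestTransitionMatrix:
    def test_zero_rates_identity(self):
        P = transition_matrix(build_generator(RateSet.zero()))
        assert np.allclose(P, np.eye(64), atol=1e-14)

    def test_two_state_closed_form(self):
        # only A>G active; middle A with T_T flanks has no competing process
        P = transition_matrix(build_generator(vec(A_G=0.1)))
        assert P[triplet_code("TAT"), triplet_code("TGT")] == pytest.approx(
            1 - np.exp(-0.1), abs=1e-12
        )

    def test_rows_sum_to_one(self, rng):
        for _ in range(3):
            P = transition_matrix(build_generator(random_rateset(rng)))
            assert np.allclose(P.sum(axis=1), 1, atol=1e-12)
            assert np.all(P >= 0)


class TestFrechet:
    def test_matches_scipy(self, rng):
        import scipy.linalg as sla

        for _ in range(3):
            Q = build_generator(random_rateset(rng))
            P, F = M._expm_and_frechet(Q, M.STRUCTURE_TENSOR)
            assert np.allclose(P, sla.expm(Q), atol=1e-11)
            for k in [0, 7, 13]:
                ref = sla.expm_frechet(Q, M.STRUCTURE_TENSOR[k], compute_expm=False)
                assert np.allclose(F[k], ref, atol=1e-10)


class TestColumnLoglik:
    def test_zero_rates_point_root(self):
        ph = Phylogeny(
            FOURTAXON,
            rates={n: RateSet.zero() for n in Phylogeny(FOURTAXON).branch_names},
            root_distribution=np.eye(64)[0],
        )
        assert column_loglik(ph, ["AAA"] * 4) == 0.0
        assert column_loglik(ph, ["AAA", "AAA", "AAA", "AAC"]) == -np.inf

    def test_matches_bruteforce_enumeration(self, rng):
        ph = Phylogeny(FOURTAXON)
        theta = rng.uniform(0.002, 0.08, (ph.n_branches, 18))
        root = rng.dirichlet(np.ones(64))
        pats = rng.integers(0, 64, (20, 4))
        ll = M.loglik_patterns(ph, pats, root_dist=root, theta=theta)
        Ps = {
            ph.branch_names[b]: transition_matrix(build_generator(theta[b]))
            for b in range(ph.n_branches)
        }
        P1, P2, P3, P4 = (Ps[s] for s in ("sp1", "sp2", "sp3", "sp4"))
        P12, P123 = Ps["sp1+sp2"], Ps["sp1+sp2+sp3"]
        for pat, expected in zip(pats, ll):
            x1, x2, x3, x4 = pat
            tot = 0.0
            for a in range(64):  # state of the (sp1,sp2,sp3) ancestor
                wa = float(np.dot(root * P123[:, a], P4[:, x4]))
                inner = 0.0
                for b in range(64):  # state of the (sp1,sp2) ancestor
                    inner += P12[a, b] * P1[b, x1] * P2[b, x2]
                tot += wa * P3[a, x3] * inner
            assert np.log(tot) == pytest.approx(expected, abs=1e-10)


class TestGradient:
    def test_matches_finite_differences(self, rng):
        ph = Phylogeny(FOURTAXON)
        theta = rng.uniform(0.002, 0.08, (ph.n_branches, 18))
        root = rng.dirichlet(np.ones(64))
        pats = rng.integers(0, 64, (30, 4))
        w = rng.uniform(1, 5, 30)
        lc = pats.T.copy()
        for conditional in (True, False):
            f0, g0 = M._nll_and_grad(theta.ravel(), ph, lc, w, root,
                                     conditional=conditional)
            eps = 1e-6
            for i in rng.choice(theta.size, 8, replace=False):
                tp = theta.ravel().copy()
                tm = tp.copy()
                tp[i] += eps
                tm[i] -= eps
                fd = (
                    M._nll_and_grad(tp, ph, lc, w, root, conditional=conditional)[0]
                    - M._nll_and_grad(tm, ph, lc, w, root, conditional=conditional)[0]
                ) / (2 * eps)
                assert g0[i] == pytest.approx(fd, rel=1e-4, abs=1e-4)


class TestEstimate:
    def test_identical_columns_give_zero_boundary(self, rng):
        ph = Phylogeny(FOURTAXON)
        codes = rng.integers(0, 64, 300)
        pats = np.stack([codes] * 4, axis=1)
        w = np.ones(300)
        rates, rep = estimate_rates(
            (pats, w), ph, EstimateOptions(restarts=1, maxiter=200)
        )
        for name, rs in rates.items():
            assert rs.to_vector().max() < 1e-4

    def test_empty_counts_rejected(self):
        ph = Phylogeny(FOURTAXON)
        with pytest.raises(ValueError):
            estimate_rates((np.zeros((0, 4), dtype=int), np.zeros(0)), ph)

    def test_revcomp_data_swaps_complementary_estimates(self, rng):
        from txsubst.seqcodes import TRIPLET_REVCOMP
        from txsubst import simulate as S

        ph = Phylogeny(FOURTAXON)
        theta = np.stack([random_rateset(rng).to_vector() for _ in range(ph.n_branches)])
        rates = {ph.branch_names[b]: RateSet.from_vector(theta[b])
                 for b in range(ph.n_branches)}
        root = rng.integers(0, 4, 20_000).astype(np.uint8)
        leaves, _ = S.simulate_tree(root, ph, rates, seed=5)
        arr = np.stack([leaves[s] for s in ph.species])
        tri = arr[:, :-2].astype(np.int64) * 16 + arr[:, 1:-1] * 4 + arr[:, 2:]
        pats, w = np.unique(tri.T, axis=0, return_counts=True)
        w = w.astype(float)
        rc_full = np.stack([TRIPLET_REVCOMP[pats[:, i]] for i in range(4)], axis=1)
        order = np.lexsort(rc_full.T[::-1])
        rc_pats, rc_w = rc_full[order], w[order]
        # tight tolerance so both optimizations reach the same optimum
        opts = EstimateOptions(restarts=1, maxiter=1500, ftol=1e-12)
        est_f, _ = estimate_rates((pats, w), ph, opts)
        est_r, _ = estimate_rates((rc_pats, rc_w), ph, opts)
        for name in ph.branch_names:
            vf = est_f[name].to_vector()
            vr = est_r[name].to_vector()
            assert np.allclose(vf, vr[M.RC_PROCESS_PERM], atol=1e-4)

    def test_more_changes_increase_mle(self, rng):
        """On a single-branch problem, adding A->G discordant sites never
        decreases the [A>G] estimate."""
        ph = Phylogeny("(sp1,sp2);")
        aaa, aga = triplet_code("AAA"), triplet_code("AGA")
        k = M.SINGLE_INDEX[(0, 2)]
        prev = -1.0
        for n_changed in (5, 20, 60):
            pats = np.array([[aaa, aaa]] * (400 - n_changed) + [[aaa, aga]] * n_changed)
            w = np.ones(len(pats))
            rates, _ = estimate_rates(
                (pats, w), ph, EstimateOptions(restarts=1, maxiter=300)
            )
            est = rates["sp1"].to_vector()[k] + rates["sp2"].to_vector()[k]
            assert est >= prev - 1e-9
            prev = est


class TestStationary:
    def test_uniform_rates_uniform_composition(self):
        comp = stationary_composition(RateSet.uniform(single=0.05))
        assert np.allclose(comp.mono, 0.25, atol=1e-7)

    def test_two_state_pool_split(self):
        v = np.full(18, 0.0)
        v[:12] = 1e-9
        v[M.SINGLE_INDEX[(1, 3)]] = 0.2  # C>T
        v[M.SINGLE_INDEX[(3, 1)]] = 0.1  # T>C
        comp = stationary_composition(RateSet.from_vector(v))
        assert comp.mono[1] == pytest.approx(1 / 6, abs=1e-5)
        assert comp.mono[3] == pytest.approx(1 / 3, abs=1e-5)

    def test_strand_symmetric_rates_zero_skews(self, rng):
        from txsubst.profiles import skew

        for _ in range(3):
            v = rng.uniform(0.01, 0.1, 18)
            sym = (v + v[M.RC_PROCESS_PERM]) / 2
            rs = RateSet.from_vector(sym)
            assert rs.is_strand_symmetric(tol=1e-12)
            ta, gc = skew(stationary_composition(rs))
            assert abs(ta) < 1e-6 and abs(gc) < 1e-6

    def test_4state_uniform(self):
        comp = stationary_4state(RateSet.uniform(single=0.03))
        assert np.allclose(comp.mono, 0.25, atol=1e-12)

    def test_4state_rejects_cpg(self):
        with pytest.raises(ValueError):
            stationary_4state(RateSet.uniform(single=0.03, cpg=0.1))

    def test_4state_rejects_reducible(self):
        # exchange only within {A,G} and within {C,T}
        v = np.zeros(18)
        v[M.SINGLE_INDEX[(0, 2)]] = v[M.SINGLE_INDEX[(2, 0)]] = 0.1
        v[M.SINGLE_INDEX[(1, 3)]] = v[M.SINGLE_INDEX[(3, 1)]] = 0.1
        with pytest.raises(ValueError, match="reducible"):
            stationary_4state(RateSet.from_vector(v))

    def test_meanfield_matches_4state_for_cpg_free(self, rng):
        for _ in range(10):
            v = np.zeros(18)
            v[:12] = rng.uniform(0.01, 0.1, 12)
            rs = RateSet.from_vector(v)
            a = stationary_composition(rs).mono
            b = stationary_4state(rs).mono
            assert np.abs(a - b).max() < 5e-3

    def test_cpg_deamination_lowers_gc_star(self):
        sym = RateSet.uniform(single=0.02)
        base = stationary_composition(sym).gc
        v = sym.to_vector()
        v[M.CPG_INDEX["CpG>TpG"]] = 0.3
        lower = stationary_composition(RateSet.from_vector(v)).gc
        assert base == pytest.approx(0.5, abs=1e-6)
        assert lower < 0.5


class TestPhylogeny:
    def test_root_adjacent_flags(self):
        ph = Phylogeny(FOURTAXON)
        flags = dict(zip(ph.branch_names, ph.root_adjacent))
        assert flags == {
            "sp1": False, "sp2": False, "sp1+sp2": False, "sp3": False,
            "sp1+sp2+sp3": True, "sp4": True,
        }

    def test_species_sorted(self):
        ph = Phylogeny("((b,a),c);")
        assert ph.species == ["a", "b", "c"]

    def test_bad_root_distribution(self):
        with pytest.raises(ValueError):
            Phylogeny(FOURTAXON, root_distribution=np.ones(64))
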