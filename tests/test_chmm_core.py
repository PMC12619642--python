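import itertools

import numpy as np
import pytest

import airrchimera as ac
from airrchimera.chmm_core import (
    HMMSpec,
    _EMIT_MATCH,
    _EMIT_MISMATCH,
    _emission_classes,
    dense_transition_matrix,
    forward_many,
)
from airrchimera.errors import ModeError, ParameterError
from airrchimera.reference_db import encode_sequence

from conftest import random_hmm_instance


def _two_ref_msa(L, n_diff, seed=0):
    """Reference 1 random; reference 2 differing at n_diff spread columns."""
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 4, size=L)
    b = a.copy()
    pos = np.linspace(0, L - 1, n_diff).astype(int)
    b[pos] = (b[pos] + 1) % 4
    bases = np.array(list("ACGT"))
    return ac.ReferenceMSA(
        [
            ac.GermlineAllele("R1*01", "".join(bases[a])),
            ac.GermlineAllele("R2*01", "".join(bases[b])),
        ]
    )


class TestEmission:
    def test_piecewise_formula(self):
        assert ac.emission_prob("A", "A", 0.005) == 1 - 0.005
        assert ac.emission_prob("A", "C", 0.03) == 0.03 / 3
        assert ac.emission_prob("A", "N", 0.2) == 1.0
        assert ac.emission_prob("A", "-", 0.2) == 1.0
        assert ac.emission_prob("N", "A", 0.3) == 1.0
        assert ac.emission_prob("-", "G", 0.3) == 1.0

    def test_invalid_inputs(self):
        from airrchimera.errors import InvalidCharacterError

        with pytest.raises(InvalidCharacterError):
            ac.emission_prob("A", "X", 0.1)
        with pytest.raises(ParameterError):
            ac.emission_prob("A", "A", 1.5)


class TestForward:
    def test_matches_dense_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            query, spec = random_hmm_instance(rng)
            fast = ac.forward(query, spec)
            slow = ac.forward_oracle(query, spec)
            assert abs(fast.chimera_posterior - slow.chimera_posterior) < 1e-9
            assert abs(fast.log_likelihood - slow.log_likelihood) < 1e-8

    def test_psi_zero_gives_posterior_exactly_zero(self):
        rng = np.random.default_rng(1)
        query, spec = random_hmm_instance(rng)
        spec0 = HMMSpec(msa=spec.msa, rates=spec.rates, psi=0.0, mu=spec.mu)
        assert ac.forward(query, spec0).chimera_posterior == 0.0

    def test_non_chimeric_query_low_posterior(self):
        msa = _two_ref_msa(100, 30)
        spec = HMMSpec(msa=msa, rates=[0.005], psi=0.002, mu=0.0)
        res = ac.forward(msa.alleles[0].aligned_seq, spec)
        assert res.chimera_posterior < 0.01
        oracle = ac.forward_oracle(msa.alleles[0].aligned_seq, spec)
        assert abs(res.chimera_posterior - oracle.chimera_posterior) < 1e-9

    def test_half_half_chimera_high_posterior(self):
        msa = _two_ref_msa(100, 30)
        a, b = (al.aligned_seq for al in msa.alleles)
        chim = a[:50] + b[50:]
        spec = HMMSpec(msa=msa, rates=[0.005], psi=0.002, mu=0.0)
        res = ac.forward(chim, spec)
        assert res.chimera_posterior > 0.99
        oracle = ac.forward_oracle(chim, spec)
        assert abs(res.chimera_posterior - oracle.chimera_posterior) < 1e-9

    def test_all_N_query_matches_closed_form(self):
        # flat emissions: the posterior is the prior probability of >=1
        # reference switch over L-1 transitions, 1 - (1 - psi)^(L-1)
        msa = _two_ref_msa(10, 3)
        psi = 0.01
        spec = HMMSpec(msa=msa, rates=[0.02], psi=psi, mu=0.0)
        res = ac.forward("N" * 10, spec)
        assert res.chimera_posterior == pytest.approx(1 - (1 - psi) ** 9, abs=1e-12)

    def test_posterior_monotone_in_psi_on_flat_query(self):
        msa = _two_ref_msa(20, 5)
        posts = []
        for psi in (0.001, 0.01, 0.05, 0.2):
            spec = HMMSpec(msa=msa, rates=[0.05], psi=psi, mu=0.0)
            posts.append(ac.forward("N" * 20, spec).chimera_posterior)
        assert all(b > a for a, b in zip(posts, posts[1:]))

    def test_reference_permutation_invariance(self):
        rng = np.random.default_rng(5)
        query, spec = random_hmm_instance(rng)
        base = ac.forward(query, spec).chimera_posterior
        perm = list(rng.permutation(spec.G))
        msa2 = ac.ReferenceMSA([spec.msa.alleles[i] for i in perm])
        spec2 = HMMSpec(msa=msa2, rates=spec.rates, psi=spec.psi, mu=spec.mu)
        assert abs(ac.forward(query, spec2).chimera_posterior - base) < 1e-12

    def test_transition_rows_stochastic(self):
        rng = np.random.default_rng(9)
        _, spec = random_hmm_instance(rng)
        A = dense_transition_matrix(spec)
        assert np.allclose(A.sum(axis=1), 1.0, atol=1e-12)

    def test_length_mismatch_rejected(self, tiny_msa):
        spec = HMMSpec(msa=tiny_msa, rates=[0.01])
        from airrchimera.errors import LatticeError

        with pytest.raises(LatticeError):
            ac.forward("ACG", spec)


class TestBackward:
    def test_forward_backward_identity_every_column(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            query, spec = random_hmm_instance(rng)
            res = ac.forward(query, spec, return_lattice=True)
            beta = ac.backward(query, spec)
            prod = (res.alpha * beta).sum(axis=(1, 2, 3))
            assert np.allclose(prod, 1.0, rtol=1e-9)

    def test_single_column_beta_is_ones(self):
        msa = _two_ref_msa(1, 1)
        spec = HMMSpec(msa=msa, rates=[0.01])
        beta = ac.backward("A", spec)
        assert np.all(beta == 1.0)

    def test_state_marginals_match_dense_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            query, spec = random_hmm_instance(rng, max_G=4, max_K=2, max_L=20)
            res = ac.forward(query, spec, return_lattice=True)
            beta = ac.backward(query, spec)
            gamma = res.alpha * beta  # (L, 2, G, K), sums to 1 per column
            # dense unscaled forward/backward
            G, K, L = spec.G, spec.K, spec.L
            A = dense_transition_matrix(spec)
            cls = _emission_classes(
                encode_sequence(query)[None, :], spec.msa.codes
            )[0]
            rates = spec.rate_matrix()

            def b_col(t):
                c = cls[:, t][:, None]
                bgk = np.where(c == _EMIT_MATCH, 1.0 - rates,
                               np.where(c == _EMIT_MISMATCH, rates / 3, 1.0))
                return np.concatenate([bgk.ravel(), bgk.ravel()])

            pi = np.zeros(2 * G * K)
            pi[: G * K] = 1 / (G * K)
            al = [pi * b_col(0)]
            for t in range(1, L):
                al.append((al[-1] @ A) * b_col(t))
            be = [np.ones(2 * G * K)]
            for t in range(L - 2, -1, -1):
                be.insert(0, A @ (b_col(t + 1) * be[0]))
            for t in range(L):
                dense_gamma = al[t] * be[t]
                dense_gamma /= dense_gamma.sum()
                ours = gamma[t].reshape(2, G, K).ravel()
                # state order: non-chimeric half then chimeric, ref-major
                assert np.allclose(ours, dense_gamma, atol=1e-9)


def _enumerate_best_logprob(query, spec):
    """Exhaustive max over all state paths (tiny instances only)."""
    G, K, L = spec.G, spec.K, spec.L
    n = 2 * G * K
    A = dense_transition_matrix(spec)
    cls = _emission_classes(encode_sequence(query)[None, :], spec.msa.codes)[0]
    rates = spec.rate_matrix()
    logb = np.empty((L, n))
    with np.errstate(divide="ignore"):
        for t in range(L):
            c = cls[:, t][:, None]
            bgk = np.where(c == _EMIT_MATCH, 1.0 - rates,
                           np.where(c == _EMIT_MISMATCH, rates / 3, 1.0))
            logb[t] = np.log(np.concatenate([bgk.ravel(), bgk.ravel()]))
        logA = np.log(A)
        logpi = np.log(np.concatenate([np.full(G * K, 1 / (G * K)),
                                       np.zeros(G * K)]))
    best = -np.inf
    best_paths = []
    for path in itertools.product(range(n), repeat=L):
        lp = logpi[path[0]] + logb[0, path[0]]
        for t in range(1, L):
            lp += logA[path[t - 1], path[t]] + logb[t, path[t]]
            if lp == -np.inf:
                break
        if lp > best:
            best, best_paths = lp, [path]
        elif lp == best and np.isfinite(lp):
            best_paths.append(path)
    return best, best_paths


class TestViterbi:
    def test_non_chimeric_path_constant_no_events(self):
        msa = _two_ref_msa(8, 3)
        spec = HMMSpec(msa=msa, rates=[0.01], psi=0.005, mu=0.0)
        v = ac.viterbi(msa.alleles[0].aligned_seq, spec)
        assert v.events == []
        assert len(set(v.state_path.tolist())) == 1
        best, paths = _enumerate_best_logprob(msa.alleles[0].aligned_seq, spec)
        assert v.log_prob == pytest.approx(best, abs=1e-9)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(8):
            query, spec = random_hmm_instance(rng, max_G=2, max_K=1, max_L=8)
            if spec.L > 8:
                continue
            v = ac.viterbi(query, spec)
            best, paths = _enumerate_best_logprob(query, spec)
            assert v.log_prob == pytest.approx(best, abs=1e-9)
            assert tuple(v.state_path.tolist()) in paths

    def test_breakpoint_near_truth_on_constructed_chimera(self):
        # parents differ every 5th column; the breakpoint is identifiable
        # only up to the interval between flanking informative columns
        L, step = 100, 5
        rng = np.random.default_rng(3)
        a = rng.integers(0, 4, size=L)
        b = a.copy()
        pos = np.arange(0, L, step)
        b[pos] = (b[pos] + 2) % 4
        bases = np.array(list("ACGT"))
        msa = ac.ReferenceMSA(
            [
                ac.GermlineAllele("P*01", "".join(bases[a])),
                ac.GermlineAllele("Q*01", "".join(bases[b])),
            ]
        )
        true_bp = 50
        chim = msa.alleles[0].aligned_seq[: true_bp - 1] + \
            msa.alleles[1].aligned_seq[true_bp - 1:]
        spec = HMMSpec(msa=msa, rates=[0.005], psi=0.002, mu=0.0)
        v = ac.viterbi(chim, spec)
        assert len(v.events) == 1
        frm, to, bp = v.events[0]
        assert (frm, to) == ("P*01", "Q*01")
        flank_lo = max(p + 1 for p in pos if p + 1 < true_bp)
        flank_hi = min(p + 1 for p in pos if p + 1 >= true_bp)
        assert flank_lo < bp <= flank_hi + 1

    def test_log_prob_never_exceeds_forward_likelihood(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            query, spec = random_hmm_instance(rng, max_L=25)
            v = ac.viterbi(query, spec)
            f = ac.forward(query, spec)
            assert v.log_prob <= f.log_likelihood + 1e-9


class TestBaumWelch:
    def _spec(self, msa, init=0.05):
        return HMMSpec(msa=msa, rates=[init], psi=0.002, mu=0.0, mode="BW")

    def test_requires_single_rate_mode(self):
        msa = _two_ref_msa(20, 5)
        spec = HMMSpec(msa=msa, rates=[0.0, 0.1], psi=0.002, mu=0.002)
        with pytest.raises(ModeError):
            ac.baum_welch_rates("A" * 20, spec)

    def test_identical_query_hits_rate_floor(self):
        msa = _two_ref_msa(60, 20)
        rates, res = ac.baum_welch_rates(
            msa.alleles[0].aligned_seq, self._spec(msa)
        )
        assert rates[0] == pytest.approx(1e-6)
        assert res.chimera_posterior < 0.05

    def test_recovers_planted_rate(self):
        msa = _two_ref_msa(300, 90, seed=2)
        rng = np.random.default_rng(77)
        errs = []
        for _ in range(20):
            q = ac.mutate_uniform(msa.alleles[0].aligned_seq, 0.10, rng)
            rates, _ = ac.baum_welch_rates(q, self._spec(msa))
            errs.append(abs(rates[0] - 0.10))
        assert np.mean(errs) < 0.03

    def test_log_likelihood_monotone_non_decreasing(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            query, spec = random_hmm_instance(rng, max_K=1)
            spec_bw = HMMSpec(msa=spec.msa, rates=[0.08], psi=spec.psi,
                              mu=0.0, mode="BW")
            _, _, traj = ac.baum_welch_rates(
                query, spec_bw, return_history=True
            )
            diffs = np.diff(traj)
            assert (diffs > -1e-8).all()

    def test_db_and_bw_calls_agree_on_unmutated_set(self, small_genotype):
        cfg = ac.SimulationConfig(
            genotype=small_genotype, n_sequences=1000, chimerism_rate=0.05,
            shm_rate=0.0, seq_error_rate=0.0, seed=19,
        )
        records, _ = ac.simulate_dataset(cfg)
        codes = np.vstack([encode_sequence(r.threaded) for r in records])
        db_spec = HMMSpec(msa=small_genotype, rates=[0.005], psi=0.002,
                          mu=0.0)
        post_db, _ = forward_many(codes, db_spec)
        bw_spec = HMMSpec(msa=small_genotype, rates=[0.05], psi=0.002,
                          mu=0.0, mode="BW")
        from airrchimera.chmm_core import baum_welch_many

        _, post_bw, _ = baum_welch_many(codes, bw_spec)
        agree = ((post_db > 0.95) == (post_bw > 0.95)).mean()
        assert agree >= 0.99


class TestPosteriorThreshold:
    def test_strictly_greater(self):
        assert ac.posterior_threshold(0.99, 0.95) is True
        assert ac.posterior_threshold(0.95, 0.95) is False
        assert ac.posterior_threshold(0.0, 0.95) is False

    def test_threshold_range_validated(self):
        with pytest.raises(ParameterError):
            ac.posterior_threshold(0.5, 1.0)
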