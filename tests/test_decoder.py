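"""Thresholding, Lagrangian relaxation, greedy binarisation and the oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ntfold as nf
from ntfold.decoder import (
    DecodingConfig,
    binarize,
    brute_force_decode,
    lagrangian_decode,
    soft_sign,
    threshold_map,
    valid_pair_mask,
)


def min_sep_mask(L, sep=4):
    idx = np.arange(L)
    return (np.abs(idx[:, None] - idx[None, :]) >= sep).astype(np.int8)


def random_symmetric(rng, L):
    A = rng.random((L, L))
    A = np.triu(A, 1)
    return A + A.T


class TestSoftSign:
    def test_at_zero(self):
        for kappa in (0.5, 1.0, 10.0, 100.0):
            assert soft_sign(0.0, kappa) == pytest.approx(0.5)

    def test_symmetry(self):
        xs = np.linspace(-5, 5, 41)
        assert np.allclose(soft_sign(xs, 3.0) + soft_sign(-xs, 3.0), 1.0)

    def test_sharpness_limit(self):
        assert soft_sign(0.1, 100.0) == pytest.approx(1.0, abs=1e-4)

    def test_monotone_and_saturating(self):
        xs = np.linspace(-1000, 1000, 101)
        ys = soft_sign(xs, 50.0)
        assert np.all(np.diff(ys) >= 0)
        assert np.all((ys >= 0) & (ys <= 1)) and np.all(np.isfinite(ys))

    def test_invalid_kappa(self):
        with pytest.raises(ValueError):
            soft_sign(1.0, 0.0)


class TestThresholdMap:
    def test_zero_stays_zero(self):
        cfg = DecodingConfig()
        assert threshold_map(np.zeros((4, 4)), cfg).sum() == 0.0

    def test_at_threshold_halved(self):
        cfg = DecodingConfig(s=0.4)
        out = threshold_map(np.full((2, 2), 0.4), cfg)
        assert np.allclose(out, 0.5 * 0.4)

    def test_pass_and_suppress(self):
        cfg = DecodingConfig(s=0.5, kappa=50.0)
        C = np.array([[0.9, 0.1], [0.1, 0.9]])
        out = threshold_map(C, cfg)
        exact_hi = 0.9 / (1.0 + math.exp(-50 * 0.4))
        exact_lo = 0.1 / (1.0 + math.exp(50 * 0.4))
        assert out[0, 0] == pytest.approx(exact_hi, rel=1e-12)
        assert out[0, 1] == pytest.approx(exact_lo, rel=1e-9)
        assert out[0, 0] > 0.89 and out[0, 1] < 1e-9

    def test_bounded_by_input(self):
        rng = np.random.default_rng(0)
        C = rng.random((10, 10))
        out = threshold_map(C, DecodingConfig())
        assert np.all(out >= 0) and np.all(out <= C)


class TestValidPairMask:
    def test_min_sep_five_positions(self):
        seq = nf.RnaSequence("s", "AAAAA")
        mask = valid_pair_mask(seq, DecodingConfig(min_sep=4))
        assert mask[0, 4] == mask[4, 0] == 1
        assert mask.sum() == 2

    def test_all_g_canonical_empty(self):
        seq = nf.RnaSequence("s", "GGGGGGGGG")
        mask = valid_pair_mask(seq, DecodingConfig(canonical_only=True))
        assert mask.sum() == 0

    def test_canonical_matches_enumeration(self):
        seq = nf.RnaSequence("s", "GCGCAAAGCGC")
        cfg = DecodingConfig(canonical_only=True)
        mask = valid_pair_mask(seq, cfg)
        canonical = {"AU", "UA", "GC", "CG", "GU", "UG"}
        for i in range(seq.L):
            for j in range(seq.L):
                legal = abs(i - j) >= 4 and seq.residues[i] + seq.residues[j] in canonical
                assert mask[i, j] == int(legal)

    def test_symmetric_zero_diagonal(self):
        seq = nf.RnaSequence("s", "ACGUNACGUNAC")
        for canonical in (False, True):
            mask = valid_pair_mask(seq, DecodingConfig(canonical_only=canonical))
            assert np.array_equal(mask, mask.T)
            assert np.all(np.diag(mask) == 0)

    def test_n_unpaired_when_canonical(self):
        seq = nf.RnaSequence("s", "NNNNNNNNNN")
        assert valid_pair_mask(seq, DecodingConfig(canonical_only=True)).sum() == 0
        assert valid_pair_mask(seq, DecodingConfig(canonical_only=False)).sum() > 0


class TestLagrangianDecode:
    def test_zero_fixed_point(self):
        cfg = DecodingConfig()
        L = 8
        A = lagrangian_decode(np.zeros((L, L)), min_sep_mask(L), cfg)
        assert np.all(A == 0)

    def test_mask_confinement_single_cell(self):
        cfg = DecodingConfig()
        L = 8
        c = np.zeros((L, L))
        c[1, 6] = c[6, 1] = 0.9
        mask = np.zeros((L, L), dtype=np.int8)
        mask[1, 6] = mask[6, 1] = 1
        A = lagrangian_decode(c, mask, cfg)
        assert 0 < A[1, 6] <= 1
        off = A.copy()
        off[1, 6] = off[6, 1] = 0
        assert np.all(off == 0)

    def test_nonsymmetric_mask_rejected(self):
        mask = min_sep_mask(6)
        mask[0, 5] = 0
        with pytest.raises(ValueError, match="symmetric"):
            lagrangian_decode(np.zeros((6, 6)), mask, DecodingConfig())

    def test_competing_pairs_stronger_wins(self):
        # nucleotide 2 can pair with 6 (score 0.9) or with 7 (score 0.6)
        cfg = DecodingConfig()
        L = 8
        c = np.zeros((L, L))
        c[2, 6] = c[6, 2] = 0.9
        c[2, 7] = c[7, 2] = 0.6
        mask = min_sep_mask(L)
        A = lagrangian_decode(c, mask, cfg)
        M = binarize(A, mask, cfg)
        oracle = brute_force_decode(A, mask, cfg.bin_threshold)
        assert M[2, 6] == 1 and M[2, 7] == 0
        assert np.array_equal(M, oracle)

    def test_iterates_stay_feasible(self):
        rng = np.random.default_rng(1)
        cfg = DecodingConfig(T=37)
        L = 12
        A = lagrangian_decode(
            threshold_map(random_symmetric(rng, L), cfg), min_sep_mask(L), cfg
        )
        assert np.all((A >= 0) & (A <= 1))
        assert np.allclose(A, A.T)

    def test_violation_nonincreasing_last_quarter(self):
        """Mean row-sum violation decreases over the tail of the iteration,
        averaged over many random instances."""
        rng = np.random.default_rng(2)
        cfg = DecodingConfig(T=100)
        starts, ends = [], []
        for _ in range(25):
            L = int(rng.integers(10, 25))
            c = threshold_map(random_symmetric(rng, L) * 1.5, cfg)
            _, viol = lagrangian_decode(
                np.clip(c, 0, None), min_sep_mask(L), cfg, return_violations=True
            )
            starts.append(viol[3 * cfg.T // 4])
            ends.append(viol[-1])
        assert np.mean(ends) <= np.mean(starts) + 1e-9


class TestBinarize:
    def test_all_below_threshold_empty(self):
        L = 8
        M = binarize(np.full((L, L), 0.3), min_sep_mask(L), DecodingConfig())
        assert M.sum() == 0

    def test_conflict_resolved_by_score(self):
        L = 8
        A = np.zeros((L, L))
        A[1, 7] = A[7, 1] = 0.9
        A[2, 7] = A[7, 2] = 0.8
        M = binarize(A, min_sep_mask(L), DecodingConfig())
        assert M[1, 7] == 1 and M[2, 7] == 0

    def test_guarantees_on_random_instances(self):
        rng = np.random.default_rng(3)
        cfg = DecodingConfig()
        for _ in range(200):
            L = int(rng.integers(5, 20))
            A = random_symmetric(rng, L)
            mask = np.triu((rng.random((L, L)) < 0.5).astype(np.int8), 1)
            mask = mask + mask.T
            M = binarize(A, mask, cfg)
            assert np.array_equal(M, M.T)
            assert np.all(np.triu(M, 1).sum(axis=0) + np.triu(M, 1).sum(axis=1) <= 1)
            assert np.all(M[mask == 0] == 0)
            assert np.all(np.diag(M) == 0)


class TestBruteForceOracle:
    def test_single_candidate(self):
        L = 6
        A = np.zeros((L, L))
        A[0, 5] = A[5, 0] = 0.9
        M = brute_force_decode(A, np.ones((L, L)), 0.5)
        assert M[0, 5] == 1 and M.sum() == 2

    def test_disjoint_candidates_both_kept(self):
        L = 8
        A = np.zeros((L, L))
        A[0, 4] = A[4, 0] = 0.7
        A[1, 5] = A[5, 1] = 0.8
        M = brute_force_decode(A, np.ones((L, L)), 0.5)
        assert M[0, 4] == 1 and M[1, 5] == 1

    def test_size_limit(self):
        with pytest.raises(ValueError):
            brute_force_decode(np.zeros((13, 13)), np.ones((13, 13)), 0.5)

    def test_oracle_dominates_greedy(self):
        """Oracle total weight >= greedy total weight always; the pair sets
        coincide whenever greedy never skips a conflicting candidate."""
        rng = np.random.default_rng(4)
        cfg = DecodingConfig()
        dominated = equal_when_conflict_free = conflict_free = 0
        for _ in range(200):
            A = random_symmetric(rng, 8)
            mask = min_sep_mask(8)
            greedy = binarize(A, mask, cfg)
            oracle = brute_force_decode(A, mask, cfg.bin_threshold)
            gw = float((A * np.triu(greedy, 1)).sum())
            ow = float((A * np.triu(oracle, 1)).sum())
            assert ow >= gw - 1e-12
            dominated += 1
            # replay greedy to see whether it ever skipped a candidate
            ii, jj = np.nonzero(np.triu((A > cfg.bin_threshold) & (mask > 0), 1))
            order = sorted(range(len(ii)), key=lambda k: (-A[ii[k], jj[k]], ii[k], jj[k]))
            used = set()
            skipped = False
            for k in order:
                i, j = int(ii[k]), int(jj[k])
                if i in used or j in used:
                    skipped = True
                else:
                    used.update((i, j))
            if not skipped:
                conflict_free += 1
                equal_when_conflict_free += np.array_equal(greedy, oracle)
        assert dominated == 200
        assert conflict_free > 0
        assert equal_when_conflict_free == conflict_free


class TestMonotonicity:
    def test_threshold_map_elementwise_nonincreasing_in_s(self):
        rng = np.random.default_rng(5)
        C = rng.random((20, 20))
        prev = None
        for s in np.linspace(0.0, 1.0, 21):
            out = threshold_map(C, DecodingConfig(s=float(s)))
            if prev is not None:
                assert np.all(out <= prev + 1e-15)
            prev = out

    def test_raising_s_never_adds_pairs_on_structured_maps(self):
        """On contact-like score maps (strong planted signal, weak background)
        the decoded pair count is non-increasing in the sparsity threshold.

        Note this holds only in the low-competition regime: on dense noise a
        higher s can remove enough competing candidates that the multiplier
        no longer suppresses a survivor, so the count is not globally
        monotone in s.
        """
        rng = np.random.default_rng(5)
        records = nf.make_dataset(
            20, {f: 1.0 for f in nf.synthetic.FAMILIES},
            nf.synthetic.compact_specs(), seed=9,
        )
        for seq, truth in records:
            M0 = nf.structure_to_contact_map(truth).astype(float)
            noise = rng.uniform(0, 0.05, M0.shape)
            noise = 0.5 * (noise + noise.T)
            C = np.where(M0 > 0, 0.95, noise)
            counts = []
            for s in np.linspace(0.0, 1.0, 11):
                cfg = DecodingConfig(s=float(s))
                mask = valid_pair_mask(seq, cfg)
                A = lagrangian_decode(threshold_map(C, cfg), mask, cfg)
                counts.append(int(np.triu(binarize(A, mask, cfg), 1).sum()))
            assert all(b <= a for a, b in zip(counts, counts[1:])), counts


@settings(derandomize=True, max_examples=40)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_decode_output_always_valid_property(seed):
    """Full decode satisfies symmetry, exclusivity, mask compliance and a zero
    diagonal for random inputs and random configs."""
    rng = np.random.default_rng(seed)
    L = int(rng.integers(5, 30))
    cfg = DecodingConfig(
        s=float(rng.uniform(0, 1)),
        kappa=float(rng.uniform(0.5, 50)),
        eta=float(rng.uniform(1e-3, 0.1)),
        eta_lambda=float(rng.uniform(1e-3, 0.1)),
        T=int(rng.integers(1, 60)),
        min_sep=int(rng.integers(1, 6)),
        canonical_only=bool(rng.integers(0, 2)),
        bin_threshold=float(rng.uniform(0.05, 0.95)),
    )
    seq = nf.RnaSequence("r", "".join("ACGUN"[k] for k in rng.integers(0, 5, L)))
    C = rng.random((L, L))
    M, A = nf.decode(C, seq, cfg)
    mask = valid_pair_mask(seq, cfg)
    assert np.array_equal(M, M.T)
    assert np.all(np.triu(M, 1).sum(axis=0) + np.triu(M, 1).sum(axis=1) <= 1)
    assert np.all(M[mask == 0] == 0)
    assert np.all(np.diag(M) == 0)
    assert np.all((A >= 0) & (A <= 1))
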