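import itertools

import numpy as np
from hypothesis import given, settings
from hypothesis import strategies as st
import pandas as pd
import pytest

from amlink import (
    GenotypeMatrix,
    HaplotypeFreqs,
    SimConfig,
    d_squared,
    draw_founders,
    draw_subpop_freqs,
    em_haplotype_freqs,
    ld_prune,
    mean_d2_cross_chromosome,
    simulate_dataset,
    thin_by_distance,
    wrights_f,
    wrights_f_per_variant,
)

from conftest import make_variants


# ---------------------------------------------------------------------------
# independent grid-search oracle for the two-locus EM
# ---------------------------------------------------------------------------

def genotype_loglik(table, pAB, pAb, paB, pab):
    """Multinomial genotype log-likelihood under random union of gametes,
    written from the probability model directly (independent of the EM code).
    Frequency arguments may be arrays (broadcast over grid points)."""
    hap = {(1, 1): pAB, (1, 0): pAb, (0, 1): paB, (0, 0): pab}
    ll = 0.0
    for a in range(3):
        for b in range(3):
            if table[a, b] == 0:
                continue
            prob = 0.0
            for a1, b1 in itertools.product((0, 1), repeat=2):
                a2, b2 = a - a1, b - b1
                if a2 in (0, 1) and b2 in (0, 1):
                    prob = prob + hap[(a1, b1)] * hap[(a2, b2)]
            ll = ll + table[a, b] * np.log(np.maximum(prob, 1e-300))
    return ll


def grid_search_max_loglik(table, final_res=1e-5):
    """Coarse-to-fine maximization of the genotype likelihood over the
    haplotype-frequency simplex (pAB, pAb, paB free; pab = 1 - sum)."""
    lo = np.zeros(3)
    hi = np.ones(3)
    res = 0.02
    best = None
    while True:
        axes = [np.arange(lo[i], hi[i] + res / 2, res) for i in range(3)]
        A, B, C = np.meshgrid(*axes, indexing="ij")
        D = 1.0 - A - B - C
        valid = D >= -1e-12
        A, B, C, D = A[valid], B[valid], C[valid], np.maximum(D[valid], 0.0)
        ll = genotype_loglik(table, A, B, C, D)
        k = int(np.argmax(ll))
        best = (float(ll[k]), A[k], B[k], C[k])
        if res <= final_res:
            return best[0]
        lo = np.maximum(np.array(best[1:]) - 2 * res, 0.0)
        hi = np.minimum(np.array(best[1:]) + 2 * res, 1.0)
        res /= 10


def random_genotype_pairs(rng, n):
    """Random two-locus genotype sample with genuine haplotype structure."""
    pA, pB = rng.uniform(0.1, 0.9, 2)
    d_max = min(pA * (1 - pB), (1 - pA) * pB)
    d = rng.uniform(-0.8, 0.8) * min(pA * pB, d_max)
    hap_p = np.array([pA * pB + d, pA * (1 - pB) - d,
                      (1 - pA) * pB - d, (1 - pA) * (1 - pB) + d])
    hap_p = np.clip(hap_p, 1e-9, None)
    hap_p /= hap_p.sum()
    haps = rng.choice(4, size=(n, 2), p=hap_p)
    a = (haps < 2).sum(axis=1)           # copies of A
    b = (haps % 2 == 0).sum(axis=1)      # copies of B
    return a.astype(np.int8), b.astype(np.int8)


class TestLdPrune:
    def _matrix(self, dosage_cols, positions, chroms=None):
        d = np.column_stack(dosage_cols).astype(np.int8)
        n = d.shape[1]
        v = make_variants(n, chroms=chroms or ["1"] * n)
        v["pos"] = positions
        return GenotypeMatrix([f"i{k}" for k in range(d.shape[0])], v, d)

    def test_duplicate_variant_removed(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, 100)
        G = self._matrix([x, x], [1000, 2000])
        kept = ld_prune(G)
        assert list(kept) == [0]

    def test_independent_variants_kept(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, 500)
        y = rng.integers(0, 3, 500)
        G = self._matrix([x, y], [1000, 2000])
        assert list(ld_prune(G)) == [0, 1]

    def test_window_limits_comparisons(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 3, 100)
        G = self._matrix([x, x], [1000, 1000 + 600_000])
        # duplicates, but farther apart than the window: both kept
        assert list(ld_prune(G, window_bp=500_000)) == [0, 1]


class TestThinByDistance:
    def test_spacing_constraint_over_orderings(self):
        v = make_variants(3)
        v["pos"] = [1, 100_000, 600_000]
        seen = set()
        for seed in range(40):
            idx = thin_by_distance(v, min_gap_bp=500_000, seed=seed)
            pos = frozenset(v["pos"].iloc[idx])
            assert not {1, 100_000} <= pos      # closer than the gap
            assert len(pos) == 2                # a maximal set always has 2
            assert 600_000 in pos
            seen.add(pos)
        assert seen == {frozenset({1, 600_000}), frozenset({100_000, 600_000})}

    def test_distinct_chromosomes_never_conflict(self):
        v = make_variants(5, chroms=["1", "2", "3", "4", "5"])
        v["pos"] = [100] * 5
        assert len(thin_by_distance(v, 500_000, seed=0)) == 5

    def test_fixed_seed_is_deterministic(self):
        v = draw_subpop_freqs(300, 0.01, 9)[["id", "chrom", "pos"]]
        a = thin_by_distance(v, 500_000, seed=5)
        b = thin_by_distance(v, 500_000, seed=5)
        np.testing.assert_array_equal(a, b)


class TestWrightsF:
    @pytest.mark.parametrize("counts,expected", [
        ((25, 50, 25), 0.0),
        ((50, 0, 50), 1.0),
        ((30, 40, 30), 0.2),
    ])
    def test_hand_computed_values(self, counts, expected):
        assert wrights_f(*counts) == pytest.approx(expected)

    def test_monomorphic_is_undefined(self):
        assert np.isnan(wrights_f(40, 0, 0))

    def test_vectorized_form_matches_scalar(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, (80, 20)).astype(np.int8)
        G = GenotypeMatrix([f"i{k}" for k in range(80)], make_variants(20), d)
        vec = wrights_f_per_variant(G, G.samples)
        for j in range(20):
            col = d[:, j]
            scalar = wrights_f(int((col == 2).sum()), int((col == 1).sum()),
                               int((col == 0).sum()))
            if np.isnan(scalar):
                assert np.isnan(vec[j])
            else:
                assert vec[j] == pytest.approx(scalar)

    def test_wahlund_closed_form(self):
        """Pooling two random-mating subpopulations: mean F matches
        (p1-p2)^2 / (4 p q) averaged over 1000 markers to within 0.01."""
        rng = np.random.default_rng(11)
        freqs = draw_subpop_freqs(1000, 0.1, rng)
        n = 500
        g1 = rng.binomial(2, np.tile(freqs["p1"], (n, 1))).astype(np.int8)
        g2 = rng.binomial(2, np.tile(freqs["p2"], (n, 1))).astype(np.int8)
        G = GenotypeMatrix([f"i{k}" for k in range(2 * n)],
                           freqs[["id", "chrom", "pos", "a1", "a2"]],
                           np.vstack([g1, g2]))
        f_obs = wrights_f_per_variant(G, G.samples)
        p1, p2 = freqs["p1"].to_numpy(), freqs["p2"].to_numpy()
        pbar = (p1 + p2) / 2
        f_exp = (p1 - p2) ** 2 / (4 * pbar * (1 - pbar))
        assert abs(np.nanmean(f_obs) - f_exp.mean()) <= 0.01


class TestEmHaplotypes:
    def test_unambiguous_coupling_counted_exactly(self):
        h = em_haplotype_freqs(np.array([2] * 50 + [0] * 50),
                               np.array([2] * 50 + [0] * 50))
        assert h.as_array() == pytest.approx([0.5, 0, 0, 0.5], abs=1e-12)
        assert h.converged

    def test_all_double_heterozygotes_fixed_point(self):
        h = em_haplotype_freqs(np.ones(40, dtype=int), np.ones(40, dtype=int))
        assert h.as_array() == pytest.approx([0.25] * 4, abs=1e-12)

    def test_missing_individuals_excluded(self):
        d1 = np.array([2, 2, 0, 0, -1])
        d2 = np.array([2, 2, 0, 0, 2])
        h = em_haplotype_freqs(d1, d2)
        assert h.n == 4

    def test_frequencies_sum_to_one_and_match_margins(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            a, b = random_genotype_pairs(rng, 60)
            h = em_haplotype_freqs(a, b)
            f = h.as_array()
            assert f.sum() == pytest.approx(1.0, abs=1e-9)
            assert f[0] + f[1] == pytest.approx(a.mean() / 2, abs=1e-6)
            assert f[0] + f[2] == pytest.approx(b.mean() / 2, abs=1e-6)

    def test_em_attains_grid_search_maximum(self):
        """EM log-likelihood matches a coarse-to-fine grid maximization to
        1e-6 on random small genotype tables."""
        rng = np.random.default_rng(77)
        for _ in range(25):
            n = int(rng.integers(10, 51))
            a, b = random_genotype_pairs(rng, n)
            h = em_haplotype_freqs(a, b)
            table = np.zeros((3, 3))
            for x, y in zip(a, b):
                table[x, y] += 1
            ll_grid = grid_search_max_loglik(table)
            assert h.log_likelihood >= ll_grid - 1e-6


class TestDSquared:
    @pytest.mark.parametrize("freqs,expected", [
        ((0.25, 0.25, 0.25, 0.25), 0.0),
        ((0.5, 0.0, 0.0, 0.5), 0.0625),
        ((0.4, 0.1, 0.2, 0.3), 0.01),
    ])
    def test_hand_computed_values(self, freqs, expected):
        h = HaplotypeFreqs(*freqs, n=10, iterations=1, converged=True,
                           log_likelihood=0.0)
        assert d_squared(h) == pytest.approx(expected)

    def test_invariant_to_allele_relabeling(self):
        base = (0.4, 0.1, 0.2, 0.3)
        swaps = [
            (base[1], base[0], base[3], base[2]),   # relabel locus 2
            (base[2], base[3], base[0], base[1]),   # relabel locus 1
            (base[3], base[2], base[1], base[0]),   # relabel both
        ]
        d0 = d_squared(np.array(base))
        for s in swaps:
            assert d_squared(np.array(s)) == pytest.approx(d0, abs=1e-15)

    def test_sampling_floor_in_homogeneous_population(self):
        """Cross-chromosome D-hat² under random mating sits near the 1/(2n)
        estimation floor — within a factor of 3 of the analytic value."""
        rng = np.random.default_rng(41)
        freqs = draw_subpop_freqs(60, 0.0, rng)
        n = 300
        g = rng.binomial(2, np.tile(freqs["p"], (n, 1))).astype(np.int8)
        G = GenotypeMatrix([f"i{k}" for k in range(n)],
                           freqs[["id", "chrom", "pos", "a1", "a2"]], g)
        mean_d2, n_pairs = mean_d2_cross_chromosome(G, G.samples, np.arange(60))
        p = freqs["p"].to_numpy()
        het = p * (1 - p)
        floor = np.mean(np.outer(het, het)) / (2 * n)
        assert n_pairs > 1000
        assert floor / 3 <= mean_d2 <= 3 * floor


class TestResamplingDesign:
    def test_fixed_seed_reproduces_summaries(self, unascertained_sim):
        from amlink import resampling_comparison

        sim = unascertained_sim
        loadings = np.random.default_rng(1).random(sim.genotypes.n_variants)
        kwargs = dict(n_iter=4, top_k=20, min_gap_bp=500_000, seed=9,
                      roles=("father",))
        r1 = resampling_comparison(sim.genotypes, sim.pedigree, loadings, **kwargs)
        r2 = resampling_comparison(sim.genotypes, sim.pedigree, loadings, **kwargs)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        for a, b in zip(r1.iterations, r2.iterations):
            pd.testing.assert_frame_equal(a.role_means, b.role_means)

    def test_small_thinned_sets_abort(self, unascertained_sim):
        from amlink import resampling_comparison

        sim = unascertained_sim
        loadings = np.ones(sim.genotypes.n_variants)
        with pytest.raises(RuntimeError):
            resampling_comparison(sim.genotypes, sim.pedigree, loadings,
                                  n_iter=3, top_k=10_000, seed=0)

    def test_d2_difference_grows_with_ancestry_assortment(self):
        """In the offspring generation the top-vs-bottom D² gap widens with
        the spousal ancestry correlation (parents' own genotypes predate
        mating and cannot respond to it)."""
        from amlink import fit_reference_pca, resampling_comparison

        gaps = []
        for rho in (0.0, 0.6):
            sim = simulate_dataset(SimConfig(
                n_snps=800, fst=0.02, n_causal=100, n_families=400,
                rho_ancestry=rho, ascertain_simplex=False, seed=53))
            G = sim.genotypes
            founders = sim.pedigree.founder_ids()
            model = fit_reference_pca(G.subset_samples(founders), founders, k=2)
            res = resampling_comparison(
                G, sim.pedigree, np.abs(model.loadings[:, 0]),
                n_iter=20, top_k=60, seed=3, roles=("sibling",))
            t = res.table
            row = t[(t.role == "sibling") & (t.statistic == "d2")].iloc[0]
            gaps.append(row["mean_top"] - row["mean_bottom"])
        assert gaps[1] > gaps[0]


class TestAlgebraicProperties:
    """Derandomized property checks of the statistic definitions."""

    @given(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_d_squared_invariant_to_any_relabeling(self, raw):
        f = np.array(raw)
        f = f / f.sum()
        pAB, pAb, paB, pab = f
        variants = [
            (pAB, pAb, paB, pab),
            (pAb, pAB, pab, paB),   # relabel locus 2
            (paB, pab, pAB, pAb),   # relabel locus 1
            (pab, paB, pAb, pAB),   # relabel both
        ]
        vals = [d_squared(np.array(v)) for v in variants]
        assert max(vals) - min(vals) <= 1e-12

    @given(st.integers(0, 80), st.integers(0, 80), st.integers(0, 80))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_wrights_f_bounded_above_by_one(self, a, h, b):
        if a + h + b == 0:
            return
        f = wrights_f(a, h, b)
        if not np.isnan(f):
            assert f <= 1.0 + 1e-12
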