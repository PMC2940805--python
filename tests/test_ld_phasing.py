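import itertools

import numpy as np
import pytest
from scipy import optimize

from hapcarrier import (
    GameteTable,
    assign_phases,
    binomial_se,
    em_gamete_frequencies,
    em_haplotype_frequencies,
    ld_statistics,
)
from hapcarrier.ld_phasing import expected_haplotype_counts


def simulate_genotypes_from_gametes(freqs, n, seed):
    """Unphased two-marker dosages from gamete frequencies (AB, Ab, aB, ab)."""
    rng = np.random.default_rng(seed)
    gametes = rng.choice(4, size=(n, 2), p=freqs)
    # gamete 0/1 carry the minor allele at marker 1; 0/2 at marker 2
    d1 = np.isin(gametes, (0, 1)).sum(axis=1).astype(float)
    d2 = np.isin(gametes, (0, 2)).sum(axis=1).astype(float)
    return d1, d2


def simulate_genotypes_from_pool(haps, freqs, n, seed):
    """Unphased dosages from a haplotype pool (tuples of 0/1)."""
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(haps), size=(n, 2), p=freqs)
    H = np.asarray(haps)
    return (H[idx[:, 0]] + H[idx[:, 1]]).astype(float)


class TestTwoMarkerEM:
    def test_no_double_heterozygotes_closed_form(self):
        d1 = np.array([0, 0, 1, 2, 2], dtype=float)
        d2 = np.array([0, 0, 0, 2, 2], dtype=float)
        g = em_gamete_frequencies(d1, d2)
        # phase unambiguous: direct gamete counts /10
        assert g.f_AB == pytest.approx(4 / 10)
        assert g.f_Ab == pytest.approx(1 / 10)
        assert g.f_aB == pytest.approx(0.0)
        assert g.f_ab == pytest.approx(5 / 10)

    def test_complete_ld_identical_columns(self):
        rng = np.random.default_rng(1)
        d = rng.choice([0.0, 1.0, 2.0], size=200, p=[0.49, 0.42, 0.09])
        g = em_gamete_frequencies(d, d)
        maf = d.sum() / 400
        assert g.f_AB == pytest.approx(maf, abs=1e-9)
        assert g.f_ab == pytest.approx(1 - maf, abs=1e-9)
        assert g.f_Ab == pytest.approx(0.0, abs=1e-9)
        assert g.f_aB == pytest.approx(0.0, abs=1e-9)

    def test_missing_pairs_dropped(self):
        d1 = np.array([0, 1, np.nan, 2])
        d2 = np.array([0, np.nan, 1, 2])
        g = em_gamete_frequencies(d1, d2)
        assert g.n_chromosomes == 4  # 2 complete individuals

    def test_em_matches_grid_search_oracle(self):
        """EM agrees with direct 1-parameter likelihood maximization over
        the double-heterozygote split."""
        d1, d2 = simulate_genotypes_from_gametes([0.5, 0.2, 0.2, 0.1], 200, 9)
        g = em_gamete_frequencies(d1, d2)

        # oracle: likelihood over the family indexed by the cis split t
        table = np.zeros((3, 3))
        for a, b in zip(d1.astype(int), d2.astype(int)):
            table[a, b] += 1
        n = len(d1)
        base = np.zeros(4)
        contrib = {
            (0, 0): (0, 0, 0, 2), (0, 1): (0, 0, 1, 1), (0, 2): (0, 0, 2, 0),
            (1, 0): (0, 1, 0, 1), (1, 2): (1, 0, 1, 0),
            (2, 0): (0, 2, 0, 0), (2, 1): (1, 1, 0, 0), (2, 2): (2, 0, 0, 0),
        }
        for gpair, gam in contrib.items():
            base += table[gpair] * np.asarray(gam)
        n_dh = table[1, 1]

        def negll(t):
            f = (base + n_dh * np.array([t, 1 - t, 1 - t, t])) / (2 * n)
            ll = 0.0
            probs = {
                (0, 0): f[3] ** 2, (0, 1): 2 * f[2] * f[3], (0, 2): f[2] ** 2,
                (1, 0): 2 * f[1] * f[3], (1, 2): 2 * f[0] * f[2],
                (2, 0): f[1] ** 2, (2, 1): 2 * f[0] * f[1], (2, 2): f[0] ** 2,
                (1, 1): 2 * f[0] * f[3] + 2 * f[1] * f[2],
            }
            for gpair, p in probs.items():
                if table[gpair]:
                    ll += table[gpair] * np.log(max(p, 1e-300))
            return -ll

        grid = np.linspace(0, 1, 2001)
        t0 = grid[np.argmin([negll(t) for t in grid])]
        res = optimize.minimize_scalar(
            negll, bounds=(max(t0 - 0.001, 0), min(t0 + 0.001, 1)),
            method="bounded", options={"xatol": 1e-12},
        )
        best = (base + n_dh * np.array(
            [res.x, 1 - res.x, 1 - res.x, res.x])) / (2 * n)
        np.testing.assert_allclose(g.freqs, best, atol=1e-6)


class TestLDStatistics:
    def test_perfect_ld(self):
        s = ld_statistics(GameteTable(0.3, 0.0, 0.0, 0.7))
        assert s.D_prime == pytest.approx(1.0)
        assert s.r2 == pytest.approx(1.0)

    def test_equilibrium(self):
        s = ld_statistics(GameteTable(0.25, 0.25, 0.25, 0.25))
        assert (s.D, s.D_prime, s.r2, s.LOD) == (0.0, 0.0, 0.0, 0.0)

    def test_hand_arithmetic(self):
        s = ld_statistics(GameteTable(0.5, 0.1, 0.3, 0.1))
        assert s.D == pytest.approx(0.5 - 0.6 * 0.8)
        assert s.r2 == pytest.approx(0.02**2 / (0.6 * 0.4 * 0.8 * 0.2))

    def test_monomorphic_undefined(self):
        s = ld_statistics(GameteTable(0.0, 0.0, 0.3, 0.7))
        assert np.isnan(s.D_prime) and np.isnan(s.r2)

    def test_bounds_and_implications(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            f = rng.dirichlet(np.ones(4))
            s = ld_statistics(GameteTable(*f, n_chromosomes=100))
            if np.isnan(s.D_prime):
                continue
            assert abs(s.D_prime) <= 1 + 1e-12
            assert -1e-12 <= s.r2 <= 1 + 1e-12
            if s.r2 > 1 - 1e-9:
                assert abs(s.D_prime) > 1 - 1e-9
        # D' = +-1 exactly when one gamete class is absent
        s = ld_statistics(GameteTable(0.5, 0.0, 0.2, 0.3))
        assert abs(s.D_prime) == pytest.approx(1.0)

    def test_lod_positive_under_ld(self):
        d1, d2 = simulate_genotypes_from_gametes([0.45, 0.05, 0.05, 0.45], 200, 3)
        s = ld_statistics(em_gamete_frequencies(d1, d2))
        assert s.LOD > 3


class TestBinomialSE:
    def test_published_se_value(self):
        assert round(binomial_se(0.679, 358), 3) == 0.025

    @pytest.mark.parametrize("freq", [0.0, 1.0])
    def test_degenerate(self, freq):
        assert binomial_se(freq, 100) == 0.0

    def test_closed_form(self):
        assert binomial_se(0.5, 100) == pytest.approx(0.05)


TABLE6_POOL = {
    "AATA": 0.679, "AGTG": 0.003, "CATA": 0.073, "CACA": 0.114,
    "CACG": 0.003, "CGTA": 0.031, "CGTG": 0.097,
}


def pool_codes(pool):
    """0/1 haplotype tuples (1 = minor allele by pool frequency)."""
    haps = list(pool)
    k = len(haps[0])
    codes = []
    for h in haps:
        code = []
        for j in range(k):
            chars = sorted({x[j] for x in haps})
            freq = {c: sum(f for x, f in pool.items() if x[j] == c)
                    for c in chars}
            minor = min(chars, key=lambda c: (freq[c], c))
            code.append(1 if h[j] == minor else 0)
        codes.append(tuple(code))
    return codes


class TestMultiMarkerEM:
    def test_all_homozygous_equals_direct_counts(self):
        geno = np.array([[0, 0, 2], [2, 2, 0], [0, 0, 2], [0, 0, 0]], dtype=float)
        dist = em_haplotype_frequencies(geno, seed=1)
        f = {h: p for h, p in zip(dist.haplotypes, dist.frequencies)}
        assert f["001"] == pytest.approx(4 / 8)
        assert f["110"] == pytest.approx(2 / 8)
        assert f["000"] == pytest.approx(2 / 8)

    def test_matches_full_simplex_numerical_maximization(self):
        """3 markers, 30 individuals: EM frequencies agree with direct
        likelihood maximization over the full 8-haplotype simplex."""
        haps = [(0, 0, 0), (1, 1, 0), (0, 1, 1), (1, 0, 1)]
        geno = simulate_genotypes_from_pool(haps, [0.4, 0.3, 0.2, 0.1], 30, 13)
        dist = em_haplotype_frequencies(geno, seed=2, prune_floor=0.0,
                                        restarts=10)

        all_haps = list(itertools.product((0, 1), repeat=3))
        pairs_per_ind = []
        for row in geno.astype(int):
            pairs = [
                (h1, h2)
                for i, h1 in enumerate(all_haps)
                for h2 in all_haps[i:]
                if all(a + b == g for a, b, g in zip(h1, h2, row))
            ]
            pairs_per_ind.append(pairs)

        def negll(z):
            f = np.exp(z - z.max())
            f = f / f.sum()
            fd = dict(zip(all_haps, f))
            ll = 0.0
            for pairs in pairs_per_ind:
                p = sum(
                    fd[h1] * fd[h2] * (2 if h1 != h2 else 1) for h1, h2 in pairs
                )
                ll += np.log(max(p, 1e-300))
            return -ll

        rng = np.random.default_rng(0)
        best = None
        for _ in range(20):
            res = optimize.minimize(negll, rng.normal(size=8), method="Nelder-Mead",
                                    options={"maxiter": 20000, "fatol": 1e-12,
                                             "xatol": 1e-9})
            if best is None or res.fun < best.fun:
                best = res
        f = np.exp(best.x - best.x.max())
        f = f / f.sum()
        oracle = dict(zip(all_haps, f))
        est = {c: p for c, p in zip(dist.codes, dist.frequencies)}
        for h in all_haps:
            assert est.get(h, 0.0) == pytest.approx(oracle[h], abs=1e-4)

    def test_recovers_published_pool_at_n_1000(self):
        haps = list(TABLE6_POOL)
        freqs = np.array(list(TABLE6_POOL.values()))
        codes = pool_codes(TABLE6_POOL)
        geno = simulate_genotypes_from_pool(codes, freqs, 1000, 99)
        dist = em_haplotype_frequencies(geno, seed=4)
        est = {c: p for c, p in zip(dist.codes, dist.frequencies)}
        for h, code in zip(haps, codes):
            assert abs(est.get(code, 0.0) - TABLE6_POOL[h]) < 0.02

    def test_loglik_monotone_and_frequencies_normalized(self):
        geno = simulate_genotypes_from_pool(
            [(0, 0, 0, 0), (1, 1, 0, 0), (0, 0, 1, 1), (1, 1, 1, 1)],
            [0.4, 0.3, 0.2, 0.1], 120, 21,
        )
        dist = em_haplotype_frequencies(geno, seed=5)
        trace = np.array(dist.loglik_trace)
        assert (np.diff(trace) >= -1e-9).all()
        assert dist.frequencies.sum() == pytest.approx(1.0)

    def test_partition_ligation_matches_full_em_12_markers(self):
        rng = np.random.default_rng(8)
        haps = [tuple(rng.integers(0, 2, size=12)) for _ in range(6)]
        freqs = rng.dirichlet(np.ones(6) * 3)
        geno = simulate_genotypes_from_pool(haps, freqs, 300, 77)
        full = em_haplotype_frequencies(geno, seed=6, full_em_limit=12)
        pl = em_haplotype_frequencies(geno, seed=6)  # k=12 > 10 -> ligation
        keys = set(full.codes) | set(pl.codes)
        f_full = {c: p for c, p in zip(full.codes, full.frequencies)}
        f_pl = {c: p for c, p in zip(pl.codes, pl.frequencies)}
        tv = 0.5 * sum(abs(f_full.get(k, 0) - f_pl.get(k, 0)) for k in keys)
        assert tv < 1e-3

    def test_empty_subset_errors(self):
        geno = np.zeros((4, 2))
        with pytest.raises(ValueError, match="subset"):
            em_haplotype_frequencies(geno, subset=np.zeros(4, dtype=bool))

    def test_all_missing_marker_errors(self):
        geno = np.array([[0.0, np.nan], [1.0, np.nan]])
        with pytest.raises(ValueError, match="M2"):
            em_haplotype_frequencies(geno)


class TestAssignPhases:
    def test_single_heterozygous_site_unique_pair(self):
        geno = simulate_genotypes_from_pool(
            [(0, 0), (1, 1)], [0.6, 0.4], 100, 3
        )
        dist = em_haplotype_frequencies(geno, seed=1)
        out = assign_phases(np.array([[1.0, 1.0]]), dist)
        assert out[0].posterior > 0.9  # only the cis pair is retained

    def test_double_heterozygote_posterior_arithmetic(self):
        geno = simulate_genotypes_from_pool(
            [(1, 1), (1, 0), (0, 1), (0, 0)], [0.45, 0.05, 0.05, 0.45], 3000, 17
        )
        dist = em_haplotype_frequencies(geno, seed=2)
        out = assign_phases(np.array([[1.0, 1.0]]), dist)
        a = out[0]
        assert {a.hap1, a.hap2} == {"11", "00"}
        f = {c: p for c, p in zip(dist.codes, dist.frequencies)}
        cis, trans = f[(1, 1)] * f[(0, 0)], f[(1, 0)] * f[(0, 1)]
        assert a.posterior == pytest.approx(cis / (cis + trans))
        assert a.posterior == pytest.approx(0.988, abs=0.01)

    def test_homozygote_posterior_one(self):
        geno = simulate_genotypes_from_pool([(0, 0), (1, 1)], [0.6, 0.4], 50, 5)
        dist = em_haplotype_frequencies(geno, seed=3)
        out = assign_phases(np.array([[0.0, 0.0]]), dist)
        assert out[0].hap1 == out[0].hap2
        assert out[0].posterior == pytest.approx(1.0)

    def test_inconsistent_genotype_uniform_fallback(self):
        geno = simulate_genotypes_from_pool([(0, 0), (1, 1)], [0.6, 0.4], 50, 5)
        dist = em_haplotype_frequencies(geno, seed=3)
        out = assign_phases(np.array([[2.0, 0.0]]), dist)
        assert out[0].flagged

    def test_expected_counts_sum_to_two(self):
        geno = simulate_genotypes_from_pool(
            [(0, 0, 0), (1, 1, 0), (0, 1, 1)], [0.5, 0.3, 0.2], 80, 10
        )
        dist = em_haplotype_frequencies(geno, seed=7)
        counts = expected_haplotype_counts(geno, dist)
        np.testing.assert_allclose(counts.sum(axis=1), 2.0, atol=1e-9)
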