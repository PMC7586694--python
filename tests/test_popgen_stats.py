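import itertools

import numpy as np
import pytest
from scipy import stats

from oleapop.io_formats import (
    AnalysisDataset, GeneModel, GenotypeMatrix, LoadReport, PopulationManifest,
)
from oleapop.popgen_stats import (
    SFSpectrum, compare_sfs, derived_sfs, per_site_pi, tajima_constants,
    tajimas_d, tajimas_d_genes, weighted_fst, windowed_pi,
    _mwu_exact_two_sided, _mwu_from_histograms,
)
from oleapop.synthetic_data import expected_class_spectrum, simulate_class_sfs

from conftest import random_matrix


def wrap(matrix, scaffold_len=None, roles=None):
    length = scaffold_len or int(matrix.pos.max())
    reference = {str(sc): "A" * length for sc in set(matrix.scaffolds)}
    roles = roles or {s: "wild" for s in matrix.samples}
    return AnalysisDataset(matrix, [], reference,
                           PopulationManifest(roles), LoadReport())


# ---------------------------------------------------------------------------
# pi
# ---------------------------------------------------------------------------

class TestWindowedPi:
    def test_monomorphic_window_is_zero(self):
        m = GenotypeMatrix(
            samples=["a", "b"], scaffolds=np.array(["s"] * 2, dtype=object),
            pos=np.array([10, 20]),
            ref_allele=np.array(["A", "A"], dtype=object),
            alt_allele=np.array(["G", "G"], dtype=object),
            dosage=np.zeros((2, 2), dtype=np.int8))
        out = windowed_pi(wrap(m, scaffold_len=100), "wild", window_bp=100)
        assert out["pi"].iloc[0] == 0.0

    def test_two_homozygous_samples_k_over_window(self):
        k, L = 7, 20_000
        dosage = np.zeros((k, 2), dtype=np.int8)
        dosage[:, 0] = 2  # sample a carries ALT at all k sites, b REF
        m = GenotypeMatrix(
            samples=["a", "b"], scaffolds=np.array(["s"] * k, dtype=object),
            pos=np.arange(1, k + 1) * 100,
            ref_allele=np.array(["A"] * k, dtype=object),
            alt_allele=np.array(["G"] * k, dtype=object),
            dosage=dosage)
        out = windowed_pi(wrap(m, scaffold_len=L), "wild", window_bp=L)
        # 2 distinct haplotypes among 4 chromosomes: per site
        # 2*(1/2)*(1/2)*(4/3) = 2/3 -> not k/L; with two *individuals* the
        # chromosome-pair definition over 4 chromosomes applies
        expected = k * (2 * 0.5 * 0.5 * 4 / 3) / L
        assert out["pi"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_matches_bruteforce_chromosome_pairs(self):
        rng = np.random.default_rng(12)
        m = random_matrix(rng, n_variants=80, n_samples=10, missing_rate=0.1)
        ds = wrap(m, scaffold_len=1000)
        out = windowed_pi(ds, "wild", window_bp=250)
        # oracle: expand each called sample into two chromosomes; per site
        # mean pairwise difference over all chromosome pairs
        for _, row in out.iterrows():
            in_w = (m.pos >= row.start) & (m.pos <= row.end)
            total = 0.0
            for i in np.flatnonzero(in_w):
                chroms = []
                for j in range(m.n_samples):
                    d = m.dosage[i, j]
                    if d != -1:
                        chroms += [1] * d + [0] * (2 - d)
                if len(chroms) < 2:
                    continue
                diffs = sum(x != y for x, y in itertools.combinations(chroms, 2))
                total += diffs / (len(chroms) * (len(chroms) - 1) / 2)
            expected = total / (row.end - row.start + 1)
            assert row.pi == pytest.approx(expected, abs=1e-12)

    def test_tiling_conservation(self):
        rng = np.random.default_rng(13)
        m = random_matrix(rng, n_variants=120, n_samples=8)
        ds = wrap(m, scaffold_len=1200)
        fine = windowed_pi(ds, "wild", window_bp=100)
        total_fine = (fine["pi"] * (fine["end"] - fine["start"] + 1)).sum()
        assert total_fine == pytest.approx(np.nansum(per_site_pi(m.dosage)),
                                           abs=1e-9)

    def test_requires_two_samples(self):
        rng = np.random.default_rng(14)
        m = random_matrix(rng, n_variants=5, n_samples=1)
        with pytest.raises(ValueError, match=">= 2"):
            windowed_pi(wrap(m), "wild")


# ---------------------------------------------------------------------------
# Fst
# ---------------------------------------------------------------------------

def _two_pop_dataset(rng, n_var=200, nA=6, nB=6, missing_rate=0.0):
    m = random_matrix(rng, n_variants=n_var, n_samples=nA + nB,
                      missing_rate=missing_rate)
    roles = {s: ("wild" if i < nA else "cultivars_set1")
             for i, s in enumerate(m.samples)}
    return wrap(m, roles=roles), m, nA, nB


def _wc_oracle_site(dA, dB):
    """Scalar textbook Weir-Cockerham (1984) a, b, c for one site."""
    out = []
    for dos in (dA, dB):
        dos = [d for d in dos if d != -1]
        n = len(dos)
        if n == 0:
            return None
        p = sum(dos) / (2 * n)
        h = sum(1 for d in dos if d == 1) / n
        out.append((n, p, h))
    (nA, pA, hA), (nB, pB, hB) = out
    r = 2
    nbar = (nA + nB) / r
    nc = (nA + nB - (nA ** 2 + nB ** 2) / (nA + nB)) / (r - 1)
    pbar = (nA * pA + nB * pB) / (nA + nB)
    s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (nA * hA + nB * hB) / (nA + nB)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


class TestWeightedFst:
    def test_no_differentiation_near_zero(self):
        rng = np.random.default_rng(20)
        p = rng.uniform(0.1, 0.9, size=1000)
        dosage = rng.binomial(2, p[:, None], size=(1000, 100)).astype(np.int8)
        m = GenotypeMatrix(
            samples=[f"s{i}" for i in range(100)],
            scaffolds=np.array(["s"] * 1000, dtype=object),
            pos=np.arange(1, 1001),
            ref_allele=np.array(["A"] * 1000, dtype=object),
            alt_allele=np.array(["G"] * 1000, dtype=object),
            dosage=dosage)
        roles = {s: ("wild" if i < 50 else "cultivars_set1")
                 for i, s in enumerate(m.samples)}
        fst = weighted_fst(wrap(m, roles=roles), "wild", "cultivars_set1")
        assert abs(fst) < 0.02

    def test_complete_fixation_is_one(self):
        dosage = np.hstack([np.zeros((50, 4)), np.full((50, 4), 2)]).astype(np.int8)
        m = GenotypeMatrix(
            samples=[f"s{i}" for i in range(8)],
            scaffolds=np.array(["s"] * 50, dtype=object),
            pos=np.arange(1, 51),
            ref_allele=np.array(["A"] * 50, dtype=object),
            alt_allele=np.array(["G"] * 50, dtype=object),
            dosage=dosage)
        roles = {s: ("wild" if i < 4 else "cultivars_set1")
                 for i, s in enumerate(m.samples)}
        assert weighted_fst(wrap(m, roles=roles), "wild",
                            "cultivars_set1") == pytest.approx(1.0)

    def test_matches_independent_scalar_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            ds, m, nA, nB = _two_pop_dataset(rng, n_var=60, missing_rate=0.1)
            fst = weighted_fst(ds, "wild", "cultivars_set1")
            num = den = 0.0
            for i in range(m.n_variants):
                comps = _wc_oracle_site(list(m.dosage[i, :nA]),
                                        list(m.dosage[i, nA:]))
                if comps is None:
                    continue
                a, b, c = comps
                num += a
                den += a + b + c
            assert fst == pytest.approx(num / den, abs=1e-10)

    def test_population_swap_invariance(self):
        rng = np.random.default_rng(22)
        ds, *_ = _two_pop_dataset(rng)
        f1 = weighted_fst(ds, "wild", "cultivars_set1")
        f2 = weighted_fst(ds, "cultivars_set1", "wild")
        assert f1 == pytest.approx(f2, abs=1e-12)

    def test_all_monomorphic_is_missing(self):
        rng = np.random.default_rng(23)
        m = random_matrix(rng, n_variants=10, n_samples=8)
        m.dosage[:] = 0
        roles = {s: ("wild" if i < 4 else "cultivars_set1")
                 for i, s in enumerate(m.samples)}
        assert np.isnan(weighted_fst(wrap(m, roles=roles), "wild",
                                     "cultivars_set1"))


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def _tajima_oracle(S, pi_sum, n):
    """Independent transcription of Tajima's constants."""
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi_sum - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimasD:
    def test_formula_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(30)
        for _ in range(100):
            n = int(rng.integers(4, 60))
            S = int(rng.integers(1, 50))
            pi_sum = float(rng.uniform(0, 3 * S))
            assert tajimas_d(S, pi_sum, n) == pytest.approx(
                _tajima_oracle(S, pi_sum, n), abs=1e-10)

    def test_all_singletons_negative(self):
        n = 20
        S = 10
        # each singleton site: p = 1/n, pi = 2*(1/n)*(1-1/n)*n/(n-1) = 2/n
        pi_sum = S * 2 / n
        assert tajimas_d(S, pi_sum, n) < 0

    def test_gene_below_min_snps_skipped(self, cohort_sim):
        table, skipped = tajimas_d_genes(cohort_sim.dataset, "wild",
                                         min_snps=4)
        assert set(table["gene_id"]).isdisjoint(set(skipped["gene_id"]))
        assert (table["n_snps"] >= 4).all()
        total = len(table) + len(skipped)
        assert total == len(cohort_sim.dataset.genes)

    def test_fewer_than_four_chromosomes_is_error(self):
        with pytest.raises(ValueError):
            tajima_constants(3)

    def test_neutral_coalescent_expectation_msprime(self):
        """Independent oracle: msprime constant-size neutral genes should
        average D ~ 0; diversity must match tskit's computation."""
        import msprime

        n_dip = 10
        d_values = []
        rng_seeds = range(1, 201)
        for seed in rng_seeds:
            ts = msprime.sim_ancestry(
                samples=n_dip, population_size=1000, sequence_length=3000,
                recombination_rate=0, random_seed=seed)
            mts = msprime.sim_mutations(ts, rate=1.5e-6, random_seed=seed,
                                        model=msprime.BinaryMutationModel())
            geno = mts.genotype_matrix()
            if geno.shape[0] < 4:
                continue
            dosage = (geno[:, ::2] + geno[:, 1::2]).astype(np.int8)
            n = 2 * n_dip
            p = geno.mean(axis=1)
            pi_sum = float((2 * p * (1 - p) * n / (n - 1)).sum())
            S = geno.shape[0]
            d_values.append(tajimas_d(S, pi_sum, n))
            # cross-check pi against tskit's branch-agnostic site diversity
            if seed <= 20:
                pi_tskit = mts.diversity(span_normalise=False)
                assert pi_sum == pytest.approx(float(pi_tskit), rel=1e-9)
        assert len(d_values) > 150
        assert abs(np.mean(d_values)) < 0.15


# ---------------------------------------------------------------------------
# derived SFS
# ---------------------------------------------------------------------------

class TestDerivedSFS:
    def _dataset(self, dosage, out_dosage):
        n_var = dosage.shape[0]
        full = np.hstack([dosage, out_dosage[:, None]]).astype(np.int8)
        samples = [f"s{i}" for i in range(dosage.shape[1])] + ["og"]
        m = GenotypeMatrix(
            samples=samples, scaffolds=np.array(["s"] * n_var, dtype=object),
            pos=np.arange(1, n_var + 1),
            ref_allele=np.array(["A"] * n_var, dtype=object),
            alt_allele=np.array(["G"] * n_var, dtype=object),
            dosage=full)
        roles = {s: "wild" for s in samples[:-1]}
        roles["og"] = "outgroup"
        return wrap(m, roles=roles)

    def test_hom_ref_outgroup_derived_equals_alt_count(self):
        rng = np.random.default_rng(40)
        dosage = rng.integers(0, 3, size=(50, 5)).astype(np.int8)
        ds = self._dataset(dosage, np.zeros(50, dtype=np.int8))
        sfs = derived_sfs(ds, "wild")
        alt = dosage.sum(axis=1)
        seg = (alt > 0) & (alt < 10)
        assert sfs.n_sites == int(seg.sum())
        np.testing.assert_array_equal(
            sfs.counts, np.bincount(alt[seg], minlength=11)[1:10])

    def test_hom_alt_outgroup_flips_polarity(self):
        dosage = np.array([[2, 2, 0]], dtype=np.int8)  # alt count 4 of 6
        ds = self._dataset(dosage, np.array([2], dtype=np.int8))
        sfs = derived_sfs(ds, "wild")
        assert sfs.counts[2 - 1] == 1  # derived = 6 - 4 = 2

    def test_het_outgroup_excluded(self):
        dosage = np.array([[2, 0, 1]], dtype=np.int8)
        ds = self._dataset(dosage, np.array([1], dtype=np.int8))
        sfs = derived_sfs(ds, "wild")
        assert sfs.n_sites == 0 and sfs.n_excluded == 1

    def test_neutral_spectrum_matches_generator_expectation(self):
        counts = simulate_class_sfs(10_000, 30, 1.0, seed=3)
        q = expected_class_spectrum(30, 1.0)
        res = stats.chisquare(counts, q * counts.sum())
        assert res.pvalue > 0.01


# ---------------------------------------------------------------------------
# SFS comparison
# ---------------------------------------------------------------------------

class TestCompareSFS:
    def test_identical_spectra_p_near_one(self):
        counts = simulate_class_sfs(2000, 20, 1.0, seed=5)
        a = SFSpectrum("a", 20, counts)
        b = SFSpectrum("b", 20, counts.copy())
        _, p = compare_sfs(a, b)
        assert p >= 0.99

    def test_strong_left_shift_tiny_p(self):
        n = 6
        rng = np.random.default_rng(6)
        counts = rng.multinomial(1000, np.full(n - 1, 1 / (n - 1)))
        shifted = np.zeros_like(counts)
        shifted[:-1] = counts[1:]
        shifted[0] += counts[0]
        a = SFSpectrum("a", n, counts)
        b = SFSpectrum("b", n, shifted)
        _, p = compare_sfs(a, b)
        assert p < 1e-6

    def test_asymptotic_matches_scipy(self):
        rng = np.random.default_rng(50)
        n = 12
        for _ in range(100):
            ca = rng.integers(0, 30, size=n - 1)
            cb = rng.integers(0, 30, size=n - 1)
            if ca.sum() == 0 or cb.sum() == 0:
                continue
            U, p = compare_sfs(SFSpectrum("a", n, ca), SFSpectrum("b", n, cb),
                               exact_max=0)
            xa = np.repeat(np.arange(1, n), ca)
            xb = np.repeat(np.arange(1, n), cb)
            ref = stats.mannwhitneyu(xa, xb, alternative="two-sided",
                                     method="asymptotic", use_continuity=True)
            assert U == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_exact_path_matches_enumeration(self):
        rng = np.random.default_rng(51)
        checked = 0
        while checked < 20:
            ca = rng.integers(0, 3, size=5)
            cb = rng.integers(0, 3, size=5)
            if ca.sum() == 0 or cb.sum() == 0 or ca.sum() + cb.sum() > 11:
                continue
            checked += 1
            p_dp = _mwu_exact_two_sided(ca, cb)
            # oracle: enumerate all assignments of pooled values to A
            n = 6
            xa = np.repeat(np.arange(1, n), ca)
            xb = np.repeat(np.arange(1, n), cb)
            pooled = np.concatenate([xa, xb])
            n1 = len(xa)

            def ustat(x, y):
                return sum((xi > yi) + 0.5 * (xi == yi)
                           for xi in x for yi in y)

            u_obs = ustat(xa, xb)
            center = n1 * len(xb) / 2
            hits = total = 0
            for idxs in itertools.combinations(range(len(pooled)), n1):
                mask = np.zeros(len(pooled), bool)
                mask[list(idxs)] = True
                u = ustat(pooled[mask], pooled[~mask])
                total += 1
                hits += abs(u - center) >= abs(u_obs - center) - 1e-9
            assert p_dp == pytest.approx(hits / total, abs=1e-12)

    def test_empty_spectrum_gives_missing_p(self):
        a = SFSpectrum("a", 10, np.zeros(9, dtype=int))
        b = SFSpectrum("b", 10, np.arange(9))
        _, p = compare_sfs(a, b)
        assert np.isnan(p)
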