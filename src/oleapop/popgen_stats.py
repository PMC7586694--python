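"""Diversity and neutrality statistics: windowed pi, Weir-Cockerham Fst,
per-gene Tajima's D, outgroup-polarized derived SFS and SFS contrasts.

pi uses the unbiased per-site estimator 2 p (1-p) n/(n-1) over called
chromosomes, summed over sites and divided by window length; windows are
fixed 20-kb tiles anchored at position 1 of each scaffold, with the
trailing partial window using its true bp length as denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AnalysisDataset, GenotypeMatrix, MISSING


def _resolve_population(dataset: AnalysisDataset, population) -> np.ndarray:
    """Role name, list of sample names, or index array -> sample indices."""
    if isinstance(population, str):
        samples = dataset.manifest.samples_for(population)
        if samples:
            return dataset.genotypes.sample_indices(samples)
        if population in dataset.genotypes.samples:
            return dataset.genotypes.sample_indices([population])
        raise ValueError(f"{population!r} is neither a role with samples "
                         "nor a sample name")
    population = list(population)
    if population and isinstance(population[0], str):
        return dataset.genotypes.sample_indices(population)
    return np.asarray(population, dtype=np.intp)


# ---------------------------------------------------------------------------
# pi
# ---------------------------------------------------------------------------

def per_site_pi(dosage: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity 2 p (1-p) n/(n-1) over called
    chromosomes; NaN where fewer than 2 chromosomes are called."""
    called = dosage != MISSING
    n = 2 * called.sum(axis=1).astype(float)
    alt = np.where(called, dosage, 0).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / n
        pi = 2 * p * (1 - p) * n / (n - 1)
    pi[n < 2] = np.nan
    return pi


def windowed_pi(dataset: AnalysisDataset, population,
                window_bp: int = 20_000) -> pd.DataFrame:
    """Nucleotide diversity per fixed window of ``window_bp``.

    Returns columns scaffold, start, end, n_snps, pi.  Windows tile each
    scaffold from position 1; pi is NaN for windows where every site is
    uncallable (all-missing), 0 for windows without SNPs.
    """
    idx = _resolve_population(dataset, population)
    if len(idx) < 2:
        raise ValueError("population must have >= 2 samples")
    gm = dataset.genotypes
    site_pi = per_site_pi(gm.dosage[:, idx])
    rows = []
    for sc, length in dataset.scaffold_lengths().items():
        on = gm.scaffolds == sc
        pos = gm.pos[on]
        vals = site_pi[on]
        for wstart in range(1, length + 1, window_bp):
            wend = min(wstart + window_bp - 1, length)
            in_w = (pos >= wstart) & (pos <= wend)
            v = vals[in_w]
            n_snps = int(in_w.sum())
            if n_snps and np.isnan(v).all():
                value = np.nan
            else:
                value = float(np.nansum(v)) / (wend - wstart + 1)
            rows.append((sc, wstart, wend, n_snps, value))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end",
                                       "n_snps", "pi"])


# ---------------------------------------------------------------------------
# Weir-Cockerham Fst
# ---------------------------------------------------------------------------

def _wc_components(dosA: np.ndarray, dosB: np.ndarray):
    """Per-site Weir-Cockerham (1984) variance components a, b, c for two
    populations of diploids, vectorized over sites."""
    r = 2.0
    comps = []
    for dos in (dosA, dosB):
        called = dos != MISSING
        n_i = called.sum(axis=1).astype(float)              # individuals
        alt = np.where(called, dos, 0).sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = alt / (2 * n_i)
            h_i = np.where(called, dos == 1, False).sum(axis=1) / n_i
        comps.append((n_i, p_i, h_i))
    (nA, pA, hA), (nB, pB, hB) = comps
    usable = (nA > 0) & (nB > 0)
    n_sum = nA + nB
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_sum / r
        nc = (n_sum - (nA ** 2 + nB ** 2) / n_sum) / (r - 1)
        pbar = (nA * pA + nB * pB) / n_sum
        s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (nA * hA + nB * hB) / n_sum
        a = (nbar / nc) * (s2 - (1 / (nbar - 1))
                           * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2
                                   - ((2 * nbar - 1) / (4 * nbar)) * hbar)
        c = hbar / 2
    for arr in (a, b, c):
        arr[~usable] = np.nan
    return a, b, c


def weighted_fst(dataset: AnalysisDataset, popA, popB,
                 per_window: bool = False, window_bp: int = 20_000):
    """Weir-Cockerham weighted Fst between two populations.

    The weighted value is the ratio of summed variance components
    (sum a / sum(a+b+c)) across sites, not the mean of per-site ratios.
    Returns a float, or a window DataFrame when ``per_window``.  NaN when
    every site is monomorphic in the union.
    """
    iA = _resolve_population(dataset, popA)
    iB = _resolve_population(dataset, popB)
    if len(iA) < 2 or len(iB) < 2:
        raise ValueError("both populations need >= 2 samples")
    gm = dataset.genotypes
    a, b, c = _wc_components(gm.dosage[:, iA], gm.dosage[:, iB])
    if not per_window:
        num = np.nansum(a)
        den = np.nansum(a + b + c)
        return float(num / den) if den > 0 else np.nan
    rows = []
    for sc, length in dataset.scaffold_lengths().items():
        on = gm.scaffolds == sc
        pos = gm.pos[on]
        for wstart in range(1, length + 1, window_bp):
            wend = min(wstart + window_bp - 1, length)
            in_w = (pos >= wstart) & (pos <= wend)
            num = np.nansum(a[on][in_w])
            den = np.nansum((a + b + c)[on][in_w])
            rows.append((sc, wstart, wend, int(in_w.sum()),
                         float(num / den) if den > 0 else np.nan))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end",
                                       "n_snps", "fst"])


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict:
    """The a1, a2, b1, b2, c1, c2, e1, e2 constants for sample size n
    (chromosomes)."""
    if n < 4:
        raise ValueError("Tajima's D requires >= 4 chromosomes")
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(n_segregating: int, pi_sum: float, n: int) -> float:
    """Tajima's D from segregating-site count, summed pairwise diversity
    and sample size n (chromosomes); NaN when S = 0."""
    if n_segregating == 0:
        return np.nan
    k = tajima_constants(n)
    S = n_segregating
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    return float((pi_sum - S / k["a1"]) / np.sqrt(var))


def tajimas_d_genes(dataset: AnalysisDataset, population, genes=None,
                    min_snps: int = 4, n_chromosomes: int | None = None):
    """Per-gene Tajima's D over CDS sites for one population.

    Genes with fewer than ``min_snps`` segregating CDS sites are omitted
    from the result and listed in the returned skipped report.  The sample
    size defaults to 2 x samples; sites with any missing call in the
    population are excluded.
    """
    idx = _resolve_population(dataset, population)
    if len(idx) < 2:
        raise ValueError("population must have >= 2 samples")
    n = n_chromosomes if n_chromosomes is not None else 2 * len(idx)
    if n < 4:
        raise ValueError("need >= 4 chromosomes for Tajima's D")
    genes = genes if genes is not None else dataset.genes
    gm = dataset.genotypes
    dos = gm.dosage[:, idx]
    complete = (dos != MISSING).all(axis=1)
    alt = dos.sum(axis=1)
    seg = complete & (alt > 0) & (alt < 2 * len(idx))
    p = alt / (2.0 * len(idx))
    site_pi = 2 * p * (1 - p) * (2 * len(idx)) / (2 * len(idx) - 1)

    rows, skipped = [], []
    for gene in genes:
        on = gm.scaffolds == gene.scaffold
        in_cds = np.zeros(gm.n_variants, dtype=bool)
        for s, e in gene.cds_intervals:
            in_cds |= on & (gm.pos >= s) & (gm.pos <= e)
        sites = in_cds & seg
        S = int(sites.sum())
        if S < min_snps:
            skipped.append({"gene_id": gene.gene_id, "n_snps": S})
            continue
        d = tajimas_d(S, float(site_pi[sites].sum()), n)
        rows.append({"gene_id": gene.gene_id, "scaffold": gene.scaffold,
                     "n_snps": S, "tajimas_d": d})
    return (pd.DataFrame(rows, columns=["gene_id", "scaffold", "n_snps",
                                        "tajimas_d"]),
            pd.DataFrame(skipped, columns=["gene_id", "n_snps"]))


# ---------------------------------------------------------------------------
# derived SFS
# ---------------------------------------------------------------------------

@dataclass
class SFSpectrum:
    """Histogram of derived-allele counts (1..n-1) for one functional class."""

    class_label: str
    n_chromosomes: int
    counts: np.ndarray       # counts[k-1] = number of sites with k derived
    n_excluded: int = 0      # unpolarizable (het/missing outgroup) sites

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != self.n_chromosomes - 1:
            raise ValueError("counts must have length n_chromosomes - 1")

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())

    def expand(self) -> np.ndarray:
        """Per-site derived counts implied by the histogram."""
        return np.repeat(np.arange(1, self.n_chromosomes), self.counts)


def polarize(dataset: AnalysisDataset, outgroup=None):
    """Ancestral-state assignment from a homozygous outgroup.

    Returns (polarizable mask, ancestral_is_ref bool array).  Sites where
    any outgroup sample is heterozygous, missing, or outgroup samples
    disagree are unpolarizable.
    """
    gm = dataset.genotypes
    og = (_resolve_population(dataset, outgroup) if outgroup is not None
          else dataset.genotypes.sample_indices(dataset.manifest.outgroup_samples))
    if len(og) == 0:
        raise ValueError("polarization requires >= 1 outgroup sample")
    dos = gm.dosage[:, og]
    hom_ref = (dos == 0).all(axis=1)
    hom_alt = (dos == 2).all(axis=1)
    polarizable = hom_ref | hom_alt
    return polarizable, hom_ref


def derived_sfs(dataset: AnalysisDataset, population, class_mask=None,
                outgroup=None, class_label: str = "all") -> SFSpectrum:
    """Outgroup-polarized derived site frequency spectrum.

    The ancestral allele is the one carried homozygously by the outgroup;
    sites with a heterozygous or missing outgroup are excluded (tallied in
    n_excluded).  Only sites with complete calls in the population enter
    the histogram so every site has the same chromosome count.
    """
    idx = _resolve_population(dataset, population)
    n = 2 * len(idx)
    gm = dataset.genotypes
    polarizable, anc_is_ref = polarize(dataset, outgroup)
    if class_mask is None:
        class_mask = np.ones(gm.n_variants, dtype=bool)
    class_mask = np.asarray(class_mask, dtype=bool)
    dos = gm.dosage[:, idx]
    complete = (dos != MISSING).all(axis=1)
    use = polarizable & complete & class_mask
    alt = dos.sum(axis=1)
    derived = np.where(anc_is_ref, alt, n - alt)[use]
    derived = derived[(derived >= 1) & (derived <= n - 1)]
    counts = np.bincount(derived, minlength=n)[1:n]
    n_excluded = int((class_mask & ~polarizable).sum())
    return SFSpectrum(class_label, n, counts, n_excluded)


# ---------------------------------------------------------------------------
# Mann-Whitney comparison of spectra
# ---------------------------------------------------------------------------

def _mwu_from_histograms(a: np.ndarray, b: np.ndarray):
    """U statistic of sample A vs B from aligned histograms, with tie info.

    Returns (U, n1, n2, tie_term) where tie_term = sum(t^3 - t) over tie
    groups of the pooled sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.sum(), b.sum()
    cum_b = np.concatenate(([0.0], np.cumsum(b)[:-1]))  # b strictly below bin i
    U = float(np.sum(a * (cum_b + 0.5 * b)))
    g = a + b
    tie_term = float(np.sum(g ** 3 - g))
    return U, n1, n2, tie_term


def _mwu_exact_two_sided(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided permutation p-value of the MWU statistic for
    histogram data, by dynamic programming over tie groups.

    Enumerates, with multiplicity, every way of drawing n1 of the pooled
    values into sample A, tracking 2U (integer).  Two-sided p is the
    probability of |U - n1 n2 / 2| at least as large as observed.
    """
    from math import comb

    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    n1, n2 = int(a.sum()), int(b.sum())
    g = a + b
    U_obs, _, _, _ = _mwu_from_histograms(a, b)
    # State: (items assigned to A so far, 2U so far).  B items below the
    # current bin are implied: below - A_below.
    dp = {(0, 0): 1}
    below = 0
    for gi in map(int, g):
        if gi == 0:
            continue
        new = {}
        for (c, twoU), weight in dp.items():
            b_below = below - c
            for take in range(0, min(gi, n1 - c) + 1):
                w = weight * comb(gi, take)
                # each taken item: beats b_below B items fully (2U += 2 each)
                # and ties with (gi - take) B items in this bin (2U += 1 each)
                d2u = take * 2 * b_below + take * (gi - take)
                key = (c + take, twoU + d2u)
                new[key] = new.get(key, 0) + w
        dp = new
        below += gi
    total = comb(n1 + n2, n1)
    center = n1 * n2  # = 2 * n1*n2/2
    obs_dev = abs(2 * U_obs - center)
    hits = sum(w for (c, twoU), w in dp.items()
               if c == n1 and abs(twoU - center) >= obs_dev - 1e-9)
    return hits / total


def compare_sfs(sfs_a: SFSpectrum, sfs_b: SFSpectrum,
                exact_max: int = 20):
    """Mann-Whitney U comparison of two derived spectra.

    The test is applied to the per-site derived-count samples implied by
    the histograms; p is two-sided, from the tie-corrected normal
    approximation (with continuity correction), or by exact enumeration
    when both spectra have at most ``exact_max`` sites.  Returns (U, p);
    p is NaN when either spectrum is empty.
    """
    if sfs_a.n_chromosomes != sfs_b.n_chromosomes:
        raise ValueError("spectra must share n_chromosomes")
    a, b = sfs_a.counts, sfs_b.counts
    U, n1, n2, tie_term = _mwu_from_histograms(a, b)
    if n1 == 0 or n2 == 0:
        return U, np.nan
    if n1 <= exact_max and n2 <= exact_max:
        return U, _mwu_exact_two_sided(a, b)
    N = n1 + n2
    mean = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return U, 1.0
    z = (U - mean - np.sign(U - mean) * 0.5) / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return U, float(min(p, 1.0))
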