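"""McDonald-Kreitman tests and a SweepFinder-style CLR sweep scan.

The MK test contrasts, for coding sites, nonsynonymous vs synonymous
counts among polymorphisms within a focal population and among fixed
differences between the focal and a comparison population; the neutrality
index NI = (Pn/Ps)/(Fn/Fs) is > 1 under negative and < 1 under positive
selection, with a two-sided Fisher exact p per table and BH correction
across genes.

The sweep scan models, at each grid point, a recent selective sweep of
strength alpha: a lineage sampled at distance d escapes the sweep by
recombination with probability 1 - exp(-alpha d); escaped lineages carry
the derived allele at the site's pre-sweep frequency (drawn from the
genome-wide background SFS) while non-escaped lineages all descend from
the single sweeping haplotype.  Lineages are independent, so conditional
on the pre-sweep frequency x and the sweeping haplotype's state B the
derived count is Binomial(n, pe*x + (1-pe)*B), conditioned on the site
being polymorphic (only SNPs are observed).  The composite likelihood
ratio is CLR = 2 (max_alpha log L_sweep - log L_background), floored at 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AnalysisDataset, MISSING, RegionSet
from .popgen_stats import _resolve_population, polarize


# ---------------------------------------------------------------------------
# McDonald-Kreitman
# ---------------------------------------------------------------------------

@dataclass
class MKResult:
    scope: str
    Fn: int
    Fs: int
    Pn: int
    Ps: int
    NI: float
    p: float
    q: float = np.nan

    @staticmethod
    def neutrality_index(Fn, Fs, Pn, Ps) -> float:
        if Ps > 0 and Fn > 0 and Fs > 0:
            return (Pn / Ps) / (Fn / Fs)
        return np.nan


def _mk_site_status(dos_focal, dos_comp):
    """Per-site polymorphic-in-focal and fixed-difference flags."""
    called_f = dos_focal != MISSING
    called_c = dos_comp != MISSING
    nf = called_f.sum(axis=1)
    nc = called_c.sum(axis=1)
    alt_f = np.where(called_f, dos_focal, 0).sum(axis=1)
    alt_c = np.where(called_c, dos_comp, 0).sum(axis=1)
    poly = (nf > 0) & (alt_f > 0) & (alt_f < 2 * nf)
    fixed = (nf > 0) & (nc > 0) & (
        ((alt_f == 2 * nf) & (alt_c == 0)) | ((alt_f == 0) & (alt_c == 2 * nc)))
    return poly, fixed


def mk_test(dataset: AnalysisDataset, focal, comparison,
            classes: pd.DataFrame, scope: str = "genome"):
    """MK test genome-wide or per gene.

    A coding site is *polymorphic* when segregating within the focal
    population and a *fixed difference* when the two populations are fixed
    for different alleles with no sharing.  Returns a single
    :class:`MKResult` for scope='genome' or a list (one per gene with at
    least one informative site, BH-corrected) for scope='per_gene'.
    Zero-margin tables get p = 1 and NI missing by convention.
    """
    fi = _resolve_population(dataset, focal)
    ci = _resolve_population(dataset, comparison)
    if len(fi) == 0 or len(ci) == 0:
        raise ValueError("both populations must be non-empty")
    gm = dataset.genotypes
    poly, fixed = _mk_site_status(gm.dosage[:, fi], gm.dosage[:, ci])
    nonsyn = (classes["effect"] == "nonsynonymous").to_numpy()
    syn = (classes["effect"] == "synonymous").to_numpy()

    def table(mask):
        Fn = int((fixed & nonsyn & mask).sum())
        Fs = int((fixed & syn & mask).sum())
        Pn = int((poly & nonsyn & mask).sum())
        Ps = int((poly & syn & mask).sum())
        return Fn, Fs, Pn, Ps

    def result(scope_label, mask):
        Fn, Fs, Pn, Ps = table(mask)
        _, p = stats.fisher_exact([[Fn, Fs], [Pn, Ps]], alternative="two-sided")
        return MKResult(scope_label, Fn, Fs, Pn, Ps,
                        MKResult.neutrality_index(Fn, Fs, Pn, Ps), float(p))

    if scope == "genome":
        return result("genome", np.ones(gm.n_variants, dtype=bool))
    if scope != "per_gene":
        raise ValueError("scope must be genome|per_gene")
    gene_ids = classes["gene_id"].to_numpy()
    results = []
    for gid in pd.unique(gene_ids):
        if not gid:
            continue
        mask = gene_ids == gid
        Fn, Fs, Pn, Ps = table(mask)
        if Fn + Fs + Pn + Ps == 0:
            continue
        results.append(result(gid, mask))
    ps = np.array([r.p for r in results])
    if len(ps):
        qs = stats.false_discovery_control(ps, method="bh")
        for r, q in zip(results, qs):
            r.q = float(q)
    return results


def mk_table(results) -> pd.DataFrame:
    if isinstance(results, MKResult):
        results = [results]
    return pd.DataFrame([{
        "scope": r.scope, "Fn": r.Fn, "Fs": r.Fs, "Pn": r.Pn, "Ps": r.Ps,
        "NI": r.NI, "p": r.p, "q": r.q} for r in results])


# ---------------------------------------------------------------------------
# CLR sweep scan
# ---------------------------------------------------------------------------

DEFAULT_ALPHA_GRID = np.logspace(-6, 2, 41)  # per-bp sweep strengths


@dataclass
class CLRTrack:
    scaffold: str
    grid_pos: np.ndarray
    clr: np.ndarray
    alpha_hat: np.ndarray
    background_sfs: np.ndarray = field(repr=False, default=None)


def sweep_escape_probability(alpha: float, distance) -> np.ndarray:
    """Probability a lineage at ``distance`` bp escapes a sweep of
    strength ``alpha`` (per bp)."""
    return 1.0 - np.exp(-alpha * np.asarray(distance, dtype=float))


def polarized_counts(dataset: AnalysisDataset, population, outgroup=None):
    """Derived-allele counts for the population at polarizable,
    complete-call, segregating sites.

    Returns (scaffold array, pos array, count array, n chromosomes).
    """
    idx = _resolve_population(dataset, population)
    n = 2 * len(idx)
    gm = dataset.genotypes
    polarizable, anc_is_ref = polarize(dataset, outgroup)
    dos = gm.dosage[:, idx]
    complete = (dos != MISSING).all(axis=1)
    alt = dos.sum(axis=1)
    derived = np.where(anc_is_ref, alt, n - alt)
    use = polarizable & complete & (derived >= 1) & (derived <= n - 1)
    return gm.scaffolds[use], gm.pos[use], derived[use].astype(np.int64), n


def background_spectrum(counts: np.ndarray, n: int) -> np.ndarray:
    """Genome-wide derived-count frequencies over 1..n-1."""
    hist = np.bincount(counts, minlength=n)[1:n].astype(float)
    if hist.sum() == 0:
        raise ValueError("no polarized sites to estimate the background SFS")
    return hist / hist.sum()


def sweep_site_log_probs(k: np.ndarray, distances: np.ndarray, alpha: float,
                         spectrum: np.ndarray, n: int) -> np.ndarray:
    """log P(derived count k | sweep at given distances, polymorphic).

    Vectorized over sites; the mixture over pre-sweep frequencies x = j/n
    (background spectrum weights) and the sweeping haplotype's state is
    summed explicitly, then conditioned on 1 <= k <= n-1.
    """
    k = np.asarray(k)
    pe = sweep_escape_probability(alpha, distances)          # (sites,)
    x = (np.arange(1, n) / n)[:, None]                       # (bins, 1)
    w = spectrum[:, None]                                    # (bins, 1)
    eps = 1e-300
    r0 = np.clip(pe[None, :] * x, eps, 1 - 1e-12)            # B = 0
    r1 = np.clip(r0 + (1 - pe)[None, :], eps, 1 - 1e-12)     # B = 1
    from scipy.special import gammaln
    lC = (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))[None, :]

    def pmf(r, kk, lCk):
        return np.exp(lCk + kk * np.log(r) + (n - kk) * np.log1p(-r))

    def mix(kk, lCk):
        return np.sum(w * (x * pmf(r1, kk, lCk) + (1 - x) * pmf(r0, kk, lCk)),
                      axis=0)

    p_k = mix(k[None, :], lC)
    lC0 = np.zeros((1, len(k)))
    p_0 = mix(np.zeros((1, len(k))), lC0)
    p_n = mix(np.full((1, len(k)), n), lC0)
    norm = np.clip(1.0 - p_0 - p_n, 1e-300, None)
    return np.log(np.clip(p_k, 1e-300, None)) - np.log(norm)


def clr_scan(dataset: AnalysisDataset, population, outgroup=None,
             grid_bp: int = 5000, alpha_grid: np.ndarray = DEFAULT_ALPHA_GRID,
             min_sites: int = 10, scaffolds=None) -> dict:
    """Composite-likelihood-ratio sweep scan, one track per scaffold.

    Grid points sit every ``grid_bp`` (floor(scaffold_length/grid_bp)
    points per scaffold).  At each point the sweep strength alpha is
    maximized over a log-spaced grid; CLR = 2 (max log L_sweep -
    log L_background), never negative.  Scaffolds with fewer than
    ``min_sites`` polarized SNPs yield an empty track with a warning.
    The background SFS always pools every scaffold; ``scaffolds`` only
    restricts which tracks are computed.
    """
    import warnings

    scafs, pos, counts, n = polarized_counts(dataset, population, outgroup)
    spectrum = background_spectrum(counts, n)
    log_bg_site = np.log(spectrum[counts - 1])
    tracks = {}
    for sc, length in dataset.scaffold_lengths().items():
        if scaffolds is not None and sc not in scaffolds:
            continue
        on = scafs == sc
        k = counts[on]
        p = pos[on].astype(float)
        n_grid = length // grid_bp
        grid = np.arange(1, n_grid + 1) * grid_bp
        if len(k) < min_sites:
            warnings.warn(f"scaffold {sc}: only {len(k)} polarized sites; "
                          "empty CLR track", stacklevel=2)
            tracks[sc] = CLRTrack(sc, grid.astype(np.int64),
                                  np.full(len(grid), np.nan),
                                  np.full(len(grid), np.nan), spectrum)
            continue
        log_bg = float(log_bg_site[on].sum())
        clr = np.zeros(len(grid))
        alpha_hat = np.zeros(len(grid))
        for gi, g in enumerate(grid):
            d = np.abs(p - g)
            best, best_alpha = -np.inf, alpha_grid[0]
            for alpha in alpha_grid:
                ll = float(sweep_site_log_probs(k, d, alpha, spectrum, n).sum())
                if ll > best:
                    best, best_alpha = ll, alpha
            clr[gi] = max(0.0, 2.0 * (best - log_bg))
            alpha_hat[gi] = best_alpha
        tracks[sc] = CLRTrack(sc, grid.astype(np.int64), clr, alpha_hat,
                              spectrum)
    return tracks


def sweep_regions(tracks: dict, outlier_fraction: float = 0.005,
                  collapse_gap_bp: int = 10,
                  ranking: str = "clr") -> RegionSet:
    """Outlier grid points pooled across scaffolds, collapsed into regions.

    The top ``outlier_fraction`` of grid points by CLR become point
    regions (ties at the cutoff all included); points closer than
    ``collapse_gap_bp`` merge.  ``ranking='chi2_tail'`` ranks by the
    chi-square(1) tail probability of the CLR instead — order-equivalent
    to CLR rank.
    """
    entries = []
    for sc, tr in tracks.items():
        for gpos, c in zip(tr.grid_pos, tr.clr):
            if np.isfinite(c):
                entries.append((sc, int(gpos), float(c)))
    if not entries:
        return RegionSet()
    scores = np.array([e[2] for e in entries])
    if ranking == "chi2_tail":
        order_scores = -stats.chi2.sf(scores, df=1)
    elif ranking == "clr":
        order_scores = scores
    else:
        raise ValueError("ranking must be clr|chi2_tail")
    n_out = int(round(outlier_fraction * len(entries)))
    if n_out == 0:
        return RegionSet()
    cutoff = np.sort(order_scores)[::-1][n_out - 1]
    # ties at the cutoff are all included; CLR = 0 points fit the
    # background exactly and are never outliers
    keep = (order_scores >= cutoff) & (scores > 0)
    regions = [(entries[i][0], entries[i][1], entries[i][1])
               for i in np.flatnonzero(keep)]
    labels = [entries[i][2] for i in np.flatnonzero(keep)]
    return RegionSet(regions, labels).merge(gap=collapse_gap_bp)
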