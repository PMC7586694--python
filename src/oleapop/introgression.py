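"""ABBA-BABA introgression mapping.

Patterson's D contrasts the two discordant site patterns of a rooted
quartet (((P1,P2),P3),O): ABBA (derived shared by P2 and P3) and BABA
(derived shared by P1 and P3).  Under incomplete lineage sorting alone the
two arise symmetrically and D = (ABBA - BABA)/(ABBA + BABA) is 0; gene
flow between P2 and P3 inflates ABBA and pushes D positive.  We use the
frequency-weighted (population-wise) form — per polarizable site the ABBA
contribution is (1-p1) p2 p3 and the BABA contribution p1 (1-p2) p3, with
p the derived frequency in each group — which reduces to pattern counting
when each group is a single homozygous individual.  Significance comes
from a block jackknife over contiguous equal-SNP blocks, with
Benjamini-Hochberg correction across trios.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AnalysisDataset, MISSING, RegionSet
from .popgen_stats import _resolve_population, polarize


@dataclass
class Trio:
    p1: object
    p2: object
    p3: object
    resolved: bool = True


@dataclass
class TrioDResult:
    p1: object
    p2: object
    p3: object
    outgroup: object
    sum_abba: float
    sum_baba: float
    d: float
    jackknife_se: float
    z: float
    p: float
    q: float = np.nan
    n_sites: int = 0


# ---------------------------------------------------------------------------
# trio enumeration from a guide tree
# ---------------------------------------------------------------------------

def enumerate_trios(tree, samples=None, outgroup=None) -> list:
    """All (P1, P2, P3) trios compatible with a rooted guide tree.

    ``tree`` is a newick string, a path, or a Bio.Phylo tree.  For every
    3-subset of ingroup samples the cladistically closer pair (deeper
    MRCA) becomes {P1, P2} and the remaining sample P3; subsets whose
    pairing the tree does not resolve (polytomies) are flagged
    ``resolved=False``.
    """
    from io import StringIO
    from Bio import Phylo

    if isinstance(tree, str):
        handle = StringIO(tree) if tree.strip().startswith("(") else tree
        tree = Phylo.read(handle, "newick")
    terminals = {t.name: t for t in tree.get_terminals()}
    if samples is None:
        samples = [n for n in terminals if n != outgroup]
    for s in samples:
        if s not in terminals:
            raise ValueError(f"sample {s!r} absent from guide tree")
    if outgroup is not None and outgroup not in terminals:
        raise ValueError(f"outgroup {outgroup!r} absent from guide tree")

    # node depth = number of edges from root; deeper MRCA = closer pair
    depths = tree.depths(unit_branch_lengths=True)
    mrca_depth = {}
    for a, b in itertools.combinations(sorted(samples), 2):
        node = tree.common_ancestor(terminals[a], terminals[b])
        mrca_depth[(a, b)] = depths[node]

    trios = []
    for a, b, c in itertools.combinations(sorted(samples), 3):
        d_ab = mrca_depth[(a, b)]
        d_ac = mrca_depth[(a, c)]
        d_bc = mrca_depth[(b, c)]
        best = max(d_ab, d_ac, d_bc)
        winners = [pair for pair, d in ((("ab"), d_ab), (("ac"), d_ac),
                                        (("bc"), d_bc)) if d == best]
        if len(winners) != 1:
            trios.append(Trio(a, b, c, resolved=False))
            continue
        if winners[0] == "ab":
            trios.append(Trio(a, b, c))
        elif winners[0] == "ac":
            trios.append(Trio(a, c, b))
        else:
            trios.append(Trio(b, c, a))
    return trios


# ---------------------------------------------------------------------------
# Patterson's D
# ---------------------------------------------------------------------------

def _usable_sites(dataset: AnalysisDataset, groups, outgroup):
    """Polarizable sites with no missing call in any trio group.

    Returns (mask, derived frequency arrays p1, p2, p3).
    """
    gm = dataset.genotypes
    polarizable, anc_is_ref = polarize(dataset, outgroup)
    freqs, complete = [], polarizable.copy()
    for idx in groups:
        dos = gm.dosage[:, idx]
        ok = (dos != MISSING).all(axis=1)
        complete &= ok
        n = 2.0 * len(idx)
        alt = dos.sum(axis=1)
        p_alt = alt / n
        freqs.append(np.where(anc_is_ref, p_alt, 1.0 - p_alt))
    return complete, freqs


def _d_from_sums(abba: float, baba: float) -> float:
    tot = abba + baba
    return (abba - baba) / tot if tot > 0 else np.nan


def patterson_d(dataset: AnalysisDataset, trio, outgroup=None,
                n_blocks: int = 20) -> TrioDResult:
    """Patterson's D for one trio with block-jackknife significance.

    ``trio`` is a :class:`Trio` or a (P1, P2, P3) tuple of sample names,
    role names or index lists.  The standard error comes from deleting
    each of ``n_blocks`` contiguous equal-SNP blocks in turn; Z = D/SE and
    p is two-sided normal.  q is filled by :func:`fdr_correct`.
    """
    if isinstance(trio, Trio):
        members = (trio.p1, trio.p2, trio.p3)
    else:
        members = tuple(trio)
    groups = [_resolve_population(dataset, _listify(m)) for m in members]
    mask, (p1, p2, p3) = _usable_sites(dataset, groups, outgroup)
    idx = np.flatnonzero(mask)
    abba_site = (1 - p1[idx]) * p2[idx] * p3[idx]
    baba_site = p1[idx] * (1 - p2[idx]) * p3[idx]
    sum_abba, sum_baba = float(abba_site.sum()), float(baba_site.sum())
    d = _d_from_sums(sum_abba, sum_baba)

    se = np.nan
    if len(idx) >= n_blocks and np.isfinite(d):
        blocks = np.array_split(np.arange(len(idx)), n_blocks)
        d_del = []
        for bl in blocks:
            keep_abba = sum_abba - abba_site[bl].sum()
            keep_baba = sum_baba - baba_site[bl].sum()
            d_del.append(_d_from_sums(keep_abba, keep_baba))
        d_del = np.array(d_del, dtype=float)
        if np.isfinite(d_del).all():
            B = len(d_del)
            se = float(np.sqrt((B - 1) / B * np.sum((d_del - d_del.mean()) ** 2)))
    z = d / se if se and se > 0 else np.nan
    p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
    return TrioDResult(members[0], members[1], members[2],
                       outgroup if outgroup is not None else "outgroup",
                       sum_abba, sum_baba, d, se, z,
                       float(p) if np.isfinite(z) else np.nan,
                       n_sites=len(idx))


def _listify(member):
    if isinstance(member, str):
        return member
    return list(member)


def fdr_correct(results: list) -> list:
    """Benjamini-Hochberg q-values across a run of trios (in place)."""
    ps = np.array([r.p for r in results], dtype=float)
    ok = np.isfinite(ps)
    if ok.any():
        qs = stats.false_discovery_control(ps[ok], method="bh")
        it = iter(qs)
        for r, good in zip(results, ok):
            r.q = float(next(it)) if good else np.nan
    return results


def trio_table(results: list) -> pd.DataFrame:
    return pd.DataFrame([{
        "P1": r.p1, "P2": r.p2, "P3": r.p3, "outgroup": r.outgroup,
        "n_sites": r.n_sites, "ABBA": r.sum_abba, "BABA": r.sum_baba,
        "Dstatistic": r.d, "SE": r.jackknife_se, "Z": r.z,
        "p": r.p, "q": r.q} for r in results])


# ---------------------------------------------------------------------------
# windowed D and region calling
# ---------------------------------------------------------------------------

def windowed_d(dataset: AnalysisDataset, trio, outgroup=None,
               window_snps: int = 5000, step_snps: int = 1000) -> pd.DataFrame:
    """Sliding-window D over runs of consecutive usable SNPs per scaffold.

    Windows are ordinal (SNP-indexed): ``window_snps`` consecutive usable
    sites, advancing by ``step_snps``; only full windows are emitted.
    Each row carries the genomic start/end of its first/last SNP.
    """
    if isinstance(trio, Trio):
        members = (trio.p1, trio.p2, trio.p3)
    else:
        members = tuple(trio)
    groups = [_resolve_population(dataset, _listify(m)) for m in members]
    mask, (p1, p2, p3) = _usable_sites(dataset, groups, outgroup)
    gm = dataset.genotypes
    abba = (1 - p1) * p2 * p3
    baba = p1 * (1 - p2) * p3
    rows = []
    for sc in pd.unique(gm.scaffolds):
        on = np.flatnonzero((gm.scaffolds == sc) & mask)
        n = len(on)
        for start in range(0, n - window_snps + 1, step_snps):
            sl = on[start:start + window_snps]
            a, b = float(abba[sl].sum()), float(baba[sl].sum())
            rows.append((sc, int(gm.pos[sl[0]]), int(gm.pos[sl[-1]]),
                         window_snps, _d_from_sums(a, b)))
    return pd.DataFrame(rows, columns=["scaffold", "start", "end",
                                       "n_snps", "d"])


def call_introgressed_regions(windows: pd.DataFrame,
                              d_threshold: float = 0.5) -> RegionSet:
    """Union of window spans with D strictly above ``d_threshold``.

    Overlapping qualifying windows are joined; each merged region keeps
    the mean D of its contributing windows as label.
    """
    hits = windows[windows["d"] > d_threshold]
    regions = RegionSet(
        [(r.scaffold, r.start, r.end) for r in hits.itertuples()],
        labels=list(hits["d"]))
    return regions.merge()
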