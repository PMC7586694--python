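"""Functional classification of SNPs and derived per-sample summaries.

SNPs are classified by genomic location (intergenic / intronic / coding)
and, within coding sequence, by their codon-level effect (synonymous /
nonsynonymous), with flags for fourfold-degenerate positions and
deleterious changes (those altering the initiator ATG, destroying the
terminal stop, or creating a premature stop).  Classification is
one-variant-at-a-time against the reference codon: nearby variants in the
same codon are not resolved jointly (a known limitation shared with
SNP-wise pipelines).

Also implements the coverage-based gene presence / uniqueness calls used
when comparing cultivated and wild genomes: a gene is *present* when at
least 90% of its coding region has depth > 5; it is a *candidate* unique
gene when it fails depth > 20 over >= 50% of the gene span, and a
*stringent* unique gene when it fails even depth > 5 over >= 50%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .io_formats import AnalysisDataset, GeneModel, MISSING

# standard nuclear genetic code; stop codons TAA/TAG/TGA translate to '*'
_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

LOCATIONS = ("intergenic", "intronic", "coding")


@dataclass(frozen=True)
class SiteClass:
    location: str
    coding_effect: str  # synonymous | nonsynonymous | none
    fourfold: bool
    deleterious: bool

    def __post_init__(self):
        if self.fourfold and self.coding_effect != "synonymous":
            raise ValueError("fourfold implies synonymous")
        if self.deleterious and self.coding_effect != "nonsynonymous":
            raise ValueError("deleterious implies nonsynonymous")
        if self.location != "coding" and self.coding_effect != "none":
            raise ValueError("non-coding sites have no coding effect")


def codon_effect(ref_codon: str, codon_pos: int, alt_base: str,
                 is_initiator: bool, is_terminator: bool) -> SiteClass:
    """Effect of substituting ``alt_base`` at ``codon_pos`` (0..2) of
    ``ref_codon``, in coding-strand orientation."""
    ref_codon = ref_codon.upper()
    alt_codon = ref_codon[:codon_pos] + alt_base.upper() + ref_codon[codon_pos + 1:]
    aa_ref = CODON_TO_AA[ref_codon]
    aa_alt = CODON_TO_AA[alt_codon]
    if aa_alt == aa_ref:
        fourfold = all(
            CODON_TO_AA[ref_codon[:codon_pos] + b + ref_codon[codon_pos + 1:]] == aa_ref
            for b in "ACGT")
        return SiteClass("coding", "synonymous", fourfold, False)
    deleterious = (
        (is_initiator and ref_codon == "ATG")          # start-codon loss
        or (is_terminator and aa_ref == "*")           # stop-codon loss
        or (aa_alt == "*" and aa_ref != "*")           # premature stop gain
    )
    return SiteClass("coding", "nonsynonymous", False, deleterious)


def classify_variant(gene: GeneModel, cds_seq: str, pos: int,
                     ref: str, alt: str) -> SiteClass | None:
    """Classify a SNP at genomic ``pos`` inside ``gene``; None if the
    position is not in the gene's CDS."""
    cds_idx = gene.cds_index_of(pos)
    if cds_idx is None:
        return None
    if gene.strand == "-":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    codon_idx, codon_pos = divmod(cds_idx, 3)
    codon = cds_seq[3 * codon_idx:3 * codon_idx + 3]
    if codon[codon_pos] != ref:
        raise ValueError(
            f"reference mismatch at {gene.gene_id} pos {pos}: "
            f"codon {codon} position {codon_pos} != {ref}")
    n_codons = len(cds_seq) // 3
    return codon_effect(codon, codon_pos, alt,
                        is_initiator=codon_idx == 0,
                        is_terminator=codon_idx == n_codons - 1)


class _GeneIndex:
    """Sorted-span lookup of genes per scaffold (genes assumed rarely
    overlapping; first hit wins)."""

    def __init__(self, genes):
        self._by_scaffold = {}
        for g in genes:
            self._by_scaffold.setdefault(g.scaffold, []).append(g)
        self._starts = {}
        for sc, gs in self._by_scaffold.items():
            gs.sort(key=lambda g: g.span)
            self._starts[sc] = np.array([g.span[0] for g in gs])

    def gene_at(self, scaffold: str, pos: int) -> GeneModel | None:
        gs = self._by_scaffold.get(scaffold)
        if not gs:
            return None
        i = int(np.searchsorted(self._starts[scaffold], pos, side="right")) - 1
        if i >= 0 and gs[i].span[0] <= pos <= gs[i].span[1]:
            return gs[i]
        return None


def classify_sites(dataset: AnalysisDataset) -> pd.DataFrame:
    """Per-variant functional classes.

    Returns a DataFrame with columns scaffold, pos, ref, alt, location,
    effect, fourfold, deleterious, gene_id, flagged.  Variants inside
    untranslatable genes are classified by position only (intronic if
    between CDS hull bounds is still genic; we flag them and give effect
    'none').
    """
    gm = dataset.genotypes
    index = _GeneIndex(dataset.genes)
    cds_cache = {}
    rows = []
    for i in range(gm.n_variants):
        sc, pos = gm.scaffolds[i], int(gm.pos[i])
        ref, alt = gm.ref_allele[i], gm.alt_allele[i]
        gene = index.gene_at(sc, pos)
        location, effect, fourfold, deleterious = "intergenic", "none", False, False
        gene_id, flagged = "", False
        if gene is not None:
            gene_id = gene.gene_id
            in_cds = gene.cds_index_of(pos) is not None
            if not gene.translatable:
                location = "intronic"
                flagged = True
            elif in_cds:
                if gene.gene_id not in cds_cache:
                    cds_cache[gene.gene_id] = gene.cds_sequence(dataset.reference)
                sclass = classify_variant(gene, cds_cache[gene.gene_id], pos, ref, alt)
                location = "coding"
                effect = sclass.coding_effect
                fourfold = sclass.fourfold
                deleterious = sclass.deleterious
            else:
                location = "intronic"
        rows.append((sc, pos, ref, alt, location, effect, fourfold,
                     deleterious, gene_id, flagged))
    return pd.DataFrame(rows, columns=[
        "scaffold", "pos", "ref", "alt", "location", "effect",
        "fourfold", "deleterious", "gene_id", "flagged"])


# ---------------------------------------------------------------------------
# per-sample summaries and piN/piS
# ---------------------------------------------------------------------------

def annotation_lengths(dataset: AnalysisDataset) -> dict:
    """Total bp per location class: coding = union of CDS, intronic = gene
    span minus CDS, intergenic = rest of the genome."""
    genome = sum(len(s) for s in dataset.reference.values())
    coding = 0
    genic = 0
    for g in dataset.genes:
        coding += g.cds_length
        genic += g.span[1] - g.span[0] + 1
    return {"coding": coding, "intronic": genic - coding,
            "intergenic": genome - genic}


def per_sample_site_summary(dataset: AnalysisDataset,
                            classes: pd.DataFrame) -> pd.DataFrame:
    """Per-sample hom/het counts by class, plus densities per kb.

    hom = dosage 2 (homozygous ALT), het = dosage 1.  Density per location
    class = count / (class bp / 1000); reported as NaN for zero-length
    classes.
    """
    gm = dataset.genotypes
    lengths = annotation_lengths(dataset)
    loc = classes["location"].to_numpy()
    eff = classes["effect"].to_numpy()
    four = classes["fourfold"].to_numpy()
    dele = classes["deleterious"].to_numpy()
    groups = {
        "intergenic": loc == "intergenic",
        "intronic": loc == "intronic",
        "coding": loc == "coding",
        "synonymous": eff == "synonymous",
        "nonsynonymous": eff == "nonsynonymous",
        "fourfold": four,
        "deleterious": dele,
    }
    rows = []
    for j, sample in enumerate(gm.samples):
        dos = gm.dosage[:, j]
        hom, het = dos == 2, dos == 1
        row = {"sample": sample}
        for name, mask in groups.items():
            row[f"hom_{name}"] = int((mask & hom).sum())
            row[f"het_{name}"] = int((mask & het).sum())
        for name in ("intergenic", "intronic", "coding"):
            bp = lengths[name]
            total = row[f"hom_{name}"] + row[f"het_{name}"]
            row[f"density_{name}_per_kb"] = total / (bp / 1000) if bp > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def pin_pis(n_nonsyn: float, n_syn: float, coding_length: float,
            syn_fraction: float = 0.25) -> tuple:
    """piN, piS and their ratio with a fixed 1:3 synonymous:nonsynonymous
    site-opportunity split of the coding length.

    piN = Nn / ((1 - syn_fraction) * L), piS = Ns / (syn_fraction * L);
    ratio undefined (NaN) when Ns = 0.  The ratio reduces to
    (Nn/Ns) * syn_fraction/(1-syn_fraction), independent of L.
    """
    if coding_length <= 0:
        raise ValueError("coding_length must be positive")
    pi_n = n_nonsyn / ((1 - syn_fraction) * coding_length)
    pi_s = n_syn / (syn_fraction * coding_length)
    ratio = pi_n / pi_s if n_syn > 0 else np.nan
    return pi_n, pi_s, ratio


def pin_pis_per_sample(summary: pd.DataFrame, coding_length: float,
                       which: str = "total") -> pd.DataFrame:
    """piN/piS per sample from a per-sample summary table.

    ``which`` selects the SNP set: 'hom', 'het', or 'total' (hom + het),
    mirroring the three ratio columns the per-individual burden table
    carries.
    """
    if which not in ("hom", "het", "total"):
        raise ValueError("which must be hom|het|total")
    rows = []
    for _, r in summary.iterrows():
        if which == "total":
            nn = r["hom_nonsynonymous"] + r["het_nonsynonymous"]
            ns = r["hom_synonymous"] + r["het_synonymous"]
        else:
            nn = r[f"{which}_nonsynonymous"]
            ns = r[f"{which}_synonymous"]
        pi_n, pi_s, ratio = pin_pis(nn, ns, coding_length)
        rows.append({"sample": r["sample"], "piN": pi_n, "piS": pi_s,
                     "piN_piS": ratio})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# coverage-based gene presence
# ---------------------------------------------------------------------------

@dataclass
class PresenceRules:
    presence_depth: float = 5.0    # CDS base counts as mapped when depth > this
    presence_fraction: float = 0.9
    unique_depth: float = 20.0     # candidate-unique tier
    unique_fraction: float = 0.5
    stringent_depth: float = 5.0   # stringent-unique tier


def gene_presence_from_coverage(gene: GeneModel, depth_track: np.ndarray,
                                rules: PresenceRules | None = None) -> dict:
    """Presence and uniqueness calls for one gene from a per-base depth track.

    ``depth_track`` spans the full gene (index 0 = gene span start).
    Present: depth > 5 over >= 90% of the coding region.  Candidate unique
    (tier 1): NOT depth > 20 over >= 50% of the gene span; stringent unique
    (tier 2): NOT depth > 5 over >= 50% of the gene span.
    """
    rules = rules or PresenceRules()
    span_start, span_end = gene.span
    span_len = span_end - span_start + 1
    track = np.asarray(depth_track)
    if len(track) < span_len:
        raise ValueError(
            f"depth track ({len(track)} bp) shorter than gene span ({span_len} bp)")
    cds_mask = np.zeros(span_len, dtype=bool)
    for s, e in gene.cds_intervals:
        cds_mask[s - span_start:e - span_start + 1] = True
    cds_depth = track[:span_len][cds_mask]
    present = (cds_depth > rules.presence_depth).mean() >= rules.presence_fraction
    gene_cov20 = (track[:span_len] > rules.unique_depth).mean()
    gene_cov5 = (track[:span_len] > rules.stringent_depth).mean()
    return {
        "present": bool(present),
        "unique_candidate": bool(gene_cov20 < rules.unique_fraction),
        "unique_stringent": bool(gene_cov5 < rules.unique_fraction),
    }


def presence_matrix_from_tracks(genes, tracks: dict,
                                rules: PresenceRules | None = None) -> pd.DataFrame:
    """Apply :func:`gene_presence_from_coverage` over a {(gene_id, sample):
    track} mapping; returns a tidy DataFrame."""
    rows = []
    by_id = {g.gene_id: g for g in genes}
    for (gene_id, sample), track in tracks.items():
        call = gene_presence_from_coverage(by_id[gene_id], track, rules)
        rows.append({"gene_id": gene_id, "sample": sample, **call})
    return pd.DataFrame(rows)


def write_bedgraph(track: np.ndarray, scaffold: str, span_start: int, path) -> None:
    """Write a per-base depth track as bedgraph (0-based half-open runs)."""
    track = np.asarray(track)
    with open(path, "w") as fh:
        if len(track) == 0:
            return
        run_start, run_val = 0, track[0]
        for i in range(1, len(track) + 1):
            if i == len(track) or track[i] != run_val:
                s0 = span_start - 1 + run_start
                fh.write(f"{scaffold}\t{s0}\t{span_start - 1 + i}\t{run_val:g}\n")
                if i < len(track):
                    run_start, run_val = i, track[i]


def read_bedgraph(path, scaffold: str, span_start: int, span_len: int) -> np.ndarray:
    """Read a bedgraph back into a per-base track over [span_start,
    span_start + span_len)."""
    track = np.zeros(span_len)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            sc, s0, e0, val = line.split("\t")
            if sc != scaffold:
                continue
            s = max(int(s0) + 1, span_start)
            e = min(int(e0), span_start + span_len - 1)
            if s <= e:
                track[s - span_start:e - span_start + 1] = float(val)
    return track
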