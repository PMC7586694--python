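"""Synthetic inputs with known truth for every pipeline stage.

Two generators are provided:

* a four-taxon (P1, P2, P3, outgroup) site-pattern simulator with a
  closed-form pattern distribution, for calibrating the ABBA-BABA
  machinery.  Per site a gene-tree history is drawn: with probability
  ``f`` the P2 lineage joins P3 (introgression); otherwise P1 and P2
  coalesce first with probability 1 - exp(-t_internal) (concordant), else
  one of the three topologies is drawn uniformly (incomplete lineage
  sorting).  A single mutation is then placed on one branch, giving a
  biallelic pattern.

* a cohort simulator emitting FASTA + GFF3 + VCF (with GATK-style quality
  annotations) + manifest + a truth table.  Allele frequencies follow a
  neutral 1/i spectrum with Balding-Nichols population differentiation, a
  bottleneck transform pushing cultivar frequencies toward intermediate
  values, a selection proxy depressing nonsynonymous derived frequencies,
  and sweep intervals whose site frequencies follow the same
  escape/hitchhiking model the CLR scanner fits.  Frequency-based
  simulation (not a full coalescent) keeps expectations closed-form; a
  coalescent simulator is used only as an independent oracle in tests.

Identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_formats import (
    AnalysisDataset, GenotypeMatrix, GeneModel, LoadReport,
    PopulationManifest, VariantQualityFields, MISSING,
)
from .site_classification import classify_variant, CODON_TO_AA

PATTERNS = ("BAAA", "ABAA", "AABA", "BBAA", "ABBA", "BABA")

_SENSE_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")
_STOP_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa == "*")
_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


# ---------------------------------------------------------------------------
# quartet site-pattern simulation
# ---------------------------------------------------------------------------

@dataclass
class QuartetSimParams:
    """Parameters of the four-taxon site-pattern generator.

    t_internal: internal branch length (coalescent units) between the
    (P1,P2) ancestor and the (P1,P2,P3) ancestor; f: per-site probability
    that P2's lineage was acquired from P3; branch_mut: relative mutation
    weights on external vs internal branches.
    """

    t_internal: float = 1.0
    f: float = 0.0
    n_sites: int = 10_000
    branch_mut: dict = field(default_factory=lambda: {"external": 1.0, "internal": 1.0})
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f must be in [0, 1]")
        if self.t_internal < 0:
            raise ValueError("t_internal must be >= 0")
        if self.n_sites < 1:
            raise ValueError("n_sites must be positive")


def quartet_pattern_distribution(params: QuartetSimParams) -> dict:
    """Exact multinomial over the six biallelic site patterns.

    Topology probabilities: concordant ((P1,P2),P3) with
    (1-f)(c + (1-c)/3) where c = 1 - exp(-t_internal); ((P2,P3),P1) with
    f + (1-f)(1-c)/3; ((P1,P3),P2) with (1-f)(1-c)/3.  Given the topology,
    the mutation falls on the internal branch (yielding the shared-derived
    pattern of the cherry) or one of the three external branches (yielding
    a singleton) in proportion to branch_mut.
    """
    c = 1.0 - np.exp(-params.t_internal)
    f = params.f
    p_topo = {
        "BBAA": (1 - f) * (c + (1 - c) / 3),   # cherry {P1,P2}
        "ABBA": f + (1 - f) * (1 - c) / 3,     # cherry {P2,P3}
        "BABA": (1 - f) * (1 - c) / 3,         # cherry {P1,P3}
    }
    w_ext = params.branch_mut["external"]
    w_int = params.branch_mut["internal"]
    total_w = 3 * w_ext + w_int
    dist = {
        "BAAA": w_ext / total_w,
        "ABAA": w_ext / total_w,
        "AABA": w_ext / total_w,
    }
    for pattern, pt in p_topo.items():
        dist[pattern] = pt * w_int / total_w
    return dist


def _patterns_to_matrix(pattern_idx: np.ndarray, scaffold: str = "sim1",
                        pos_offset: int = 0) -> GenotypeMatrix:
    n = len(pattern_idx)
    # derived allele encoded as homozygous ALT (dosage 2)
    dosage = np.zeros((n, 4), dtype=np.int8)
    for k, pat in enumerate(PATTERNS):
        rows = pattern_idx == k
        for j, state in enumerate(pat[:3]):
            if state == "B":
                dosage[rows, j] = 2
    return GenotypeMatrix(
        samples=["P1", "P2", "P3", "OUT"],
        scaffolds=np.array([scaffold] * n, dtype=object),
        pos=np.arange(pos_offset + 1, pos_offset + n + 1),
        ref_allele=np.array(["A"] * n, dtype=object),
        alt_allele=np.array(["T"] * n, dtype=object),
        dosage=dosage,
    )


def simulate_quartet_sites(params: QuartetSimParams):
    """Draw site patterns from the exact distribution.

    Returns ``(GenotypeMatrix for P1,P2,P3,OUT, exact pattern distribution)``.
    Derived alleles are encoded as homozygous ALT genotypes; the outgroup
    is always ancestral (homozygous REF).
    """
    dist = quartet_pattern_distribution(params)
    probs = np.array([dist[p] for p in PATTERNS])
    rng = np.random.default_rng(params.seed)
    idx = rng.choice(len(PATTERNS), size=params.n_sites, p=probs)
    return _patterns_to_matrix(idx), dist


def simulate_quartet_with_tract(params: QuartetSimParams, tract_start: int,
                                tract_end: int, f_tract: float):
    """Quartet sites whose introgression probability is ``f_tract`` for
    sites with ordinal position in [tract_start, tract_end] (1-based) and
    ``params.f`` elsewhere.  Returns (matrix, (tract_start, tract_end))."""
    rng = np.random.default_rng(params.seed)
    base = quartet_pattern_distribution(params)
    tract = quartet_pattern_distribution(
        QuartetSimParams(t_internal=params.t_internal, f=f_tract,
                         n_sites=params.n_sites, branch_mut=params.branch_mut,
                         seed=params.seed))
    p_base = np.array([base[p] for p in PATTERNS])
    p_tract = np.array([tract[p] for p in PATTERNS])
    idx = np.empty(params.n_sites, dtype=np.int64)
    in_tract = np.zeros(params.n_sites, dtype=bool)
    in_tract[tract_start - 1:tract_end] = True
    idx[~in_tract] = rng.choice(len(PATTERNS), size=int((~in_tract).sum()), p=p_base)
    idx[in_tract] = rng.choice(len(PATTERNS), size=int(in_tract.sum()), p=p_tract)
    return _patterns_to_matrix(idx), (tract_start, tract_end)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortSimParams:
    """Study-shaped cohort: a wild population, an eastern cultivar
    population (cultivars_set1), an admixed cultivar population
    (cultivars_set2) and a single outgroup individual.

    theta is the per-bp Watterson mutation parameter; differentiation the
    Balding-Nichols Fst between populations; bottleneck_factor >= 1
    compresses cultivar frequencies toward 0.5 (loss of rare variants in a
    domestication bottleneck); selection_proxy in (0, 1] multiplies
    nonsynonymous derived frequencies (purifying selection);
    outgroup_divergence is the probability the outgroup is fixed for the
    derived allele (polarization noise).  generation_time and mu are
    annotation metadata carried into the truth file.
    """

    n_scaffolds: int = 2
    scaffold_length: int = 100_000
    genes_per_scaffold: int = 5
    exons_per_gene: int = 3
    exon_bp: int = 300
    intron_bp: int = 150
    n_wild: int = 10
    n_cultivars_set1: int = 10
    n_cultivars_set2: int = 10
    n_outgroup: int = 1
    theta: float = 0.004
    differentiation: float = 0.05
    admixture: float = 0.3
    bottleneck_factor: float = 1.0
    selection_proxy: float = 1.0
    sweep_spec: list = field(default_factory=list)   # (scaffold, center, alpha)
    outgroup_divergence: float = 0.02
    quality_fail_fraction: float = 0.0
    generation_time: float = 20.0
    mu: float = 7.77e-9
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.selection_proxy <= 1:
            raise ValueError("selection_proxy must be in (0, 1]")
        if self.bottleneck_factor < 1:
            raise ValueError("bottleneck_factor must be >= 1")
        if (self.exons_per_gene * self.exon_bp) % 3:
            raise ValueError("total CDS length must be divisible by 3")
        if not 0 <= self.quality_fail_fraction < 1:
            raise ValueError("quality_fail_fraction must be in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth emitted next to the simulated data."""

    variants: pd.DataFrame            # per-variant class + filter labels
    sweep_spec: list
    params: dict
    presence: pd.DataFrame | None = None

    def to_files(self, prefix) -> None:
        self.variants.to_csv(f"{prefix}.variants.tsv", sep="\t", index=False)
        with open(f"{prefix}.json", "w") as fh:
            json.dump({"truth_version": 1, "params": self.params,
                       "sweep_spec": [list(s) for s in self.sweep_spec]},
                      fh, indent=1, sort_keys=True)


@dataclass
class CohortSim:
    dataset: AnalysisDataset
    truth: SimTruth
    paths: dict | None = None


_FAIL_RULES = ("MQ", "QD", "FS", "MQRankSum", "ReadPosRankSum", "SOR", "DP", "AD")


def _make_gene(rng, scaffold, gene_num, slot_start, slot_end, p: CohortSimParams):
    """Place one gene inside [slot_start, slot_end]; returns (GeneModel, cds)."""
    gene_len = p.exons_per_gene * p.exon_bp + (p.exons_per_gene - 1) * p.intron_bp
    margin = 50
    if slot_end - slot_start + 1 < gene_len + 2 * margin:
        raise ValueError(
            "gene does not fit in its slot; use smaller genes_per_scaffold "
            "or shorter genes")
    start = int(rng.integers(slot_start + margin,
                             slot_end - gene_len - margin + 2))
    intervals = []
    at = start
    for _ in range(p.exons_per_gene):
        intervals.append((at, at + p.exon_bp - 1))
        at += p.exon_bp + p.intron_bp
    strand = "+" if rng.random() < 0.5 else "-"
    n_codons = (p.exons_per_gene * p.exon_bp) // 3
    middle = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    cds = "ATG" + "".join(_SENSE_CODONS[i] for i in middle) \
        + _STOP_CODONS[int(rng.integers(len(_STOP_CODONS)))]
    gene = GeneModel(gene_id=f"{scaffold}_g{gene_num}", scaffold=scaffold,
                     strand=strand, cds_intervals=intervals, phase=0,
                     span=(start, at - p.intron_bp - 1))
    return gene, cds


def _paste_cds(seq: list, gene: GeneModel, cds: str) -> None:
    """Write the CDS into the scaffold sequence at the gene's exons."""
    genomic = cds if gene.strand == "+" else cds.translate(_COMPLEMENT)[::-1]
    offset = 0
    for s, e in sorted(gene.cds_intervals):
        seq[s - 1:e] = list(genomic[offset:offset + e - s + 1])
        offset += e - s + 1


def _neutral_spectrum(n_chrom: int) -> np.ndarray:
    i = np.arange(1, n_chrom)
    w = 1.0 / i
    return w / w.sum()


def simulate_cohort(params: CohortSimParams, out_dir=None) -> CohortSim:
    """Generate the full synthetic cohort; optionally write FASTA, GFF3,
    VCF, manifest and truth files under ``out_dir``."""
    rng = np.random.default_rng(params.seed)
    scaffold_names = [f"scaffold_{i + 1}" for i in range(params.n_scaffolds)]

    # --- genome and genes ------------------------------------------------
    reference, genes, cds_by_gene = {}, [], {}
    for sc in scaffold_names:
        seq = list(rng.choice(_BASES, size=params.scaffold_length))
        slot = params.scaffold_length // params.genes_per_scaffold
        for g in range(params.genes_per_scaffold):
            gene, cds = _make_gene(rng, sc, g + 1, g * slot + 1,
                                   (g + 1) * slot, params)
            _paste_cds(seq, gene, cds)
            genes.append(gene)
            cds_by_gene[gene.gene_id] = cds
        reference[sc] = "".join(seq)

    # --- samples ----------------------------------------------------------
    roles = {}
    for i in range(params.n_wild):
        roles[f"wild_{i + 1}"] = "wild"
    for i in range(params.n_cultivars_set1):
        roles[f"cult1_{i + 1}"] = "cultivars_set1"
    for i in range(params.n_cultivars_set2):
        roles[f"cult2_{i + 1}"] = "cultivars_set2"
    for i in range(params.n_outgroup):
        roles[f"outgroup_{i + 1}"] = "outgroup"
    samples = list(roles)
    manifest = PopulationManifest(dict(roles))
    pop_slices = {}
    at = 0
    for role, count in (("wild", params.n_wild),
                        ("cultivars_set1", params.n_cultivars_set1),
                        ("cultivars_set2", params.n_cultivars_set2),
                        ("outgroup", params.n_outgroup)):
        pop_slices[role] = slice(at, at + count)
        at += count
    n_samples = len(samples)
    n_ingroup = params.n_wild + params.n_cultivars_set1 + params.n_cultivars_set2
    n_chrom = 2 * n_ingroup
    spectrum = _neutral_spectrum(n_chrom)

    gene_lookup = {sc: [g for g in genes if g.scaffold == sc]
                   for sc in scaffold_names}
    sweeps_by_scaffold = {}
    for sc, center, alpha in params.sweep_spec:
        sweeps_by_scaffold.setdefault(sc, []).append((center, alpha))

    # --- per-site draws ---------------------------------------------------
    a_n = np.sum(1.0 / np.arange(1, n_chrom))
    rows = []
    scafs, poss, refs, alts, dosages = [], [], [], [], []
    for sc in scaffold_names:
        # Watterson expectation: E[S] = theta * a_n * L
        n_sites = int(rng.poisson(params.theta * a_n * params.scaffold_length))
        positions = np.sort(rng.choice(params.scaffold_length, size=n_sites,
                                       replace=False)) + 1
        for pos in positions:
            ref = reference[sc][pos - 1]
            gene = next((g for g in gene_lookup[sc]
                         if g.span[0] <= pos <= g.span[1]), None)
            in_cds = gene is not None and gene.cds_index_of(int(pos)) is not None
            alt_choices = [b for b in "ACGT" if b != ref]
            alt = alt_choices[int(rng.integers(3))]
            if in_cds:
                sclass = classify_variant(gene, cds_by_gene[gene.gene_id],
                                          int(pos), ref, alt)
                location, effect = "coding", sclass.coding_effect
                fourfold, deleterious = sclass.fourfold, sclass.deleterious
            else:
                location = "intronic" if gene is not None else "intergenic"
                effect, fourfold, deleterious = "none", False, False

            i_der = int(rng.choice(n_chrom - 1, p=spectrum)) + 1
            p0 = i_der / n_chrom
            p_sel = p0 * (params.selection_proxy if effect == "nonsynonymous" else 1.0)
            q_wild = p_sel
            # bottleneck = extra drift in the cultivar lineage: rare alleles
            # are lost or drift up, flattening the segregating-site SFS
            # toward intermediate frequencies and lowering diversity
            if params.bottleneck_factor > 1:
                f_b = 1.0 - 1.0 / params.bottleneck_factor
                qq = min(max(p_sel, 1e-6), 1 - 1e-6)
                q_c1 = float(rng.beta(qq * (1 - f_b) / f_b,
                                      (1 - qq) * (1 - f_b) / f_b))
            else:
                q_c1 = p_sel
            q_c2 = params.admixture * q_wild + (1 - params.admixture) * q_c1
            base_freqs = {"wild": q_wild, "cultivars_set1": q_c1,
                          "cultivars_set2": q_c2}
            F = params.differentiation
            pop_freqs = {}
            for role, q in base_freqs.items():
                if F > 0:
                    qq = min(max(q, 1e-6), 1 - 1e-6)
                    pop_freqs[role] = rng.beta(qq * (1 - F) / F,
                                               (1 - qq) * (1 - F) / F)
                else:
                    pop_freqs[role] = q

            dos = np.zeros(n_samples, dtype=np.int8)
            sweep_here = sweeps_by_scaffold.get(sc, [])
            if sweep_here:
                center, alpha = min(sweep_here, key=lambda ca: abs(pos - ca[0]))
                p_escape = 1.0 - np.exp(-alpha * abs(int(pos) - center))
                sweeper_derived = rng.random() < p0
                for role in base_freqs:
                    r = p_escape * pop_freqs[role] + (1 - p_escape) * sweeper_derived
                    sl = pop_slices[role]
                    dos[sl] = rng.binomial(2, r, size=sl.stop - sl.start)
            else:
                for role in base_freqs:
                    sl = pop_slices[role]
                    dos[sl] = rng.binomial(2, pop_freqs[role],
                                           size=sl.stop - sl.start)
            og = pop_slices["outgroup"]
            dos[og] = 2 if rng.random() < params.outgroup_divergence else 0

            scafs.append(sc)
            poss.append(int(pos))
            refs.append(ref)
            alts.append(alt)
            dosages.append(dos)
            rows.append({"scaffold": sc, "pos": int(pos), "ref": ref, "alt": alt,
                         "location": location, "effect": effect,
                         "fourfold": fourfold, "deleterious": deleterious,
                         "gene_id": gene.gene_id if gene is not None else "",
                         "p_ancestral": p0})

    n_var = len(poss)
    dosage = np.vstack(dosages) if n_var else np.empty((0, n_samples), dtype=np.int8)

    # --- quality fields ---------------------------------------------------
    quality, fail_rule = _draw_quality(rng, dosage, params.quality_fail_fraction)
    truth_df = pd.DataFrame(rows)
    truth_df["filter_pass"] = fail_rule == ""
    truth_df["fail_rule"] = fail_rule

    matrix = GenotypeMatrix(
        samples=samples,
        scaffolds=np.array(scafs, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref_allele=np.array(refs, dtype=object),
        alt_allele=np.array(alts, dtype=object),
        dosage=dosage,
        quality=quality,
    )
    dataset = AnalysisDataset(matrix, genes, reference, manifest,
                              LoadReport(n_snp=n_var))
    truth = SimTruth(truth_df, list(params.sweep_spec), asdict(params))

    paths = None
    if out_dir is not None:
        paths = write_cohort(dataset, truth, out_dir)
    return CohortSim(dataset, truth, paths)


def _draw_quality(rng, dosage, fail_fraction):
    """Quality annotations passing every hard filter, except a labelled
    subset of records each violating exactly one named rule (the first
    three forced to sit exactly on the MQ/QD/FS thresholds)."""
    n_var, n_samples = dosage.shape
    MQ = rng.uniform(45, 60, n_var)
    QD = rng.uniform(10, 30, n_var)
    FS = rng.uniform(0, 30, n_var)
    MQRS = rng.uniform(-3, 3, n_var)
    RPRS = rng.uniform(-3, 3, n_var)
    SOR = rng.uniform(0.5, 2.5, n_var)
    DP = 10 + rng.poisson(15, size=(n_var, n_samples)).astype(np.int32)
    AD = DP.copy()
    het = dosage == 1
    if het.any():
        alt_reads = rng.binomial(DP[het], 0.5)
        AD[het] = np.clip(np.minimum(alt_reads, DP[het] - alt_reads), 5, None)
    # sites with no heterozygote have no rank-sum annotations (GATK-like)
    no_het = ~het.any(axis=1)
    MQRS[no_het] = np.nan
    RPRS[no_het] = np.nan

    fail_rule = np.array([""] * n_var, dtype=object)
    n_fail = int(round(fail_fraction * n_var))
    if n_fail:
        fail_idx = rng.choice(n_var, size=n_fail, replace=False)
        rules = [_FAIL_RULES[int(r)] for r in rng.integers(len(_FAIL_RULES),
                                                           size=n_fail)]
        # guarantee boundary records at the printed thresholds
        for k, forced in enumerate(("MQ", "QD", "FS")):
            if k < n_fail:
                rules[k] = forced
        n_bad = int(np.floor(0.2 * n_samples)) + 1  # >20% of samples
        for idx, rule in zip(fail_idx, rules):
            fail_rule[idx] = rule
            if rule == "MQ":
                MQ[idx] = 40.0 if rng.random() < 0.3 else rng.uniform(20, 40)
            elif rule == "QD":
                QD[idx] = 2.0 if rng.random() < 0.3 else rng.uniform(0, 2)
            elif rule == "FS":
                FS[idx] = 60.0 if rng.random() < 0.3 else rng.uniform(60.001, 100)
            elif rule == "MQRankSum":
                MQRS[idx] = -12.5 if rng.random() < 0.3 else rng.uniform(-20, -12.5)
            elif rule == "ReadPosRankSum":
                RPRS[idx] = -8.0 if rng.random() < 0.3 else rng.uniform(-15, -8)
            elif rule == "SOR":
                SOR[idx] = 3.0 if rng.random() < 0.3 else rng.uniform(3.001, 6)
            elif rule == "DP":
                bad = rng.choice(n_samples, size=n_bad, replace=False)
                DP[idx, bad] = rng.integers(5, 10, size=n_bad)
                AD[idx, bad] = DP[idx, bad]  # keep the AD rule satisfied
            elif rule == "AD":
                bad = rng.choice(n_samples, size=n_bad, replace=False)
                AD[idx, bad] = rng.integers(0, 5, size=n_bad)
        # forced boundary values for the first three must still fail only
        # their own rule, which holds by construction (strict inequalities).
    quality = VariantQualityFields(MQ=MQ, QD=QD, FS=FS, MQRankSum=MQRS,
                                   ReadPosRankSum=RPRS, SOR=SOR, DP=DP, AD=AD)
    return quality, fail_rule


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_cohort(dataset: AnalysisDataset, truth: SimTruth, out_dir) -> dict:
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "fasta": os.path.join(out_dir, "reference.fa"),
        "gff": os.path.join(out_dir, "genes.gff3"),
        "vcf": os.path.join(out_dir, "variants.vcf"),
        "manifest": os.path.join(out_dir, "manifest.tsv"),
        "truth": os.path.join(out_dir, "truth"),
    }
    with open(paths["fasta"], "w") as fh:
        for sc, seq in dataset.reference.items():
            fh.write(f">{sc}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    write_gff3(dataset.genes, paths["gff"])
    write_vcf(dataset.genotypes, dataset.scaffold_lengths(), paths["vcf"])
    dataset.manifest.to_tsv(paths["manifest"])
    truth.to_files(paths["truth"])
    return paths


def write_gff3(genes, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.scaffold, g.span)):
            s, e = g.span
            fh.write(f"{g.scaffold}\tsim\tgene\t{s}\t{e}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}\n")
            fh.write(f"{g.scaffold}\tsim\tmRNA\t{s}\t{e}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}.t1;Parent={g.gene_id}\n")
            cum = 0
            for (cs, ce) in g.cds_intervals:  # transcription order
                phase = (3 - cum % 3) % 3
                fh.write(f"{g.scaffold}\tsim\tCDS\t{cs}\t{ce}\t.\t{g.strand}\t"
                         f"{phase}\tID={g.gene_id}.cds;Parent={g.gene_id}.t1\n")
                cum += ce - cs + 1


def _fmt(x) -> str:
    return "." if np.isnan(x) else f"{x:.4f}"


def write_vcf(matrix: GenotypeMatrix, scaffold_lengths: dict, path) -> None:
    """Serialize a GenotypeMatrix (with quality fields) as VCFv4.2 text."""
    q = matrix.quality
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=oleapop-synthetic\n')
        for sc, ln in scaffold_lengths.items():
            fh.write(f"##contig=<ID={sc},length={ln}>\n")
        if q is not None:
            for name in ("MQ", "QD", "FS", "MQRankSum", "ReadPosRankSum", "SOR"):
                fh.write(f'##INFO=<ID={name},Number=1,Type=Float,'
                         f'Description="{name}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if q is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                     'Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        for i in range(matrix.n_variants):
            info = []
            if q is not None:
                for name in ("MQ", "QD", "FS", "MQRankSum", "ReadPosRankSum", "SOR"):
                    val = getattr(q, name)[i]
                    if not np.isnan(val):
                        info.append(f"{name}={val:.4f}")
            fields = [str(matrix.scaffolds[i]), str(matrix.pos[i]), ".",
                      str(matrix.ref_allele[i]), str(matrix.alt_allele[i]),
                      ".", "PASS", ";".join(info) or ".",
                      "GT:DP:AD" if q is not None else "GT"]
            for j in range(matrix.n_samples):
                d = int(matrix.dosage[i, j])
                if q is None:
                    fields.append(gt_str[d])
                    continue
                dp = int(q.DP[i, j])
                ad = int(q.AD[i, j])
                # AD pair arranged so min-over-called-alleles equals the scalar
                if d == 0:
                    pair = (ad, max(dp - ad, 0))
                elif d == 2:
                    pair = (max(dp - ad, 0), ad)
                elif d == 1:
                    pair = (max(dp - ad, ad), ad) if ad * 2 <= dp else (ad, ad)
                else:
                    fields.append(f"./.:.:.")
                    continue
                fields.append(f"{gt_str[d]}:{dp}:{pair[0]},{pair[1]}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# coverage tracks
# ---------------------------------------------------------------------------

def random_presence_matrix(genes, samples, p_absent: float, seed: int) -> pd.DataFrame:
    """Random gene x sample presence truth (True = present)."""
    rng = np.random.default_rng(seed)
    data = rng.random((len(genes), len(samples))) >= p_absent
    return pd.DataFrame(data, index=[g.gene_id for g in genes], columns=samples)


def simulate_coverage_tracks(genes, presence: pd.DataFrame,
                             depth_present: float = 30.0,
                             depth_absent: float = 0.0,
                             seed: int = 0) -> dict:
    """Per-base Poisson depth over each gene span for each sample.

    Present genes get Poisson(depth_present) per base, absent ones
    Poisson(depth_absent).  Returns {(gene_id, sample): np.ndarray}.
    """
    if depth_present < 0 or depth_absent < 0:
        raise ValueError("depths must be >= 0")
    rng = np.random.default_rng(seed)
    tracks = {}
    for gene in genes:
        span_len = gene.span[1] - gene.span[0] + 1
        for sample in presence.columns:
            lam = depth_present if presence.loc[gene.gene_id, sample] else depth_absent
            tracks[(gene.gene_id, sample)] = rng.poisson(lam, size=span_len)
    return tracks


# ---------------------------------------------------------------------------
# direct class-SFS sampler (shared frequency model, no genome plumbing)
# ---------------------------------------------------------------------------

def expected_class_spectrum(n_chromosomes: int, s: float = 1.0) -> np.ndarray:
    """Closed-form derived-count distribution the class sampler induces.

    A site draws frequency i/n from the neutral 1/i spectrum, scales by
    ``s`` and resamples the count Binomial(n, s i/n); the result,
    conditioned on being segregating, is the multinomial this returns
    (index k-1 = probability of derived count k).
    """
    from scipy.stats import binom

    n = n_chromosomes
    w = _neutral_spectrum(n)
    k = np.arange(n + 1)
    q = np.zeros(n + 1)
    for i, wi in enumerate(w, start=1):
        q += wi * binom.pmf(k, n, s * i / n)
    seg = q[1:n]
    return seg / seg.sum()


def simulate_class_sfs(n_sites: int, n_chromosomes: int, s: float,
                       seed: int) -> np.ndarray:
    """Derived-count histogram (index k-1 = count of sites with k derived
    copies) for a functional class with frequency multiplier ``s``.

    Sites draw a neutral 1/i frequency, scale it by ``s`` and resample the
    count binomially; only segregating outcomes (1..n-1) are kept.
    """
    rng = np.random.default_rng(seed)
    spectrum = _neutral_spectrum(n_chromosomes)
    i_der = rng.choice(n_chromosomes - 1, size=n_sites, p=spectrum) + 1
    p = s * i_der / n_chromosomes
    k = rng.binomial(n_chromosomes, p)
    k = k[(k >= 1) & (k <= n_chromosomes - 1)]
    return np.bincount(k, minlength=n_chromosomes)[1:n_chromosomes]
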