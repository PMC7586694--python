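"""Standard-format I/O and the in-memory dataset shared by every analysis stage.

The pipeline consumes a multi-sample diploid VCF, GFF3 gene models, a
reference FASTA and a sample manifest, and assembles them into an
:class:`AnalysisDataset`.  Downstream modules never re-read files: they
operate on the :class:`GenotypeMatrix` (variants x samples ALT dosage),
the list of :class:`GeneModel` and the :class:`PopulationManifest`.

Coordinates are 1-based inclusive internally (VCF/GFF native); BED export
converts to 0-based half-open at the boundary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

MISSING = -1  # dosage sentinel for uncalled genotypes

ROLES = ("wild", "cultivars_set1", "cultivars_set2", "outgroup", "excluded")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class VariantQualityFields:
    """Site-level and per-sample quality annotations used by hard filtering.

    Site-level arrays (one float per variant, NaN when the annotation is
    absent from the record): MQ, QD, FS, MQRankSum, ReadPosRankSum, SOR.
    Per-sample integer matrices (variants x samples): DP (read depth) and
    AD (depth supporting the sample's called alleles; min over the called
    alleles when heterozygous).
    """

    MQ: np.ndarray
    QD: np.ndarray
    FS: np.ndarray
    MQRankSum: np.ndarray
    ReadPosRankSum: np.ndarray
    SOR: np.ndarray
    DP: np.ndarray
    AD: np.ndarray

    def subset(self, mask: np.ndarray) -> "VariantQualityFields":
        return VariantQualityFields(
            MQ=self.MQ[mask], QD=self.QD[mask], FS=self.FS[mask],
            MQRankSum=self.MQRankSum[mask],
            ReadPosRankSum=self.ReadPosRankSum[mask],
            SOR=self.SOR[mask], DP=self.DP[mask], AD=self.AD[mask],
        )


@dataclass
class GenotypeMatrix:
    """Biallelic SNPs as an ALT-allele dosage matrix.

    ``dosage[i, j]`` is the number of ALT alleles carried by sample ``j``
    at variant ``i`` (0, 1, 2, or :data:`MISSING`).  Positions are 1-based
    and strictly increasing within a scaffold.  Heterozygote encoding is
    dosage 1 regardless of phasing; phase is discarded.
    """

    samples: list
    scaffolds: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    dosage: np.ndarray
    quality: VariantQualityFields | None = None
    multiallelic: np.ndarray | None = None  # flag, normally all False

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.scaffolds = np.asarray(self.scaffolds, dtype=object)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        if self.dosage.shape != (len(self.pos), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.pos)}, {len(self.samples)})"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2,missing}")
        for scaf in pd.unique(self.scaffolds):
            p = self.pos[self.scaffolds == scaf]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {scaf}")
        if self.multiallelic is None:
            self.multiallelic = np.zeros(len(self.pos), dtype=bool)

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, names) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in genotype matrix") from None

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            samples=list(self.samples),
            scaffolds=self.scaffolds[mask],
            pos=self.pos[mask],
            ref_allele=self.ref_allele[mask],
            alt_allele=self.alt_allele[mask],
            dosage=self.dosage[mask],
            quality=self.quality.subset(mask) if self.quality is not None else None,
            multiallelic=self.multiallelic[mask],
        )

    def alt_frequency(self, sample_idx=None) -> np.ndarray:
        """Per-variant ALT frequency over called alleles (NaN if none called)."""
        dos = self.dosage if sample_idx is None else self.dosage[:, sample_idx]
        called = dos != MISSING
        n_alleles = 2 * called.sum(axis=1)
        alt = np.where(called, dos, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)


@dataclass
class GeneModel:
    """A protein-coding gene as stranded CDS intervals (1-based inclusive).

    ``cds_intervals`` are stored in transcription (5'->3') order: ascending
    genomic coordinates on '+', descending on '-'.  ``phase`` is the phase
    of the first CDS base in transcription order.
    """

    gene_id: str
    scaffold: str
    strand: str
    cds_intervals: list
    phase: int = 0
    span: tuple | None = None  # full gene span (start, end); defaults to CDS hull

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        ivs = sorted(self.cds_intervals)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping CDS intervals in {self.gene_id}")
        self.cds_intervals = ivs if self.strand == "+" else ivs[::-1]
        if self.span is None:
            self.span = (min(s for s, _ in ivs), max(e for _, e in ivs))

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def translatable(self) -> bool:
        return self.phase == 0 and self.cds_length % 3 == 0

    @property
    def intron_intervals(self) -> list:
        ivs = sorted(self.cds_intervals)
        return [(e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(ivs, ivs[1:])]

    def cds_positions(self) -> np.ndarray:
        """Genomic position of each CDS base, in transcription order."""
        chunks = []
        for s, e in self.cds_intervals:
            block = np.arange(s, e + 1, dtype=np.int64)
            chunks.append(block if self.strand == "+" else block[::-1])
        return np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)

    def cds_sequence(self, reference: dict) -> str:
        """Spliced CDS, reverse-complemented on '-' strand."""
        seq = reference[self.scaffold]
        parts = [seq[s - 1:e] for s, e in sorted(self.cds_intervals)]
        cds = "".join(parts)
        if self.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return cds

    def cds_index_of(self, pos: int) -> int | None:
        """0-based index in the spliced CDS of genomic ``pos``, or None."""
        offset = 0
        for s, e in self.cds_intervals:
            if s <= pos <= e:
                return offset + (pos - s if self.strand == "+" else e - pos)
            offset += e - s + 1
        return None


@dataclass
class PopulationManifest:
    """Mapping sample -> role (wild / cultivars_set1 / cultivars_set2 /
    outgroup / excluded)."""

    roles: dict

    def __post_init__(self) -> None:
        for sample, role in self.roles.items():
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r} for sample {sample!r}")

    def samples_for(self, role: str) -> list:
        return [s for s, r in self.roles.items() if r == role]

    @property
    def outgroup_samples(self) -> list:
        return self.samples_for("outgroup")

    def validate_against(self, samples) -> None:
        for s in samples:
            if s not in self.roles:
                raise ValueError(f"sample {s!r} missing from population manifest")

    @classmethod
    def from_tsv(cls, path) -> "PopulationManifest":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"sample", "role"} <= set(df.columns):
            raise ValueError("manifest must have columns: sample, role")
        return cls(dict(zip(df["sample"], df["role"])))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\trole\n")
            for s, r in self.roles.items():
                fh.write(f"{s}\t{r}\n")


class RegionSet:
    """Scaffold intervals, 1-based inclusive, with merge/containment algebra.

    Shared by the introgression caller, the sweep caller and the overlap
    permutation test.  After :meth:`merge`, intervals are pairwise disjoint
    and sorted.
    """

    def __init__(self, regions=(), labels=None):
        self.regions = [(str(sc), int(s), int(e)) for sc, s, e in regions]
        for sc, s, e in self.regions:
            if s > e:
                raise ValueError(f"region start > end: {(sc, s, e)}")
        self.labels = list(labels) if labels is not None else None
        if self.labels is not None and len(self.labels) != len(self.regions):
            raise ValueError("labels length mismatch")

    def __len__(self):
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __eq__(self, other):
        return isinstance(other, RegionSet) and self.regions == other.regions

    def __repr__(self):
        return f"RegionSet({len(self.regions)} regions, {self.total_length()} bp)"

    def total_length(self) -> int:
        return sum(e - s + 1 for _, s, e in self.regions)

    def merge(self, gap: int = 0) -> "RegionSet":
        """Union of intervals; intervals separated by < ``gap`` bp are joined.

        With ``gap=0`` only overlapping/abutting intervals merge.  Labels,
        when numeric, are averaged over the merged members.
        """
        if not self.regions:
            return RegionSet()
        order = sorted(range(len(self.regions)), key=lambda i: self.regions[i])
        merged, lab_groups = [], []
        for i in order:
            sc, s, e = self.regions[i]
            if merged:
                msc, ms, me = merged[-1]
                # distance between intervals: s - me - 1 (0 when abutting)
                if sc == msc and s - me - 1 < max(gap, 1):
                    merged[-1] = (msc, ms, max(me, e))
                    lab_groups[-1].append(i)
                    continue
            merged.append((sc, s, e))
            lab_groups.append([i])
        labels = None
        if self.labels is not None:
            try:
                labels = [float(np.mean([self.labels[i] for i in g])) for g in lab_groups]
            except TypeError:
                labels = [self.labels[g[0]] for g in lab_groups]
        return RegionSet(merged, labels)

    def contains_region(self, scaffold: str, start: int, end: int) -> bool:
        """True if (start, end) lies entirely inside one interval."""
        return any(sc == scaffold and s <= start and end <= e
                   for sc, s, e in self.regions)

    def intersect_length(self, other: "RegionSet") -> int:
        """Total overlapping bp between the two (merged) sets."""
        a = self.merge().regions
        b = other.merge().regions
        total = 0
        for sc, s, e in a:
            for sc2, s2, e2 in b:
                if sc == sc2:
                    total += max(0, min(e, e2) - max(s, s2) + 1)
        return total


@dataclass
class LoadReport:
    """Counts of VCF records set aside during dataset assembly."""

    n_snp: int = 0
    n_multiallelic: int = 0
    n_indel: int = 0
    n_spanning_deletion: int = 0
    untranslatable_genes: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_snp": self.n_snp,
            "n_multiallelic": self.n_multiallelic,
            "n_indel": self.n_indel,
            "n_spanning_deletion": self.n_spanning_deletion,
            "untranslatable_genes": list(self.untranslatable_genes),
        }


@dataclass
class AnalysisDataset:
    """Everything downstream stages need: genotypes, gene models, reference
    sequences and the population manifest."""

    genotypes: GenotypeMatrix
    genes: list
    reference: dict
    manifest: PopulationManifest
    report: LoadReport = field(default_factory=LoadReport)

    def population_indices(self, role: str) -> np.ndarray:
        return self.genotypes.sample_indices(self.manifest.samples_for(role))

    def scaffold_lengths(self) -> dict:
        return {name: len(seq) for name, seq in self.reference.items()}


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

_SITE_INFO = ("MQ", "QD", "FS", "MQRankSum", "ReadPosRankSum", "SOR")


def load_genotypes(vcf_path) -> tuple:
    """Parse a VCF into a GenotypeMatrix of biallelic SNPs plus a LoadReport.

    Multiallelic and indel records are counted, not silently dropped;
    spanning-deletion ALTs (``*``) are tallied separately.  Heterozygous
    calls become dosage 1 regardless of phase; half-missing genotypes are
    missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    n = len(samples)
    declared = set()
    for h in vcf.header_iter():
        try:
            d = h.info()
            declared.add((d.get("HeaderType"), d.get("ID")))
        except Exception:
            continue
    has_dp = ("FORMAT", "DP") in declared
    has_ad = ("FORMAT", "AD") in declared
    has_quality = has_dp or has_ad or any(("INFO", k) in declared
                                          for k in _SITE_INFO)
    report = LoadReport()
    scafs, poss, refs, alts, dosages = [], [], [], [], []
    site_info = {k: [] for k in _SITE_INFO}
    dps, ads = [], []

    for v in vcf:
        if len(v.ALT) != 1:
            report.n_multiallelic += 1
            continue
        alt = v.ALT[0]
        if alt == "*":
            report.n_spanning_deletion += 1
            continue
        if len(v.REF) != 1 or len(alt) != 1:
            report.n_indel += 1
            continue
        report.n_snp += 1
        scafs.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(alt)
        dos = np.empty(n, dtype=np.int8)
        for j, gt in enumerate(v.genotypes):
            a, b = gt[0], gt[1] if len(gt) > 2 else gt[0]
            dos[j] = MISSING if (a < 0 or b < 0) else a + b
        dosages.append(dos)
        for k in _SITE_INFO:
            val = v.INFO.get(k)
            site_info[k].append(np.nan if val is None else float(val))
        dp = v.format("DP") if has_dp else None
        dps.append(np.full(n, -1, dtype=np.int32) if dp is None
                   else np.where(dp[:, 0] < 0, -1, dp[:, 0]).astype(np.int32))
        ad = v.format("AD") if has_ad else None
        if ad is None:
            ads.append(np.full(n, -1, dtype=np.int32))
        else:
            ads.append(_called_allele_depth(ad, dos))

    m = len(poss)
    quality = None
    if has_quality:
        quality = VariantQualityFields(
            **{k: np.array(site_info[k], dtype=float) for k in _SITE_INFO},
            DP=np.vstack(dps) if m else np.empty((0, n), dtype=np.int32),
            AD=np.vstack(ads) if m else np.empty((0, n), dtype=np.int32),
        )
    matrix = GenotypeMatrix(
        samples=samples,
        scaffolds=np.array(scafs, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref_allele=np.array(refs, dtype=object),
        alt_allele=np.array(alts, dtype=object),
        dosage=(np.vstack(dosages) if m else np.empty((0, n), dtype=np.int8)),
        quality=quality,
    )
    return matrix, report


def _called_allele_depth(ad: np.ndarray, dosage: np.ndarray) -> np.ndarray:
    """Depth supporting the called genotype: min over called alleles."""
    ad = np.where(ad < 0, 0, ad)
    ref_d, alt_d = ad[:, 0], ad[:, 1] if ad.shape[1] > 1 else ad[:, 0]
    out = np.empty(len(dosage), dtype=np.int32)
    for j, d in enumerate(dosage):
        if d == MISSING:
            out[j] = -1
        elif d == 0:
            out[j] = ref_d[j]
        elif d == 2:
            out[j] = alt_d[j]
        else:
            out[j] = min(ref_d[j], alt_d[j])
    return out


def load_genes(gff_path) -> list:
    """Read GFF3 gene models via gffutils; CDS grouped by gene, ordered in
    transcription order with the first-CDS phase."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique",
        keep_order=True, force=True,
    )
    genes = []
    for g in db.features_of_type("gene"):
        cds = list(db.children(g, featuretype="CDS", order_by="start"))
        if not cds:
            continue
        intervals = [(c.start, c.end) for c in cds]
        first = cds[0] if g.strand == "+" else cds[-1]
        try:
            phase = int(first.frame)
        except (TypeError, ValueError):
            phase = 0
        genes.append(GeneModel(
            gene_id=g.id, scaffold=g.seqid, strand=g.strand,
            cds_intervals=intervals, phase=phase, span=(g.start, g.end),
        ))
    return genes


def load_reference(fasta_path) -> dict:
    """FASTA -> {scaffold: sequence str}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta_path), "fasta")}


def load_dataset(vcf_path, gff_path, fasta_path, manifest_path) -> AnalysisDataset:
    """Assemble the full in-memory dataset from the four standard files.

    Raises if a VCF sample is absent from the manifest; genes whose CDS
    length is not divisible by 3 are flagged untranslatable with a warning.
    """
    matrix, report = load_genotypes(vcf_path)
    genes = load_genes(gff_path)
    reference = load_reference(fasta_path)
    manifest = PopulationManifest.from_tsv(manifest_path)
    manifest.validate_against(matrix.samples)
    for gene in genes:
        if not gene.translatable:
            report.untranslatable_genes.append(gene.gene_id)
            warnings.warn(
                f"gene {gene.gene_id}: CDS length {gene.cds_length} with phase "
                f"{gene.phase} is untranslatable", stacklevel=2)
    return AnalysisDataset(matrix, genes, reference, manifest, report)


# ---------------------------------------------------------------------------
# region I/O
# ---------------------------------------------------------------------------

BED_DIALECT = "bed_half_open_0based"
TSV_DIALECT = "inclusive_1based_tsv"


def read_regions(path, dialect: str = BED_DIALECT) -> RegionSet:
    """Read intervals from BED (0-based half-open) or TSV (1-based inclusive)."""
    regions, labels, any_label = [], [], False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            sc, s, e = parts[0], int(parts[1]), int(parts[2])
            if dialect == BED_DIALECT:
                s, e = s + 1, e
            elif dialect != TSV_DIALECT:
                raise ValueError(f"unknown coordinate dialect {dialect!r}")
            if s > e:
                raise ValueError(f"{path}:{lineno}: start > end")
            regions.append((sc, s, e))
            if len(parts) > 3:
                any_label = True
                labels.append(parts[3])
            else:
                labels.append(None)
    return RegionSet(regions, labels if any_label else None)


def write_regions(regions: RegionSet, path, dialect: str = BED_DIALECT) -> None:
    with open(path, "w") as fh:
        for i, (sc, s, e) in enumerate(regions):
            if dialect == BED_DIALECT:
                coords = f"{s - 1}\t{e}"
            elif dialect == TSV_DIALECT:
                coords = f"{s}\t{e}"
            else:
                raise ValueError(f"unknown coordinate dialect {dialect!r}")
            lab = ""
            if regions.labels is not None and regions.labels[i] is not None:
                lab = f"\t{regions.labels[i]}"
            fh.write(f"{sc}\t{coords}{lab}\n")


def region_io(path, direction: str, dialect: str = BED_DIALECT,
              regions: RegionSet | None = None):
    """Unified entry point: direction 'read' returns a RegionSet; 'write'
    serializes ``regions`` to ``path``."""
    if direction == "read":
        return read_regions(path, dialect)
    if direction == "write":
        if regions is None:
            raise ValueError("regions required for write")
        write_regions(regions, path, dialect)
        return None
    raise ValueError(f"direction must be read|write, got {direction!r}")


# ---------------------------------------------------------------------------
# phylogenetic pseudo-alignment
# ---------------------------------------------------------------------------

_IUPAC = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


def export_pseudoalignment(dataset: AnalysisDataset, samples=None,
                           mode: str = "homozygous_only"):
    """Per-sample pseudo-sequences at SNP positions, trimmed to variable columns.

    Each sample's sequence is the reference with its SNP alleles substituted;
    columns identical across all samples (non-informative) are removed.  In
    ``homozygous_only`` mode heterozygous calls contribute the reference
    allele; ``iupac_het`` encodes hets as IUPAC ambiguity codes.  Returns
    ``(sequences: {sample: str}, n_columns, kept_index)``.
    """
    if mode not in ("homozygous_only", "iupac_het"):
        raise ValueError(f"unknown mode {mode!r}")
    gm = dataset.genotypes
    if samples is None:
        samples = [s for s in gm.samples if dataset.manifest.roles.get(s) != "excluded"]
    idx = gm.sample_indices(samples)
    n_var = gm.n_variants
    cols = np.empty((n_var, len(samples)), dtype="U1")
    for i in range(n_var):
        ref, alt = gm.ref_allele[i], gm.alt_allele[i]
        for k, j in enumerate(idx):
            d = gm.dosage[i, j]
            if d == 2:
                cols[i, k] = alt
            elif d == 1 and mode == "iupac_het":
                cols[i, k] = _IUPAC.get(frozenset((ref, alt)), "N")
            else:  # dosage 0, missing, or het under homozygous_only
                cols[i, k] = ref
    if n_var:
        variable = np.array([len(set(cols[i])) > 1 for i in range(n_var)])
    else:
        variable = np.zeros(0, dtype=bool)
    kept = np.flatnonzero(variable)
    if len(kept) == 0:
        warnings.warn("no variable columns remain in pseudo-alignment", stacklevel=2)
    seqs = {s: "".join(cols[kept, k]) for k, s in enumerate(samples)}
    return seqs, len(kept), kept


def write_fasta(sequences: dict, path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


# ---------------------------------------------------------------------------
# versioned dataset container
# ---------------------------------------------------------------------------

CONTAINER_VERSION = 1


def save_dataset(dataset: AnalysisDataset, path) -> None:
    """Serialize an AnalysisDataset to a versioned .npz container."""
    gm = dataset.genotypes
    q = gm.quality
    genes_json = json.dumps([
        {"gene_id": g.gene_id, "scaffold": g.scaffold, "strand": g.strand,
         "cds_intervals": [list(iv) for iv in sorted(g.cds_intervals)],
         "phase": g.phase, "span": list(g.span)}
        for g in dataset.genes
    ])
    np.savez_compressed(
        path,
        container_version=np.array([CONTAINER_VERSION]),
        samples=np.array(gm.samples, dtype="U64"),
        scaffolds=gm.scaffolds.astype("U64"),
        pos=gm.pos,
        ref_allele=gm.ref_allele.astype("U8"),
        alt_allele=gm.alt_allele.astype("U8"),
        dosage=gm.dosage,
        has_quality=np.array([q is not None]),
        **({k: getattr(q, k) for k in
            (*_SITE_INFO, "DP", "AD")} if q is not None else {}),
        reference_json=np.array([json.dumps(dataset.reference)]),
        genes_json=np.array([genes_json]),
        manifest_json=np.array([json.dumps(dataset.manifest.roles)]),
        report_json=np.array([json.dumps(dataset.report.as_dict())]),
    )


def load_saved_dataset(path) -> AnalysisDataset:
    with np.load(path, allow_pickle=False) as z:
        version = int(z["container_version"][0])
        if version != CONTAINER_VERSION:
            raise ValueError(f"unsupported container version {version}")
        quality = None
        if bool(z["has_quality"][0]):
            quality = VariantQualityFields(
                **{k: z[k] for k in _SITE_INFO}, DP=z["DP"], AD=z["AD"])
        gm = GenotypeMatrix(
            samples=[str(s) for s in z["samples"]],
            scaffolds=z["scaffolds"].astype(object),
            pos=z["pos"],
            ref_allele=z["ref_allele"].astype(object),
            alt_allele=z["alt_allele"].astype(object),
            dosage=z["dosage"],
            quality=quality,
        )
        genes = [GeneModel(
            gene_id=g["gene_id"], scaffold=g["scaffold"], strand=g["strand"],
            cds_intervals=[tuple(iv) for iv in g["cds_intervals"]],
            phase=g["phase"], span=tuple(g["span"]))
            for g in json.loads(str(z["genes_json"][0]))]
        reference = json.loads(str(z["reference_json"][0]))
        manifest = PopulationManifest(json.loads(str(z["manifest_json"][0])))
        rep = json.loads(str(z["report_json"][0]))
        report = LoadReport(
            n_snp=rep["n_snp"], n_multiallelic=rep["n_multiallelic"],
            n_indel=rep["n_indel"],
            n_spanning_deletion=rep["n_spanning_deletion"],
            untranslatable_genes=rep["untranslatable_genes"])
    return AnalysisDataset(gm, genes, reference, manifest, report)
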