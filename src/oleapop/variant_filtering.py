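"""GATK-style hard filtering and site-level (biallelic / MAF) filtering.

A record is retained iff MQ > 40, QD > 2, FS < 60, MQRankSum > -12.5,
ReadPosRankSum > -8, SOR < 3, DP >= 10 in at least 80% of individuals and
AD >= 5 in at least 80% of individuals — strict inequalities exactly as
printed.  Sites with missing alleles or a spanning deletion are removed
first and reported separately.  Missing site-level annotations (e.g. the
rank sums at sites without a heterozygote) pass their rule, mirroring
common GATK practice, and are tallied separately in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, MISSING


@dataclass
class FilterThresholds:
    mq_min: float = 40.0
    qd_min: float = 2.0
    fs_max: float = 60.0
    mqranksum_min: float = -12.5
    readposranksum_min: float = -8.0
    sor_max: float = 3.0
    dp_min: float = 10.0
    ad_min: float = 5.0
    sample_fraction: float = 0.8
    max_alleles: int = 2
    maf_min: float = 0.008

    def __post_init__(self):
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")


# rule evaluation order used for first-violation attribution
RULE_ORDER = ("missing_or_spandel", "MQ", "QD", "FS", "MQRankSum",
              "ReadPosRankSum", "SOR", "DP", "AD")


@dataclass
class FilterReport:
    n_input: int = 0
    n_retained: int = 0
    n_failed_first: dict = field(default_factory=dict)
    n_failed_any: dict = field(default_factory=dict)
    n_missing_annotation: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rule": list(RULE_ORDER),
            "n_failed_first": [self.n_failed_first.get(r, 0) for r in RULE_ORDER],
            "n_failed_any": [self.n_failed_any.get(r, 0) for r in RULE_ORDER],
        })


def _rule_masks(matrix: GenotypeMatrix, t: FilterThresholds) -> dict:
    """Per-rule boolean fail masks (True = record violates the rule)."""
    q = matrix.quality
    if q is None:
        raise ValueError("quality fields required for hard filtering")
    n = matrix.n_samples

    def site_fail(values, ok):
        absent = np.isnan(values)
        fails = np.where(absent, False, ~ok(values))
        return fails, absent

    masks, absent_counts = {}, {}
    masks["missing_or_spandel"] = (matrix.dosage == MISSING).any(axis=1)
    masks["MQ"], a = site_fail(q.MQ, lambda v: v > t.mq_min)
    absent_counts["MQ"] = int(a.sum())
    masks["QD"], a = site_fail(q.QD, lambda v: v > t.qd_min)
    absent_counts["QD"] = int(a.sum())
    masks["FS"], a = site_fail(q.FS, lambda v: v < t.fs_max)
    absent_counts["FS"] = int(a.sum())
    masks["MQRankSum"], a = site_fail(q.MQRankSum, lambda v: v > t.mqranksum_min)
    absent_counts["MQRankSum"] = int(a.sum())
    masks["ReadPosRankSum"], a = site_fail(q.ReadPosRankSum,
                                           lambda v: v > t.readposranksum_min)
    absent_counts["ReadPosRankSum"] = int(a.sum())
    masks["SOR"], a = site_fail(q.SOR, lambda v: v < t.sor_max)
    absent_counts["SOR"] = int(a.sum())
    # DP/AD: fraction over all manifest samples ("in at least the 80% of
    # individuals" read as a fraction of all individuals)
    masks["DP"] = (q.DP >= t.dp_min).sum(axis=1) / n < t.sample_fraction
    masks["AD"] = (q.AD >= t.ad_min).sum(axis=1) / n < t.sample_fraction
    return masks, absent_counts


def apply_hard_filters(matrix: GenotypeMatrix,
                       thresholds: FilterThresholds | None = None):
    """Apply the hard-filter battery; returns (retained matrix, FilterReport).

    The report carries both first-violation attribution (each failing
    record counted once, in RULE_ORDER) and any-violation tallies.
    """
    t = thresholds or FilterThresholds()
    masks, absent = _rule_masks(matrix, t)
    report = FilterReport(n_input=matrix.n_variants,
                          n_missing_annotation=absent)
    any_fail = np.zeros(matrix.n_variants, dtype=bool)
    attributed = np.zeros(matrix.n_variants, dtype=bool)
    for rule in RULE_ORDER:
        m = masks[rule]
        report.n_failed_any[rule] = int(m.sum())
        first = m & ~attributed
        report.n_failed_first[rule] = int(first.sum())
        attributed |= m
        any_fail |= m
    retained = matrix.subset_variants(~any_fail)
    report.n_retained = retained.n_variants
    return retained, report


def minor_allele_frequency(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-variant MAF over called alleles (missing genotypes excluded
    from the denominator); NaN when no allele is called."""
    p = matrix.alt_frequency()
    return np.minimum(p, 1 - p)


def apply_site_filters(matrix: GenotypeMatrix, max_alleles: int = 2,
                       maf_min: float = 0.008) -> GenotypeMatrix:
    """Retain biallelic SNPs with minor-allele frequency >= maf_min.

    Monomorphic sites (MAF 0) and records flagged multiallelic at load are
    removed.  Runs after :func:`apply_hard_filters`.
    """
    maf = minor_allele_frequency(matrix)
    keep = ~np.isnan(maf) & (maf >= maf_min) & (maf > 0)
    if max_alleles < 2:
        raise ValueError("max_alleles must be >= 2")
    keep &= ~matrix.multiallelic
    return matrix.subset_variants(keep)
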