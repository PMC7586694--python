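import numpy as np
import pandas as pd
import pytest

from oleapop.io_formats import (
    AnalysisDataset, GeneModel, GenotypeMatrix, LoadReport, PopulationManifest,
)
from oleapop.site_classification import (
    PresenceRules, classify_sites, codon_effect, gene_presence_from_coverage,
    per_sample_site_summary, pin_pis, pin_pis_per_sample, read_bedgraph,
    write_bedgraph,
)


class TestCodonEffect:
    @pytest.mark.parametrize("codon,pos,alt,effect,fourfold,deleterious", [
        ("GGA", 2, "G", "synonymous", True, False),     # Gly -> Gly, fourfold
        ("ATG", 1, "C", "nonsynonymous", False, True),  # initiator loss
        ("AAA", 2, "G", "synonymous", False, False),    # Lys twofold site
        ("TGG", 2, "A", "nonsynonymous", False, True),  # Trp -> stop (gain)
        ("TTA", 0, "C", "synonymous", False, False),    # Leu -> Leu
        ("GCT", 0, "A", "nonsynonymous", False, False), # Ala -> Thr
    ])
    def test_single_codon_cases(self, codon, pos, alt, effect, fourfold,
                                deleterious):
        sc = codon_effect(codon, pos, alt, is_initiator=(codon == "ATG"),
                          is_terminator=False)
        assert (sc.coding_effect, sc.fourfold, sc.deleterious) == \
            (effect, fourfold, deleterious)

    def test_terminal_stop_loss_is_deleterious(self):
        sc = codon_effect("TAA", 2, "C", is_initiator=False, is_terminator=True)
        assert sc.coding_effect == "nonsynonymous" and sc.deleterious

    def test_stop_to_stop_is_synonymous_not_deleterious(self):
        sc = codon_effect("TAA", 2, "G", is_initiator=False, is_terminator=True)
        assert sc.coding_effect == "synonymous" and not sc.deleterious

    def test_internal_atg_change_not_deleterious(self):
        sc = codon_effect("ATG", 2, "A", is_initiator=False, is_terminator=False)
        assert sc.coding_effect == "nonsynonymous" and not sc.deleterious


def _tiny_dataset():
    """6-bp gene ATG TAA on + strand at 11..16 in a 30-bp scaffold, and a
    minus-strand gene at 21..26 whose CDS reads ATGTGA."""
    ref = list("A" * 30)
    ref[10:16] = list("ATGTAA")
    ref[20:26] = list("TCACAT")  # revcomp = ATGTGA
    reference = {"s": "".join(ref)}
    genes = [
        GeneModel("gplus", "s", "+", [(11, 16)]),
        GeneModel("gminus", "s", "-", [(21, 26)]),
    ]
    #        pos 5: intergenic | pos 12 (+ gene, T of ATG) | pos 22 (- gene)
    m = GenotypeMatrix(
        samples=["a", "b"],
        scaffolds=np.array(["s"] * 3, dtype=object),
        pos=np.array([5, 12, 22]),
        ref_allele=np.array(["A", "T", "C"], dtype=object),
        alt_allele=np.array(["G", "C", "T"], dtype=object),
        dosage=np.array([[1, 0], [2, 0], [0, 1]], dtype=np.int8))
    manifest = PopulationManifest({"a": "wild", "b": "wild"})
    return AnalysisDataset(m, genes, reference, manifest, LoadReport())


class TestClassifySites:
    def test_locations_and_strand_awareness(self):
        ds = _tiny_dataset()
        cls = classify_sites(ds)
        assert list(cls["location"]) == ["intergenic", "coding", "coding"]
        assert cls.loc[0, "effect"] == "none"
        # pos 12 is ATG -> ACG (Met->Thr): initiator loss
        assert cls.loc[1, "effect"] == "nonsynonymous"
        assert bool(cls.loc[1, "deleterious"])
        # pos 22 on '-' strand: genomic C->T is G->A on the coding strand,
        # terminal codon TGA -> TAA (stop to stop): synonymous
        assert cls.loc[2, "effect"] == "synonymous"
        assert not bool(cls.loc[2, "deleterious"])

    def test_class_partition_on_cohort(self, cohort_sim):
        cls = classify_sites(cohort_sim.dataset)
        counts = cls["location"].value_counts()
        assert counts.sum() == cohort_sim.dataset.genotypes.n_variants
        assert set(counts.index) <= {"intergenic", "intronic", "coding"}

    def test_untranslatable_gene_flagged(self):
        ds = _tiny_dataset()
        ds.genes.append(GeneModel("bad", "s", "+", [(1, 5)]))  # len 5 % 3 != 0
        m = ds.genotypes
        m2 = GenotypeMatrix(
            samples=m.samples,
            scaffolds=np.array(["s"], dtype=object), pos=np.array([3]),
            ref_allele=np.array(["A"], dtype=object),
            alt_allele=np.array(["G"], dtype=object),
            dosage=np.array([[1, 1]], dtype=np.int8))
        ds2 = AnalysisDataset(m2, ds.genes, ds.reference, ds.manifest,
                              LoadReport())
        cls = classify_sites(ds2)
        assert bool(cls.loc[0, "flagged"])
        assert cls.loc[0, "effect"] == "none"


class TestSummaries:
    def test_density_arithmetic(self):
        """10 intergenic SNPs over 2 kb of intergenic sequence -> 5 SNPs/kb."""
        ref = {"s": "A" * 2600}
        genes = [GeneModel("g", "s", "+", [(2001, 2600)])]
        pos = np.arange(1, 11) * 100
        m = GenotypeMatrix(
            samples=["x"], scaffolds=np.array(["s"] * 10, dtype=object),
            pos=pos, ref_allele=np.array(["A"] * 10, dtype=object),
            alt_allele=np.array(["G"] * 10, dtype=object),
            dosage=np.full((10, 1), 1, dtype=np.int8))
        ds = AnalysisDataset(m, genes, ref, PopulationManifest({"x": "wild"}),
                             LoadReport())
        summary = per_sample_site_summary(ds, classify_sites(ds))
        row = summary.iloc[0]
        assert row["het_intergenic"] == 10 and row["hom_intergenic"] == 0
        assert row["density_intergenic_per_kb"] == pytest.approx(5.0)

    def test_sample_without_alt_has_zero_counts(self, cohort_sim):
        ds = cohort_sim.dataset
        cls = classify_sites(ds)
        summary = per_sample_site_summary(ds, cls)
        count_cols = [c for c in summary.columns
                      if c.startswith(("hom_", "het_"))]
        # totals across samples match truth tallies
        truth = cohort_sim.truth.variants
        total_coding = summary["hom_coding"].sum() + summary["het_coding"].sum()
        gm = ds.genotypes
        coding = (truth["location"] == "coding").to_numpy()
        expected = int(((gm.dosage[coding] == 2).sum()
                        + (gm.dosage[coding] == 1).sum()))
        assert total_coding == expected
        assert (summary[count_cols].to_numpy() >= 0).all()


class TestPinPis:
    def test_ratio_arithmetic(self):
        pi_n, pi_s, ratio = pin_pis(9, 3, 1200)
        assert pi_n == pytest.approx(9 / 900)
        assert pi_s == pytest.approx(3 / 300)
        assert ratio == pytest.approx(1.0)

    def test_zero_nonsyn_gives_zero_ratio(self):
        assert pin_pis(0, 5, 1200)[2] == 0

    def test_zero_syn_gives_missing_not_infinity(self):
        assert np.isnan(pin_pis(5, 0, 1200)[2])

    def test_ratio_invariant_to_coding_length(self):
        r1 = pin_pis(7, 4, 900)[2]
        r2 = pin_pis(7, 4, 123456)[2]
        assert r1 == pytest.approx(r2, abs=1e-15)
        assert r1 == pytest.approx((7 / 4) / 3)

    def test_per_sample_variants(self, cohort_sim):
        from oleapop.site_classification import (annotation_lengths,
                                                 per_sample_site_summary)

        ds = cohort_sim.dataset
        summary = per_sample_site_summary(ds, classify_sites(ds))
        L = annotation_lengths(ds)["coding"]
        total = pin_pis_per_sample(summary, L, "total")
        hom = pin_pis_per_sample(summary, L, "hom")
        het = pin_pis_per_sample(summary, L, "het")
        assert np.allclose(total["piN"], hom["piN"] + het["piN"])


class TestGenePresence:
    def _gene(self):
        return GeneModel("g", "s", "+", [(1, 300), (601, 900)], span=(1, 900))

    def test_uniform_high_depth_present_not_unique(self):
        gene = self._gene()
        call = gene_presence_from_coverage(gene, np.full(900, 30))
        assert call == {"present": True, "unique_candidate": False,
                        "unique_stringent": False}

    def test_zero_depth_absent_unique_both_tiers(self):
        gene = self._gene()
        call = gene_presence_from_coverage(gene, np.zeros(900))
        assert call == {"present": False, "unique_candidate": True,
                        "unique_stringent": True}

    def test_presence_uses_cds_uniqueness_uses_gene_span(self):
        gene = self._gene()
        track = np.zeros(900)
        track[:300] = 30
        track[600:900] = 30  # CDS fully covered (600 bp), intron at 0
        call = gene_presence_from_coverage(gene, track)
        assert call["present"]             # 100% of CDS > 5
        # 600/900 = 66.7% of the span > 20 -> not unique at tier 1
        assert not call["unique_candidate"]
        track2 = track.copy()
        track2[600:900] = 0                # only 300/900 = 33% covered
        call2 = gene_presence_from_coverage(gene, track2)
        assert not call2["present"]        # only 50% of CDS covered
        assert call2["unique_candidate"] and call2["unique_stringent"]

    def test_exact_fraction_boundaries(self):
        gene = GeneModel("g", "s", "+", [(1, 10)], span=(1, 10))
        track = np.array([30] * 9 + [0])   # exactly 90% of CDS > 5
        assert gene_presence_from_coverage(gene, track)["present"]
        track = np.array([30] * 8 + [0, 0])
        assert not gene_presence_from_coverage(gene, track)["present"]
        # exactly 50% of span > 20 -> NOT unique (rule is < 50%)
        track = np.array([30] * 5 + [0] * 5)
        assert not gene_presence_from_coverage(gene, track)["unique_candidate"]

    def test_short_track_is_error(self):
        with pytest.raises(ValueError, match="shorter"):
            gene_presence_from_coverage(self._gene(), np.zeros(100))

    def test_bedgraph_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        track = rng.poisson(12, size=250).astype(float)
        path = tmp_path / "t.bedgraph"
        write_bedgraph(track, "s", 101, path)
        back = read_bedgraph(path, "s", 101, 250)
        np.testing.assert_array_equal(back, track)
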