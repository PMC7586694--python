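import numpy as np
import pytest

from oleapop.io_formats import (
    AnalysisDataset, GenotypeMatrix, LoadReport, PopulationManifest,
)


QUARTET_MANIFEST = PopulationManifest({
    "P1": "wild", "P2": "cultivars_set1", "P3": "cultivars_set2",
    "OUT": "outgroup",
})


def quartet_dataset(matrix: GenotypeMatrix) -> AnalysisDataset:
    """Wrap a four-taxon genotype matrix in a minimal AnalysisDataset."""
    length = int(matrix.pos.max()) if matrix.n_variants else 1
    reference = {str(sc): "A" * length for sc in set(matrix.scaffolds)}
    return AnalysisDataset(matrix, [], reference, QUARTET_MANIFEST, LoadReport())


def random_matrix(rng, n_variants=50, n_samples=6, scaffold="sc1",
                  missing_rate=0.0, with_outgroup_hom_ref=False):
    """Random biallelic dosage matrix for property tests."""
    dosage = rng.integers(0, 3, size=(n_variants, n_samples)).astype(np.int8)
    if missing_rate > 0:
        miss = rng.random((n_variants, n_samples)) < missing_rate
        dosage[miss] = -1
    if with_outgroup_hom_ref:
        dosage[:, -1] = 0
    pos = np.sort(rng.choice(10 * n_variants, size=n_variants, replace=False)) + 1
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, n_variants)]
    alt = np.array([bases[(list(bases).index(r) + 1 + rng.integers(3)) % 4]
                    for r in ref])
    alt = np.where(alt == ref, "T", alt)
    alt[alt == ref] = "G"
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n_samples)],
        scaffolds=np.array([scaffold] * n_variants, dtype=object),
        pos=pos,
        ref_allele=ref.astype(object),
        alt_allele=alt.astype(object),
        dosage=dosage,
    )


@pytest.fixture(scope="session")
def cohort_sim(tmp_path_factory):
    """One mid-sized seeded cohort, written to disk, shared across tests."""
    from oleapop.synthetic_data import CohortSimParams, simulate_cohort

    out = tmp_path_factory.mktemp("cohort")
    params = CohortSimParams(seed=42, quality_fail_fraction=0.2,
                             differentiation=0.1)
    return simulate_cohort(params, out_dir=str(out))


@pytest.fixture(scope="session")
def loaded_cohort(cohort_sim):
    """The same cohort re-read from its files through the standard loader."""
    from oleapop.io_formats import load_dataset

    p = cohort_sim.paths
    return load_dataset(p["vcf"], p["gff"], p["fasta"], p["manifest"])
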