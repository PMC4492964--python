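import numpy as np
import pytest

from msatpop.genotype import GenotypeMatrix, LocusDef, SampleRecord


def build_matrix(rows, locus_ids=None, mito_types=None):
    """Hand-build a matrix from rows of genotype tuples.

    ``rows`` is {sample_id: [(a, b), ...]}; loci default to L1..Ln.
    """
    first = next(iter(rows.values()))
    n_loci = len(first)
    locus_ids = locus_ids or [f"L{j + 1}" for j in range(n_loci)]
    mito_types = mito_types or {}
    samples = [
        SampleRecord(
            colony_id=sid,
            mito_type=mito_types.get(sid, "mt-L"),
            genotypes=dict(zip(locus_ids, genos)),
        )
        for sid, genos in rows.items()
    ]
    return GenotypeMatrix(loci=[LocusDef(lid) for lid in locus_ids], samples=samples)


def random_matrix(seed, n_samples=6, n_loci=4, n_alleles=5, p_missing=0.1, two_types=True):
    """A random but reproducible matrix; types assigned in blocks."""
    rng = np.random.default_rng(seed)
    ladders = [100 + 20 * j + 3 * np.arange(n_alleles) for j in range(n_loci)]
    rows = {}
    mito = {}
    for i in range(n_samples):
        sid = f"s{i + 1}"
        genos = []
        for j in range(n_loci):
            if rng.random() < p_missing:
                genos.append((0, 0))
            else:
                a, b = rng.choice(ladders[j], size=2)
                genos.append((int(min(a, b)), int(max(a, b))))
        rows[sid] = genos
        mito[sid] = "mt-L" if (not two_types or i < n_samples // 2 + 1) else "mt-S"
    return build_matrix(rows, mito_types=mito)


@pytest.fixture
def two_by_two():
    return build_matrix(
        {"c1": [(100, 104), (200, 200)], "c2": [(100, 100), (0, 0)]},
        locus_ids=["LA", "LB"],
        mito_types={"c1": "mt-L", "c2": "mt-S"},
    )
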