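import numpy as np
import pandas as pd
import pytest

from parallodrome.io import GenotypeMatrix


def make_meta(rows):
    """rows: list of (sample_id, population, region, ecotype, ploidy)."""
    return pd.DataFrame(
        rows, columns=["sample_id", "population", "region", "ecotype", "ploidy"]
    )


def make_matrix(meta, dosages, positions=None, chrom="chr1", ancestral="A",
                polarized=True):
    dosages = np.asarray(dosages, dtype=np.int16)
    n_loci = dosages.shape[1]
    if positions is None:
        positions = np.arange(1, n_loci + 1) * 200_000
    loci = pd.DataFrame({
        "chrom": [chrom] * n_loci,
        "pos": list(positions),
        "ref": ["A"] * n_loci,
        "alt": ["T"] * n_loci,
        "ancestral": [ancestral] * n_loci,
    })
    return GenotypeMatrix(samples=meta, loci=loci, dosages=dosages,
                          polarized=polarized)


@pytest.fixture
def mixed_meta():
    """Three samples: one diploid, two tetraploid, two populations."""
    return make_meta([
        ("s1", "popA", "NT", "foothill", 2),
        ("s2", "popB", "NT", "alpine", 4),
        ("s3", "popB", "NT", "alpine", 4),
    ])


@pytest.fixture(scope="session")
def small_study_matrix():
    """Reduced synthetic study genotypes shared across recovery tests."""
    from parallodrome.synthdata import StudyDesign, simulate_study_genotypes

    design = StudyDesign(genotyped_per_pop=2)
    return simulate_study_genotypes(design, n_loci=1500, seed=42)
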