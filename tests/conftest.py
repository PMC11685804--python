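import numpy as np
import pytest

from canegps.genorel import GenotypeMatrix, Pedigree


def make_genotype_matrix(dosages, chrom=None, pos=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a raw dosage array with auto labels."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypeMatrix(
        ids=np.array([f"g{i}" for i in range(n)], dtype=object),
        marker_ids=np.array([f"m{j}" for j in range(m)], dtype=object),
        chrom=np.asarray(chrom if chrom is not None else ["1"] * m, dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(1, m + 1)),
        dosages=dosages,
    )


def make_pedigree(rows) -> Pedigree:
    """rows: list of (id, sire, dam) with None for unknown parents."""
    ids = np.array([r[0] for r in rows], dtype=object)
    sire = np.array([r[1] for r in rows], dtype=object)
    dam = np.array([r[2] for r in rows], dtype=object)
    return Pedigree(id=ids, sire=sire, dam=dam,
                    genotyped=np.ones(len(rows), dtype=bool))


@pytest.fixture
def fullsib_pedigree() -> Pedigree:
    """Two founders and two full-sib offspring."""
    return make_pedigree(
        [("f1", None, None), ("f2", None, None),
         ("s1", "f1", "f2"), ("s2", "f1", "f2")]
    )
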