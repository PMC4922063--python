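import numpy as np
import pytest

from recmap.core import GenotypeMatrix, Marker, PhenotypeTable


def make_matrix(calls, chrom="13", start=1_000_000, spacing=10_000,
                alleleA="A", alleleB="G"):
    """GenotypeMatrix from a plain list-of-lists of codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    markers = [Marker(id=f"M{i}", chrom=chrom, pos=start + i * spacing,
                      alleleA=alleleA, alleleB=alleleB) for i in range(m)]
    return GenotypeMatrix(sample_ids=[f"S{i}" for i in range(n)],
                          markers=markers, calls=calls)


def make_phenotype(affected_flags):
    ids = [f"S{i}" for i in range(len(affected_flags))]
    return PhenotypeTable.from_groups(
        affected=[s for s, a in zip(ids, affected_flags) if a],
        unaffected=[s for s, a in zip(ids, affected_flags) if not a])


@pytest.fixture(scope="session")
def default_promoter_pair():
    """The default promoter allele pair (9-bp INS + GC>TT SUB + 14-bp INS
    with SOX payload on a motif-free reference), shared across tests."""
    from recmap.simulate import sim_promoter_pair

    return sim_promoter_pair(seed=11)
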