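import numpy as np
import pandas as pd
import pytest

from polybrix.genotype import LocusGenotypeTable


def make_table(loci_rows, calls_rows, samples):
    """Build a LocusGenotypeTable directly from literal rows.

    loci_rows: list of (chrom, pos, ref, alts-tuple)
    calls_rows: list (per locus) of per-sample calls (tuple of ints or None)
    """
    ids = [f"{c}:{p}" for c, p, _, _ in loci_rows]
    loci = pd.DataFrame(
        {
            "chrom": [r[0] for r in loci_rows],
            "pos": [r[1] for r in loci_rows],
            "ref": [r[2] for r in loci_rows],
            "alts": [r[3] for r in loci_rows],
        },
        index=pd.Index(ids, name="locus"),
    )
    calls = np.empty((len(loci_rows), len(samples)), dtype=object)
    for i, row in enumerate(calls_rows):
        for s, call in enumerate(row):
            calls[i, s] = None if call is None else tuple(sorted(call))
    return LocusGenotypeTable(loci=loci, calls=calls, samples=list(samples))


@pytest.fixture
def tiny_table():
    """3 loci x 4 tetraploid samples with one missing cell."""
    return make_table(
        [
            ("Ro01", 100, "A", ("T",)),
            ("Ro01", 200, "C", ("G", "CT")),
            ("Ro02", 50, "G", ("A",)),
        ],
        [
            [(0, 0, 1, 1), (0, 0, 0, 0), (1, 1, 1, 1), None],
            [(0, 1, 2, 2), (0, 0, 1, 1), (0, 0, 0, 2), (0, 0, 0, 0)],
            [(0, 0, 0, 1), (0, 0, 0, 0), (0, 0, 0, 0), (0, 0, 0, 0)],
        ],
        ["s1", "s2", "s3", "s4"],
    )


def random_table(rng, n_loci=20, n_samples=8, ploidy=4, missing_rate=0.1,
                 max_alleles=4):
    """A random genotype table for exhaustive-oracle comparisons."""
    loci_rows, calls_rows = [], []
    bases = ["A", "C", "G", "T"]
    for i in range(n_loci):
        k = int(rng.integers(1, max_alleles + 1))
        alts = tuple(bases[1:k])
        calls = []
        for _ in range(n_samples):
            if rng.random() < missing_rate:
                calls.append(None)
            else:
                calls.append(tuple(int(a) for a in rng.integers(0, k, ploidy)))
        loci_rows.append(("Ro01", 1000 + i, bases[0], alts))
        calls_rows.append(calls)
    return make_table(loci_rows, calls_rows, [f"s{j}" for j in range(n_samples)])
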