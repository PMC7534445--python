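"""Packaged reference tables used throughout the pipeline.

Three small TSVs ship with the package:

* the 40-sample sequencing cohort summary (breeding program, mean SSC in
  °Brix, CCS read counts, and the two k-means cluster assignments),
* the cross-genus syntenic blocks and the sugar-related QTL they contain
  for peach, strawberry and apple, and
* the 13-sample x 3-position sequencing-vs-KASP genotype panel with the
  target diagnostic allele of each assay.

Loaders validate structural invariants and raise :class:`FixtureError` if
a file has been corrupted.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "FixtureError",
    "sequenced_samples",
    "syntenic_blocks",
    "sugar_qtl",
    "kasp_concordance",
]

#: °Brix threshold splitting the cohort into high and low SSC classes
HIGH_SSC_THRESHOLD = 11.5


class FixtureError(RuntimeError):
    """A packaged data file failed its integrity checks."""


def _read(name: str) -> pd.DataFrame:
    path = resources.files("polybrix.data").joinpath(name)
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def sequenced_samples() -> pd.DataFrame:
    """The 40-sample discovery cohort summary.

    Columns: program, name, mean_ssc_brix, ccs_reads, mean_ccs_len,
    median_ccs_len, hv1_group, rov3_group, plus a derived ``ssc_class``
    ('high' for mean SSC > 11.5 °Brix, else 'low').
    """
    df = _read("sequenced_samples.tsv")
    if len(df) != 40:
        raise FixtureError(f"expected 40 samples, found {len(df)}")
    counts = df["program"].value_counts()
    if not (counts == 20).all():
        raise FixtureError(f"expected 20 samples per program, got {counts.to_dict()}")
    if (df["ccs_reads"] < 0).any():
        raise FixtureError("negative CCS read count")
    df = df.copy()
    df["ssc_class"] = (df["mean_ssc_brix"] > HIGH_SSC_THRESHOLD).map(
        {True: "high", False: "low"}
    )
    return df


def syntenic_blocks() -> pd.DataFrame:
    """Conserved syntenic blocks, one row per (block, genome) segment."""
    df = _read("syntenic_blocks.tsv")
    if (df["start"] > df["end"]).any():
        raise FixtureError("block segment with start > end")
    n_genomes = df.groupby("block_id")["genome"].nunique()
    if (n_genomes < 2).any():
        raise FixtureError("every syntenic block needs >= 2 member genomes")
    return df


def sugar_qtl() -> pd.DataFrame:
    """Sugar-related QTL intervals for peach, strawberry and apple."""
    df = _read("sugar_qtl.tsv")
    if (df["start"] > df["end"]).any():
        raise FixtureError("QTL with start > end")
    known = set(syntenic_blocks()["genome"])
    unknown = set(df["genome"]) - known
    if unknown:
        raise FixtureError(f"QTL on unknown genomes: {sorted(unknown)}")
    return df


def kasp_concordance() -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Sequencing-vs-KASP genotype panel.

    Returns ``(sequencing, kasp, targets)``: two samples x positions frames
    of colon-separated genotype strings and the target diagnostic allele per
    assayed position.
    """
    long = _read("kasp_concordance.tsv")
    targets = _read("kasp_targets.tsv").set_index("position")["target_allele"]
    seq = long.pivot(index="sample", columns="position", values="sequencing")
    kasp = long.pivot(index="sample", columns="position", values="kasp")
    if seq.shape != (13, 3) or seq.isna().any().any() or kasp.isna().any().any():
        raise FixtureError("concordance panel must be complete 13 x 3")
    if set(targets.index) != set(seq.columns):
        raise FixtureError("target alleles do not match assayed positions")
    return seq, kasp, targets
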