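"""Locus-named genotype tables from multi-sample, mixed-ploidy VCFs.

The central container is :class:`LocusGenotypeTable`: one row per variant
record (multiallelic records are kept whole), one call per sample, where a
call is the multiset of allele indices of that sample's ploidy or MISSING.
A companion read-depth table enforces the rule that a cell with zero reads
is recorded as missing even if a genotype was emitted for it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeTableError",
    "LocusGenotypeTable",
    "build_genotype_table",
    "apply_depth_missingness",
    "read_depth_table",
    "write_genotype_table",
    "read_genotype_table",
    "summarize_ccs",
]


class GenotypeTableError(ValueError):
    """Malformed genotype input (reported with the offending locus id)."""


@dataclass
class LocusGenotypeTable:
    """Per-locus, per-sample allele calls with depth-derived missingness.

    Attributes
    ----------
    loci
        DataFrame indexed by locus id (``"chrom:pos"``, 1-based position)
        with columns ``chrom``, ``pos``, ``ref``, ``alts`` (tuple of str),
        sorted by (chrom, pos).
    calls
        Object array of shape (n_loci, n_samples); each cell is a sorted
        tuple of allele indices (length = that sample's ploidy) or ``None``
        for MISSING.
    samples
        Sample identifiers, column order of ``calls``.
    """

    loci: pd.DataFrame
    calls: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.loci), len(self.samples)):
            raise ValueError("calls shape does not match loci x samples")
        if self.loci.index.has_duplicates:
            dups = self.loci.index[self.loci.index.duplicated()].tolist()
            raise GenotypeTableError(f"duplicate locus ids: {dups}")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_loci, n_samples) array marking MISSING cells."""
        return np.vectorize(lambda c: c is None, otypes=[bool])(self.calls) \
            if self.calls.size else np.zeros(self.calls.shape, dtype=bool)

    def missing_fraction(self) -> pd.Series:
        mask = self.missing_mask()
        return pd.Series(mask.mean(axis=1), index=self.loci.index)

    def allele_strings(self, i: int) -> list[str]:
        row = self.loci.iloc[i]
        return [row["ref"], *row["alts"]]

    def observed_alleles(self, i: int) -> list[str]:
        """Distinct allele strings seen in non-missing calls at locus ``i``."""
        names = self.allele_strings(i)
        seen: set[int] = set()
        for call in self.calls[i]:
            if call is not None:
                seen.update(call)
        return [names[a] for a in sorted(seen)]

    def subset_loci(self, keep: Iterable[str]) -> "LocusGenotypeTable":
        keep = list(keep)
        pos = self.loci.index.get_indexer(keep)
        return LocusGenotypeTable(
            loci=self.loci.loc[keep].copy(),
            calls=self.calls[pos].copy(),
            samples=list(self.samples),
        )


def _sorted_loci(rows: list[dict], calls: list[list]) -> tuple[pd.DataFrame, np.ndarray]:
    frame = pd.DataFrame(rows)
    order = np.lexsort((frame["pos"].to_numpy(), frame["chrom"].to_numpy()))
    frame = frame.iloc[order].set_index("locus")
    arr = np.empty((len(calls), len(calls[0]) if calls else 0), dtype=object)
    for r, row in enumerate(calls):
        arr[r, :] = row
    return frame, arr[order]


def build_genotype_table(
    vcf_path,
    samples: list[str] | None = None,
    ploidies: Mapping[str, int] | None = None,
) -> LocusGenotypeTable:
    """Decode a multi-sample VCF into a :class:`LocusGenotypeTable`.

    Multiallelic records are kept as single loci with their full ALT list.
    A genotype with any uncalled entry (``.``) is treated as wholly MISSING
    for that cell. If ``ploidies`` is given, a called genotype whose entry
    count disagrees with the sample's declared ploidy raises
    :class:`GenotypeTableError` naming the locus.
    """
    import pysam

    vf = pysam.VariantFile(str(vcf_path))
    vcf_samples = list(vf.header.samples)
    if samples is None:
        samples = vcf_samples
    else:
        absent = set(samples) - set(vcf_samples)
        if absent:
            raise GenotypeTableError(f"samples not in VCF: {sorted(absent)}")

    rows: list[dict] = []
    calls: list[list] = []
    for rec in vf:
        locus_id = f"{rec.chrom}:{rec.pos}"
        alts = tuple(rec.alts) if rec.alts else ()
        row_calls = []
        for s in samples:
            gt = rec.samples[s]["GT"]
            if gt is None or len(gt) == 0 or any(a is None for a in gt):
                row_calls.append(None)
                continue
            if ploidies is not None and len(gt) != ploidies[s]:
                raise GenotypeTableError(
                    f"{locus_id}: sample {s} GT has {len(gt)} entries, "
                    f"declared ploidy is {ploidies[s]}"
                )
            if any(a > len(alts) for a in gt):
                raise GenotypeTableError(
                    f"{locus_id}: sample {s} allele index exceeds ALT count"
                )
            row_calls.append(tuple(sorted(gt)))
        rows.append(
            {"locus": locus_id, "chrom": rec.chrom, "pos": rec.pos,
             "ref": rec.ref, "alts": alts}
        )
        calls.append(row_calls)

    if not rows:
        loci = pd.DataFrame(
            columns=["chrom", "pos", "ref", "alts"],
            index=pd.Index([], name="locus"),
        )
        return LocusGenotypeTable(
            loci=loci, calls=np.empty((0, len(samples)), dtype=object),
            samples=list(samples),
        )
    loci, arr = _sorted_loci(rows, calls)
    return LocusGenotypeTable(loci=loci, calls=arr, samples=list(samples))


def read_depth_table(path) -> pd.DataFrame:
    """Read a long-format depth table (columns chrom, pos, sample, depth)."""
    depth = pd.read_csv(path, sep="\t")
    required = {"chrom", "pos", "sample", "depth"}
    if not required.issubset(depth.columns):
        raise ValueError(f"depth table must have columns {sorted(required)}")
    return depth


def apply_depth_missingness(
    table: LocusGenotypeTable, depth: pd.DataFrame
) -> LocusGenotypeTable:
    """Force every zero-depth cell to MISSING; leave covered cells untouched.

    ``depth`` is a long table (chrom, pos, sample, depth). Cells absent from
    the depth table keep their call, except cells already MISSING, which are
    logged as audited-at-depth-0. Returns a new table; the input is not
    modified. The operation is idempotent.
    """
    depth = depth.copy()
    depth["locus"] = depth["chrom"].astype(str) + ":" + depth["pos"].astype(str)
    wide = depth.pivot_table(
        index="locus", columns="sample", values="depth", aggfunc="min"
    )

    calls = table.calls.copy()
    locus_ids = table.loci.index
    for i, locus in enumerate(locus_ids):
        for s, sample in enumerate(table.samples):
            try:
                d = wide.at[locus, sample]
            except KeyError:
                d = np.nan
            if np.isnan(d):
                if calls[i, s] is None:
                    logger.warning(
                        "no depth entry for MISSING cell (%s, %s); "
                        "treated as depth 0", locus, sample,
                    )
                continue
            if d == 0:
                calls[i, s] = None
    return LocusGenotypeTable(
        loci=table.loci.copy(), calls=calls, samples=list(table.samples)
    )


def write_genotype_table(table: LocusGenotypeTable, path) -> None:
    """Serialize the table as TSV, calls as slash-joined indices or '.'."""
    records = []
    for i, (locus, row) in enumerate(table.loci.iterrows()):
        rec = {
            "locus": locus, "chrom": row["chrom"], "pos": row["pos"],
            "ref": row["ref"], "alt": ",".join(row["alts"]) or ".",
        }
        for s, sample in enumerate(table.samples):
            call = table.calls[i, s]
            rec[sample] = "." if call is None else "/".join(map(str, call))
        records.append(rec)
    pd.DataFrame(records).to_csv(path, sep="\t", index=False)


def read_genotype_table(path) -> LocusGenotypeTable:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    meta_cols = ["locus", "chrom", "pos", "ref", "alt"]
    samples = [c for c in frame.columns if c not in meta_cols]
    rows, calls = [], []
    for _, r in frame.iterrows():
        alts = tuple(r["alt"].split(",")) if r["alt"] != "." else ()
        rows.append(
            {"locus": r["locus"], "chrom": r["chrom"], "pos": int(r["pos"]),
             "ref": r["ref"], "alts": alts}
        )
        calls.append(
            [None if r[s] == "." else tuple(int(x) for x in r[s].split("/"))
             for s in samples]
        )
    if not rows:
        loci = pd.DataFrame(
            columns=["chrom", "pos", "ref", "alts"], index=pd.Index([], name="locus")
        )
        return LocusGenotypeTable(
            loci=loci, calls=np.empty((0, len(samples)), dtype=object),
            samples=samples,
        )
    loci, arr = _sorted_loci(rows, calls)
    return LocusGenotypeTable(loci=loci, calls=arr, samples=samples)


def summarize_ccs(metadata: pd.DataFrame) -> dict:
    """Total and per-program circular-consensus read counts.

    ``metadata`` needs columns ``program`` and ``ccs_reads``. Per-program
    totals partition the grand total. An empty frame yields total 0.
    """
    if len(metadata) == 0:
        return {"total_reads": 0, "per_program": {}}
    if (metadata["ccs_reads"] < 0).any():
        raise ValueError("CCS read counts must be nonnegative")
    per = metadata.groupby("program")["ccs_reads"].sum().astype(int).to_dict()
    return {"total_reads": int(metadata["ccs_reads"].sum()), "per_program": per}
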