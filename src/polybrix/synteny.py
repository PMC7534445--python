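"""Cross-genus syntenic QTL intersection and capture-bait arithmetic.

A syntenic block is a set of co-linear segments, one per genome (1-based
inclusive coordinates throughout this module). A block becomes a conserved
trait region when QTL intervals from at least ``min_species`` distinct
genomes overlap its member segments — the criterion used to pick capture
targets that are supported by more than one crop's QTL evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import round_half_up

__all__ = [
    "find_conserved_qtl_regions",
    "map_markers_to_regions",
    "tile_baits",
    "coverage_percentage",
    "BaitDesign",
]

_BLOCK_COLS = ["block_id", "genome", "chrom", "start", "end"]
_QTL_COLS = ["qtl_name", "genome", "chrom", "start", "end"]


def _check_intervals(df: pd.DataFrame, what: str) -> None:
    if (df["start"] > df["end"]).any():
        bad = df.loc[df["start"] > df["end"]]
        raise ValueError(f"{what} with start > end:\n{bad}")


def find_conserved_qtl_regions(
    blocks: pd.DataFrame, qtls: pd.DataFrame, min_species: int = 2
) -> pd.DataFrame:
    """Blocks whose segments overlap QTL from >= ``min_species`` genomes.

    ``blocks`` has one row per (block_id, genome) segment; ``qtls`` one row
    per QTL interval. Overlap requires the same genome and chromosome and
    at least one shared base (1-based inclusive intervals). Returns one row
    per (block, supporting QTL) for qualifying blocks, with an
    ``n_species`` column; empty inputs yield an empty frame. The result is
    invariant under row-order permutations of either input, and raising
    ``min_species`` can only shrink it.
    """
    blocks = blocks[_BLOCK_COLS + [c for c in blocks.columns if c not in _BLOCK_COLS]]
    _check_intervals(blocks, "block segment")
    if len(qtls):
        _check_intervals(qtls, "QTL")
    merged = blocks.merge(
        qtls[[c for c in qtls.columns if c in set(_QTL_COLS) | {"trait", "crop"}]],
        on=["genome", "chrom"],
        suffixes=("", "_qtl"),
        how="inner",
    )
    if merged.empty:
        return pd.DataFrame(
            columns=["block_id", "genome", "qtl_name", "n_species"]
        )
    overlap = (merged["start"] <= merged["end_qtl"]) & (
        merged["end"] >= merged["start_qtl"]
    )
    support = merged[overlap]
    n_species = support.groupby("block_id")["genome"].nunique()
    keep = n_species[n_species >= min_species].index
    out = support[support["block_id"].isin(keep)].copy()
    out["n_species"] = out["block_id"].map(n_species)
    out = out.sort_values(["block_id", "genome", "qtl_name"]).reset_index(drop=True)
    return out


def map_markers_to_regions(
    markers: pd.DataFrame, regions: pd.DataFrame
) -> pd.DataFrame:
    """Annotate each marker with the region(s) containing it.

    ``markers`` needs columns ``chrom`` and ``pos``; ``regions`` needs
    ``region_id``, ``chrom``, ``start``, ``end``. Containment is inclusive
    of both endpoints; a marker in no region gets an empty string, one in
    several gets a comma-joined list.
    """
    _check_intervals(regions, "region")
    assigned = []
    for _, m in markers.iterrows():
        hits = regions[
            (regions["chrom"] == m["chrom"])
            & (regions["start"] <= m["pos"])
            & (regions["end"] >= m["pos"])
        ]["region_id"].tolist()
        assigned.append(",".join(str(h) for h in hits))
    out = markers.copy()
    out["region_id"] = assigned
    return out


@dataclass
class BaitDesign:
    """Result of tiling capture baits over a set of exon sequences."""

    exons: pd.DataFrame  # exon_id, length, status, n_baits, starts
    n_submitted: int
    n_designable: int
    n_removed: int
    total_baits: int
    coverage_pct: float  # % of submitted exon length that is designable


def tile_baits(
    exons,
    bait_length: int = 80,
    tiling: int = 2,
    min_exon: int = 50,
) -> BaitDesign:
    """Place capture baits at ``tiling``X density over each exon.

    Exons shorter than ``min_exon`` are removed before design. Designable
    exons of at least ``bait_length`` receive baits starting every
    ``bait_length / tiling`` bases plus a terminal bait flush with the exon
    end; shorter designable exons get a single exon-length bait flagged
    ``short_bait``. ``coverage_pct`` is the designable fraction of the
    total submitted length, one decimal.
    """
    if bait_length % tiling != 0:
        raise ValueError("tiling must divide bait_length evenly")
    step = bait_length // tiling
    rows = []
    total_len = 0
    designable_len = 0
    total_baits = 0
    for exon_id, length in exons:
        length = int(length)
        if length <= 0:
            raise ValueError(f"exon {exon_id} has nonpositive length")
        total_len += length
        if length < min_exon:
            rows.append((exon_id, length, "removed_short", 0, ()))
            continue
        designable_len += length
        if length < bait_length:
            rows.append((exon_id, length, "short_bait", 1, (1,)))
            total_baits += 1
            continue
        flush = length - bait_length + 1
        starts = list(range(1, flush + 1, step))
        if starts[-1] != flush:
            starts.append(flush)
        rows.append((exon_id, length, "tiled", len(starts), tuple(starts)))
        total_baits += len(starts)
    frame = pd.DataFrame(
        rows, columns=["exon_id", "length", "status", "n_baits", "starts"]
    )
    n_removed = int((frame["status"] == "removed_short").sum())
    coverage = (
        round_half_up(100.0 * designable_len / total_len, 1) if total_len else 0.0
    )
    return BaitDesign(
        exons=frame,
        n_submitted=len(frame),
        n_designable=len(frame) - n_removed,
        n_removed=n_removed,
        total_baits=total_baits,
        coverage_pct=coverage,
    )


def coverage_percentage(n_covered: int, n_total: int) -> float:
    """``100 * n_covered / n_total`` rounded half-up to one decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_covered <= n_total:
        raise ValueError("n_covered must lie in [0, n_total]")
    return round_half_up(100.0 * n_covered / n_total, 1)
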