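"""Marker validation, assay concordance and KASP template design.

Candidate alleles from the discovery stage are re-tested on independent
panels, environment by environment (each location-year is its own test
family for multiple-testing purposes), genotype calls from two methods are
audited for concordance, and flanking consensus sequences are prepared for
competitive allele-specific PCR (KASP) assay design.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import round_half_up
from .association import bh_adjust, welch_screen

__all__ = [
    "ConcordanceReport",
    "ConsensusTemplate",
    "Variant",
    "validate_per_environment",
    "concordance",
    "design_consensus",
    "assay_attrition_report",
    "IUPAC",
]

#: IUPAC ambiguity code for each set of bases
IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("GC"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


# ---------------------------------------------------------------------------
# per-environment validation
# ---------------------------------------------------------------------------

def validate_per_environment(
    calls: pd.DataFrame,
    phenotypes: pd.DataFrame,
    alpha: float = 0.05,
    min_class_size: int = 3,
) -> pd.DataFrame:
    """Welch + BH validation of each marker in each environment.

    Parameters
    ----------
    calls
        samples x markers frame of target-allele calls (1 present,
        0 absent, NaN missing).
    phenotypes
        Long frame with columns ``sample``, ``environment``, ``ssc_brix``
        (replicate rows are averaged per sample-environment).
    alpha
        BH significance level; the correction family is the set of markers
        tested within one environment.

    Returns a tidy frame (marker, environment) with carrier counts, Welch
    t/df/p, q, ``significant`` and the carrier-minus-non-carrier effect in
    °Brix. Marker-environment pairs with fewer than ``min_class_size``
    samples in either class carry NaN statistics.
    """
    per_env = (
        phenotypes.groupby(["sample", "environment"])["ssc_brix"]
        .mean()
        .reset_index()
    )
    out = []
    for env, sub in per_env.groupby("environment", sort=True):
        ssc = sub.set_index("sample")["ssc_brix"]
        common = calls.index.intersection(ssc.index)
        res = welch_screen(
            calls.loc[common], ssc.loc[common], min_class_size=min_class_size
        )
        q, sig = bh_adjust(res["p"], alpha=alpha)
        res = res.assign(q=q, significant=sig, environment=env)
        res.index.name = "marker"
        out.append(res.reset_index())
    result = pd.concat(out, ignore_index=True)
    cols = [
        "marker", "environment", "n_present", "n_absent",
        "effect_brix", "t", "df", "p", "q", "significant",
    ]
    return result[cols]


# ---------------------------------------------------------------------------
# sequencing-vs-assay concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceReport:
    """Per-sample, per-position agreement between two genotyping methods."""

    matches: pd.DataFrame  # samples x positions, bool
    concordant: pd.Series  # per-sample flag: all positions match
    n_concordant: int
    n_total: int

    @property
    def discordant_samples(self) -> list[str]:
        return sorted(self.concordant.index[~self.concordant])


def _parse_call(call: str) -> Counter:
    return Counter(call.split(":"))


def _project(call: Counter, target: str) -> Counter:
    """Collapse alleles to {target, other}, as a biallelic assay reports."""
    out: Counter = Counter()
    for allele, n in call.items():
        out[allele if allele == target else "other"] += n
    return out


def concordance(
    report_a: pd.DataFrame,
    report_b: pd.DataFrame,
    targets: pd.Series | dict | None = None,
) -> ConcordanceReport:
    """Compare two samples x positions tables of genotype strings.

    Calls are colon-separated allele strings compared as unordered
    multisets (``"A:T"`` matches ``"T:A"``). When ``targets`` maps each
    position to its assay's target allele, every allele is first collapsed
    to target/other before comparison: a biallelic assay such as KASP
    cannot distinguish off-assay alleles from the non-target allele, so a
    sequencing call like ``A:G`` and an assay call ``A:A`` agree for a
    T-target assay, whereas ``A:T`` vs ``T:T`` do not.
    """
    if list(report_a.index) != list(report_b.index) or list(
        report_a.columns
    ) != list(report_b.columns):
        raise ValueError(
            "inputs must share samples and positions; got "
            f"samples {list(report_a.index)} vs {list(report_b.index)}, "
            f"positions {list(report_a.columns)} vs {list(report_b.columns)}"
        )
    targets = dict(targets) if targets is not None else {}
    matches = pd.DataFrame(
        index=report_a.index, columns=report_a.columns, dtype=bool
    )
    for pos in report_a.columns:
        target = targets.get(pos)
        for s in report_a.index:
            a = _parse_call(report_a.at[s, pos])
            b = _parse_call(report_b.at[s, pos])
            if target is not None:
                a, b = _project(a, target), _project(b, target)
            matches.at[s, pos] = a == b
    concordant = matches.all(axis=1)
    return ConcordanceReport(
        matches=matches,
        concordant=concordant,
        n_concordant=int(concordant.sum()),
        n_total=len(concordant),
    )


# ---------------------------------------------------------------------------
# KASP consensus template design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Variant:
    """A polymorphic site: 1-based position, REF string, ALT strings."""

    pos: int
    ref: str
    alts: tuple[str, ...]

    @property
    def is_length_preserving(self) -> bool:
        return all(len(a) == len(self.ref) for a in self.alts)


@dataclass
class ConsensusTemplate:
    """Flanking consensus sequence for one target diagnostic allele.

    The target allele sits verbatim (never ambiguity-coded) at
    ``target_offset`` within ``sequence``; other SNP/MNP sites in the
    window are IUPAC-coded over reference plus alternates; flanking indel
    sites are flagged rather than spliced in, since assay templates must
    stay ungapped — an indel starting within 25 bp of the target is the
    failure mechanism known to break allele-specific primers.
    """

    locus: str
    target_allele: str
    flank: int
    sequence: str
    target_offset: int
    indel_flags: list[dict] = field(default_factory=list)

    @property
    def has_near_indel(self) -> bool:
        return any(f["near_target"] for f in self.indel_flags)


def design_consensus(
    reference: str,
    target_pos: int,
    target_allele: str,
    variants: list[Variant],
    flank: int = 50,
    chrom: str = "",
) -> ConsensusTemplate:
    """Build the consensus template around one target diagnostic allele.

    ``reference`` is the reference sequence of the chromosome (1-based
    addressing); it must cover ``[target_pos - flank, target_pos + flank]``
    around the target variant. The variant record at ``target_pos`` must
    list ``target_allele`` among its REF/ALT strings. Deterministic.
    """
    by_pos = {v.pos: v for v in variants}
    tv = by_pos.get(target_pos)
    if tv is None:
        raise ValueError(f"no variant record at target position {target_pos}")
    if target_allele != tv.ref and target_allele not in tv.alts:
        raise ValueError(
            f"target allele {target_allele!r} absent from variant at "
            f"{target_pos} (ref {tv.ref!r}, alts {tv.alts})"
        )
    start = target_pos - flank  # 1-based window start
    end = target_pos + len(tv.ref) - 1 + flank
    if start < 1 or end > len(reference):
        raise ValueError(
            f"reference does not cover the window [{start}, {end}]"
        )

    seq = list(reference[start - 1 : end])
    target_offset = flank
    # substitute the target allele (replaces the REF allele span)
    seq[target_offset : target_offset + len(tv.ref)] = list(target_allele)

    indel_flags: list[dict] = []
    shift = len(target_allele) - len(tv.ref)
    for v in variants:
        if v.pos == target_pos or v.pos + len(v.ref) - 1 < start or v.pos > end:
            continue
        offset = v.pos - start + (shift if v.pos > target_pos else 0)
        if v.is_length_preserving:
            for k in range(len(v.ref)):
                bases = {v.ref[k]} | {alt[k] for alt in v.alts}
                code = IUPAC.get(frozenset(b.upper() for b in bases))
                if code is None:
                    raise ValueError(f"non-ACGT alleles at position {v.pos}")
                idx = offset + k
                if 0 <= idx < len(seq) and not (
                    target_offset <= idx < target_offset + len(target_allele)
                ):
                    seq[idx] = code
        else:
            distance = (
                v.pos - (target_pos + len(tv.ref) - 1)
                if v.pos > target_pos
                else target_pos - (v.pos + len(v.ref) - 1)
            )
            indel_flags.append(
                {
                    "pos": v.pos,
                    "distance_bp": int(distance),
                    "near_target": bool(distance <= 25),
                }
            )

    sequence = "".join(seq)
    locus = f"{chrom}:{target_pos}" if chrom else str(target_pos)
    return ConsensusTemplate(
        locus=locus,
        target_allele=target_allele,
        flank=flank,
        sequence=sequence,
        target_offset=target_offset,
        indel_flags=indel_flags,
    )


def assay_attrition_report(n_designed: int, n_failed: int) -> dict:
    """Usable-marker count and failure percentage for an assay batch.

    ``pct_failed`` is reported to one decimal (half-up), e.g. 27 failures
    among 111 designed assays gives 84 usable markers and 24.3% failed.
    """
    if n_designed < 0 or n_failed < 0:
        raise ValueError("counts must be nonnegative")
    if n_failed > n_designed:
        raise ValueError("n_failed cannot exceed n_designed")
    if n_designed == 0:
        return {"n_usable": 0, "pct_failed": 0.0}
    return {
        "n_usable": n_designed - n_failed,
        "pct_failed": round_half_up(100.0 * n_failed / n_designed, 1),
    }
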