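"""Synthetic mixed-ploidy cohorts with planted trait effects.

The generator emulates a clonal breeding cohort of the kind used for
allele-trait discovery in autopolyploid berry crops: a few dozen samples
of even ploidy (4x-8x), a few thousand biallelic-to-tetraallelic loci,
2-4 population groups with group-divergent allele frequencies, depth-driven
missingness, and soluble-solids-content (SSC) phenotypes recorded as
replicate measurements in several location-year environments.

Every random draw is governed by a single seed; the draw order is fixed
(allele frequencies, dosages, missingness, depth, environment residuals,
replicate noise) so that a given :class:`SimConfig` always produces a
bitwise-identical :class:`SimCohort`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CausalAllele",
    "SimConfig",
    "SimCohort",
    "simulate_cohort",
    "write_cohort",
]

_BASES = ("A", "C", "G", "T")

#: default location-year effects, °Brix; two locations x two seasons with
#: modest year-to-year swings comparable to breeding-record variation
DEFAULT_ENV_EFFECTS: Mapping[str, float] = {
    "loc1-2015": 0.35,
    "loc1-2016": -0.35,
    "loc2-2015": 0.15,
    "loc2-2016": -0.15,
}


class CausalAllele(NamedTuple):
    """A planted allele effect: carrying >=1 copy shifts SSC by ``effect``."""

    locus: int
    allele: int
    effect: float


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cohort.

    Parameters
    ----------
    n_samples
        Number of clonal individuals.
    ploidies
        Even ploidy per sample. A single int applies to every sample; a
        sequence is cycled over samples. Must be even and >= 2.
    n_loci
        Number of variant loci.
    n_groups
        Number of population groups (breeding-program style structure).
    group_assignment
        Optional explicit 0-based group label per sample; defaults to a
        round-robin assignment giving balanced groups.
    group_shifts
        Additive group-level SSC shift (°Brix) per group; defaults to zeros.
    causal_alleles
        Planted structure-independent effects, ``(locus, allele, effect)``.
        Carriers (>=1 copy) of the allele gain ``effect`` °Brix.
    confounded_alleles
        Planted structure-confounded effects: the effect is sign-flipped
        across groups (+effect in group 0, -effect elsewhere) and applied
        to the group-centered carrier indicator, so it is a pure
        group x allele interaction: it contributes no group-level mean
        shift and no marginal allele effect, only opposite within-group
        effects.
    baseline_ssc
        Intercept, °Brix.
    env_effects
        Additive offset per environment label (location-year), °Brix.
    residual_sd
        SD of the per-sample-per-environment phenotype residual, °Brix.
    replicate_sd
        Extra SD of individual replicate measurements around the
        sample-environment value (default 0: replicates repeat it exactly).
    n_replicates
        Replicate measurements per sample per environment.
    missing_rate
        Probability that a (locus, sample) cell has zero read depth and a
        missing genotype (missing completely at random).
    depth_mean
        Mean read depth of non-missing cells.
    allele_count_probs
        Probabilities that a locus carries 2, 3 or 4 alleles.
    group_divergence
        Dirichlet concentration for per-group allele frequencies; smaller
        values give more divergent (better separated) groups.
    seed
        Seed fixing all randomness.
    """

    n_samples: int = 40
    ploidies: int | Sequence[int] = (4, 4, 6, 6, 8, 8)
    n_loci: int = 1000
    n_groups: int = 2
    group_assignment: Sequence[int] | None = None
    group_shifts: Sequence[float] | None = None
    causal_alleles: Sequence[CausalAllele] = ()
    confounded_alleles: Sequence[CausalAllele] = ()
    baseline_ssc: float = 10.0
    env_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENV_EFFECTS)
    )
    residual_sd: float = 1.5
    replicate_sd: float = 0.0
    n_replicates: int = 3
    missing_rate: float = 0.05
    depth_mean: float = 20.0
    allele_count_probs: Sequence[float] = (0.85, 0.10, 0.05)
    group_divergence: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        ploidies = self.sample_ploidies()
        if np.any(ploidies < 2) or np.any(ploidies % 2 != 0):
            raise ValueError("ploidies must all be even and >= 2")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.group_assignment is not None:
            labels = np.asarray(self.group_assignment)
            if labels.shape != (self.n_samples,):
                raise ValueError("group_assignment must have one label per sample")
            if labels.min() < 0 or labels.max() >= self.n_groups:
                raise ValueError("group labels must lie in [0, n_groups)")
        if self.group_shifts is not None and len(self.group_shifts) != self.n_groups:
            raise ValueError("group_shifts must have one entry per group")
        for planted in (*self.causal_alleles, *self.confounded_alleles):
            locus, allele, effect = planted
            if not 0 <= locus < self.n_loci:
                raise ValueError(f"causal locus {locus} out of range")
            if not 0 <= allele < 4:
                raise ValueError(f"causal allele index {allele} out of range")
            if not np.isfinite(effect):
                raise ValueError("planted effects must be finite")
        if abs(sum(self.allele_count_probs) - 1.0) > 1e-9:
            raise ValueError("allele_count_probs must sum to 1")
        if self.residual_sd < 0 or self.replicate_sd < 0:
            raise ValueError("standard deviations must be nonnegative")

    def sample_ploidies(self) -> np.ndarray:
        if isinstance(self.ploidies, (int, np.integer)):
            return np.full(self.n_samples, int(self.ploidies))
        reps = -(-self.n_samples // len(self.ploidies))
        return np.asarray(list(self.ploidies) * reps)[: self.n_samples].astype(int)

    def sample_groups(self) -> np.ndarray:
        if self.group_assignment is not None:
            return np.asarray(self.group_assignment, dtype=int)
        return np.arange(self.n_samples) % self.n_groups


@dataclass
class SimCohort:
    """A realized cohort: genotypes (VCF semantics), depths, phenotypes, truth.

    ``dosage[i, s, a]`` counts copies of allele ``a`` at locus ``i`` in sample
    ``s`` (allele 0 is REF). ``missing`` marks zero-depth cells, whose
    genotype is unobserved regardless of the underlying dosage.
    """

    config: SimConfig
    samples: list[str]
    ploidy: np.ndarray
    group: np.ndarray
    loci: pd.DataFrame  # index locus_id; columns chrom, pos, ref, alts
    n_alleles: np.ndarray
    dosage: np.ndarray  # (n_loci, n_samples, 4)
    depth: np.ndarray  # (n_loci, n_samples)
    phenotypes: pd.DataFrame  # sample, environment, replicate, ssc_brix
    sample_env_value: pd.DataFrame  # samples x environments, °Brix
    truth: pd.DataFrame  # locus_id, allele, effect, kind

    @property
    def missing(self) -> np.ndarray:
        return self.depth == 0

    def allele_strings(self, locus_index: int) -> list[str]:
        row = self.loci.iloc[locus_index]
        return [row["ref"], *row["alts"]]

    def mean_ssc(self) -> pd.Series:
        """Per-sample mean SSC over all environments and replicates (°Brix)."""
        out = self.phenotypes.groupby("sample", sort=False)["ssc_brix"].mean()
        return out.reindex(self.samples)

    def allele_matrix(self) -> pd.DataFrame:
        """Presence/absence matrix straight from the dosage tensor.

        Columns are ``(locus_id, allele_string)`` pairs for alleles observed
        in at least one non-missing call; entries are 1.0 (present),
        0.0 (absent) or NaN (missing cell). Equals the round-trip through
        VCF writing, table building and dominant encoding.
        """
        present = self.dosage > 0
        obs = present & ~self.missing[:, :, None]
        cols: list[tuple[str, str]] = []
        data: list[np.ndarray] = []
        miss = self.missing
        locus_ids = self.loci.index.to_numpy()
        for i in range(len(locus_ids)):
            alleles = self.allele_strings(i)
            for a in range(self.n_alleles[i]):
                if not obs[i, :, a].any():
                    continue
                col = present[i, :, a].astype(float)
                col[miss[i]] = np.nan
                cols.append((locus_ids[i], alleles[a]))
                data.append(col)
        if not cols:
            return pd.DataFrame(
                index=pd.Index(self.samples, name="sample"),
                columns=pd.MultiIndex.from_tuples([], names=["locus", "allele"]),
                dtype=float,
            )
        mat = pd.DataFrame(
            np.column_stack(data),
            index=pd.Index(self.samples, name="sample"),
            columns=pd.MultiIndex.from_tuples(cols, names=["locus", "allele"]),
        )
        return mat

    def to_genotype_table(self):
        """Materialize the truth calls as a :class:`~polybrix.genotype.LocusGenotypeTable`."""
        from .genotype import LocusGenotypeTable

        n_loci, n_samples = self.depth.shape
        calls = np.empty((n_loci, n_samples), dtype=object)
        for i in range(n_loci):
            for s in range(n_samples):
                if self.missing[i, s]:
                    calls[i, s] = None
                else:
                    counts = self.dosage[i, s]
                    calls[i, s] = tuple(
                        idx for idx in range(4) for _ in range(counts[idx])
                    )
        loci = self.loci.copy()
        return LocusGenotypeTable(loci=loci, calls=calls, samples=list(self.samples))


def _locus_frame(n_loci: int) -> tuple[pd.DataFrame, np.ndarray]:
    per_chrom = -(-n_loci // 7)
    chroms = [f"Ro{i // per_chrom + 1:02d}" for i in range(n_loci)]
    pos = [10_000 + 137 * (i % per_chrom) for i in range(n_loci)]
    ids = [f"{c}:{p}" for c, p in zip(chroms, pos)]
    frame = pd.DataFrame(
        {"chrom": chroms, "pos": pos},
        index=pd.Index(ids, name="locus"),
    )
    return frame, np.asarray(pos)


def simulate_cohort(config: SimConfig) -> SimCohort:
    """Draw one cohort under ``config``.

    The phenotype of sample ``s`` in environment ``e`` is::

        baseline + env_effect(e) + group_shift(group(s))
        + sum(effect for planted alleles carried by s)
        + Normal(0, residual_sd)

    with sign-flipped contributions for structure-confounded alleles, and
    each replicate measurement adds ``Normal(0, replicate_sd)`` on top.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_loci
    ploidy = config.sample_ploidies()
    group = config.sample_groups()
    samples = [f"S{j + 1:03d}" for j in range(n)]

    # --- allele counts and per-group frequencies -------------------------
    n_alleles = rng.choice([2, 3, 4], size=m, p=list(config.allele_count_probs))
    planted = list(config.causal_alleles) + list(config.confounded_alleles)
    for locus, allele, _ in planted:
        n_alleles[locus] = max(n_alleles[locus], allele + 1, 2)

    freqs = np.zeros((m, config.n_groups, 4))
    for k in (2, 3, 4):
        sel = n_alleles == k
        if not sel.any():
            continue
        gamma = rng.gamma(
            config.group_divergence, size=(int(sel.sum()), config.n_groups, k)
        )
        gamma = np.maximum(gamma, 1e-12)
        freqs[sel, :, :k] = gamma / gamma.sum(axis=-1, keepdims=True)

    # planted loci: frequencies shared across groups, carrier fraction ~ 1/2
    mean_ploidy = float(ploidy.mean())
    f_causal = 1.0 - 0.5 ** (1.0 / mean_ploidy)
    for locus, allele, _ in planted:
        k = n_alleles[locus]
        shared = np.full(k, (1.0 - f_causal) / (k - 1))
        shared[allele] = f_causal
        freqs[locus, :, :k] = shared
        freqs[locus, :, k:] = 0.0

    # --- dosages: ploidy-many copies drawn from the group's frequencies --
    dosage = np.zeros((m, n, 4), dtype=np.int16)
    for g in range(config.n_groups):
        for p in np.unique(ploidy[group == g]):
            idx = np.flatnonzero((group == g) & (ploidy == p))
            for k in (2, 3, 4):
                sel = np.flatnonzero(n_alleles == k)
                if sel.size == 0:
                    continue
                pv = np.broadcast_to(
                    freqs[sel, g, :k], (idx.size, sel.size, k)
                )
                draws = rng.multinomial(int(p), pv)  # (n_idx, n_sel, k)
                dosage[np.ix_(sel, idx, np.arange(k))] = draws.transpose(1, 0, 2)

    # --- depth-driven missingness ----------------------------------------
    missing = rng.random((m, n)) < config.missing_rate
    lam = max(config.depth_mean - 1.0, 0.0)
    depth = 1 + rng.poisson(lam, size=(m, n))
    depth[missing] = 0

    # --- phenotypes -------------------------------------------------------
    shifts = (
        np.zeros(config.n_groups)
        if config.group_shifts is None
        else np.asarray(config.group_shifts, dtype=float)
    )
    genetic = np.full(n, config.baseline_ssc) + shifts[group]
    for locus, allele, effect in config.causal_alleles:
        genetic += effect * (dosage[locus, :, allele] > 0)
    sign = np.where(group == 0, 1.0, -1.0)
    for locus, allele, effect in config.confounded_alleles:
        carrier = (dosage[locus, :, allele] > 0).astype(float)
        # center within group: pure interaction, no group main effect
        for g in range(config.n_groups):
            in_g = group == g
            if in_g.any():
                carrier[in_g] -= carrier[in_g].mean()
        genetic += effect * sign * carrier

    envs = list(config.env_effects)
    offsets = np.asarray([config.env_effects[e] for e in envs], dtype=float)
    env_value = (
        genetic[:, None]
        + offsets[None, :]
        + rng.normal(0.0, config.residual_sd, size=(n, len(envs)))
    )
    reps = np.repeat(env_value[:, :, None], config.n_replicates, axis=2)
    if config.replicate_sd > 0:
        reps = reps + rng.normal(0.0, config.replicate_sd, size=reps.shape)

    pheno = pd.DataFrame(
        {
            "sample": np.repeat(samples, len(envs) * config.n_replicates),
            "environment": np.tile(
                np.repeat(envs, config.n_replicates), n
            ),
            "replicate": np.tile(
                np.arange(1, config.n_replicates + 1), n * len(envs)
            ),
            "ssc_brix": reps.reshape(-1),
        }
    )
    env_frame = pd.DataFrame(
        env_value, index=pd.Index(samples, name="sample"), columns=envs
    )

    loci, _ = _locus_frame(m)
    base_cycle = [
        tuple(_BASES[(i + r) % 4] for r in range(4)) for i in range(4)
    ]
    refs, alts = [], []
    for i in range(m):
        letters = base_cycle[i % 4]
        refs.append(letters[0])
        alts.append(tuple(letters[1 : n_alleles[i]]))
    loci["ref"] = refs
    loci["alts"] = alts

    truth_rows = []
    allele_names = lambda i: [loci["ref"].iloc[i], *loci["alts"].iloc[i]]
    for locus, allele, effect in config.causal_alleles:
        truth_rows.append(
            (loci.index[locus], allele_names(locus)[allele], effect, "independent")
        )
    for locus, allele, effect in config.confounded_alleles:
        truth_rows.append(
            (loci.index[locus], allele_names(locus)[allele], effect, "confounded")
        )
    truth = pd.DataFrame(
        truth_rows, columns=["locus", "allele", "effect_brix", "kind"]
    )

    return SimCohort(
        config=config,
        samples=samples,
        ploidy=ploidy,
        group=group,
        loci=loci,
        n_alleles=n_alleles,
        dosage=dosage,
        depth=depth,
        phenotypes=pheno,
        sample_env_value=env_frame,
        truth=truth,
    )


def write_cohort(cohort: SimCohort, out_dir) -> dict[str, str]:
    """Write the cohort as VCF 4.2 + TSV depth table + TSV phenotypes.

    Genotypes are unphased, ploidy-many slash-separated allele indices
    (``0/0/1/1`` for a 4x sample); zero-depth cells are fully missing
    (``./././.``). Returns the mapping of artifact name to path.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vcf_path = out / "cohort.vcf"
    depth_path = out / "depth.tsv"
    pheno_path = out / "phenotypes.tsv"

    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=polybrix-simulate\n")
        for chrom in pd.unique(cohort.loci["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.samples)
            + "\n"
        )
        miss = cohort.missing
        for i, (locus_id, row) in enumerate(cohort.loci.iterrows()):
            alt = ",".join(row["alts"]) if row["alts"] else "."
            fields = [
                row["chrom"], str(row["pos"]), ".", row["ref"], alt,
                ".", ".", ".", "GT",
            ]
            for s in range(len(cohort.samples)):
                p = cohort.ploidy[s]
                if miss[i, s]:
                    fields.append("/".join(["."] * p))
                else:
                    counts = cohort.dosage[i, s]
                    gt = [str(a) for a in range(4) for _ in range(counts[a])]
                    fields.append("/".join(gt))
            fh.write("\t".join(fields) + "\n")

    depth_long = pd.DataFrame(
        {
            "chrom": np.repeat(cohort.loci["chrom"].to_numpy(), len(cohort.samples)),
            "pos": np.repeat(cohort.loci["pos"].to_numpy(), len(cohort.samples)),
            "sample": np.tile(cohort.samples, len(cohort.loci)),
            "depth": cohort.depth.reshape(-1),
        }
    )
    depth_long.to_csv(depth_path, sep="\t", index=False)
    cohort.phenotypes.to_csv(pheno_path, sep="\t", index=False)
    return {
        "vcf": str(vcf_path),
        "depth": str(depth_path),
        "phenotypes": str(pheno_path),
    }
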