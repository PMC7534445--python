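"""One-command orchestration: simulate -> table -> associate -> validate -> report.

Every artifact a run writes carries the hash of the configuration that
produced it, so a run directory is self-describing and a rerun with the
same configuration is bit-identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, genotype, simulate, validation

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "summarize_run"]

_ALL_STAGES = ("simulate", "genotype", "associate", "validate", "report")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything a run needs; serializable and round-trippable via YAML."""

    stages: tuple[str, ...] = _ALL_STAGES
    seed: int = 0
    alpha: float = 0.05
    max_missing: float = 0.20
    min_alleles: int = 2
    max_alleles: int = 4
    min_class_size: int = 3
    structure: str = "infer"  # "infer" | "external"
    external_groups: dict | None = None  # sample -> group label
    k_min: int = 1
    k_max: int = 10
    pc_variance: float = 0.9
    n_starts: int = 50
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    vcf: str | None = None
    depth: str | None = None
    phenotypes: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.structure not in ("infer", "external"):
            raise ValueError("structure must be 'infer' or 'external'")
        if self.structure == "external" and self.external_groups is None:
            raise ValueError("external structure requires external_groups")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the enabled stages in order, writing artifacts to ``out_dir``.

    A stage failure raises :class:`PipelineError` naming the stage; outputs
    of completed stages are preserved.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.hash()
    config.to_yaml(out / "config.yaml")
    log_lines = [f"config_hash={h}"]
    stage = "setup"
    cohort = None
    vcf_path, depth_path, pheno_path = config.vcf, config.depth, config.phenotypes
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            sim_kwargs = dict(config.sim)
            sim_kwargs.setdefault("seed", config.seed)
            if "causal_alleles" in sim_kwargs:
                sim_kwargs["causal_alleles"] = [
                    simulate.CausalAllele(*c) for c in sim_kwargs["causal_alleles"]
                ]
            cfg = simulate.SimConfig(**sim_kwargs)
            cohort = simulate.simulate_cohort(cfg)
            paths = simulate.write_cohort(cohort, out / "cohort")
            vcf_path, depth_path, pheno_path = (
                paths["vcf"], paths["depth"], paths["phenotypes"],
            )
            log_lines.append(
                f"simulate: {cfg.n_samples} samples, {cfg.n_loci} loci"
            )

        table = None
        if "genotype" in config.stages:
            stage = "genotype"
            if vcf_path is None or depth_path is None:
                raise ValueError("genotype stage needs vcf and depth inputs")
            table = genotype.build_genotype_table(vcf_path)
            table = genotype.apply_depth_missingness(
                table, genotype.read_depth_table(depth_path)
            )
            genotype.write_genotype_table(table, out / "genotype_table.tsv")
            log_lines.append(f"genotype: {table.n_loci} loci decoded")

        records = None
        matrix = None
        pheno = None
        if "associate" in config.stages:
            stage = "associate"
            if table is None:
                raise ValueError("associate stage needs the genotype stage")
            if pheno_path is None:
                raise ValueError("associate stage needs phenotypes")
            pheno = pd.read_csv(pheno_path, sep="\t")
            filtered, fstats = association.filter_loci(
                table,
                max_missing=config.max_missing,
                min_alleles=config.min_alleles,
                max_alleles=config.max_alleles,
            )
            matrix = association.encode_presence_absence(filtered)
            ssc = pheno.groupby("sample")["ssc_brix"].mean()
            if config.structure == "external":
                groups = pd.Series(config.external_groups).reindex(matrix.index)
            else:
                grouping = association.infer_structure_groups(
                    matrix,
                    k_range=range(config.k_min, config.k_max + 1),
                    pc_variance=config.pc_variance,
                    n_starts=config.n_starts,
                    seed=config.seed,
                )
                groups = grouping.labels
            records = association.screen_alleles(
                matrix,
                ssc,
                groups,
                alpha=config.alpha,
                min_class_size=config.min_class_size,
            )
            flat = records.reset_index()
            flat.columns = ["locus", "allele", *records.columns]
            _write_tsv(flat, out / "association.tsv", h)
            _write_tsv(
                pd.DataFrame({"sample": matrix.index, "group": np.asarray(groups)}),
                out / "structure.tsv", h,
            )
            _write_tsv(
                pd.DataFrame(
                    [
                        ("loci_in", fstats.n_input),
                        ("removed_missing", fstats.n_removed_missing),
                        ("removed_allele_count", fstats.n_removed_allele_count),
                        ("loci_kept", fstats.n_kept),
                    ],
                    columns=["step", "count"],
                ),
                out / "filter_attrition.tsv", h,
            )
            log_lines.append(
                f"associate: {fstats.n_kept}/{fstats.n_input} loci kept, "
                f"{int(records['p'].notna().sum())} columns screened, "
                f"{int(records['screen_significant'].sum())} BH-significant, "
                f"{int(records['selected'].sum())} selected"
            )

        if "validate" in config.stages:
            stage = "validate"
            if records is None or matrix is None or pheno is None:
                raise ValueError("validate stage needs the associate stage")
            chosen = records.index[records["selected"]]
            if len(chosen):
                calls = matrix[chosen]
                calls.columns = [f"{l}|{a}" for l, a in calls.columns]
                result = validation.validate_per_environment(
                    calls, pheno,
                    alpha=config.alpha,
                    min_class_size=config.min_class_size,
                )
            else:
                result = pd.DataFrame(
                    columns=[
                        "marker", "environment", "n_present", "n_absent",
                        "effect_brix", "t", "df", "p", "q", "significant",
                    ]
                )
            _write_tsv(result, out / "validation.tsv", h)
            log_lines.append(
                f"validate: {result['significant'].sum() if len(result) else 0} "
                f"significant (marker, environment) pairs"
            )

        (out / "log.txt").write_text("\n".join(log_lines) + "\n")

        if "report" in config.stages:
            stage = "report"
            summarize_run(out)
    except PipelineError:
        raise
    except Exception as exc:  # preserve partial outputs, name the stage
        (out / "log.txt").write_text("\n".join(log_lines) + f"\nFAILED: {stage}\n")
        raise PipelineError(stage, exc) from exc
    return out


def _count_or_zero(path: Path, fn) -> tuple[int, bool]:
    if not path.exists():
        return 0, False
    try:
        return int(fn(_read_tsv(path))), True
    except Exception:
        return 0, False


def summarize_run(run_dir) -> pd.DataFrame:
    """Recount the attrition funnel from the stage TSVs and write the report.

    Counts are recomputed from the files (never copied from logs); stages
    whose outputs are absent are reported as such with zero counts. Writes
    ``funnel.tsv`` and ``report.md`` into the run directory and returns the
    funnel frame.
    """
    run_dir = Path(run_dir)
    cfg_path = run_dir / "config.yaml"
    h = RunConfig.from_yaml(cfg_path).hash() if cfg_path.exists() else "unknown"

    gt = run_dir / "genotype_table.tsv"
    assoc = run_dir / "association.tsv"
    val = run_dir / "validation.tsv"

    loci_in, has_gt = _count_or_zero(gt, len)
    after_filter, _ = _count_or_zero(assoc, lambda d: d["locus"].nunique())
    screened, _ = _count_or_zero(assoc, lambda d: d["p"].notna().sum())
    bh_sig, _ = _count_or_zero(
        assoc, lambda d: d["screen_significant"].astype(bool).sum()
    )
    selected, has_assoc = _count_or_zero(
        assoc, lambda d: d["selected"].astype(bool).sum()
    )
    validated, has_val = _count_or_zero(
        val,
        lambda d: d.loc[d["significant"].astype(bool), "marker"].nunique()
        if len(d) else 0,
    )

    funnel = pd.DataFrame(
        [
            ("loci_in", loci_in),
            ("after_filter", after_filter),
            ("columns_screened", screened),
            ("bh_significant", bh_sig),
            ("model_selected", selected),
            ("validated_markers", validated),
        ],
        columns=["stage", "count"],
    )
    _write_tsv(funnel, run_dir / "funnel.tsv", h)

    lines = [
        "# Run report",
        "",
        f"config hash: `{h}`",
        "",
        "## Attrition funnel",
        "",
        "```", funnel.to_string(index=False), "```",
        "",
    ]
    for name, present in [
        ("genotype_table.tsv", has_gt),
        ("association.tsv", has_assoc),
        ("validation.tsv", has_val),
    ]:
        if not present:
            lines.append(f"- stage output absent: `{name}`")
    if (run_dir / "structure.tsv").exists():
        groups = _read_tsv(run_dir / "structure.tsv")
        sizes = groups["group"].value_counts().sort_index()
        lines += [
            "",
            "## Population groups",
            "",
            "\n".join(f"- group {g}: {n} samples" for g, n in sizes.items()),
        ]
    if has_assoc:
        d = _read_tsv(assoc)
        sel = d[d["selected"].astype(bool)]
        if len(sel):
            lines += [
                "",
                "## Selected alleles",
                "",
                "```",
                sel[["locus", "allele", "effect_brix", "q", "p_within"]]
                .to_string(index=False),
                "```",
            ]
    (run_dir / "report.md").write_text("\n".join(lines) + "\n")
    return funnel
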