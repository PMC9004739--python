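"""In-process pipeline orchestration and the output folder hierarchy.

A run walks: read cleanup -> unique-read count table -> CPM normalization
-> rare-read filter -> identity annotation + artifact purge -> the keyed
output families, written under::

    <out>/
      totalCounts/{sRNA,miRNA}/          A_*, B_*, Int_seedKeyed*, C_*, D_*, E_*, F_*
      differential/<contrast>/{sRNA,miRNA}/   A_diff_*, B_*, ...

Each stage logs row counts in and out so the conservation ledger (reads in
-> filtered -> annotated -> collapsed) can be reconstructed from the log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from seedtox import counting
from seedtox.annotate import AnnotatedCountTable, ReferenceSet, annotate_table
from seedtox.counting import CountTable
from seedtox.differential import (
    ComparisonDesign,
    read_comparisons,
    select_differential,
    test_differential,
)
from seedtox.outputs import (
    bin_to_C,
    collapse_to_B,
    expand_to_D,
    expand_to_E,
    expand_to_F,
    mirna_content,
    write_output_A,
)
from seedtox.preprocess import TrimConfig, preprocess_file
from seedtox.seeds import SeedViabilityTable

logger = logging.getLogger("seedtox")

BRANCHES = ("sRNA", "miRNA")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    """A pipeline stage failed; completed outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything one run needs; validated up front."""

    output_dir: Path
    viability_tsv: Path
    mirna_fasta: Path
    rnaworld_fasta: Path
    input_kind: str = "fastq"  # or "count_table"
    fastq_files: dict[str, Path] = field(default_factory=dict)
    count_table: Path | None = None
    organism: str = "human"
    mode: str = "risc"  # or "total"
    branches: tuple[str, ...] = BRANCHES
    analyses: tuple[str, ...] = ("totalCounts",)
    comparisons: Path | None = None
    sample_groups: dict[str, str] = field(default_factory=dict)
    trim: TrimConfig = field(default_factory=TrimConfig)
    skip_trim: bool = False
    diff_mode: str = "padj"  # or "pvalue"
    dispersion_mode: str = "common"

    def validate(self) -> None:
        problems = []
        if self.input_kind not in ("fastq", "count_table"):
            problems.append(f"input_kind must be fastq/count_table, got {self.input_kind!r}")
        if self.input_kind == "fastq" and not self.fastq_files:
            problems.append("fastq input requires at least one sample file")
        if self.input_kind == "count_table" and self.count_table is None:
            problems.append("count_table input requires a table path")
        if self.organism not in ("human", "mouse"):
            problems.append(f"organism must be human/mouse, got {self.organism!r}")
        unknown = set(self.branches) - set(BRANCHES)
        if unknown:
            problems.append(f"unknown branches: {sorted(unknown)}")
        unknown = set(self.analyses) - {"totalCounts", "differential"}
        if unknown:
            problems.append(f"unknown analyses: {sorted(unknown)}")
        if "differential" in self.analyses and self.comparisons is None:
            problems.append("differential analysis requires a comparisons file")
        if problems:
            raise ConfigError("; ".join(problems))


def plan(config: PipelineConfig) -> str:
    """Human-readable, deterministic stage plan (commented script style)."""
    config.validate()
    lines = [
        "# seedtox pipeline plan",
        f"# organism={config.organism} mode={config.mode}",
        f"# output: {config.output_dir}",
    ]
    step = 0

    def add(text: str, comment: str) -> None:
        nonlocal step
        step += 1
        lines.append(f"# step {step}: {comment}")
        lines.append(text)

    if config.input_kind == "fastq":
        if not config.skip_trim:
            add(
                f"seedtox-trim --adapter3 {config.trim.three_prime_adapter} "
                f"--umi5 {config.trim.umi_length_5p}",
                "remove 5' adapters/UMI then truncate at the 3' adapter",
            )
        add(f"seedtox-length-filter --mode {config.mode}", "mode-dependent length window")
        add("seedtox-count", "tally unique reads per sample into the count table")
    else:
        add(f"seedtox-load-table {config.count_table}", "load pre-built count table")
        add(f"seedtox-length-filter --mode {config.mode}", "mode-dependent length window")
    add("seedtox-normalize --cpm", "normalize each sample column to 1e6 reads")
    add("seedtox-rare-filter", "drop reads with total normCount < n (n = sample count)")
    add(
        f"seedtox-annotate --mirna {config.mirna_fasta} --rnaworld {config.rnaworld_fasta} "
        f"--viability {config.viability_tsv}",
        "assign identities, purge artifact hits, attach seed + viability",
    )
    for analysis in config.analyses:
        for branch in config.branches:
            add(
                f"seedtox-outputs --analysis {analysis} --branch {branch}",
                f"write A/B/Int_seedKeyed/C/D/E/F under {analysis}/{branch}",
            )
    return "\n".join(lines) + "\n"


@dataclass
class PipelineResult:
    """Handles on everything a run produced."""

    config: PipelineConfig
    annotated: AnnotatedCountTable
    artifacts: pd.DataFrame
    prefilter: CountTable
    removed: CountTable
    mirna_percent: pd.Series
    files: list[Path]
    differential: dict[str, AnnotatedCountTable] = field(default_factory=dict)


def _load_counts(config: PipelineConfig) -> CountTable:
    if config.input_kind == "fastq":
        per_sample = {
            sample: list(preprocess_file(path, config.trim, skip_trim=config.skip_trim))
            for sample, path in config.fastq_files.items()
        }
        for sample, reads in per_sample.items():
            logger.info("sample %s: %d reads after cleanup", sample, len(reads))
        return counting.build_count_table(per_sample)
    table = CountTable.from_tsv(config.count_table)
    from seedtox.preprocess import length_filter  # applied to table rows too

    keep = set(length_filter(list(table.raw.index), config.trim))
    kept = table.raw.loc[[s in keep for s in table.raw.index]]
    logger.info("count table: %d of %d rows pass the length window", len(kept), len(table))
    return CountTable(raw=kept)


def _write_branch_outputs(
    annotated: AnnotatedCountTable,
    directory: Path,
    viability: SeedViabilityTable,
    groups: dict[str, list[str]] | None,
    use_delta: bool,
    files: list[Path],
    flavor_tag: str = "",
) -> None:
    b, seed_keyed = collapse_to_B(annotated, use_delta=use_delta)
    directory.mkdir(parents=True, exist_ok=True)
    tag = f"_{flavor_tag}" if flavor_tag else ""
    for name, df in (("B_collapsed", b), ("Int_seedKeyed", seed_keyed)):
        path = directory / f"{name}{tag}.txt"
        df.to_csv(path, sep="\t", index=False)
        files.append(path)
    c = bin_to_C(b, viability.bin_range)
    path = directory / f"C_binned{tag}.txt"
    c.to_csv(path, sep="\t", index=False)
    files.append(path)
    for maker, prefix in ((expand_to_D, "D_toxAnalysis"), (expand_to_E, "E_seedAnalysis"), (expand_to_F, "F_seedExpand")):
        if use_delta or groups is None:
            expanded = maker(b, per="replicate")
            scope = "rep"
        else:
            expanded = maker(b, per="avg", groups=groups)
            scope = "avg"
        path = directory / f"{prefix}_{scope}{tag}.txt"
        expanded.to_csv(path, sep="\t", index=False)
        files.append(path)
    logger.info(
        "%s: B=%d rows, seedKeyed=%d rows, C bins=%d", directory, len(b), len(seed_keyed), len(c)
    )


def run(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline; see module docstring for the layout."""
    config.validate()
    viability = SeedViabilityTable.from_tsv(config.viability_tsv, species=config.organism)
    mirna_refs = ReferenceSet.from_fasta(config.mirna_fasta, "mirna")
    rnaworld_refs = ReferenceSet.from_fasta(config.rnaworld_fasta, "rnaworld")
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    stage = "counting"
    try:
        table = _load_counts(config)
        logger.info("count table: %d unique reads x %d samples", len(table), table.n_samples)
        stage = "normalize"
        table = counting.normalize_cpm(table)
        path = out_root / "Int_allReads.txt"
        table.to_tsv(path)
        files.append(path)
        stage = "rare-filter"
        kept, removed = counting.filter_rare_reads(table)
        logger.info("rare-read filter: kept %d, removed %d rows", len(kept), len(removed))
        stage = "annotate"
        annotated, artifacts = annotate_table(kept, mirna_refs, rnaworld_refs, viability)
        logger.info(
            "annotation: %d rows kept, %d artifact rows purged", len(annotated.ann), len(artifacts)
        )
        mirna_pct = mirna_content(annotated)
    except Exception as exc:  # noqa: BLE001 - rewrap with the failing stage
        raise StageError(stage, exc) from exc

    groups = None
    if config.sample_groups:
        groups = {}
        for sample, gname in config.sample_groups.items():
            groups.setdefault(gname, []).append(sample)

    result = PipelineResult(
        config=config,
        annotated=annotated,
        artifacts=artifacts,
        prefilter=table,
        removed=removed,
        mirna_percent=mirna_pct,
        files=files,
    )

    if "totalCounts" in config.analyses:
        for branch in config.branches:
            stage = f"totalCounts/{branch}"
            try:
                subset = annotated if branch == "sRNA" else annotated.mirna_only()
                directory = out_root / "totalCounts" / branch
                directory.mkdir(parents=True, exist_ok=True)
                files.append(write_output_A(subset, "rawCounts", directory))
                files.append(write_output_A(subset, "normCounts", directory))
                _write_branch_outputs(subset, directory, viability, groups, False, files)
            except Exception as exc:  # noqa: BLE001
                raise StageError(stage, exc) from exc

    if "differential" in config.analyses:
        designs = read_comparisons(config.comparisons)
        for design in designs:
            stage = f"differential/{design.name}"
            try:
                tested = test_differential(annotated, design, config.dispersion_mode)
                selected = select_differential(tested, mode=config.diff_mode)
                result.differential[design.name] = selected
                for branch in config.branches:
                    subset = selected if branch == "sRNA" else selected.mirna_only()
                    directory = out_root / "differential" / design.name / branch
                    directory.mkdir(parents=True, exist_ok=True)
                    stats_cols = tested.table.columns.difference(subset.ann.columns)
                    frame = subset.ann.join(tested.table.loc[subset.ann.index, stats_cols])
                    path = directory / f"A_diff_{design.name}.txt"
                    frame.to_csv(path, sep="\t", index_label="sequence")
                    files.append(path)
                    _write_branch_outputs(
                        subset, directory, viability, None, True, files, flavor_tag=design.name
                    )
            except Exception as exc:  # noqa: BLE001
                raise StageError(stage, exc) from exc

    return result


def make_design(name: str, coding: dict[str, int]) -> ComparisonDesign:
    """Convenience re-export for API users."""
    return ComparisonDesign(name, coding)


__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "ConfigError",
    "StageError",
    "plan",
    "run",
    "read_comparisons",
    "make_design",
]
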