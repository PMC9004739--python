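"""Synthetic fixtures with known ground truth for every pipeline stage.

Generates reference FASTA sets (mature-miRNA-like and small-RNA-catalog
sequences, optionally including artifact-named entries), a complete
4096-seed viability resource whose toxicity gradient follows G/C content
(G-rich seeds are the most toxic), and per-sample FASTQ read sets with
group-dependent seed-composition shifts and negative-binomial count noise.
Everything is driven by one seeded generator so fixtures are byte
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from seedtox.preprocess import DEFAULT_ADAPTER3
from seedtox.seeds import SEED_SPACE_SIZE, SeedViabilityTable, enumerate_seed_space, extract_seed


@dataclass
class GroupSpec:
    """Per-group simulation knobs."""

    name: str
    n_samples: int = 3
    mirna_fraction: float = 0.7
    #: multiplicative enrichment of reads whose seed carries G at the
    #: planted positions (1-based); 1.0 = no shift
    g_enrichment: float = 1.0
    planted_positions: tuple[int, ...] = (1, 2, 3)


@dataclass
class SimulationSpec:
    """Complete recipe for one synthetic dataset."""

    seed: int = 0
    groups: list[GroupSpec] = field(
        default_factory=lambda: [GroupSpec("control"), GroupSpec("disease")]
    )
    n_mirna: int = 40
    n_rnaworld: int = 60
    n_artifact: int = 3
    library_size: int = 50_000
    nb_dispersion: float = 0.05
    n_expressed: int = 300  # distinct reads drawn per group's pool
    read_length_range: tuple[int, int] = (18, 25)
    adapter3: str = DEFAULT_ADAPTER3
    umi_length: int = 0
    #: fraction of pool reads planted as differential (log2FC +2 in the
    #: last group) when > 0
    diff_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library size must be positive")
        for g in self.groups:
            if not 0 <= g.mirna_fraction <= 1:
                raise ValueError("mirna_fraction must be in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


ARTIFACT_NAME_TEMPLATES = (
    "Tuschl_spikein_{i}",
    "linker-artifical-{i}",
    "adapter_dimer_{i}",
    "size_marker_{i}",
    "artificial_construct_{i}",
)


def _random_seq(rng: np.random.Generator, length: int, p: np.ndarray | None = None) -> str:
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def make_references(spec: SimulationSpec) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Deterministic (miRNA, RNA-world) reference entry lists.

    RNA-world entries include the miRNA sequences embedded in longer
    precursors (so miRNA reads also receive a catalog hit) plus independent
    fragment-like entries and, if requested, artifact-named entries.
    """
    rng = np.random.default_rng(spec.seed + 1)
    mirna = [
        (f"syn-mir-{i + 1}", _random_seq(rng, int(rng.integers(20, 23))))
        for i in range(spec.n_mirna)
    ]
    rnaworld = []
    for i, (name, seq) in enumerate(mirna):
        pad5 = _random_seq(rng, int(rng.integers(5, 15)))
        pad3 = _random_seq(rng, int(rng.integers(5, 15)))
        rnaworld.append((f"precursor_{name}", pad5 + seq + pad3))
    kinds = ("tRNA-fragment", "rRNA-fragment", "snoRNA", "yRNA")
    for i in range(spec.n_rnaworld):
        kind = kinds[i % len(kinds)]
        rnaworld.append(
            (f"{kind}_{i + 1}", _random_seq(rng, int(rng.integers(30, 80))))
        )
    for i in range(spec.n_artifact):
        template = ARTIFACT_NAME_TEMPLATES[i % len(ARTIFACT_NAME_TEMPLATES)]
        rnaworld.append(
            (template.format(i=i + 1), _random_seq(rng, int(rng.integers(18, 40))))
        )
    return mirna, rnaworld


def write_fasta(entries: list[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n{seq}\n")
    return path


def make_viability_table(
    spec: SimulationSpec, species: str = "human", n_lines: int = 3
) -> SeedViabilityTable:
    """Complete synthetic viability resource with a G/C toxicity gradient.

    Per-cell-line viability = 100 - 14 x (#G) - 9 x (#C) + noise, clipped at
    0; the consensus toxic seed GGGGGC lands in the lowest decile by
    construction, mimicking the published gradient.
    """
    rng = np.random.default_rng(spec.seed + 2)
    seeds = enumerate_seed_space()
    n_g = np.array([s.count("G") for s in seeds], dtype=float)
    n_c = np.array([s.count("C") for s in seeds], dtype=float)
    base = 100.0 - 14.0 * n_g - 9.0 * n_c
    data = {
        f"{species}_line{i + 1}": np.clip(base + rng.normal(0, 2, SEED_SPACE_SIZE), 0, None)
        for i in range(n_lines)
    }
    per_line = pd.DataFrame(data, index=pd.Index(seeds, name="seed"))
    return SeedViabilityTable(species=species, per_line=per_line)


@dataclass
class SimulatedDataset:
    """Reads plus ground truth for one simulation."""

    spec: SimulationSpec
    reads: dict[str, list[str]]  # sample -> decorated read sequences
    truth: pd.DataFrame  # read, source, kind, seed, group weights
    sample_groups: dict[str, str]

    def write_fastq(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for sample, seqs in self.reads.items():
            path = directory / f"{sample}.fastq"
            with open(path, "w") as fh:
                for i, seq in enumerate(seqs):
                    fh.write(f"@{sample}_read{i}\n{seq}\n+\n{'I' * len(seq)}\n")
            paths[sample] = path
        return paths


def _read_pool(
    spec: SimulationSpec,
    mirna: list[tuple[str, str]],
    rnaworld: list[tuple[str, str]],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Candidate insert sequences drawn from the references."""
    lo, hi = spec.read_length_range
    rows = []
    for name, seq in mirna:
        insert = seq[: min(len(seq), hi)]
        if len(insert) >= lo:
            rows.append({"read": insert, "source": name, "kind": "mirna"})
    fragments = [(n, s) for n, s in rnaworld if not n.startswith("precursor_")]
    for name, seq in fragments:
        if len(seq) < lo:
            continue
        length = int(rng.integers(lo, min(hi, len(seq)) + 1))
        start = int(rng.integers(0, len(seq) - length + 1))
        rows.append({"read": seq[start : start + length], "source": name, "kind": "rnaworld"})
    pool = pd.DataFrame(rows).drop_duplicates(subset="read").reset_index(drop=True)
    pool["seed"] = [extract_seed(r) for r in pool["read"]]
    return pool


def simulate_reads(spec: SimulationSpec) -> SimulatedDataset:
    """Per-sample read lists with planted group effects and NB noise.

    Group composition shifts are realized by re-weighting pool reads whose
    seed carries G at the group's planted positions by ``g_enrichment``.
    Reads are decorated with the 3' adapter (plus a random tail) and an
    optional 5' UMI so the trimming stage has real work to do.
    """
    rng = spec.rng()
    mirna, rnaworld = make_references(spec)
    pool = _read_pool(spec, mirna, rnaworld, rng)
    is_mirna = (pool["kind"] == "mirna").to_numpy()

    n_diff = int(spec.diff_fraction * len(pool))
    diff_idx = rng.choice(len(pool), size=n_diff, replace=False) if n_diff else np.array([], int)
    pool["diff_up"] = False
    pool.loc[diff_idx, "diff_up"] = True

    reads: dict[str, list[str]] = {}
    sample_groups: dict[str, str] = {}
    for g_i, group in enumerate(spec.groups):
        weights = np.where(is_mirna, group.mirna_fraction, 1 - group.mirna_fraction)
        g_hits = np.array(
            [
                sum(seed[p - 1] == "G" for p in group.planted_positions)
                for seed in pool["seed"]
            ],
            dtype=float,
        )
        weights = weights * group.g_enrichment ** g_hits
        if group.name == spec.groups[-1].name and n_diff:
            weights = weights * np.where(pool["diff_up"], 4.0, 1.0)  # log2FC = 2
        mean_counts = weights / weights.sum() * spec.library_size
        for rep in range(group.n_samples):
            sample = f"{group.name}_{rep + 1}"
            sample_groups[sample] = group.name
            if spec.nb_dispersion > 0:
                r = 1.0 / spec.nb_dispersion
                counts = rng.negative_binomial(r, r / (r + mean_counts))
            else:
                counts = rng.poisson(mean_counts)
            seqs = np.repeat(pool["read"].to_numpy(), counts)
            rng.shuffle(seqs)
            decorated = [
                _random_seq(rng, spec.umi_length)
                + s
                + spec.adapter3
                + _random_seq(rng, 5)
                for s in seqs
            ]
            reads[sample] = decorated
    return SimulatedDataset(spec=spec, reads=reads, truth=pool, sample_groups=sample_groups)
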