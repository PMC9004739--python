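"""Core value types: reads, 6mer seeds, and the seed-viability lookup.

A "6mer seed" is the substring at 1-based positions 2-7 of a small RNA read,
reported in the RNA alphabet (A/C/G/U).  Reads themselves stay in the DNA
alphabet as sequenced; the T->U transliteration happens exactly once, inside
:func:`extract_seed`.

Seed viability is the % cell viability measured after transfecting cells
with an siRNA carrying a given seed; low viability means a toxic seed.  The
lookup resource maps every one of the 4096 possible seeds to per-cell-line
viability values; downstream stages use the per-species average.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

RNA_ALPHABET = ("A", "C", "G", "U")
DNA_ALPHABET = ("A", "C", "G", "T")
SEED_LENGTH = 6
SEED_SPACE_SIZE = 4 ** SEED_LENGTH  # 4096
#: 1-based, inclusive read positions the seed is taken from.
SEED_START, SEED_END = 2, 7

Seed6 = str  # 6-letter string over {A, C, G, U}


class SeedError(ValueError):
    """Raised for malformed reads, seeds, or viability resources."""


def validate_read(bases: str) -> str:
    """Check that *bases* is a non-empty DNA string; return it unchanged."""
    if not bases:
        raise SeedError("empty read sequence")
    if any(b not in DNA_ALPHABET for b in bases):
        raise SeedError(f"read contains non-ACGT characters: {bases!r}")
    return bases


def validate_seed(bases: str) -> Seed6:
    """Check that *bases* is a valid 6-letter RNA seed; return it unchanged."""
    if len(bases) != SEED_LENGTH:
        raise SeedError(f"seed must be exactly {SEED_LENGTH} nt, got {bases!r}")
    if any(b not in RNA_ALPHABET for b in bases):
        raise SeedError(f"seed contains non-ACGU characters: {bases!r}")
    return bases


def extract_seed(read: str) -> Seed6:
    """Return the 6mer seed (positions 2-7, 5'->3') of *read*, as RNA.

    Parameters
    ----------
    read
        DNA read sequence, at least 7 nt long.

    Raises
    ------
    SeedError
        If the read is shorter than 7 nt (no position 7 exists; the caller
        should have length-filtered).
    """
    if len(read) < SEED_END:
        raise SeedError(
            f"read {read!r} is {len(read)} nt; need >= {SEED_END} nt to extract a seed"
        )
    return read[SEED_START - 1 : SEED_END].replace("T", "U")


def enumerate_seed_space() -> list[Seed6]:
    """All 4096 possible 6mer seeds, lexicographic in A<C<G<U order."""
    return ["".join(p) for p in itertools.product(RNA_ALPHABET, repeat=SEED_LENGTH)]


@dataclass
class SeedViabilityTable:
    """Complete map from every 6mer seed to % viability.

    Attributes
    ----------
    species
        ``"human"`` or ``"mouse"``; selects which resource was loaded.
    per_line
        DataFrame indexed by seed, one column per cell line, values in
        percent viability.  Values above 100 are legal (growth stimulation).
    averaged
        Series indexed by seed: arithmetic mean over the cell lines.
    """

    species: str
    per_line: pd.DataFrame
    averaged: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        seeds = self.per_line.index
        if len(seeds) != SEED_SPACE_SIZE or seeds.has_duplicates:
            raise SeedError(
                f"viability table must contain all {SEED_SPACE_SIZE} seeds exactly "
                f"once, got {len(seeds)} rows ({seeds.nunique()} distinct)"
            )
        for s in seeds:
            validate_seed(s)
        if (self.per_line.to_numpy() < 0).any():
            raise SeedError("negative viability value in resource table")
        self.averaged = self.per_line.mean(axis=1)

    def lookup(self, seed: Seed6) -> float:
        """Species-averaged % viability for *seed*."""
        try:
            return float(self.averaged.loc[seed])
        except KeyError:
            raise SeedError(f"seed {seed!r} missing from viability table") from None

    def annotate(self, seeds: pd.Series | list[Seed6]) -> pd.Series:
        """Vectorised lookup; raises on any unknown seed."""
        seeds = pd.Series(seeds)
        out = self.averaged.reindex(seeds)
        if out.isna().any():
            bad = seeds[out.isna().to_numpy()].iloc[0]
            raise SeedError(f"seed {bad!r} missing from viability table")
        out.index = seeds.index
        return out

    @property
    def bin_range(self) -> tuple[int, int]:
        """[floor(min), ceil(max)] of the averaged viability, for 1% binning."""
        return (
            int(np.floor(self.averaged.min())),
            int(np.ceil(self.averaged.max())),
        )

    @classmethod
    def from_tsv(cls, path: str | Path, species: str = "human") -> "SeedViabilityTable":
        """Load a resource TSV with header ``seed<TAB>cellline1<TAB>...``."""
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        df = df.set_index(df.columns[0])
        df.index.name = "seed"
        return cls(species=species, per_line=df.astype(float))

    def to_tsv(self, path: str | Path) -> None:
        self.per_line.to_csv(path, sep="\t")
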