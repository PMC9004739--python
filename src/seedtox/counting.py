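"""Unique-read count table: construction, CPM normalization, rare-read filter.

The count table has one row per distinct read sequence observed in any
sample and one column per sample.  Normalization is counts-per-million per
column.  The rare-read filter deletes reads whose total normalized count
(summed over samples) is below n, the number of samples -- these are mostly
sequencing errors.  The unfiltered table is persisted as ``Int_allReads``
so users can rerun without the threshold.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

CPM_SCALE = 1_000_000


@dataclass
class CountTable:
    """Unique read sequences x samples.

    ``raw`` holds integer counts indexed by sequence; ``norm`` holds the CPM
    normalization of ``raw`` (None until :func:`normalize_cpm` is applied).
    """

    raw: pd.DataFrame
    norm: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.raw.index.has_duplicates:
            raise ValueError("count table row sequences must be unique")
        if (self.raw.to_numpy() < 0).any():
            raise ValueError("negative raw count")

    @property
    def samples(self) -> list[str]:
        return list(self.raw.columns)

    @property
    def n_samples(self) -> int:
        return len(self.raw.columns)

    def __len__(self) -> int:
        return len(self.raw)

    def to_tsv(self, path: str | Path, normalized: bool = False) -> None:
        df = self.norm if normalized else self.raw
        if df is None:
            raise ValueError("table not normalized yet")
        df.to_csv(path, sep="\t", index_label="sequence")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        """Read the entry-point TSV dialect: ``sequence`` column then samples."""
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        df = df.set_index(df.columns[0])
        df.index.name = "sequence"
        return cls(raw=df.astype(int))


def build_count_table(per_sample_reads: Mapping[str, Iterable[str]]) -> CountTable:
    """Tally per-sample read multiplicities into a :class:`CountTable`.

    Rows are sorted by descending total count, ties broken lexicographically
    by sequence, so the table is deterministic and human-scannable.
    """
    if not per_sample_reads:
        raise ValueError("at least one sample is required")
    counters = {sample: Counter(reads) for sample, reads in per_sample_reads.items()}
    df = pd.DataFrame(counters).fillna(0).astype(int)
    df = df.reindex(columns=list(per_sample_reads))
    df.index.name = "sequence"
    total = df.sum(axis=1)
    order = sorted(df.index, key=lambda s: (-total.loc[s], s))
    return CountTable(raw=df.loc[order])


def normalize_cpm(table: CountTable) -> CountTable:
    """Attach CPM normalization: each column rescaled to sum to 1e6.

    All-zero columns stay all-zero rather than dividing by zero.
    """
    colsum = table.raw.sum(axis=0)
    scale = colsum.where(colsum > 0, 1)
    norm = table.raw / scale * CPM_SCALE
    return CountTable(raw=table.raw, norm=norm)


def filter_rare_reads(table: CountTable) -> tuple[CountTable, CountTable]:
    """Partition rows by the rare-read rule: total CPM across samples >= n keeps.

    Returns ``(kept, removed)``.  The kept table is re-normalized so its CPM
    columns again sum to 1e6 (final outputs are described per million reads
    of the retained pool); the removed table carries the pre-filter norm.
    """
    if table.norm is None:
        raise ValueError("normalize_cpm must run before the rare-read filter")
    n = table.n_samples
    keep = table.norm.sum(axis=1) >= n
    kept = normalize_cpm(CountTable(raw=table.raw.loc[keep]))
    removed = CountTable(raw=table.raw.loc[~keep], norm=table.norm.loc[~keep])
    return kept, removed
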