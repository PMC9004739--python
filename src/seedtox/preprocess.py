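"""Read cleanup: 5'/3' adapter removal, UMI stripping, length filtering.

Adapter matching is exact-substring (no error tolerance): 5' adapters are
removed as prefixes, then everything from the first occurrence of the 3'
adapter onward is dropped.  Users with non-standard libraries can pre-trim
externally and run with trimming skipped.

Two length-filter modes exist:

* ``risc``  -- RISC-bound libraries: keep reads > 6 nt (so a seed at
  positions 2-7 is extractable).
* ``total`` -- total small-RNA libraries: keep 18-25 nt reads only.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from seedtox.seeds import SEED_END

#: Default 3' adapter substring removed from library reads.
DEFAULT_ADAPTER3 = "TCCGACGATC"

TOTAL_MIN_LEN, TOTAL_MAX_LEN = 18, 25
RISC_MIN_LEN = SEED_END  # > 6 nt, i.e. >= 7


@dataclass
class TrimConfig:
    """Trimming and length-filter settings for one run."""

    five_prime_adapters: list[str] = field(default_factory=list)
    three_prime_adapter: str = DEFAULT_ADAPTER3
    umi_length_5p: int = 0
    mode: str = "risc"  # or "total"

    def __post_init__(self) -> None:
        if self.mode not in ("risc", "total"):
            raise ValueError(f"mode must be 'risc' or 'total', got {self.mode!r}")
        if self.umi_length_5p < 0:
            raise ValueError("umi_length_5p must be >= 0")
        if not self.three_prime_adapter:
            raise ValueError("three_prime_adapter must be non-empty")


def trim_read(read: str, cfg: TrimConfig) -> str:
    """Strip UMI, 5' adapter prefix, and 3' adapter suffix from *read*.

    Steps, in order: (1) drop the first ``umi_length_5p`` bases; (2) drop any
    configured 5' adapter found as an exact prefix (longest match wins);
    (3) truncate at the first exact occurrence of the 3' adapter.  An empty
    result is legal; the length filter removes it downstream.
    """
    read = read[cfg.umi_length_5p :]
    for adapter in sorted(cfg.five_prime_adapters, key=len, reverse=True):
        if adapter and read.startswith(adapter):
            read = read[len(adapter) :]
            break
    pos = read.find(cfg.three_prime_adapter)
    if pos >= 0:
        read = read[:pos]
    return read


def length_filter(reads: Iterable[str], cfg: TrimConfig) -> Iterator[str]:
    """Yield reads passing the mode-dependent length window, order preserved."""
    if cfg.mode == "total":
        lo, hi = TOTAL_MIN_LEN, TOTAL_MAX_LEN
    else:
        lo, hi = RISC_MIN_LEN, None
    for read in reads:
        if len(read) >= lo and (hi is None or len(read) <= hi):
            yield read


def load_reads(path: str | Path, drop_ambiguous: bool = True) -> Iterator[str]:
    """Stream read sequences from a FASTQ/FASTA file (optionally gzipped).

    Reads containing characters outside A/C/G/T (e.g. N calls) are dropped
    when *drop_ambiguous* is set; downstream stages require a clean alphabet.
    """
    path = Path(path)
    fmt = _guess_format(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, fmt):
            seq = str(record.seq).upper()
            if drop_ambiguous and any(b not in "ACGT" for b in seq):
                continue
            yield seq


def _guess_format(path: Path) -> str:
    name = path.name[: -len(".gz")] if path.name.endswith(".gz") else path.name
    suffix = Path(name).suffix.lower()
    if suffix in (".fq", ".fastq"):
        return "fastq"
    if suffix in (".fa", ".fasta", ".fna"):
        return "fasta"
    raise ValueError(f"cannot guess FASTA/FASTQ format from file name {path.name!r}")


def preprocess_file(
    path: str | Path, cfg: TrimConfig, skip_trim: bool = False
) -> Iterator[str]:
    """Load, trim (unless *skip_trim*), and length-filter one sample file."""
    reads = load_reads(path)
    if not skip_trim:
        reads = (trim_read(r, cfg) for r in reads)
    return length_filter(reads, cfg)
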