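"""Read identity assignment against miRNA and RNA-world references.

Two ungapped identity criteria are used:

* miRNA: a read is assigned to a mature miRNA if the two share an exact
  (ungapped) common substring of at least 18 nt.
* RNA world: the full read is slid along each catalog sequence without
  gaps; a hit requires >= 95% identity over the read length (mismatches
  only).

Reads whose RNA-world assignment names an artificial sequence (spike-ins,
markers, adapters) are purged before any downstream analysis.  The purge is
a case-sensitive keyword test; the misspelled keyword "artifical" is kept
deliberately because catalog entries carry it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from seedtox.counting import CountTable, normalize_cpm
from seedtox.seeds import SeedViabilityTable, extract_seed

#: RNA-world assignment names containing any of these substrings are purged.
ARTIFACT_KEYWORDS = ("Tuschl", "artifical", "marker", "adapter", "artificial")

MIRNA_MIN_IDENTITY_NT = 18
RNAWORLD_MIN_IDENTITY = 0.95
UNKNOWN_NAME = "unknown"


@dataclass
class ReferenceSet:
    """Named reference sequences of one kind (``mirna`` or ``rnaworld``)."""

    kind: str
    entries: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.kind not in ("mirna", "rnaworld"):
            raise ValueError(f"unknown reference kind {self.kind!r}")
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("reference names must be unique within a set")
        if any(not s for _, s in self.entries):
            raise ValueError("empty reference sequence")

    @classmethod
    def from_fasta(cls, path: str | Path, kind: str) -> "ReferenceSet":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"reference FASTA not found: {path}")
        entries = [
            (rec.id, str(rec.seq).upper().replace("U", "T"))
            for rec in SeqIO.parse(str(path), "fasta")
        ]
        return cls(kind=kind, entries=entries)


def longest_common_run(a: str, b: str) -> tuple[int, int]:
    """Length and earliest a-start of the longest exact ungapped common
    substring of *a* and *b* (dynamic programming; used for miRNA identity)."""
    best_len, best_start = 0, 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        ai = a[i - 1]
        for j in range(1, len(b) + 1):
            if ai == b[j - 1]:
                run = prev[j - 1] + 1
                cur[j] = run
                start = i - run
                if run > best_len or (run == best_len and start < best_start):
                    best_len, best_start = run, start
        prev = cur
    return best_len, best_start


class _MirnaMatcher:
    """18-mer index accelerating the >=18 nt shared-substring search."""

    def __init__(self, refs: ReferenceSet):
        if refs.kind != "mirna":
            raise ValueError("expected a mirna reference set")
        self.refs = refs
        self._index: dict[str, set[int]] = {}
        for ri, (_, seq) in enumerate(refs.entries):
            for p in range(len(seq) - MIRNA_MIN_IDENTITY_NT + 1):
                kmer = seq[p : p + MIRNA_MIN_IDENTITY_NT]
                self._index.setdefault(kmer, set()).add(ri)

    def match(self, read: str) -> str | None:
        candidates: set[int] = set()
        for p in range(len(read) - MIRNA_MIN_IDENTITY_NT + 1):
            candidates |= self._index.get(read[p : p + MIRNA_MIN_IDENTITY_NT], set())
        best: tuple[int, int, str] | None = None
        for ri in candidates:
            name, seq = self.refs.entries[ri]
            run, start = longest_common_run(read, seq)
            if run < MIRNA_MIN_IDENTITY_NT:
                continue  # index hit was on the ref's k-mer set; recheck anyway
            key = (-run, start, name)
            if best is None or key < best:
                best = key
        return best[2] if best else None


def match_mirna(read: str, refs: ReferenceSet) -> str | None:
    """Best miRNA assignment for *read*, or None below the 18 nt threshold.

    Ties among references: longest shared substring, then earliest match
    start on the read, then lexicographic name.
    """
    return _MirnaMatcher(refs).match(read)


class _RnaWorldMatcher:
    """Vectorised sliding full-read alignment over a concatenated catalog."""

    _CODE = {"A": 1, "C": 2, "G": 3, "T": 4}

    def __init__(self, refs: ReferenceSet):
        if refs.kind != "rnaworld":
            raise ValueError("expected an rnaworld reference set")
        self.refs = refs
        chunks, owner, starts = [], [], []
        pos = 0
        for ri, (_, seq) in enumerate(refs.entries):
            arr = np.array([self._CODE[b] for b in seq], dtype=np.int8)
            chunks.append(arr)
            chunks.append(np.zeros(1, dtype=np.int8))  # sentinel: matches nothing
            owner.append(np.full(len(seq) + 1, ri, dtype=np.int32))
            starts.append(np.arange(len(seq) + 1, dtype=np.int32))
            pos += len(seq) + 1
        self._cat = np.concatenate(chunks) if chunks else np.zeros(0, dtype=np.int8)
        self._owner = np.concatenate(owner) if owner else np.zeros(0, dtype=np.int32)
        self._start = np.concatenate(starts) if starts else np.zeros(0, dtype=np.int32)

    def match(self, read: str) -> str | None:
        L = len(read)
        if L == 0 or L > len(self._cat):
            return None
        need = math.ceil(RNAWORLD_MIN_IDENTITY * L)
        query = np.array([self._CODE[b] for b in read], dtype=np.int8)
        windows = np.lib.stride_tricks.sliding_window_view(self._cat, L)
        matches = (windows == query).sum(axis=1)
        hits = np.nonzero(matches >= need)[0]
        # windows crossing a sentinel can never reach 95% only if the
        # sentinel mismatch pushes them under the threshold; verify ownership.
        best: tuple[float, str, int] | None = None
        for w in hits:
            ri = self._owner[w]
            if self._start[w] + L > len(self.refs.entries[ri][1]):
                continue  # window spills past this reference into the next
            ident = matches[w] / L
            name = self.refs.entries[ri][0]
            key = (-ident, name, int(self._start[w]))
            if best is None or key < best:
                best = key
        return best[1] if best else None


def match_rnaworld(read: str, refs: ReferenceSet) -> str | None:
    """Best RNA-world assignment for *read* at >= 95% ungapped identity."""
    return _RnaWorldMatcher(refs).match(read)


def purge_artifacts(name: str | None) -> bool:
    """True iff the RNA-world assignment names an artificial sequence."""
    if name is None:
        return False
    return any(kw in name for kw in ARTIFACT_KEYWORDS)


@dataclass
class AnnotatedCountTable:
    """Count table plus per-read annotations (Output A contents).

    ``ann`` is indexed like the count table and carries columns ``seed``,
    ``viability``, ``miRNA``, ``RNAworld``, ``name``; ``counts`` holds the
    raw and CPM matrices of the retained (non-artifact) rows.
    """

    ann: pd.DataFrame
    counts: CountTable

    @property
    def samples(self) -> list[str]:
        return self.counts.samples

    def frame(self, which: str = "norm") -> pd.DataFrame:
        """Annotations joined with counts (``which`` in raw/norm)."""
        values = self.counts.norm if which == "norm" else self.counts.raw
        if values is None:
            raise ValueError("counts not normalized")
        return self.ann.join(values)

    def subset(self, mask: pd.Series) -> "AnnotatedCountTable":
        kept = CountTable(
            raw=self.counts.raw.loc[mask],
            norm=None if self.counts.norm is None else self.counts.norm.loc[mask],
        )
        return AnnotatedCountTable(ann=self.ann.loc[mask], counts=kept)

    def mirna_only(self) -> "AnnotatedCountTable":
        return self.subset(self.ann["miRNA"].notna())


def annotate_table(
    table: CountTable,
    mirna_refs: ReferenceSet,
    rnaworld_refs: ReferenceSet,
    viability: SeedViabilityTable,
    renormalize: bool = True,
) -> tuple[AnnotatedCountTable, pd.DataFrame]:
    """Annotate every row of *table* and drop artifact rows.

    Each retained row carries its 6mer seed, species-averaged viability,
    miRNA hit, RNA-world hit, and a display name (miRNA hit if any, else
    RNA-world hit, else ``"unknown"``).  Returns the annotated table and a
    frame of the purged artifact rows (for the conservation ledger).
    """
    mirna = _MirnaMatcher(mirna_refs)
    rnaworld = _RnaWorldMatcher(rnaworld_refs)
    records = []
    for seq in table.raw.index:
        m = mirna.match(seq)
        r = rnaworld.match(seq)
        records.append(
            {
                "seed": extract_seed(seq),
                "miRNA": m,
                "RNAworld": r,
                "name": m or r or UNKNOWN_NAME,
                "is_artifact": purge_artifacts(r),
            }
        )
    ann = pd.DataFrame(records, index=table.raw.index)
    ann["viability"] = viability.annotate(ann["seed"])
    ann = ann[["seed", "viability", "miRNA", "RNAworld", "name", "is_artifact"]]

    keep = ~ann["is_artifact"]
    artifacts = ann.loc[~keep].join(table.raw.loc[~keep])
    kept_counts = CountTable(raw=table.raw.loc[keep])
    if renormalize:
        kept_counts = normalize_cpm(kept_counts)
    elif table.norm is not None:
        kept_counts.norm = table.norm.loc[keep]
    return (
        AnnotatedCountTable(ann=ann.loc[keep].drop(columns="is_artifact"), counts=kept_counts),
        artifacts,
    )
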