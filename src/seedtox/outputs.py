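"""The six keyed output families (A-F) and the seed-keyed intermediary.

Output semantics:

* **A** -- annotated count table (rawCounts / normCounts / diff flavors).
* **B** -- rows collapsed by (6mer seed, assigned name), counts summed;
  ``Int_seedKeyed`` additionally collapses over names so each seed appears
  once.
* **C** -- counts aggregated into 1% seed-viability bins (a row per bin
  over the full resource range, zeros included, so it plots directly).
* **D** -- each B row expanded into round(count/1000) rows holding the
  row's viability value (boxplot / rank-test input).
* **E** -- as D but rows hold the seed string (logo input).
* **F** -- as E but each seed instance becomes 6 rows indexed by position
  1..6 with one nucleotide per row; seeds with a pre-scaling count below
  1000 are omitted.  F has exactly 6N rows, N = total scaled seed count.

File name prefixes match the keyed families exactly: ``A_rawCounts``,
``A_normCounts``, ``A_diff``, ``B_collapsed``, ``Int_seedKeyed``,
``C_binned``, ``D_toxAnalysis``, ``E_seedAnalysis``, ``F_seedExpand``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from seedtox.annotate import AnnotatedCountTable
from seedtox.seeds import RNA_ALPHABET, SEED_LENGTH

EXPANSION_DIVISOR = 1000
F_MIN_COUNT = 1000


def round_half_away(x: np.ndarray | float) -> np.ndarray | float:
    """Round to nearest integer, halves away from zero (spreadsheet rule)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def write_output_A(
    table: AnnotatedCountTable,
    flavor: str,
    directory: str | Path,
    contrast: str | None = None,
) -> Path:
    """Write an Output A TSV; returns the file path.

    Flavors: ``rawCounts``, ``normCounts``, ``diff`` (diff expects the
    table produced by ``select_differential`` and writes delta/direction).
    """
    if flavor not in ("rawCounts", "normCounts", "diff"):
        raise ValueError(f"unknown Output A flavor {flavor!r}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = f"_{contrast}" if contrast else ""
    path = directory / f"A_{flavor}{suffix}.txt"
    which = "raw" if flavor == "rawCounts" else "norm"
    table.frame(which).to_csv(path, sep="\t", index_label="sequence")
    return path


def _value_frame(table: AnnotatedCountTable, use_delta: bool) -> pd.DataFrame:
    """Per-row value columns for collapsing: |delta| by direction, or CPM."""
    if use_delta:
        if "delta" not in table.ann.columns:
            raise ValueError("differential branch requires delta/direction columns")
        values = pd.DataFrame(index=table.ann.index)
        for direction in ("Up", "Down"):
            mask = table.ann["direction"] == direction
            values[direction] = np.where(mask, table.ann["delta"].abs(), 0.0)
        return values
    if table.counts.norm is None:
        raise ValueError("normalized counts required")
    return table.counts.norm


def collapse_to_B(
    table: AnnotatedCountTable, use_delta: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse Output A rows by (seed, name); also build ``Int_seedKeyed``.

    In the differential branch (*use_delta*) the value columns are the
    absolute delta counts split into Up/Down groups; otherwise they are the
    per-sample normalized counts.  Returns ``(B, Int_seedKeyed)``.
    """
    values = _value_frame(table, use_delta)
    joined = table.ann[["seed", "name", "viability"]].join(values)
    value_cols = list(values.columns)
    b = (
        joined.groupby(["seed", "name"], as_index=False)
        .agg({"viability": "first", **{c: "sum" for c in value_cols}})
        .sort_values(["seed", "name"], kind="mergesort")
        .reset_index(drop=True)
    )
    seed_keyed = (
        b.groupby("seed", as_index=False)
        .agg({"viability": "first", **{c: "sum" for c in value_cols}})
        .sort_values("seed", kind="mergesort")
        .reset_index(drop=True)
    )
    return b, seed_keyed


def bin_to_C(table_b: pd.DataFrame, bin_range: tuple[int, int]) -> pd.DataFrame:
    """Aggregate B counts into 1% viability bins over *bin_range*.

    Bin index is the viability rounded half-away-from-zero; every bin in the
    range gets a row even at count 0 so the table plots directly.
    """
    lo, hi = bin_range
    value_cols = [c for c in table_b.columns if c not in ("seed", "name", "viability")]
    bins = round_half_away(table_b["viability"].to_numpy()).astype(int)
    if len(bins) and (bins.min() < lo or bins.max() > hi):
        raise ValueError("viability outside the declared bin range")
    out = pd.DataFrame({"bin": np.arange(lo, hi + 1)}).set_index("bin")
    for c in value_cols:
        out[c] = 0.0
    grouped = table_b.assign(bin=bins).groupby("bin")[value_cols].sum()
    out.loc[grouped.index, value_cols] = grouped
    return out.reset_index()


def _scaled_counts(counts: pd.Series, min_count: float | None) -> pd.Series:
    kept = counts if min_count is None else counts.where(counts >= min_count, 0.0)
    return pd.Series(
        round_half_away(kept.to_numpy() / EXPANSION_DIVISOR).astype(int),
        index=counts.index,
    )


def _group_value_columns(
    table_b: pd.DataFrame, groups: Mapping[str, list[str]] | None, per: str
) -> pd.DataFrame:
    """One value column per output unit: group averages or per-sample columns."""
    value_cols = [c for c in table_b.columns if c not in ("seed", "name", "viability")]
    if per == "replicate" or groups is None:
        return table_b[value_cols]
    if per != "avg":
        raise ValueError(f"per must be 'avg' or 'replicate', got {per!r}")
    out = pd.DataFrame(index=table_b.index)
    for gname, samples in groups.items():
        missing = [s for s in samples if s not in value_cols]
        if missing:
            raise ValueError(f"group {gname!r} names unknown columns: {missing}")
        out[gname] = table_b[samples].mean(axis=1)
    return out


def expand_to_D(
    table_b: pd.DataFrame,
    per: str = "avg",
    groups: Mapping[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Expand B rows into one viability value per rescaled seed instance.

    Tidy result: columns ``unit`` (group or sample), ``viability``; each B
    row contributes round(count/1000) rows per unit.
    """
    values = _group_value_columns(table_b, groups, per)
    frames = []
    for unit in values.columns:
        reps = _scaled_counts(values[unit], min_count=None)
        viab = np.repeat(table_b["viability"].to_numpy(), reps.to_numpy())
        frames.append(pd.DataFrame({"unit": unit, "viability": viab}))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["unit", "viability"]
    )


def expand_to_E(
    table_b: pd.DataFrame,
    per: str = "avg",
    groups: Mapping[str, list[str]] | None = None,
) -> pd.DataFrame:
    """As :func:`expand_to_D` but each instance row holds the seed string."""
    values = _group_value_columns(table_b, groups, per)
    frames = []
    for unit in values.columns:
        reps = _scaled_counts(values[unit], min_count=None)
        seeds = np.repeat(table_b["seed"].to_numpy(), reps.to_numpy())
        frames.append(pd.DataFrame({"unit": unit, "seed": seeds}))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["unit", "seed"]
    )


def expand_to_F(
    table_b: pd.DataFrame,
    per: str = "avg",
    groups: Mapping[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Per-position nucleotide expansion feeding the composition model.

    Seeds with a pre-scaling count < 1000 are omitted entirely; every kept
    instance contributes 6 rows (position 1..6, one nucleotide each) under a
    unit-unique ``instance_id``.  Row count is exactly 6N per unit, N being
    the unit's total scaled seed count.
    """
    values = _group_value_columns(table_b, groups, per)
    frames = []
    for unit in values.columns:
        reps = _scaled_counts(values[unit], min_count=F_MIN_COUNT).to_numpy()
        n_inst = int(reps.sum())
        seeds = np.repeat(table_b["seed"].to_numpy(), reps)
        instance = np.arange(n_inst)
        frames.append(
            pd.DataFrame(
                {
                    "unit": unit,
                    "instance_id": np.repeat(instance, SEED_LENGTH),
                    "seed": np.repeat(seeds, SEED_LENGTH),
                    "position": np.tile(
                        np.arange(1, SEED_LENGTH + 1), n_inst
                    ),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["unit", "instance_id", "seed", "position", "nucleotide"])
    out = pd.concat(frames, ignore_index=True)
    out["nucleotide"] = [
        s[p - 1] for s, p in zip(out["seed"], out["position"])
    ]
    return out


def position_frequency_matrix(table_e: pd.DataFrame, unit: str | None = None) -> pd.DataFrame:
    """4 x 6 nucleotide frequency matrix over Output E rows (logo input).

    Rows A/C/G/U, columns positions 1..6; every column sums to 1.
    """
    seeds = table_e if unit is None else table_e[table_e["unit"] == unit]
    if seeds.empty:
        raise ValueError("no seed instances to build a frequency matrix from")
    mat = np.zeros((len(RNA_ALPHABET), SEED_LENGTH))
    idx = {b: i for i, b in enumerate(RNA_ALPHABET)}
    for seed in seeds["seed"]:
        for j, base in enumerate(seed):
            mat[idx[base], j] += 1
    mat /= mat.sum(axis=0, keepdims=True)
    return pd.DataFrame(mat, index=list(RNA_ALPHABET), columns=range(1, SEED_LENGTH + 1))


def mirna_content(table: AnnotatedCountTable, which: str = "raw") -> pd.Series:
    """Percent of each sample's count mass assigned to a miRNA."""
    values = table.counts.raw if which == "raw" else table.counts.norm
    if values is None:
        raise ValueError("counts not normalized")
    total = values.sum(axis=0)
    if (total == 0).any():
        raise ValueError("sample with zero total counts")
    assigned = values.loc[table.ann["miRNA"].notna()].sum(axis=0)
    return 100.0 * assigned / total
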