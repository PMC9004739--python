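"""Differential read abundance between two groups of samples.

Per read, a negative-binomial exact test conditional on the group-sum total
is performed, after equalizing library sizes by scaling every sample to the
geometric-mean library size.  Dispersion is shared across reads and
estimated by maximizing the conditional likelihood; ``poisson`` mode forces
dispersion 0, in which case the conditional distribution is binomial.

Significance for the "diff" output branch is adjusted p < 0.05 together
with |logFC| > 0.585 (1.5-fold); the selected reads carry their delta
normalized count (Group2 mean - Group1 mean) and an Up/Down direction
label into the downstream outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from seedtox.annotate import AnnotatedCountTable

PADJ_CUTOFF = 0.05
LOGFC_CUTOFF = 0.585
LOGFC_PSEUDOCOUNT = 0.5


class DesignError(ValueError):
    pass


@dataclass
class ComparisonDesign:
    """One pairwise contrast: sample -> 1 (Group1/control), -1 (Group2), 0."""

    name: str
    coding: dict[str, int]

    def __post_init__(self) -> None:
        bad = {v for v in self.coding.values()} - {1, -1, 0}
        if bad:
            raise DesignError(f"comparison codes must be 1/-1/0, got {sorted(bad)}")
        if not self.group1 or not self.group2:
            raise DesignError(
                f"contrast {self.name!r} needs at least one sample coded 1 and one coded -1"
            )

    @property
    def group1(self) -> list[str]:
        return [s for s, c in self.coding.items() if c == 1]

    @property
    def group2(self) -> list[str]:
        return [s for s, c in self.coding.items() if c == -1]

    def swapped(self) -> "ComparisonDesign":
        return ComparisonDesign(self.name, {s: -c for s, c in self.coding.items()})


def read_comparisons(path: str | Path) -> list[ComparisonDesign]:
    """Parse the comma-separated comparisons table.

    Columns are sample names (an optional leading ``name`` column labels the
    contrast); each row codes one pairwise comparison with 1/-1/0.
    """
    df = pd.read_csv(path)
    cols = list(df.columns)
    designs = []
    for i, row in df.iterrows():
        if cols[0].lower() == "name":
            name = str(row[cols[0]])
            coding = {c: int(row[c]) for c in cols[1:]}
        else:
            name = f"comparison{i + 1}"
            coding = {c: int(row[c]) for c in cols}
        designs.append(ComparisonDesign(name, coding))
    return designs


@dataclass
class DifferentialResult:
    """Per-read test results for one contrast."""

    design: ComparisonDesign
    table: pd.DataFrame  # logFC, pvalue, padj, mean_norm_g1, mean_norm_g2, delta, significant
    dispersion: float
    source: AnnotatedCountTable = field(repr=False)


def _nb_exact_pvalues(y1: np.ndarray, y2: np.ndarray, n1: int, n2: int, phi: float) -> np.ndarray:
    """Two-sided exact p for group sums y1 vs y2 conditional on y1+y2.

    Under NB with common per-sample mean and dispersion *phi* (libraries
    equalized), the group sums are NB with sizes n1/phi and n2/phi, and the
    conditional law of y1 given the total does not depend on the mean.  At
    phi == 0 it reduces to Binomial(total, n1/(n1+n2)).  The two-sided p is
    the total probability of outcomes no more likely than the observed one.
    """
    pvals = np.ones(len(y1))
    for i, (a, b) in enumerate(zip(y1, y2)):
        t = int(a + b)
        if t == 0:
            continue
        y = np.arange(t + 1)
        if phi <= 0:
            logp = (
                gammaln(t + 1) - gammaln(y + 1) - gammaln(t - y + 1)
                + y * np.log(n1 / (n1 + n2)) + (t - y) * np.log(n2 / (n1 + n2))
            )
        else:
            # beta-binomial conditional, built from successive log ratios so
            # huge shape parameters (tiny phi) stay numerically stable
            r1, r2 = n1 / phi, n2 / phi
            yy = y[:-1].astype(float)
            ratios = (
                np.log(yy + r1) + np.log(t - yy)
                - np.log(yy + 1) - np.log(t - yy - 1 + r2)
            )
            logp = np.concatenate([[0.0], np.cumsum(ratios)])
        p = np.exp(logp - logsumexp(logp))
        obs = p[int(a)]
        pvals[i] = min(1.0, float(p[p <= obs * (1 + 1e-10)].sum()))
    return pvals


def _conditional_loglik(counts: np.ndarray, phi: float) -> float:
    """Log conditional likelihood of equal-mean NB counts given their sum.

    *counts* is reads x samples within one group; used for common-dispersion
    estimation by conditional maximum likelihood.
    """
    n = counts.shape[1]
    r = 1.0 / phi
    z = counts.sum(axis=1)
    ll = (
        gammaln(counts + r).sum(axis=1)
        + gammaln(n * r)
        - gammaln(z + n * r)
        - n * gammaln(r)
    )
    return float(ll.sum())


def estimate_common_dispersion(counts_by_group: list[np.ndarray]) -> float:
    """Common NB dispersion maximizing the summed conditional log-likelihood.

    Parameterized through delta = phi/(1+phi) on (0, 1); groups with a
    single sample carry no conditional information and are skipped.
    """
    groups = [g for g in counts_by_group if g.shape[1] >= 2]
    if not groups:
        return 0.0

    def neg(delta: float) -> float:
        phi = delta / (1 - delta)
        return -sum(_conditional_loglik(g, phi) for g in groups)

    res = minimize_scalar(neg, bounds=(1e-6, 1 - 1e-6), method="bounded")
    delta = float(res.x)
    # treat a boundary solution as Poisson-like
    if delta < 2e-6:
        return 0.0
    return delta / (1 - delta)


def test_differential(
    table: AnnotatedCountTable,
    design: ComparisonDesign,
    dispersion_mode: str = "common",
) -> DifferentialResult:
    """NB exact test per read for one contrast, on raw counts.

    Library sizes are equalized by scaling each sample to the geometric mean
    library size (rounded to integers for the exact test).  ``poisson`` mode
    forces dispersion 0; ``common`` estimates a shared dispersion by
    conditional maximum likelihood.
    """
    if dispersion_mode not in ("common", "poisson"):
        raise ValueError(f"unknown dispersion_mode {dispersion_mode!r}")
    missing = [s for s in design.coding if s not in table.samples]
    if missing:
        raise DesignError(f"comparison names unknown samples: {missing}")

    g1, g2 = design.group1, design.group2
    raw = table.counts.raw
    lib = raw[g1 + g2].sum(axis=0).astype(float)
    if (lib[g1].sum() == 0) or (lib[g2].sum() == 0):
        raise DesignError("a comparison group has zero total counts")
    ref_lib = float(np.exp(np.log(lib[lib > 0]).mean()))
    scaled = (raw[g1 + g2] * (ref_lib / lib)).round().astype(int)

    if dispersion_mode == "poisson":
        phi = 0.0
    else:
        phi = estimate_common_dispersion(
            [scaled[g1].to_numpy(), scaled[g2].to_numpy()]
        )

    y1 = scaled[g1].sum(axis=1).to_numpy()
    y2 = scaled[g2].sum(axis=1).to_numpy()
    pvalue = _nb_exact_pvalues(y1, y2, len(g1), len(g2), phi)
    padj = multipletests(pvalue, method="fdr_bh")[1]

    if table.counts.norm is None:
        raise ValueError("normalized counts required for logFC/delta")
    norm = table.counts.norm
    m1 = norm[g1].mean(axis=1)
    m2 = norm[g2].mean(axis=1)
    logfc = np.log2((m2 + LOGFC_PSEUDOCOUNT) / (m1 + LOGFC_PSEUDOCOUNT))

    out = pd.DataFrame(
        {
            "logFC": logfc,
            "pvalue": pvalue,
            "padj": padj,
            "mean_norm_g1": m1,
            "mean_norm_g2": m2,
            "delta": m2 - m1,
        },
        index=raw.index,
    )
    out["significant"] = (out["padj"] < PADJ_CUTOFF) & (out["logFC"].abs() > LOGFC_CUTOFF)
    return DifferentialResult(design=design, table=out, dispersion=phi, source=table)


def select_differential(
    result: DifferentialResult, mode: str = "padj"
) -> AnnotatedCountTable:
    """Rows passing the significance rule, annotated with delta and direction.

    ``mode`` selects whether the adjusted or the raw p-value is thresholded
    at 0.05; |logFC| > 0.585 is required either way.  The returned table's
    annotation frame gains ``delta`` (signed) and ``direction`` (Up = higher
    in Group2) columns.
    """
    if mode not in ("padj", "pvalue"):
        raise ValueError(f"unknown selection mode {mode!r}")
    stats = result.table
    passed = (stats[mode] < PADJ_CUTOFF) & (stats["logFC"].abs() > LOGFC_CUTOFF)
    if not passed.any():
        warnings.warn(
            f"contrast {result.design.name!r}: no read passes the "
            f"{mode} < {PADJ_CUTOFF} and |logFC| > {LOGFC_CUTOFF} rule",
            stacklevel=2,
        )
    selected = result.source.subset(passed)
    selected.ann = selected.ann.copy()
    selected.ann["delta"] = stats.loc[passed, "delta"]
    selected.ann["direction"] = np.where(stats.loc[passed, "delta"] > 0, "Up", "Down")
    return selected
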