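"""Group comparisons of seed toxicity and positional seed composition.

Two analyses consume the expanded outputs:

* Rank tests on the toxicity expansion (Output D): Wilcoxon rank-sum for
  two groups, Kruskal-Wallis for more.

* A baseline-category multinomial mixed-effects logit on the per-position
  nucleotide expansion (Output F).  For seed instance i at position j the
  log odds of nucleotide k in {C, G, U} against the reference A are

      log P(k) / P(A) = eta_{g(i), j, k} + b_{ik},

  where eta carries the fixed effects (group, position, and optionally
  their interaction) and b_ik ~ N(0, sigma_k^2) is a per-instance random
  intercept, independent across instances and categories, inducing the
  within-seed correlation between the 6 positions.  A is the reference
  because A-rich seeds are the least toxic.

  The marginal likelihood integrates the three random intercepts per
  instance with tensor-product Gauss-Hermite quadrature whose nodes are
  scaled by the current sigma (the integral does not factorize across
  categories because the multinomial denominator couples them).  Instances
  enter the likelihood only through their group, their per-position
  nucleotides (fixed-effect term) and their per-category nucleotide totals
  (random-effect integral), so the integrals are shared across instances
  with equal totals -- at most 84 distinct integrals per group regardless
  of sample size.

Group comparisons are reported as odds ratios OR(k, position, group pair)
with Wald intervals; p-values over the set of pairwise group contrasts are
adjusted by Tukey's method (multivariate normal/t of the contrast vector).
For display, OR < 1 is accompanied by OR* = 1/OR.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from seedtox.seeds import SEED_LENGTH

CATEGORIES = ("C", "G", "U")  # non-reference nucleotide categories
REFERENCE = "A"
N_CAT = len(CATEGORIES)
DEFAULT_QUAD_NODES = 15
RIDGE_PENALTY = 1e-4


class ConvergenceError(RuntimeError):
    """Model fit failed; carries the final gradient norm."""

    def __init__(self, message: str, grad_norm: float):
        super().__init__(f"{message} (gradient norm {grad_norm:.3g})")
        self.grad_norm = grad_norm


# ---------------------------------------------------------------------------
# rank tests on the toxicity expansion
# ---------------------------------------------------------------------------

@dataclass
class RankTestResult:
    test: str  # "wilcoxon" or "kruskal"
    statistic: float
    pvalue: float


def toxicity_rank_test(
    groups: Mapping[str, Sequence[float]], method: str = "auto"
) -> RankTestResult:
    """Nonparametric comparison of viability distributions between groups.

    Two groups: two-sided Wilcoxon rank-sum (Mann-Whitney U statistic);
    exact for small tie-free samples, otherwise the tie-corrected normal
    approximation.  More than two groups: Kruskal-Wallis.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {name: np.asarray(vals, dtype=float) for name, vals in groups.items()}
    for name, arr in arrays.items():
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
    pooled = np.concatenate(list(arrays.values()))
    if np.all(pooled == pooled[0]):
        # degenerate: every observation identical; no evidence either way
        if len(arrays) == 2:
            n1, n2 = (a.size for a in arrays.values())
            return RankTestResult("wilcoxon", n1 * n2 / 2.0, 1.0)
        return RankTestResult("kruskal", 0.0, 1.0)
    if len(arrays) == 2:
        x, y = arrays.values()
        if method == "auto":
            tie_free = pd.unique(pooled).size == pooled.size
            method = "exact" if (tie_free and max(x.size, y.size) <= 25) else "asymptotic"
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method=method, use_continuity=False
        )
        return RankTestResult("wilcoxon", float(res.statistic), float(res.pvalue))
    h, p = stats.kruskal(*arrays.values())
    return RankTestResult("kruskal", float(h), float(p))


# ---------------------------------------------------------------------------
# multinomial mixed-effects model
# ---------------------------------------------------------------------------

@dataclass
class _SufficientStats:
    """Per-group reductions of the expanded table F."""

    groups: list[str]
    # m[g, j, k]: count of category k (C,G,U) at position j in group g
    m: np.ndarray
    # per group: distinct per-instance category-total vectors and multiplicities
    totals: list[np.ndarray]
    counts: list[np.ndarray]
    n_instances: np.ndarray
    # full nucleotide counts incl. A, for start values / separation checks
    m_full: np.ndarray


def _reduce(table_f: pd.DataFrame, group_col: str) -> _SufficientStats:
    required = {group_col, "instance_id", "position", "nucleotide"}
    missing = required - set(table_f.columns)
    if missing:
        raise ValueError(f"expanded table missing columns: {sorted(missing)}")
    groups = sorted(table_f[group_col].unique())
    cat_idx = {c: i for i, c in enumerate(CATEGORIES)}
    m = np.zeros((len(groups), SEED_LENGTH, N_CAT))
    m_full = np.zeros((len(groups), SEED_LENGTH, N_CAT + 1))
    totals, counts, n_inst = [], [], []
    for gi, g in enumerate(groups):
        sub = table_f[table_f[group_col] == g]
        sizes = sub.groupby("instance_id").size()
        if not (sizes == SEED_LENGTH).all():
            raise ValueError(
                f"group {g!r}: every seed instance must have exactly "
                f"{SEED_LENGTH} position rows"
            )
        for k, c in enumerate(CATEGORIES):
            mk = sub[sub["nucleotide"] == c].groupby("position").size()
            m[gi, mk.index.to_numpy() - 1, k] = mk.to_numpy()
        for k, c in enumerate((REFERENCE,) + CATEGORIES):
            mk = sub[sub["nucleotide"] == c].groupby("position").size()
            m_full[gi, mk.index.to_numpy() - 1, k] = mk.to_numpy()
        per_inst = (
            sub.pivot_table(
                index="instance_id", columns="nucleotide", aggfunc="size", fill_value=0
            )
            .reindex(columns=list(CATEGORIES), fill_value=0)
            .to_numpy()
        )
        uniq, cnt = np.unique(per_inst, axis=0, return_counts=True)
        totals.append(uniq.astype(float))
        counts.append(cnt.astype(float))
        n_inst.append(per_inst.shape[0])
        _ = cat_idx  # kept for clarity of the category ordering
    return _SufficientStats(
        groups=groups,
        m=m,
        totals=totals,
        counts=counts,
        n_instances=np.asarray(n_inst),
        m_full=m_full,
    )


def _design_matrix(n_groups: int, interaction: bool) -> np.ndarray:
    """Cell design: row per (group, position) cell, treatment coding."""
    rows = []
    for g in range(n_groups):
        for j in range(SEED_LENGTH):
            row = [1.0]
            row += [1.0 if g == gg else 0.0 for gg in range(1, n_groups)]
            row += [1.0 if j == jj else 0.0 for jj in range(1, SEED_LENGTH)]
            if interaction:
                row += [
                    1.0 if (g == gg and j == jj) else 0.0
                    for gg in range(1, n_groups)
                    for jj in range(1, SEED_LENGTH)
                ]
            rows.append(row)
    return np.asarray(rows)


def _quadrature(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Tensor-product probabilists' Gauss-Hermite rule for 3 N(0,1) factors."""
    z, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    w = w / np.sqrt(2 * np.pi)
    zz = np.stack(np.meshgrid(z, z, z, indexing="ij"), axis=-1).reshape(-1, 3)
    ww = (w[:, None, None] * w[None, :, None] * w[None, None, :]).reshape(-1)
    return zz, np.log(ww)


class _Likelihood:
    """Marginal negative log-likelihood and analytic gradient."""

    def __init__(self, ss: _SufficientStats, X: np.ndarray, n_nodes: int, ridge: float):
        self.ss = ss
        self.X = X
        self.p = X.shape[1]
        self.Z, self.logW = _quadrature(n_nodes)
        self.ridge = ridge

    def unpack(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        beta = x[: 3 * self.p].reshape(N_CAT, self.p)
        sigma = x[3 * self.p :]
        return beta, sigma

    def __call__(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        ss, X = self.ss, self.X
        beta, sigma = self.unpack(x)
        n_groups = len(ss.groups)
        eta = (X @ beta.T).reshape(n_groups, SEED_LENGTH, N_CAT)
        B = self.Z * sigma  # (Q, 3) random-effect values at the nodes
        expB = np.exp(B)
        loglik = float(np.sum(ss.m * eta))
        grad_eta = ss.m.copy()
        grad_sigma = np.zeros(N_CAT)
        for gi in range(n_groups):
            E = np.exp(eta[gi])  # (6, 3)
            SS = expB @ E.T  # (Q, 6): sum_k exp(eta + b_k)
            logD = np.log1p(SS).sum(axis=1)  # (Q,)
            N = ss.totals[gi]  # (T, 3)
            c = ss.counts[gi]  # (T,)
            logIq = N @ B.T - logD[None, :] + self.logW[None, :]  # (T, Q)
            logI = logsumexp(logIq, axis=1)
            loglik += float(c @ logI)
            # P[q, j, k]: probability of category k at position j given b_q
            P = (expB[:, None, :] * E[None, :, :]) / (1.0 + SS)[:, :, None]
            A = np.exp(logIq - logI[:, None])  # normalized node weights per total
            V = c @ A  # (Q,)
            grad_eta[gi] -= np.einsum("q,qjk->jk", V, P)
            T = P.sum(axis=1)  # (Q, 3)
            M = A.T @ (c[:, None] * N)  # (Q, 3)
            grad_sigma += np.einsum("qk,qk->k", self.Z, M - V[:, None] * T)
        grad_beta = np.einsum("cj,jk->kc", X.T, grad_eta.reshape(-1, N_CAT)).reshape(-1)
        grad = np.concatenate([grad_beta, grad_sigma])
        if self.ridge > 0:
            loglik -= 0.5 * self.ridge * float(x[: 3 * self.p] @ x[: 3 * self.p])
            grad[: 3 * self.p] -= self.ridge * x[: 3 * self.p]
        return -loglik, -grad


@dataclass
class SeedCompositionModel:
    """Fitted multinomial mixed-effects model of positional seed composition."""

    groups: list[str]
    interaction: bool
    beta: np.ndarray  # (3, p) per-category fixed effects
    sigma: np.ndarray  # (3,) random-intercept SDs for C, G, U
    cov: np.ndarray  # covariance of the free parameters
    free_index: np.ndarray  # positions of free parameters in the packed vector
    loglik: float
    n_instances: int
    n_quad: int
    X: np.ndarray = field(repr=False)
    _stats: _SufficientStats = field(repr=False)

    @property
    def n_params(self) -> int:
        return 3 * self.X.shape[1] + N_CAT

    def _cell(self, group: str, position: int) -> int:
        gi = self.groups.index(group)
        return gi * SEED_LENGTH + (position - 1)

    def eta(self) -> np.ndarray:
        """Fitted fixed-effect log odds, shape (groups, positions, categories)."""
        return (self.X @ self.beta.T).reshape(len(self.groups), SEED_LENGTH, N_CAT)

    def cell_probabilities(self) -> np.ndarray:
        """Fitted per-cell multinomial probabilities at b = 0.

        Shape (groups, positions, 4) ordered A, C, G, U; sums to 1 per cell.
        """
        e = np.exp(self.eta())
        denom = 1.0 + e.sum(axis=2, keepdims=True)
        probs = np.concatenate([1.0 / denom, e / denom], axis=2)
        return probs

    def contrast_vector(self, category: str, position: int, g1: str, g2: str) -> np.ndarray:
        """Packed-parameter contrast for eta(g2) - eta(g1) at one position."""
        if category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}, got {category!r}")
        if not (1 <= position <= SEED_LENGTH):
            raise ValueError(f"position must be 1..{SEED_LENGTH}")
        for g in (g1, g2):
            if g not in self.groups:
                raise ValueError(f"unknown group {g!r}")
        k = CATEGORIES.index(category)
        p = self.X.shape[1]
        vec = np.zeros(self.n_params)
        xdiff = self.X[self._cell(g2, position)] - self.X[self._cell(g1, position)]
        vec[k * p : (k + 1) * p] = xdiff
        return vec

    def _contrast_variance(self, vecs: np.ndarray) -> np.ndarray:
        free = vecs[:, self.free_index]
        return free @ self.cov @ free.T


def _start_values(ss: _SufficientStats, X: np.ndarray) -> np.ndarray:
    """Empirical-logit least-squares start for beta; modest start for sigma."""
    n_groups = len(ss.groups)
    ref = ss.m_full[:, :, 0]
    beta0 = np.zeros((N_CAT, X.shape[1]))
    for k in range(N_CAT):
        logit = np.log((ss.m_full[:, :, k + 1] + 0.5) / (ref + 0.5)).reshape(
            n_groups * SEED_LENGTH
        )
        beta0[k] = np.linalg.lstsq(X, logit, rcond=None)[0]
    return np.concatenate([beta0.reshape(-1), np.full(N_CAT, 0.3)])


def fit_seed_composition_model(
    table_f: pd.DataFrame,
    group_col: str = "unit",
    interaction: bool = True,
    n_quad: int = DEFAULT_QUAD_NODES,
    fix_sigma: float | None = None,
    max_iter: int = 500,
    compute_cov: bool = True,
) -> SeedCompositionModel:
    """Fit the mixed-effects baseline-category logit to an Output F table.

    Parameters
    ----------
    table_f
        Long table with columns *group_col*, ``instance_id``, ``position``
        (1..6) and ``nucleotide`` (A/C/G/U).
    interaction
        Include the group x position interaction (the full model).
    n_quad
        Gauss-Hermite nodes per random-effect dimension.
    fix_sigma
        If given, the random-intercept SDs are held at this value instead of
        being estimated (0 recovers the fixed-effects multinomial logit).
    """
    ss = _reduce(table_f, group_col)
    if len(ss.groups) < 2:
        raise ValueError("need at least two groups to fit the model")
    X = _design_matrix(len(ss.groups), interaction)
    ridge = 0.0
    if (ss.m_full == 0).any():
        warnings.warn(
            "some group x position cell has a nucleotide never observed; "
            f"applying a weak ridge penalty ({RIDGE_PENALTY}) to keep the "
            "fit finite",
            stacklevel=2,
        )
        ridge = RIDGE_PENALTY
    nll = _Likelihood(ss, X, n_quad, ridge)
    x0 = _start_values(ss, X)
    p3 = 3 * X.shape[1]
    if fix_sigma is not None:
        x0[p3:] = fix_sigma
        bounds = [(None, None)] * p3 + [(fix_sigma, fix_sigma)] * N_CAT
    else:
        bounds = [(None, None)] * p3 + [(0.0, 5.0)] * N_CAT
    res = optimize.minimize(
        nll, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter, "maxfun": 5 * max_iter, "ftol": 1e-11, "gtol": 1e-7},
    )
    grad_norm = float(np.linalg.norm(res.jac))
    scale = max(1.0, float(ss.n_instances.sum()))
    if not res.success and grad_norm / scale > 1e-4:
        raise ConvergenceError("composition model failed to converge", grad_norm)
    beta, sigma = nll.unpack(res.x)

    # observed information over the free parameters (sigma rows at the zero
    # boundary or fixed by the caller are excluded)
    free = list(range(p3))
    if fix_sigma is None:
        free += [p3 + k for k in range(N_CAT) if sigma[k] > 1e-3]
    free_index = np.asarray(free)
    if compute_cov:
        H = _numerical_hessian(nll, res.x, free_index)
        cov = _safe_inverse(H)
    else:
        cov = np.full((len(free), len(free)), np.nan)

    return SeedCompositionModel(
        groups=ss.groups,
        interaction=interaction,
        beta=beta,
        sigma=sigma,
        cov=cov,
        free_index=free_index,
        loglik=-float(res.fun),
        n_instances=int(ss.n_instances.sum()),
        n_quad=n_quad,
        X=X,
        _stats=ss,
    )


def _numerical_hessian(
    nll: _Likelihood, x: np.ndarray, free_index: np.ndarray
) -> np.ndarray:
    """Central finite differences of the analytic gradient."""
    n = len(free_index)
    H = np.zeros((n, n))
    for a, idx in enumerate(free_index):
        h = 1e-5 * (1.0 + abs(x[idx]))
        xp, xm = x.copy(), x.copy()
        xp[idx] += h
        xm[idx] -= h
        gp = nll(xp)[1]
        gm = nll(xm)[1]
        H[a] = (gp[free_index] - gm[free_index]) / (2 * h)
    return 0.5 * (H + H.T)


def _safe_inverse(H: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


@dataclass
class PairwiseOR:
    category: str
    position: int
    group1: str
    group2: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    pvalue: float
    pvalue_adj: float

    @property
    def or_star(self) -> float:
        """Display value: 1/OR when OR < 1 (A more likely in g2)."""
        return self.odds_ratio if self.odds_ratio >= 1 else 1.0 / self.odds_ratio


def pairwise_or(
    model: SeedCompositionModel,
    category: str,
    position: int,
    group_pair: tuple[str, str],
    alpha: float = 0.05,
) -> PairwiseOR:
    """Odds ratio for *category* vs A between two groups at one position.

    The Wald p-value is adjusted over all pairwise group contrasts at this
    (category, position) by Tukey's method: the joint multivariate-normal
    law of the standardized contrasts gives P(max |Z| >= |t_observed|).
    """
    g1, g2 = group_pair
    if g1 == g2:
        return PairwiseOR(category, position, g1, g2, 1.0, 1.0, 1.0, 1.0, 1.0)

    pairs = list(itertools.combinations(model.groups, 2))
    vecs = np.stack(
        [model.contrast_vector(category, position, a, b) for a, b in pairs]
    )
    V = model._contrast_variance(vecs)
    se = np.sqrt(np.clip(np.diag(V), 1e-300, None))
    flat_beta = np.concatenate([model.beta.reshape(-1), model.sigma])
    ests = vecs @ flat_beta

    try:
        idx = pairs.index((g1, g2))
        sign = 1.0
    except ValueError:
        idx = pairs.index((g2, g1))
        sign = -1.0
    est = sign * ests[idx]
    s = se[idx]
    z = stats.norm.ppf(1 - alpha / 2)
    t_obs = est / s
    p_raw = 2 * stats.norm.sf(abs(t_obs))
    p_adj = _tukey_adjust(abs(t_obs), V) if len(pairs) > 1 else p_raw
    return PairwiseOR(
        category=category,
        position=position,
        group1=g1,
        group2=g2,
        odds_ratio=float(np.exp(est)),
        ci_low=float(np.exp(est - z * s)),
        ci_high=float(np.exp(est + z * s)),
        pvalue=float(p_raw),
        pvalue_adj=float(min(1.0, p_adj)),
    )


def _tukey_adjust(t_abs: float, V: np.ndarray) -> float:
    """P(max_i |Z_i| >= t) for Z ~ MVN(0, corr(V)) over the contrast set."""
    d = np.sqrt(np.diag(V))
    R = V / np.outer(d, d)
    m = R.shape[0]
    dist = stats.multivariate_normal(mean=np.zeros(m), cov=R, allow_singular=True)
    inside = dist.cdf(np.full(m, t_abs), lower_limit=np.full(m, -t_abs))
    return float(np.clip(1.0 - inside, 0.0, 1.0))


def summarize_pairwise(model: SeedCompositionModel) -> pd.DataFrame:
    """All (category, position, group-pair) odds ratios as a tidy table."""
    rows = []
    for category in CATEGORIES:
        for position in range(1, SEED_LENGTH + 1):
            for g1, g2 in itertools.combinations(model.groups, 2):
                r = pairwise_or(model, category, position, (g1, g2))
                rows.append(
                    {
                        "category": r.category,
                        "position": r.position,
                        "group1": r.group1,
                        "group2": r.group2,
                        "OR": r.odds_ratio,
                        "CI_low": r.ci_low,
                        "CI_high": r.ci_high,
                        "p": r.pvalue,
                        "p_adj": r.pvalue_adj,
                        "OR_star": r.or_star,
                    }
                )
    return pd.DataFrame(rows)


def interaction_test(
    table_f: pd.DataFrame,
    group_col: str = "unit",
    n_quad: int = DEFAULT_QUAD_NODES,
    **fit_kwargs,
) -> tuple[float, float]:
    """Likelihood-ratio test of the group x position interaction block.

    Returns ``(statistic, pvalue)``; the chi-square reference has
    3 x 5 x (G - 1) degrees of freedom.
    """
    full = fit_seed_composition_model(
        table_f, group_col=group_col, interaction=True, n_quad=n_quad,
        compute_cov=False, **fit_kwargs
    )
    reduced = fit_seed_composition_model(
        table_f, group_col=group_col, interaction=False, n_quad=n_quad,
        compute_cov=False, **fit_kwargs
    )
    statistic = 2.0 * (full.loglik - reduced.loglik)
    if statistic < -1e-6:
        raise ConvergenceError(
            "reduced model attained a higher likelihood than the full model",
            abs(statistic),
        )
    df = N_CAT * (SEED_LENGTH - 1) * (len(full.groups) - 1)
    pvalue = float(stats.chi2.sf(max(statistic, 0.0), df))
    return float(statistic), pvalue


def simulate_composition(
    eta: np.ndarray,
    sigma: Sequence[float],
    n_per_group: int | Sequence[int],
    rng: np.random.Generator,
    group_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Draw seed instances from the model itself (oracle for recovery tests).

    *eta* has shape (groups, 6, 3): fixed-effect log odds of C, G, U vs A.
    Returns a table in Output F layout (unit, instance_id, position,
    nucleotide).
    """
    eta = np.asarray(eta, dtype=float)
    n_groups = eta.shape[0]
    if eta.shape != (n_groups, SEED_LENGTH, N_CAT):
        raise ValueError(f"eta must have shape (G, {SEED_LENGTH}, {N_CAT})")
    sigma = np.asarray(sigma, dtype=float)
    if np.isscalar(n_per_group) or isinstance(n_per_group, int):
        n_per_group = [int(n_per_group)] * n_groups
    if group_names is None:
        group_names = [f"group{g + 1}" for g in range(n_groups)]
    nucs = np.array([REFERENCE, *CATEGORIES])
    frames = []
    for g in range(n_groups):
        n = n_per_group[g]
        b = rng.normal(0.0, sigma, size=(n, N_CAT))  # (n, 3)
        logits = eta[g][None, :, :] + b[:, None, :]  # (n, 6, 3)
        e = np.exp(logits)
        denom = 1.0 + e.sum(axis=2, keepdims=True)
        probs = np.concatenate([1.0 / denom, e / denom], axis=2)  # (n, 6, 4)
        u = rng.random((n, SEED_LENGTH, 1))
        draws = (u > probs.cumsum(axis=2)).sum(axis=2)  # (n, 6) in 0..3
        frames.append(
            pd.DataFrame(
                {
                    "unit": group_names[g],
                    "instance_id": np.repeat(np.arange(n), SEED_LENGTH),
                    "position": np.tile(np.arange(1, SEED_LENGTH + 1), n),
                    "nucleotide": nucs[draws.reshape(-1)],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
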