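"""Repeated-measures inference battery.

Standalone implementations of the tests the analysis relies on: one- and
two-way repeated-measures ANOVAs with Greenhouse-Geisser sphericity
correction and partial eta squared, FDR-corrected pairwise post-hocs,
Wilcoxon signed-rank and Mann-Whitney U wrappers with rank-based effect
sizes, a cluster-based permutation test over adjacent analysis units,
repeated-measures correlation (ANCOVA formulation with subject as blocking
factor), and dominance analysis over a correlation matrix. Each closed-form
test is written directly from its sums-of-squares / ranking definition so it
can be verified against brute-force enumeration on small tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sst
from scipy.linalg import helmert
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "StatResult",
    "ClusterResult",
    "rm_anova_1way",
    "rm_anova_2way",
    "pairwise_posthoc",
    "wilcoxon_vs_constant",
    "mann_whitney",
    "cluster_perm_F",
    "chain_adjacency",
    "rmcorr",
    "dominance",
    "fdr_bh",
]


@dataclass
class StatResult:
    effect: str
    statistic: float
    df1: float
    df2: "float | None"
    p: float
    p_gg: "float | None" = None
    eps_gg: "float | None" = None
    effect_size: "float | None" = None
    effect_size_name: str = ""
    n: int = 0
    p_adj: "float | None" = None

    def as_row(self) -> dict:
        return {
            "effect": self.effect,
            "stat": self.statistic,
            "df1": self.df1,
            "df2": self.df2,
            "p": self.p,
            "p_gg": self.p_gg,
            "p_adj": self.p_adj,
            "effect_size": self.effect_size,
            "effect_size_name": self.effect_size_name,
            "n": self.n,
        }


@dataclass
class ClusterResult:
    clusters: list  # list of (member index array, mass, p_perm)
    n_perm: int
    cluster_alpha: float
    seed: int
    f_units: np.ndarray = field(default_factory=lambda: np.empty(0))
    f_crit: float = float("nan")

    @property
    def significant(self) -> list:
        return [c for c in self.clusters if c[2] < 0.05]


def _as_matrix(table) -> np.ndarray:
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a subjects x conditions table")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing or non-finite cells are not allowed (no imputation)")
    return x


def _gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the sample covariance of condition scores."""
    k = scores.shape[1]
    if k < 3:
        return 1.0
    s = np.cov(scores, rowvar=False)
    # double-center the covariance matrix
    row = s.mean(axis=0, keepdims=True)
    col = s.mean(axis=1, keepdims=True)
    sd = s - row - col + s.mean()
    num = np.trace(sd) ** 2
    den = (k - 1) * np.sum(sd * sd)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def _f_p(F: float, df1: float, df2: float) -> float:
    return float(sst.f.sf(F, df1, df2))


def rm_anova_1way(table, effect: str = "condition") -> StatResult:
    """One-way repeated-measures ANOVA on a subjects x conditions table.

    Returns the within-subject F with Greenhouse-Geisser-corrected p and
    partial eta squared (SS_effect / (SS_effect + SS_error)).
    """
    x = _as_matrix(table)
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if n < 3:
        raise ValueError("insufficient replication: need at least 3 subjects")
    grand = x.mean()
    ss_cond = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = max(ss_tot - ss_cond - ss_subj, 0.0)
    df1, df2 = k - 1, (n - 1) * (k - 1)
    if ss_cond <= 0:
        return StatResult(effect, 0.0, df1, df2, 1.0, p_gg=1.0, eps_gg=_gg_epsilon(x),
                          effect_size=0.0, effect_size_name="eta2p", n=n)
    if ss_err <= 0:
        return StatResult(effect, float("inf"), df1, df2, 0.0, p_gg=0.0,
                          eps_gg=_gg_epsilon(x), effect_size=1.0,
                          effect_size_name="eta2p", n=n)
    F = (ss_cond / df1) / (ss_err / df2)
    eps = _gg_epsilon(x)
    return StatResult(
        effect=effect,
        statistic=float(F),
        df1=df1,
        df2=df2,
        p=_f_p(F, df1, df2),
        p_gg=_f_p(F, eps * df1, eps * df2),
        eps_gg=eps,
        effect_size=float(ss_cond / (ss_cond + ss_err)),
        effect_size_name="eta2p",
        n=n,
    )


def rm_anova_2way(data, factor_names: tuple[str, str] = ("A", "B")) -> dict[str, StatResult]:
    """Two-way fully-within-subject ANOVA on a (subjects, A, B) array.

    Each effect (A, B, A x B) is tested against its subject-by-effect
    interaction error term, with per-effect Greenhouse-Geisser correction.
    Returns a dict keyed by effect name.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 3:
        raise ValueError("expected a (subjects, A-levels, B-levels) array")
    if np.any(~np.isfinite(y)):
        raise ValueError("unbalanced design: missing cells are not allowed")
    n, a, b = y.shape
    if n < 3 or a < 2 or b < 2:
        raise ValueError("need >= 3 subjects and >= 2 levels per factor")
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_sa = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_sb = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    resid = (
        y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_sab = np.sum(resid**2)

    def _one(name, ss_eff, ss_err, df1, df2, scores):
        if ss_eff <= 0:
            return StatResult(name, 0.0, df1, df2, 1.0, p_gg=1.0, eps_gg=1.0,
                              effect_size=0.0, effect_size_name="eta2p", n=n)
        if ss_err <= 0:
            return StatResult(name, float("inf"), df1, df2, 0.0, p_gg=0.0, eps_gg=1.0,
                              effect_size=1.0, effect_size_name="eta2p", n=n)
        F = (ss_eff / df1) / (ss_err / df2)
        eps = 1.0 if scores is None else _gg_epsilon(scores)
        return StatResult(
            effect=name, statistic=float(F), df1=df1, df2=df2,
            p=_f_p(F, df1, df2), p_gg=_f_p(F, eps * df1, eps * df2), eps_gg=eps,
            effect_size=float(ss_eff / (ss_eff + ss_err)), effect_size_name="eta2p", n=n,
        )

    fa, fb = factor_names
    results = {
        fa: _one(fa, ss_a, ss_sa, a - 1, (n - 1) * (a - 1), m_sa),
        fb: _one(fb, ss_b, ss_sb, b - 1, (n - 1) * (b - 1), m_sb),
        f"{fa} x {fb}": _one(
            f"{fa} x {fb}", ss_ab, ss_sab, (a - 1) * (b - 1),
            (n - 1) * (a - 1) * (b - 1), None,
        ),
    }
    # interaction epsilon from the interaction contrast subspace of the cell
    # covariance (orthonormal Helmert contrasts per factor, Kronecker product)
    inter = results[f"{fa} x {fb}"]
    if np.isfinite(inter.statistic) and inter.statistic > 0:
        C = np.kron(helmert(a, full=False), helmert(b, full=False))
        S = np.cov(y.reshape(n, a * b), rowvar=False)
        M = C @ S @ C.T
        den = M.shape[0] * np.sum(M * M)
        eps = float(np.clip(np.trace(M) ** 2 / den, 1.0 / M.shape[0], 1.0)) if den > 0 else 1.0
        inter.eps_gg = eps
        inter.p_gg = _f_p(inter.statistic, eps * inter.df1, eps * inter.df2)
    return results


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotonicity enforced)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return np.clip(adj, 0.0, 1.0)


def pairwise_posthoc(
    table,
    condition_names: "list[str] | None" = None,
    method: str = "paired_t",
    correction: str = "fdr",
) -> list[StatResult]:
    """All pairwise within-subject comparisons with BH-FDR correction.

    ``method`` is ``paired_t`` (Cohen's d on the paired differences) or
    ``wilcoxon`` (rank-biserial effect size, mid-ranks for ties).
    """
    x = _as_matrix(table)
    n, k = x.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    names = condition_names or [f"cond-{i + 1}" for i in range(k)]
    results: list[StatResult] = []
    for i, j in combinations(range(k), 2):
        d = x[:, i] - x[:, j]
        label = f"{names[i]} vs {names[j]}"
        if method == "paired_t":
            sd = d.std(ddof=1)
            if sd == 0:
                if np.allclose(d, 0):
                    results.append(StatResult(label, 0.0, n - 1, None, 1.0,
                                              effect_size=0.0, effect_size_name="cohen_d", n=n))
                    continue
                raise ValueError(
                    f"zero-variance nonzero differences for {label}; use method='wilcoxon'"
                )
            t, p = sst.ttest_rel(x[:, i], x[:, j])
            results.append(StatResult(label, float(t), n - 1, None, float(p),
                                      effect_size=float(d.mean() / sd),
                                      effect_size_name="cohen_d", n=n))
        elif method == "wilcoxon":
            if np.allclose(d, 0):
                results.append(StatResult(label, 0.0, n, None, 1.0,
                                          effect_size=0.0, effect_size_name="rank_biserial", n=n))
                continue
            res = sst.wilcoxon(d, zero_method="wilcox", method="auto")
            nz = d[d != 0]
            ranks = sst.rankdata(np.abs(nz))
            w_pos = ranks[nz > 0].sum()
            w_neg = ranks[nz < 0].sum()
            rb = (w_pos - w_neg) / (w_pos + w_neg)
            results.append(StatResult(label, float(res.statistic), nz.size, None,
                                      float(res.pvalue), effect_size=float(rb),
                                      effect_size_name="rank_biserial", n=n))
        else:
            raise ValueError(f"unknown method {method!r}")
    if correction == "fdr":
        adj = fdr_bh([r.p for r in results])
        for r, a in zip(results, adj):
            r.p_adj = float(a)
    return results


def wilcoxon_vs_constant(values, c: float) -> StatResult:
    """Wilcoxon signed-rank test of ``values`` against the constant ``c``.

    Ties among |differences| use mid-ranks; zero differences are dropped
    (Wilcoxon's rule). Reports the normal-approximation z alongside the
    (exact when possible) p-value.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise ValueError("need at least 5 observations")
    d = v - c
    if np.allclose(d, 0):
        return StatResult("vs constant", 0.0, v.size, None, 1.0,
                          effect_size=0.0, effect_size_name="z", n=v.size)
    res = sst.wilcoxon(d, zero_method="wilcox", method="auto")
    nz = d[d != 0]
    n = nz.size
    ranks = sst.rankdata(np.abs(nz))
    w_pos = ranks[nz > 0].sum()
    mu = n * (n + 1) / 4.0
    # tie correction for the normal approximation
    _, counts = np.unique(ranks, return_counts=True)
    tie = np.sum(counts**3 - counts)
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie / 48.0)
    z = (w_pos - mu) / sigma if sigma > 0 else 0.0
    return StatResult("vs constant", float(z), n, None, float(res.pvalue),
                      effect_size=float(z), effect_size_name="z", n=v.size)


def mann_whitney(group_a, group_b) -> StatResult:
    """Mann-Whitney U test with rank-biserial effect size."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    res = sst.mannwhitneyu(a, b, alternative="two-sided")
    u = float(res.statistic)
    rb = 2.0 * u / (a.size * b.size) - 1.0
    return StatResult("group A vs B", u, a.size, b.size, float(res.pvalue),
                      effect_size=float(rb), effect_size_name="rank_biserial",
                      n=a.size + b.size)


def chain_adjacency(n_units: int) -> csr_matrix:
    """Adjacency of a 1-D chain (e.g. consecutive frequency bins)."""
    i = np.arange(n_units - 1)
    rows = np.concatenate([i, i + 1])
    cols = np.concatenate([i + 1, i])
    return csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n_units, n_units))


def _rm_f_units(data: np.ndarray) -> np.ndarray:
    """Vectorized one-way RM-ANOVA F over the trailing (units) axis."""
    n, k, _ = data.shape
    grand = data.mean(axis=(0, 1))
    c = data.mean(axis=0)
    s = data.mean(axis=1)
    ss_cond = n * np.sum((c - grand) ** 2, axis=0)
    ss_subj = k * np.sum((s - grand) ** 2, axis=0)
    ss_tot = np.sum((data - grand) ** 2, axis=(0, 1))
    ss_err = np.maximum(ss_tot - ss_cond - ss_subj, 0.0)
    df1, df2 = k - 1, (n - 1) * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_cond / df1) / (ss_err / df2)
    F = np.where(ss_err <= 0, np.where(ss_cond > 0, np.inf, 0.0), F)
    return F


def _clusters_from_mask(mask: np.ndarray, adjacency) -> list[np.ndarray]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    if adjacency is None:  # chain: contiguous runs
        breaks = np.flatnonzero(np.diff(idx) > 1)
        return np.split(idx, breaks + 1)
    sub = adjacency[idx][:, idx]
    n_comp, labels = connected_components(csr_matrix(sub), directed=False)
    return [idx[labels == c] for c in range(n_comp)]


def _max_cluster_mass(F: np.ndarray, f_crit: float, adjacency) -> float:
    best = 0.0
    for cl in _clusters_from_mask(F > f_crit, adjacency):
        mass = float(F[cl].sum())
        if mass > best:
            best = mass
    return best


def cluster_perm_F(
    data,
    adjacency=None,
    n_perm: int = 10000,
    cluster_alpha: float = 0.05,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-based permutation test of a condition effect over adjacent units.

    ``data`` is (subjects, conditions, units). A one-way repeated-measures F
    is computed per unit; units with F above the parametric critical value at
    ``cluster_alpha`` form clusters under ``adjacency`` (None = 1-D chain of
    consecutive units), with cluster mass = sum of F. Condition labels are
    shuffled within subject ``n_perm`` times and the maximum cluster mass of
    each shuffle builds the null; cluster p = (1 + #{null >= observed}) /
    (n_perm + 1), so p is never 0.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected (subjects, conditions, units)")
    n, k, u = x.shape
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse permutation p", stacklevel=2)
    if adjacency is not None:
        adjacency = csr_matrix(adjacency)
        if adjacency.shape != (u, u):
            raise ValueError("adjacency must be units x units")
    f_crit = float(sst.f.ppf(1.0 - cluster_alpha, k - 1, (n - 1) * (k - 1)))
    f_obs = _rm_f_units(x)
    obs_clusters = _clusters_from_mask(f_obs > f_crit, adjacency)
    obs_masses = [float(f_obs[cl].sum()) for cl in obs_clusters]

    rng = np.random.default_rng(seed)
    base = np.tile(np.arange(k), (n, 1))
    null = np.empty(n_perm)
    for p in range(n_perm):
        idx = rng.permuted(base, axis=1)
        xp = np.take_along_axis(x, idx[:, :, None], axis=1)
        null[p] = _max_cluster_mass(_rm_f_units(xp), f_crit, adjacency)

    clusters = []
    for cl, mass in zip(obs_clusters, obs_masses):
        p_val = float((1 + np.sum(null >= mass)) / (n_perm + 1))
        clusters.append((cl, mass, p_val))
    clusters.sort(key=lambda c: c[1], reverse=True)
    return ClusterResult(
        clusters=clusters, n_perm=n_perm, cluster_alpha=cluster_alpha,
        seed=seed, f_units=f_obs, f_crit=f_crit,
    )


def rmcorr(x, y, subjects) -> tuple[float, int, float]:
    """Repeated-measures correlation (common within-subject association).

    ANCOVA formulation: x and y are centered within subject, the correlation
    of the centered values gives the common slope's sign and magnitude, and
    df = N - k - 1 for k subjects with N total observations. Subjects with a
    single observation are dropped with a warning. Returns ``(r, df, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    subjects = np.asarray(subjects)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y, subjects = x[ok], y[ok], subjects[ok]
    uniq, counts = np.unique(subjects, return_counts=True)
    singles = uniq[counts < 2]
    if singles.size:
        warnings.warn(f"dropping {singles.size} subject(s) with < 2 observations",
                      stacklevel=2)
        keep = ~np.isin(subjects, singles)
        x, y, subjects = x[keep], y[keep], subjects[keep]
        uniq = np.unique(subjects)
    k = uniq.size
    if k < 3:
        raise ValueError("need >= 2 observations per subject for >= 3 subjects")
    xc = x.copy()
    yc = y.copy()
    for s in uniq:
        m = subjects == s
        xc[m] -= xc[m].mean()
        yc[m] -= yc[m].mean()
    sxx = np.sum(xc**2)
    syy = np.sum(yc**2)
    if sxx <= 0 or syy <= 0:
        return float("nan"), int(x.size - k - 1), float("nan")
    r = float(np.sum(xc * yc) / np.sqrt(sxx * syy))
    df = int(x.size - k - 1)
    if df < 1:
        return r, df, float("nan")
    r_cl = min(abs(r), 1.0 - 1e-15)
    t = abs(r) * np.sqrt(df / (1.0 - r_cl**2))
    p = float(2.0 * sst.t.sf(t, df))
    return r, df, p


def dominance(
    corr: "pd.DataFrame | np.ndarray",
    outcome: "str | int" = -1,
) -> tuple[dict, float]:
    """General dominance weights from a correlation matrix.

    For predictors S, the model R^2 is ``r_yS' R_SS^-1 r_yS``. The general
    dominance of predictor i averages, over subset sizes, the mean increment
    in R^2 from adding i to subsets of that size; the weights sum to the
    full-model R^2. Returns ``({predictor: dominance}, full_R2)``.
    """
    if isinstance(corr, pd.DataFrame):
        names = list(corr.columns)
        R = corr.to_numpy(dtype=float)
    else:
        R = np.asarray(corr, dtype=float)
        names = [f"x{i}" for i in range(R.shape[0])]
    if R.shape[0] != R.shape[1] or not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("correlation matrix must be square and symmetric")
    y_idx = names.index(outcome) if isinstance(outcome, str) else (outcome % R.shape[0])
    pred_idx = [i for i in range(R.shape[0]) if i != y_idx]
    preds = [names[i] for i in pred_idx]
    p = len(pred_idx)

    def r2_of(subset: tuple[int, ...]) -> float:
        if not subset:
            return 0.0
        ids = [pred_idx[i] for i in subset]
        rss = R[np.ix_(ids, ids)]
        rys = R[ids, y_idx]
        try:
            sol = np.linalg.solve(rss, rys)
        except np.linalg.LinAlgError as e:
            raise ValueError(
                f"singular predictor subset {[names[i] for i in ids]}"
            ) from e
        return float(rys @ sol)

    cache = {s: r2_of(s) for m in range(1, p + 1) for s in combinations(range(p), m)}
    cache[()] = 0.0
    dom = {}
    for i in range(p):
        by_size = []
        others = [j for j in range(p) if j != i]
        for size in range(p):
            incs = [
                cache[tuple(sorted(s + (i,)))] - cache[s]
                for s in combinations(others, size)
            ]
            by_size.append(np.mean(incs))
        dom[preds[i]] = float(np.mean(by_size))
    full = cache[tuple(range(p))]
    return dom, float(full)
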