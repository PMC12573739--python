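"""Group statistics: cluster-mass permutation tests, gated two-sample
comparisons, and rank correlations with Bonferroni correction.

Cluster tests threshold pointwise t-statistics at the two-sided p <= 0.05
quantile of the t distribution, merge suprathreshold members of the same
sign that are adjacent (an electrode neighbourhood graph, or consecutive
time points), and score each cluster by the sum of its t-values.  Corrected
p-values come from the permutation null of the maximum absolute cluster
mass: sign flips for one-sample designs, group-label exchange for
two-sample designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats


@dataclass
class TestResult:
    """Outcome of a two-sample, paired, or correlation test."""

    statistic: float
    p: float
    effect: float
    method: str
    z: float | None = None
    ci: tuple[float, float] | None = None


@dataclass
class Cluster:
    members: np.ndarray  # indices (electrodes or time points)
    mass: float
    p_corrected: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_obs: np.ndarray
    threshold: float
    n_permutations: int

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_corrected < 0.05]

    @property
    def t_max(self) -> float:
        """Largest |t| within any significant cluster (nan if none)."""
        sig = self.significant
        if not sig:
            return float("nan")
        return float(
            max(np.max(np.abs(self.t_obs[c.members])) for c in sig)
        )


def _components(nodes: np.ndarray, adjacency: np.ndarray) -> list[np.ndarray]:
    """Connected components of the subgraph induced by ``nodes``."""
    node_set = set(int(i) for i in nodes)
    seen: set[int] = set()
    comps = []
    for start in nodes:
        start = int(start)
        if start in seen:
            continue
        stack = [start]
        comp = []
        seen.add(start)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in np.where(adjacency[u])[0]:
                v = int(v)
                if v in node_set and v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append(np.array(sorted(comp)))
    return comps


def _clusters_signed(t: np.ndarray, thr: float, adjacency: np.ndarray):
    """Same-sign suprathreshold clusters and their masses."""
    out = []
    for sign in (1, -1):
        nodes = np.where(sign * t > thr)[0]
        if len(nodes) == 0:
            continue
        for comp in _components(nodes, adjacency):
            out.append((comp, float(t[comp].sum())))
    return out


def _max_mass(t: np.ndarray, thr: float, adjacency: np.ndarray) -> float:
    clusters = _clusters_signed(t, thr, adjacency)
    if not clusters:
        return 0.0
    return max(abs(m) for _, m in clusters)


def _chain_adjacency(n: int) -> np.ndarray:
    adj = np.zeros((n, n), dtype=bool)
    idx = np.arange(n - 1)
    adj[idx, idx + 1] = adj[idx + 1, idx] = True
    return adj


def cluster_perm_electrodes(
    values: np.ndarray,
    adjacency: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    cluster_alpha: float = 0.05,
) -> ClusterResult:
    """One-sample cluster-mass permutation test across electrodes.

    ``values`` is subjects x electrodes; the null of zero mean is simulated
    by random sign flips of whole subjects.  Disconnected adjacency graphs
    are allowed.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be subjects x electrodes")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse permutation null")
    S, E = values.shape
    adjacency = np.asarray(adjacency, dtype=bool)
    if adjacency.shape != (E, E):
        raise ValueError("adjacency must be n_electrodes x n_electrodes")
    thr = spstats.t.ppf(1 - cluster_alpha / 2, S - 1)

    ex2 = (values**2).sum(axis=0)

    def tstat(mean_vec):
        var = (ex2 - S * mean_vec**2) / (S - 1)
        sd = np.sqrt(np.clip(var, 1e-300, None))
        return mean_vec / (sd / np.sqrt(S))

    t_obs = tstat(values.mean(axis=0))
    obs_clusters = _clusters_signed(t_obs, thr, adjacency)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, S))
    null_means = signs @ values / S
    null_max = np.empty(n_perm)
    for i in range(n_perm):
        null_max[i] = _max_mass(tstat(null_means[i]), thr, adjacency)
    clusters = [
        Cluster(
            members=comp,
            mass=mass,
            p_corrected=float((1 + np.sum(null_max >= abs(mass))) / (n_perm + 1)),
        )
        for comp, mass in obs_clusters
    ]
    return ClusterResult(
        clusters=clusters, t_obs=t_obs, threshold=thr, n_permutations=n_perm
    )


def cluster_perm_time(
    env_a: np.ndarray,
    env_b: np.ndarray,
    lags_ms: np.ndarray,
    window_ms: tuple[float, float] = (0.0, 40.0),
    n_perm: int = 10000,
    seed: int = 0,
    cluster_alpha: float = 0.05,
) -> ClusterResult:
    """Two-sample cluster-mass permutation test over contiguous time lags.

    ``env_a``/``env_b`` are subjects x lags (e.g. TRF Hilbert envelopes);
    the analysis is restricted to ``window_ms`` and the permutation null
    exchanges group labels.  Returned cluster members index into the
    windowed lag axis (see ``ClusterResult.t_obs`` alignment with
    ``lags_ms[window mask]``).
    """
    env_a = np.asarray(env_a, dtype=float)
    env_b = np.asarray(env_b, dtype=float)
    lags_ms = np.asarray(lags_ms, dtype=float)
    if env_a.shape[1] != env_b.shape[1] or env_a.shape[1] != len(lags_ms):
        raise ValueError("groups must share the lag grid")
    sel = (lags_ms >= window_ms[0]) & (lags_ms <= window_ms[1])
    if not sel.any():
        raise ValueError("analysis window outside the lag range")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse permutation null")
    a = env_a[:, sel]
    b = env_b[:, sel]
    na, nb = len(a), len(b)
    X = np.vstack([a, b])
    L = X.shape[1]
    df = na + nb - 2
    thr = spstats.t.ppf(1 - cluster_alpha / 2, df)
    sum_all = X.sum(axis=0)
    ssq_all = (X**2).sum(axis=0)

    def tstat(sum_a, ssq_a):
        sum_b = sum_all - sum_a
        ssq_b = ssq_all - ssq_a
        ma, mb = sum_a / na, sum_b / nb
        ssa = ssq_a - na * ma**2
        ssb = ssq_b - nb * mb**2
        sp2 = np.clip((ssa + ssb) / df, 1e-300, None)
        return (ma - mb) / np.sqrt(sp2 * (1 / na + 1 / nb))

    chain = _chain_adjacency(L)
    t_obs = tstat(a.sum(axis=0), (a**2).sum(axis=0))
    obs_clusters = _clusters_signed(t_obs, thr, chain)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for i in range(n_perm):
        pick = rng.choice(na + nb, na, replace=False)
        null_max[i] = _max_mass(
            tstat(X[pick].sum(axis=0), (X[pick] ** 2).sum(axis=0)), thr, chain
        )
    clusters = [
        Cluster(
            members=comp,
            mass=mass,
            p_corrected=float((1 + np.sum(null_max >= abs(mass))) / (n_perm + 1)),
        )
        for comp, mass in obs_clusters
    ]
    return ClusterResult(
        clusters=clusters, t_obs=t_obs, threshold=thr, n_permutations=n_perm
    )


def gated_two_sample(x: np.ndarray, y: np.ndarray, normality_alpha: float = 0.05) -> TestResult:
    """Normality-gated group comparison.

    Shapiro-Wilk on each sample: if both look normal (p > alpha), Welch's
    t-test with Cohen's d and a CI on the mean difference; otherwise (or if
    a sample is constant) a Mann-Whitney U test with rank-biserial r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs n >= 3")
    normal = True
    for s in (x, y):
        if np.ptp(s) == 0:
            normal = False  # Shapiro undefined on constant data
            break
        if spstats.shapiro(s).pvalue <= normality_alpha:
            normal = False
            break
    if normal:
        res = spstats.ttest_ind(x, y, equal_var=False)
        n1, n2 = len(x), len(y)
        s1, s2 = x.var(ddof=1), y.var(ddof=1)
        sp = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
        d = (x.mean() - y.mean()) / sp if sp > 0 else 0.0
        se = np.sqrt(s1 / n1 + s2 / n2)
        dfw = (s1 / n1 + s2 / n2) ** 2 / (
            (s1 / n1) ** 2 / (n1 - 1) + (s2 / n2) ** 2 / (n2 - 1)
        )
        tcrit = spstats.t.ppf(0.975, dfw)
        diff = x.mean() - y.mean()
        return TestResult(
            statistic=float(res.statistic),
            p=float(res.pvalue),
            effect=float(d),
            method="welch-t",
            ci=(float(diff - tcrit * se), float(diff + tcrit * se)),
        )
    res = spstats.mannwhitneyu(x, y, alternative="two-sided")
    n1, n2 = len(x), len(y)
    mu = n1 * n2 / 2
    sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
    z = (res.statistic - mu) / sigma if sigma > 0 else 0.0
    return TestResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        effect=float(1 - 2 * res.statistic / (n1 * n2)),
        method="mann-whitney-u",
        z=float(z),
    )


def spearman_with_bonferroni(
    pairs: list[tuple[np.ndarray, np.ndarray]], m: int | None = None
) -> list[TestResult]:
    """Spearman rank correlations with Bonferroni-adjusted p-values.

    ``m`` is the number of comparisons in the family (default:
    ``len(pairs)``); adjusted p = min(1, m * p).  Ties use average ranks.
    """
    if m is None:
        m = len(pairs)
    results = []
    for x, y in pairs:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) != len(y) or len(x) < 4:
            raise ValueError("each pair needs matched n >= 4")
        rho, p = spstats.spearmanr(x, y)
        results.append(
            TestResult(
                statistic=float(rho),
                p=float(min(1.0, m * p)),
                effect=float(rho),
                method="spearman",
            )
        )
    return results
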