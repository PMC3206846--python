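"""Alpha diversity, rarefaction, Bray-Curtis, NMDS, ANOSIM and G tests.

Conventions follow the classical clone-library literature: Shannon H' in
natural log, evenness J = H'/ln(S_obs), classic Chao1 with the
bias-corrected fallback when no doubletons exist, analytic hypergeometric
rarefaction, and Bray-Curtis on square-root-transformed relative
abundances. ANOSIM uses mid-rank ties and the add-one permutation p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2, rankdata

__all__ = [
    "AlphaDiversityResult",
    "AnosimResult",
    "GTestResult",
    "OrdinationResult",
    "alpha_diversity",
    "rarefaction_curve",
    "bray_curtis",
    "nmds",
    "anosim",
    "gtest_independence",
]


@dataclass(frozen=True)
class AlphaDiversityResult:
    S_obs: int
    F1: int
    F2: int
    S_chao1: float
    H_prime: float
    J: float | None  # undefined for a single-OTU sample


def alpha_diversity(counts: Sequence[int] | np.ndarray) -> AlphaDiversityResult:
    """Observed richness, Chao1, Shannon H' (nats) and evenness J."""
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all-zero count vector")
    s_obs = int(c.size)
    f1 = int(np.sum(c == 1))
    f2 = int(np.sum(c == 2))
    if f2 > 0:
        chao1 = s_obs + f1 * f1 / (2.0 * f2)
    else:
        chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    p = c / c.sum()
    h = float(-np.sum(p * np.log(p)))
    j = h / math.log(s_obs) if s_obs >= 2 else None
    return AlphaDiversityResult(s_obs, f1, f2, float(chao1), h, j)


def rarefaction_curve(
    counts: Sequence[int] | np.ndarray, depths: Sequence[int]
) -> np.ndarray:
    """Analytic expected richness E[S_m] at each subsampling depth m.

    E[S_m] = sum_i 1 - C(N - N_i, m) / C(N, m), the hypergeometric
    probability that species i appears in a uniform draw of m individuals.
    """
    c = np.asarray(counts, dtype=int)
    c = c[c > 0]
    n = int(c.sum())
    out = np.empty(len(depths), dtype=float)
    for k, m in enumerate(depths):
        if not 0 < m <= n:
            raise ValueError(f"depth {m} outside (0, {n}]")
        # log-gamma form of C(N-Ni, m)/C(N, m) avoids overflow
        log_denom = _log_comb(n, m)
        miss = np.zeros(c.shape, dtype=float)
        feasible = (n - c) >= m
        if feasible.any():
            miss[feasible] = np.exp(_log_comb(n - c[feasible], m) - log_denom)
        out[k] = float(np.sum(1.0 - miss))
    return out


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    return (
        np.vectorize(math.lgamma)(n + 1)
        - math.lgamma(k + 1)
        - np.vectorize(math.lgamma)(n - k + 1)
    )


def bray_curtis(
    matrix: pd.DataFrame | np.ndarray,
    transform: Literal["sqrt", "none"] = "sqrt",
    relative: bool = True,
) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between sample rows.

    Rows are converted to relative abundances (unless ``relative=False``),
    optionally square-root transformed. A pair of all-zero rows has
    distance 0 by convention.
    """
    if isinstance(matrix, pd.DataFrame):
        labels = list(matrix.index)
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        labels = list(range(x.shape[0]))
    if np.any(x < 0):
        raise ValueError("negative abundances")
    if relative:
        sums = x.sum(axis=1, keepdims=True)
        x = np.divide(x, sums, out=np.zeros_like(x), where=sums > 0)
    if transform == "sqrt":
        x = np.sqrt(x)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    d = squareform(pdist(x, metric="braycurtis"))
    d = np.nan_to_num(d, nan=0.0)  # all-zero pairs
    return pd.DataFrame(d, index=labels, columns=labels)


@dataclass(frozen=True)
class OrdinationResult:
    coordinates: pd.DataFrame
    stress: float
    n_restarts: int
    seed: int


def nmds(
    d: pd.DataFrame,
    k: int = 2,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    eps: float = 1e-7,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1, best of random restarts."""
    from sklearn.manifold import MDS

    dm = d.to_numpy(dtype=float)
    if dm.shape[0] < k + 1:
        raise ValueError("need at least k+1 samples")
    if np.allclose(dm, dm.flat[1] * (1 - np.eye(len(dm)))):
        # degenerate: all off-diagonal distances equal; any configuration fits
        rng = np.random.default_rng(seed)
        coords = rng.standard_normal((len(dm), k))
        return OrdinationResult(
            pd.DataFrame(coords, index=d.index), 0.0, n_restarts, seed
        )
    model = MDS(
        n_components=k,
        metric=False,
        dissimilarity="precomputed",
        n_init=n_restarts,
        max_iter=max_iter,
        eps=eps,
        random_state=seed,
        normalized_stress=True,
    )
    coords = model.fit_transform(dm)
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=d.index),
        stress=float(model.stress_),
        n_restarts=n_restarts,
        seed=seed,
    )


@dataclass(frozen=True)
class AnosimResult:
    R: float
    p: float
    r_between: float
    r_within: float
    M: int
    n_perm: int


def _anosim_r(ranks: np.ndarray, between: np.ndarray, M: int) -> tuple[float, float, float]:
    r_b = float(ranks[between].mean())
    r_w = float(ranks[~between].mean())
    return (r_b - r_w) / (M / 2.0), r_b, r_w


def anosim(
    d: pd.DataFrame,
    groups: Mapping[str, str] | Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> AnosimResult:
    """Rank-based test of between- vs within-group dissimilarity.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    mid-rank ties over all M = n(n-1)/2 pairs; p is the add-one one-sided
    permutation tail (>= observed R) under random label reassignment.
    ``exhaustive=True`` enumerates every distinct labeling instead (small n
    only) and returns the exact tail fraction.
    """
    labels = list(d.index)
    if isinstance(groups, Mapping):
        g = np.array([groups[s] for s in labels])
    else:
        g = np.asarray(list(groups))
    uniq, counts = np.unique(g, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    small = uniq[counts < 2]
    if small.size:
        raise ValueError(f"group(s) with a single sample: {list(small)}")

    dm = d.to_numpy(dtype=float)
    iu = np.triu_indices(len(labels), k=1)
    ranks = rankdata(dm[iu])
    M = len(ranks)
    between = g[iu[0]] != g[iu[1]]
    r_obs, r_b, r_w = _anosim_r(ranks, between, M)

    if exhaustive:
        import itertools

        seen = set()
        hits = total = 0
        for perm in itertools.permutations(g):
            if perm in seen:
                continue
            seen.add(perm)
            total += 1
            arr = np.asarray(perm)
            b = arr[iu[0]] != arr[iu[1]]
            r_perm, _, _ = _anosim_r(ranks, b, M)
            if r_perm >= r_obs:
                hits += 1
        return AnosimResult(R=r_obs, p=hits / total, r_between=r_b,
                            r_within=r_w, M=M, n_perm=total)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(g)
        b = perm[iu[0]] != perm[iu[1]]
        r_perm, _, _ = _anosim_r(ranks, b, M)
        if r_perm >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return AnosimResult(R=r_obs, p=p, r_between=r_b, r_within=r_w, M=M, n_perm=n_perm)


def pairwise_anosim(
    d: pd.DataFrame,
    groups: Mapping[str, str],
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Post-hoc pairwise ANOSIM with raw and Bonferroni-adjusted p-values."""
    import itertools

    uniq = sorted(set(groups.values()))
    pairs = list(itertools.combinations(uniq, 2))
    rows = []
    for i, (a, b) in enumerate(pairs):
        keep = [s for s in d.index if groups[s] in (a, b)]
        sub = d.loc[keep, keep]
        res = anosim(sub, {s: groups[s] for s in keep}, n_perm=n_perm, seed=seed + i)
        rows.append((a, b, res.R, res.p, min(1.0, res.p * len(pairs))))
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "R", "p", "p_bonferroni"]
    )


@dataclass(frozen=True)
class GTestResult:
    G: float
    df: int
    p: float
    observed: np.ndarray
    expected: np.ndarray


def gtest_independence(table: pd.DataFrame | np.ndarray) -> GTestResult:
    """Likelihood-ratio (G) test of independence on an r x c count table."""
    O = np.asarray(table, dtype=float)
    if O.size == 0:
        raise ValueError("empty table")
    if np.any(O.sum(axis=0) <= 0) or np.any(O.sum(axis=1) <= 0):
        raise ValueError("rows and columns must each have positive totals")
    E = np.outer(O.sum(axis=1), O.sum(axis=0)) / O.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(O > 0, O * np.log(O / E), 0.0)
    g = float(2.0 * terms.sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    return GTestResult(G=g, df=df, p=float(chi2.sf(g, df)), observed=O, expected=E)
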