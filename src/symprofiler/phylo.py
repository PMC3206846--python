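"""Tree- and distance-based community comparison statistics.

Implements the classical toolkit for asking whether bacterial lineages sort
by host: Tajima-Nei (1984) pairwise distances, the P-test (parsimony
lineage sorting), NRI/NTI phylogenetic dispersion z-scores, LIBSHUFF
coverage-curve library comparison, and hierarchical AMOVA with an F_ST
permutation test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io import SequenceRecord

__all__ = [
    "tajima_nei_distance",
    "tajima_nei_matrix",
    "fitch_length",
    "ptest",
    "nri_nti",
    "libshuff",
    "amova",
    "PhyloDispersionResult",
    "LibshuffResult",
    "AmovaResult",
    "patristic_matrix",
]

_BASES = "ACGT"


def tajima_nei_distance(a: SequenceRecord, b: SequenceRecord) -> float:
    """Tajima-Nei (1984) evolutionary distance between two aligned sequences.

    d = -b_hat * ln(1 - p / b_hat), with
    b_hat = (1 - sum_i g_i^2 + p^2 / h) / 2 and
    h = sum_{i<j} x_ij^2 / (2 g_i g_j),
    where p is the proportion of mismatched sites, g_i the mean base
    frequencies of the pair, and x_ij the frequency of sites showing the
    unordered base pair {i, j}. Columns containing gaps or ambiguity codes
    are pairwise-deleted. Saturated pairs (p >= b_hat) return +inf.
    """
    if len(a.sequence) != len(b.sequence):
        raise ValueError("sequences must be pre-aligned to equal length")
    sa, sb = a.sequence, b.sequence
    pairs = [
        (x, y) for x, y in zip(sa, sb) if x in _BASES and y in _BASES
    ]
    n = len(pairs)
    if n == 0:
        raise ValueError("no comparable columns after pairwise deletion")
    diffs = [(x, y) for x, y in pairs if x != y]
    p = len(diffs) / n
    if p == 0.0:
        return 0.0
    freq = {base: 0.0 for base in _BASES}
    for x, y in pairs:
        freq[x] += 0.5
        freq[y] += 0.5
    g = np.array([freq[base] / n for base in _BASES])
    x_ij = {}
    for x, y in diffs:
        key = tuple(sorted((x, y)))
        x_ij[key] = x_ij.get(key, 0.0) + 1.0 / n
    h = 0.0
    for (i, j), x in x_ij.items():
        gi = g[_BASES.index(i)]
        gj = g[_BASES.index(j)]
        h += x * x / (2.0 * gi * gj)
    b_hat = 0.5 * (1.0 - float(np.sum(g * g)) + p * p / h)
    if p >= b_hat:
        return math.inf
    return -b_hat * math.log(1.0 - p / b_hat)


def tajima_nei_matrix(seqs: Sequence[SequenceRecord]) -> pd.DataFrame:
    ids = [s.id for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = tajima_nei_distance(seqs[i], seqs[j])
    return pd.DataFrame(d, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# P-test


def fitch_length(tree: dendropy.Tree, states: Mapping[str, str]) -> int:
    """Parsimony length of a discrete character on the tree topology.

    Hartigan's generalization of the Fitch set recurrence, exact for
    multifurcating nodes: a node keeps the states of maximal child support
    and pays one change per child outside that majority.
    """
    changes = 0
    node_sets: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node_sets[node] = frozenset([states[node.taxon.label]])
            continue
        count: dict[str, int] = {}
        kids = node.child_nodes()
        for child in kids:
            for s in node_sets[child]:
                count[s] = count.get(s, 0) + 1
        kmax = max(count.values())
        node_sets[node] = frozenset(s for s, k in count.items() if k == kmax)
        changes += len(kids) - kmax
    return changes


def ptest(
    tree: dendropy.Tree,
    labels: Mapping[str, str],
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> tuple[int, float]:
    """Phylogenetic lineage-sorting test.

    Observed parsimony changes of the source label on the tree are compared
    to random tip-label permutations; small observed values mean lineages
    sort by source. Returns (observed changes, p). ``exhaustive=True``
    enumerates every distinct labeling (small trees only) and returns the
    exact tail fraction.
    """
    tips = [t.label for t in tree.taxon_namespace]
    srcs = [labels[t] for t in tips]
    if len(set(srcs)) < 2:
        raise ValueError("need at least two sources")
    obs = fitch_length(tree, labels)
    if exhaustive:
        seen = set()
        hits = total = 0
        for perm in itertools.permutations(srcs):
            if perm in seen:
                continue
            seen.add(perm)
            total += 1
            if fitch_length(tree, dict(zip(tips, perm))) <= obs:
                hits += 1
        return obs, hits / total
    rng = np.random.default_rng(seed)
    hits = 0
    arr = list(srcs)
    for _ in range(n_perm):
        rng.shuffle(arr)
        if fitch_length(tree, dict(zip(tips, arr))) <= obs:
            hits += 1
    return obs, (1 + hits) / (1 + n_perm)


# ---------------------------------------------------------------------------
# NRI / NTI


def patristic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    labels = [t.label for t in taxa]
    n = len(taxa)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return pd.DataFrame(d, index=labels, columns=labels)


@dataclass(frozen=True)
class PhyloDispersionResult:
    MPD_obs: float
    MNTD_obs: float
    null_mean: dict = field(default_factory=dict)
    null_sd: dict = field(default_factory=dict)
    NRI: float | None = None
    NTI: float | None = None
    n_null: int = 0
    null_model: str = "tip-shuffle"


def _mpd(d: np.ndarray, idx: Sequence[int]) -> float:
    sub = d[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].mean())


def _mntd(d: np.ndarray, idx: Sequence[int]) -> float:
    sub = d[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def nri_nti(
    tree: dendropy.Tree,
    community: Sequence[str],
    pool: Sequence[str] | None = None,
    null_model: str = "tip-shuffle",
    n_null: int = 999,
    seed: int = 0,
) -> PhyloDispersionResult:
    """Net relatedness and nearest-taxon indices against a tip-shuffle null.

    Positive values indicate phylogenetic clustering (observed distances
    smaller than random draws of equal size from the pool). The null
    standard deviation uses the sample (n-1) denominator; a degenerate null
    (sd = 0) leaves the index undefined. ``null_model="exhaustive"``
    enumerates all subsets of the pool.
    """
    dmat = patristic_matrix(tree)
    labels = list(dmat.index)
    pool = list(pool) if pool is not None else labels
    community = list(community)
    if not set(community) <= set(pool) <= set(labels):
        raise ValueError("require community <= pool <= tree tips")
    if len(community) < 2:
        raise ValueError("community needs at least two members")
    pos = {t: i for i, t in enumerate(labels)}
    d = dmat.to_numpy()
    obs_idx = [pos[t] for t in community]
    mpd_obs = _mpd(d, obs_idx)
    mntd_obs = _mntd(d, obs_idx)

    pool_idx = [pos[t] for t in pool]
    k = len(community)
    if null_model == "exhaustive":
        draws = [list(c) for c in itertools.combinations(pool_idx, k)]
    elif null_model == "tip-shuffle":
        rng = np.random.default_rng(seed)
        draws = [list(rng.choice(pool_idx, size=k, replace=False)) for _ in range(n_null)]
    else:
        raise ValueError(f"unknown null model {null_model!r}")
    null_mpd = np.array([_mpd(d, idx) for idx in draws])
    null_mntd = np.array([_mntd(d, idx) for idx in draws])

    def z(obs: float, null: np.ndarray) -> float | None:
        sd = float(null.std(ddof=1)) if len(null) > 1 else 0.0
        if sd <= 1e-12 * max(1.0, abs(float(null.mean()))):  # degenerate null
            return None
        return -(obs - float(null.mean())) / sd

    return PhyloDispersionResult(
        MPD_obs=mpd_obs,
        MNTD_obs=mntd_obs,
        null_mean={"MPD": float(null_mpd.mean()), "MNTD": float(null_mntd.mean())},
        null_sd={
            "MPD": float(null_mpd.std(ddof=1)) if len(null_mpd) > 1 else 0.0,
            "MNTD": float(null_mntd.std(ddof=1)) if len(null_mntd) > 1 else 0.0,
        },
        NRI=z(mpd_obs, null_mpd),
        NTI=z(mntd_obs, null_mntd),
        n_null=len(draws),
        null_model=null_model,
    )


# ---------------------------------------------------------------------------
# LIBSHUFF


@dataclass(frozen=True)
class LibshuffResult:
    grid: np.ndarray
    coverage_hom: np.ndarray  # C_X(D)
    coverage_het: np.ndarray  # C_XY(D)
    delta_c: float
    p: float | None = None


def _coverage_curves(
    d: np.ndarray, ia: np.ndarray, ib: np.ndarray, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    sub = d[np.ix_(ia, ia)].copy()
    np.fill_diagonal(sub, np.inf)
    nn_hom = sub.min(axis=1)
    nn_het = d[np.ix_(ia, ib)].min(axis=1)
    c_hom = (nn_hom[None, :] <= grid[:, None]).mean(axis=1)
    c_het = (nn_het[None, :] <= grid[:, None]).mean(axis=1)
    # one-sided Cramer-von Mises sum: only a coverage *deficit* of Y with
    # respect to X signals distinct libraries, so a library covered better
    # by the other than by itself (e.g. an exact duplicate) scores zero
    gap = np.clip(c_hom - c_het, 0.0, None)
    return c_hom, c_het, float(np.sum(gap**2))


def libshuff(
    dist: pd.DataFrame,
    lib_a: Sequence[str],
    lib_b: Sequence[str],
    grid: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> dict[str, LibshuffResult]:
    """Directed LIBSHUFF comparisons of two sequence libraries.

    Homologous coverage C_X(D) is the fraction of X members with another X
    member within distance D; heterologous C_XY(D) substitutes the other
    library. Delta C_XY sums the squared positive coverage deficit
    (C_X - C_XY where positive) over the distance grid; the
    p-value shuffles sequences between libraries (add-one convention).
    Returns results keyed "A_vs_B" and "B_vs_A".
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 0.50 + 1e-12, 0.01), 4)
    grid = np.asarray(grid, dtype=float)
    lib_a, lib_b = list(lib_a), list(lib_b)
    if set(lib_a) & set(lib_b):
        raise ValueError("libraries must be disjoint")
    if min(len(lib_a), len(lib_b)) < 2:
        raise ValueError("each library needs at least two sequences")
    pos = {t: i for i, t in enumerate(dist.index)}
    d = dist.to_numpy(dtype=float)
    ia = np.array([pos[t] for t in lib_a])
    ib = np.array([pos[t] for t in lib_b])

    obs = {}
    for key, (x, y) in {"A_vs_B": (ia, ib), "B_vs_A": (ib, ia)}.items():
        obs[key] = _coverage_curves(d, x, y, grid)

    rng = np.random.default_rng(seed)
    hits = {"A_vs_B": 0, "B_vs_A": 0}
    combined = np.concatenate([ia, ib])
    for _ in range(n_perm):
        perm = rng.permutation(combined)
        pa, pb = perm[: len(ia)], perm[len(ia):]
        for key, (x, y) in {"A_vs_B": (pa, pb), "B_vs_A": (pb, pa)}.items():
            _, _, dc = _coverage_curves(d, x, y, grid)
            if dc >= obs[key][2]:
                hits[key] += 1
    return {
        key: LibshuffResult(
            grid=grid,
            coverage_hom=obs[key][0],
            coverage_het=obs[key][1],
            delta_c=obs[key][2],
            p=(1 + hits[key]) / (1 + n_perm),
        )
        for key in obs
    }


# ---------------------------------------------------------------------------
# AMOVA


@dataclass(frozen=True)
class AmovaResult:
    sigma_among_groups: float
    sigma_among_samples: float
    sigma_within: float
    F_ST: float
    p: float
    n_perm: int
    degenerate: bool = False
    design: str = "three-level"


def _ssd(d2: np.ndarray, idx: Sequence[int]) -> float:
    sub = d2[np.ix_(idx, idx)]
    n = len(idx)
    iu = np.triu_indices(n, k=1)
    return float(sub[iu].sum()) / n


def _amova_fst(
    d2: np.ndarray,
    sample_idx: Mapping[str, list[int]],
    groups: Mapping[str, list[str]],
) -> tuple[float, tuple[float, float, float]]:
    """Excoffier-style three-level variance decomposition from squared
    distances; returns F_ST (among-group share of total variance) and the
    (sigma_a, sigma_b, sigma_c) components."""
    all_idx = [i for s in sample_idx.values() for i in s]
    n_total = len(all_idx)
    n_samples = sum(1 for s in sample_idx.values() if s)
    n_groups = len(groups)

    ssd_total = _ssd(d2, all_idx)
    ssd_ws = sum(_ssd(d2, idx) for idx in sample_idx.values() if len(idx) > 0)
    ssd_wg = 0.0
    group_sizes = {}
    for gname, samples in groups.items():
        gidx = [i for s in samples for i in sample_idx[s]]
        group_sizes[gname] = len(gidx)
        ssd_wg += _ssd(d2, gidx)
    ssd_as = ssd_wg - ssd_ws
    ssd_ag = ssd_total - ssd_wg

    df_ag = n_groups - 1
    df_as = n_samples - n_groups
    df_ws = n_total - n_samples

    msd_ws = ssd_ws / df_ws if df_ws else 0.0
    msd_as = ssd_as / df_as if df_as else 0.0
    msd_ag = ssd_ag / df_ag if df_ag else 0.0

    sizes = {s: len(idx) for s, idx in sample_idx.items()}
    sum_ni2_by_group = {
        g: sum(sizes[s] ** 2 for s in samples) for g, samples in groups.items()
    }
    # coefficients for unbalanced designs (Excoffier, Smouse & Quattro)
    n_prime = (
        (n_total - sum(sum_ni2_by_group[g] / group_sizes[g] for g in groups))
        / df_as
        if df_as
        else 0.0
    )
    n_dprime = (
        (
            sum(sum_ni2_by_group[g] / group_sizes[g] for g in groups)
            - sum(sizes[s] ** 2 for s in sizes) / n_total
        )
        / df_ag
    )
    n_tprime = (
        n_total - sum(group_sizes[g] ** 2 for g in groups) / n_total
    ) / df_ag

    sigma_c = msd_ws
    sigma_b = (msd_as - sigma_c) / n_prime if n_prime else 0.0
    sigma_a = (msd_ag - sigma_c - n_dprime * sigma_b) / n_tprime
    total = sigma_a + sigma_b + sigma_c
    fst = sigma_a / total if total > 0 else 0.0
    return fst, (sigma_a, sigma_b, sigma_c)


def _amova_fst2(
    d2: np.ndarray, group_idx: Mapping[str, list[int]]
) -> tuple[float, tuple[float, float]]:
    """Two-level decomposition: sequences within groups."""
    all_idx = [i for idx in group_idx.values() for i in idx]
    n_total = len(all_idx)
    n_groups = len(group_idx)
    ssd_total = _ssd(d2, all_idx)
    ssd_wg = sum(_ssd(d2, idx) for idx in group_idx.values())
    ssd_ag = ssd_total - ssd_wg
    df_ag = n_groups - 1
    df_wg = n_total - n_groups
    msd_wg = ssd_wg / df_wg if df_wg else 0.0
    msd_ag = ssd_ag / df_ag
    n0 = (n_total - sum(len(i) ** 2 for i in group_idx.values()) / n_total) / df_ag
    sigma_w = msd_wg
    sigma_a = (msd_ag - sigma_w) / n0 if n0 else 0.0
    total = sigma_a + sigma_w
    return (sigma_a / total if total > 0 else 0.0), (sigma_a, sigma_w)


def amova(
    dist: pd.DataFrame,
    sample_of: Mapping[str, str],
    source_of: Mapping[str, str],
    n_perm: int = 1000,
    seed: int = 0,
) -> AmovaResult:
    """Hierarchical AMOVA: sequences within samples within sources.

    F_ST is the among-source share of total molecular variance; its
    significance is assessed by permuting whole samples among sources
    (add-one convention). A source holding a single sample forces a
    two-level design (sequences within sources, sequences permuted).
    """
    ids = list(dist.index)
    pos = {t: i for i, t in enumerate(ids)}
    d2 = dist.to_numpy(dtype=float) ** 2

    sample_idx: dict[str, list[int]] = {}
    for sid in ids:
        sample_idx.setdefault(sample_of[sid], []).append(pos[sid])
    groups: dict[str, list[str]] = {}
    for s in sample_idx:
        groups.setdefault(source_of[s], []).append(s)
    if len(groups) < 2:
        raise ValueError("need at least two sources")

    design = "three-level"
    if any(len(samples) < 2 for samples in groups.values()):
        design = "two-level"

    if np.allclose(d2, 0.0):
        return AmovaResult(0.0, 0.0, 0.0, 0.0, 1.0, n_perm, degenerate=True,
                           design=design)

    rng = np.random.default_rng(seed)
    if design == "two-level":
        group_idx = {
            g: [i for s in samples for i in sample_idx[s]]
            for g, samples in groups.items()
        }
        fst_obs, (sa, sw) = _amova_fst2(d2, group_idx)
        seq_labels = [g for g, idx in group_idx.items() for _ in idx]
        seq_pos = [i for idx in group_idx.values() for i in idx]
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(seq_labels)
            pg: dict[str, list[int]] = {}
            for i, g in zip(seq_pos, perm):
                pg.setdefault(g, []).append(i)
            fst_p, _ = _amova_fst2(d2, pg)
            if fst_p >= fst_obs:
                hits += 1
        return AmovaResult(
            sigma_among_groups=sa,
            sigma_among_samples=0.0,
            sigma_within=sw,
            F_ST=fst_obs,
            p=(1 + hits) / (1 + n_perm),
            n_perm=n_perm,
            design=design,
        )

    fst_obs, (sa, sb, sc) = _amova_fst(d2, sample_idx, groups)
    sample_names = list(sample_idx)
    group_of_sample = {s: g for g, ss in groups.items() for s in ss}
    labels = [group_of_sample[s] for s in sample_names]
    hits = 0
    for _ in range(n_perm):
        perm = list(rng.permutation(labels))
        perm_groups: dict[str, list[str]] = {}
        for s, g in zip(sample_names, perm):
            perm_groups.setdefault(g, []).append(s)
        fst_p, _ = _amova_fst(d2, sample_idx, perm_groups)
        if fst_p >= fst_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return AmovaResult(
        sigma_among_groups=sa,
        sigma_among_samples=sb,
        sigma_within=sc,
        F_ST=fst_obs,
        p=p,
        n_perm=n_perm,
        design=design,
    )
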