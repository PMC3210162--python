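"""Genotype distances, distance trees and between-population CNV sharing.

The distance between two individuals is the raw count of loci at which their
assigned copy-state genotypes differ (loci missing in either are excluded).
The distance between two populations is the mean of that count over all
cross-population pairs; the within-population "diagonal" is the mean over all
unordered within-population pairs, so a distance table carries a non-zero
diagonal by convention.

Trees: UPGMA (arithmetic-average linkage, ultrametric) and neighbor joining
(Saitou-Nei; negative branch lengths clamped to zero and flagged), both on the
population distance matrix, with bootstrap support from resampling loci with
replacement and a majority-rule (>50%) consensus.

Sharing: a CNVR is shared by a set of groups when it contains calls from each
of them. Because larger cohorts accumulate more regions, groups are first
subsampled to the smallest group size; regions whose carriers are all removed
vanish from the subsampled universe. Venn-cell counts are averaged over
replicates and may be non-integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .cnv_map import CNVR, build_cnvrs


def individual_diff(gi, gj) -> tuple[int, int]:
    """(number of differing loci, number of loci non-missing in both)."""
    a = np.asarray(gi, dtype=float)
    b = np.asarray(gj, dtype=float)
    if a.shape != b.shape:
        raise ValueError("genotype vectors must cover the same loci")
    both = ~(np.isnan(a) | np.isnan(b))
    return int((a[both] != b[both]).sum()), int(both.sum())


def population_distance(
    genotypes: pd.DataFrame, populations: pd.Series, pop_a: str, pop_b: str
) -> tuple[float, float]:
    """Mean pairwise genotype-difference count between (or within) populations.

    Returns ``(mean diff count, mean compared-locus count)`` so callers can
    normalize; within-population distance with a single sample is NaN.
    """
    pops = populations.reindex(genotypes.index)
    ia = genotypes.index[pops == pop_a]
    ib = genotypes.index[pops == pop_b]
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("empty population")
    if pop_a == pop_b:
        if len(ia) < 2:
            return np.nan, np.nan
        pairs = list(combinations(ia, 2))
    else:
        pairs = [(x, y) for x in ia for y in ib]
    G = genotypes.to_numpy()
    loc = {s: i for i, s in enumerate(genotypes.index)}
    diffs, compared = [], []
    for x, y in pairs:
        d, c = individual_diff(G[loc[x]], G[loc[y]])
        diffs.append(d)
        compared.append(c)
    return float(np.mean(diffs)), float(np.mean(compared))


def _per_locus_mean_diff(
    genotypes: pd.DataFrame, populations: pd.Series
) -> tuple[list[str], dict[tuple[str, str], np.ndarray]]:
    """Per-locus mean pairwise-difference contribution for every population pair.

    The distance between two populations is additive over loci (a pair's diff
    count is a sum of per-locus indicators, missing counting 0), so the mean
    over pairs decomposes into per-locus means. Cross pairs: nA * nB
    denominators; within-population: all unordered pairs. Computed from
    per-state count vectors, so it is O(pops^2 * loci), not O(samples^2).
    """
    pops = populations.reindex(genotypes.index)
    names = sorted(pops.dropna().unique())
    G = genotypes.to_numpy(dtype=float)
    counts = {}
    valid = {}
    n_of = {}
    for p in names:
        sub = G[(pops == p).to_numpy()]
        n_of[p] = sub.shape[0]
        c = np.stack([(sub == s).sum(axis=0) for s in range(5)])  # (5, loci)
        counts[p] = c
        valid[p] = c.sum(axis=0)
    out = {}
    for i, a in enumerate(names):
        for b in names[i:]:
            if a == b:
                n_pairs = n_of[a] * (n_of[a] - 1) / 2
                if n_pairs == 0:
                    out[(a, a)] = np.full(G.shape[1], np.nan)
                    continue
                same = (counts[a] * (counts[a] - 1)).sum(axis=0) / 2
                diff = valid[a] * (valid[a] - 1) / 2 - same
                out[(a, a)] = diff / n_pairs
            else:
                n_pairs = n_of[a] * n_of[b]
                same = (counts[a] * counts[b]).sum(axis=0)
                diff = valid[a] * valid[b] - same
                out[(a, b)] = out[(b, a)] = diff / n_pairs
    return names, out


def population_distance_matrix(
    genotypes: pd.DataFrame, populations: pd.Series
) -> pd.DataFrame:
    """Square table of population distances; diagonal = within-population mean."""
    names, per_locus = _per_locus_mean_diff(genotypes, populations)
    D = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i:]:
            d = float(per_locus[(a, b)].sum())
            D.loc[a, b] = D.loc[b, a] = d
    return D


# ---------------------------------------------------------------------------
# Trees


def _offdiag(D: pd.DataFrame) -> np.ndarray:
    M = D.to_numpy(dtype=float).copy()
    np.fill_diagonal(M, 0.0)
    return M


def upgma(D: pd.DataFrame) -> TreeNode:
    """UPGMA tree (average linkage); leaf-to-root depths are equal."""
    Z = average(squareform(_offdiag(D), checks=False))
    tree = TreeNode.from_linkage_matrix(Z, list(D.index))
    # linkage heights are cluster heights; skbio assigns them as lengths already
    return tree


def neighbor_joining(D: pd.DataFrame) -> TreeNode:
    """Saitou-Nei neighbor joining; negative branch lengths clamped to 0."""
    dm = DistanceMatrix(_offdiag(D), ids=list(D.index))
    tree = nj(dm)
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    tree.clamped_negative_branches = clamped
    return tree


def _clades(tree: TreeNode, rooted: bool) -> set[frozenset]:
    """Non-trivial leaf-name clades (rooted) or bipartition halves (unrooted).

    Unrooted halves are canonicalized as the side not containing the
    lexicographically smallest taxon — equivalently, clades of the tree
    re-rooted at that taxon — so nesting them builds the consensus directly.
    """
    names = frozenset(l.name for l in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(l.name for l in node.tips())
        if not rooted:
            if min(names) in clade:
                clade = names - clade
        if 1 < len(clade) < len(names):
            out.add(clade)
    return out


def bootstrap_consensus(
    genotypes: pd.DataFrame,
    populations: pd.Series,
    n_reps: int = 1000,
    method: str = "upgma",
    seed: int | None = None,
) -> TreeNode:
    """Majority-rule consensus of trees built from locus bootstrap replicates.

    Each replicate resamples CNVR columns with replacement, recomputes the
    population distance matrix and the tree. Clades present in >50% of
    replicates form the consensus, annotated with support percentages.
    """
    builder = {"upgma": upgma, "nj": neighbor_joining}[method]
    names = sorted(populations.reindex(genotypes.index).dropna().unique())
    if len(names) < 3:
        raise ValueError("bootstrap consensus requires >= 3 populations")
    rng = np.random.default_rng(seed)
    n_loci = genotypes.shape[1]
    _, per_locus = _per_locus_mean_diff(genotypes, populations)
    counts: dict[frozenset, int] = {}
    empty = pd.DataFrame(
        np.zeros((len(names), len(names))), index=names, columns=names
    )
    for _ in range(n_reps):
        cols = rng.integers(0, n_loci, size=n_loci)
        D = empty.copy()
        for i, a in enumerate(names):
            for b in names[i:]:
                d = float(per_locus[(a, b)][cols].sum())
                D.loc[a, b] = D.loc[b, a] = d
        for clade in _clades(builder(D), rooted=method == "upgma"):
            counts[clade] = counts.get(clade, 0) + 1
    majority = {c: k for c, k in counts.items() if k > n_reps / 2}
    return _consensus_from_clades(set(names), majority, n_reps)


def _consensus_from_clades(
    names: set, majority: dict[frozenset, int], n_reps: int
) -> TreeNode:
    """Build the (unique) tree whose internal nodes are the majority clades.

    Majority clades are pairwise compatible (two clades each in >50% of
    replicates must co-occur in at least one), so nesting them by size gives
    a tree. Support percentages go on `.support`, which the Newick writer
    emits as the internal-node label.
    """
    full = frozenset(names)
    root = TreeNode(name=None)
    node_of: dict[frozenset, TreeNode] = {full: root}
    # insert larger clades first so parents exist before children
    for clade in sorted(majority, key=len, reverse=True):
        parent = min(
            (c for c in node_of if clade < c), key=len, default=full
        )
        node = TreeNode(name=None)
        node.support = 100.0 * majority[clade] / n_reps
        node_of[parent].append(node)
        node_of[clade] = node
    for leaf in sorted(names):
        parent = min((c for c in node_of if leaf in c), key=len)
        node_of[parent].append(TreeNode(name=leaf))
    return root


# ---------------------------------------------------------------------------
# Sharing


@dataclass
class SharingResult:
    groups: list[str]
    cells: pd.DataFrame  # columns: membership pattern per group + count columns
    reps: int
    subsample_n: int


def _membership_patterns(calls: pd.DataFrame, groups: dict[str, list[str]]):
    """Venn-cell counts (by CNVR class) for one concrete cohort."""
    cnvrs = build_cnvrs(calls)
    sample_group = {s: g for g, ss in groups.items() for s in ss}
    patterns: dict[tuple, dict[str, int]] = {}
    for r in cnvrs:
        present = tuple(
            sorted({sample_group[s] for s in r.members["sample_id"] if s in sample_group})
        )
        if not present:
            continue
        d = patterns.setdefault(present, {"deletion": 0, "duplication": 0, "multiallelic": 0})
        d[r.cnv_class] += 1
    return patterns


def sharing_venn(
    calls: pd.DataFrame,
    populations: pd.Series,
    groups: dict[str, list[str]],
    reps: int = 100,
    seed: int | None = None,
) -> SharingResult:
    """Sample-size-adjusted CNV sharing among groups.

    ``groups`` maps a group label to its member sample_ids. Every group is
    subsampled (without replacement) to the smallest group's size; CNVRs are
    rebuilt from the retained samples' calls; Venn cells are counted and
    averaged over ``reps`` replicates.
    """
    if len(groups) < 2:
        raise ValueError("sharing requires >= 2 groups")
    sizes = {g: len(ss) for g, ss in groups.items()}
    if min(sizes.values()) == 0:
        raise ValueError("empty group")
    n_min = min(sizes.values())
    rng = np.random.default_rng(seed)

    acc: dict[tuple, np.ndarray] = {}
    classes = ["deletion", "duplication", "multiallelic"]
    for _ in range(reps):
        kept = []
        sub_groups = {}
        for g, ss in groups.items():
            pick = list(rng.choice(ss, size=n_min, replace=False)) if len(ss) > n_min else list(ss)
            kept.extend(pick)
            sub_groups[g] = pick
        sub_calls = calls[calls["sample_id"].isin(kept)]
        for pattern, by_class in _membership_patterns(sub_calls, sub_groups).items():
            vec = np.array([by_class[c] for c in classes], dtype=float)
            acc[pattern] = acc.get(pattern, np.zeros(3)) + vec

    rows = []
    for pattern, total in sorted(acc.items()):
        mean = total / reps
        rows.append(
            {
                "pattern": "&".join(pattern),
                "n_groups": len(pattern),
                **{c: mean[i] for i, c in enumerate(classes)},
                "total": float(mean.sum()),
            }
        )
    return SharingResult(
        groups=sorted(groups),
        cells=pd.DataFrame(rows),
        reps=reps,
        subsample_n=n_min,
    )


def pairwise_sharing(
    cnvrs: list[CNVR], populations: pd.Series, pop_i: str, pop_j: str
) -> float:
    """#CNVRs with calls from both i and j, divided by #CNVRs with calls from j."""
    pop_of = populations.to_dict()
    both = in_j = 0
    for r in cnvrs:
        pops = {pop_of.get(s) for s in r.members["sample_id"]}
        if pop_j in pops:
            in_j += 1
            if pop_i in pops:
                both += 1
    return both / in_j if in_j else np.nan
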