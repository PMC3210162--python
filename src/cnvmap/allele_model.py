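"""Three-allele frequency inference and Weir-Cockerham F_ST.

Copy-state genotypes 0-4 are diploid sums of three haploid alleles carrying
0 (loss, l), 1 (normal, n) or 2 (gain, g) copies. Under Hardy-Weinberg
equilibrium the genotype probabilities are

    P0 = p_l^2        P1 = 2 p_l p_n      P2 = p_n^2 + 2 p_l p_g
    P3 = 2 p_n p_g    P4 = p_g^2

The 2-copy state is a mixture of the n/n and l/g configurations, so allele
frequencies are not directly countable; an EM algorithm splits the observed
2-copy class between the two configurations in proportion p_n^2 : 2 p_l p_g
at each E-step and re-counts alleles at the M-step. The log-likelihood is
monotone non-decreasing and the multinomial likelihood is unimodal over the
2-simplex, so the deterministic (1/3, 1/3, 1/3) start needs no restarts.

F_ST uses the Weir-Cockerham (1984) variance components summed over the three
alleles. Genotypic phase is unobservable for the 2-copy class, so observed
heterozygosity is replaced by its HWE expectation 2 p(1-p) computed from the
EM frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class AlleleFreq:
    """Estimated (loss, normal, gain) allele frequencies at one locus."""

    p_l: float
    p_n: float
    p_g: float
    n_eff: int  # non-missing diploid sample count
    loglik: float
    iterations: int
    converged: bool
    history: list | None = None  # per-iteration log-likelihoods when requested

    def as_array(self) -> np.ndarray:
        return np.array([self.p_l, self.p_n, self.p_g])


@dataclass
class FstResult:
    theta: float | None  # None when undefined (all populations monomorphic alike)
    a: np.ndarray  # per-allele among-population component
    b: np.ndarray  # per-allele among-individual component
    c: np.ndarray  # per-allele within-individual component


def genotype_counts(column: pd.Series | np.ndarray) -> np.ndarray:
    """Tally copy-state genotypes 0..4, skipping missing values."""
    arr = np.asarray(column, dtype=float)
    arr = arr[~np.isnan(arr)].astype(int)
    return np.bincount(arr, minlength=5)[:5]


def hwe_genotype_probs(p: np.ndarray) -> np.ndarray:
    """Five-state genotype probabilities from (p_l, p_n, p_g) under HWE."""
    pl, pn, pg = p
    return np.array(
        [pl * pl, 2 * pl * pn, pn * pn + 2 * pl * pg, 2 * pn * pg, pg * pg]
    )


def _loglik(counts: np.ndarray, p: np.ndarray) -> float:
    probs = hwe_genotype_probs(p)
    mask = counts > 0
    with np.errstate(divide="ignore"):
        lp = np.log(probs[mask])
    if np.any(np.isinf(lp)):
        return -np.inf
    return float(np.dot(counts[mask], lp))


def em_allele_freq(
    counts, tol: float = 1e-8, max_iter: int = 10000, keep_history: bool = False
) -> AlleleFreq:
    """EM estimate of (p_l, p_n, p_g) from genotype counts (n0..n4).

    Iterates until the log-likelihood improves by less than ``tol``;
    non-convergence at ``max_iter`` is flagged, not raised.
    """
    n = np.asarray(counts, dtype=float)
    if n.shape != (5,) or (n < 0).any():
        raise ValueError("counts must be 5 non-negative genotype tallies")
    total = n.sum()
    if total < 1:
        raise ValueError("no genotyped samples at locus")

    # slightly asymmetric start: the uniform point (1/3, 1/3, 1/3) is an exact
    # fixed point of the EM map when only the 2-copy class is observed
    p = np.array([0.3, 0.4, 0.3])
    ll = _loglik(n, p)
    history = [ll] if keep_history else None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pl, pn, pg = p
        # E-step: split the 2-copy class between n/n and l/g
        denom = pn * pn + 2 * pl * pg
        w_nn = (pn * pn / denom) if denom > 0 else 1.0
        n2_nn = n[2] * w_nn
        n2_lg = n[2] - n2_nn
        # M-step: expected allele counts
        loss = 2 * n[0] + n[1] + n2_lg
        norm = n[1] + 2 * n2_nn + n[3]
        gain = n2_lg + n[3] + 2 * n[4]
        p = np.array([loss, norm, gain]) / (2 * total)
        new_ll = _loglik(n, p)
        if history is not None:
            history.append(new_ll)
        if abs(new_ll - ll) < tol:
            ll = new_ll
            converged = True
            break
        ll = new_ll
    return AlleleFreq(
        p_l=float(p[0]),
        p_n=float(p[1]),
        p_g=float(p[2]),
        n_eff=int(total),
        loglik=ll,
        iterations=it,
        converged=converged,
        history=history,
    )


def fst_wc(freqs: list[AlleleFreq] | np.ndarray, sizes) -> FstResult:
    """Weir-Cockerham theta over the three CNV alleles.

    ``freqs``: per-population allele frequencies (AlleleFreq or (r, 3) array);
    ``sizes``: per-population diploid sample counts. Heterozygote frequencies
    are the HWE expectations 2 p (1 - p) per allele (phase unobservable).
    """
    P = np.array([f.as_array() if isinstance(f, AlleleFreq) else f for f in freqs])
    n = np.asarray(sizes, dtype=float)
    r = len(n)
    if r < 2 or (n < 2).any():
        raise ValueError("need >=2 populations with n >= 2")

    nbar = n.mean()
    nc = (n.sum() - (n**2).sum() / n.sum()) / (r - 1)
    h = 2 * P * (1 - P)  # HWE-expected heterozygote frequency per allele

    pbar = (n[:, None] * P).sum(axis=0) / (r * nbar)
    s2 = (n[:, None] * (P - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n[:, None] * h).sum(axis=0) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2

    denom = float((a + b + c).sum())
    theta = float(a.sum() / denom) if denom != 0 else None
    return FstResult(theta=theta, a=a, b=b, c=c)


def fst_scan(
    genotypes: pd.DataFrame,
    populations: pd.Series,
    pairs: list[tuple[str, str]] | None = None,
    min_call_rate: float = 0.5,
) -> pd.DataFrame:
    """Per-locus pairwise theta from EM frequencies.

    Loci with a call rate below ``min_call_rate`` in either population of a
    pair, or monomorphic across the pair, yield NaN for that pair.
    Returns a tidy table (locus, pop_a, pop_b, theta, n_a, n_b).
    """
    pops = populations.reindex(genotypes.index)
    groups = {p: genotypes.index[pops == p] for p in pops.dropna().unique()}
    if pairs is None:
        names = sorted(groups)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]

    rows = []
    for locus in genotypes.columns:
        col = genotypes[locus]
        for pa, pb in pairs:
            sub = [col.loc[groups[pa]], col.loc[groups[pb]]]
            theta = np.nan
            ns = [int(s.notna().sum()) for s in sub]
            rates = [s.notna().mean() if len(s) else 0.0 for s in sub]
            if min(rates) >= min_call_rate and min(ns) >= 2:
                fr = [em_allele_freq(genotype_counts(s)) for s in sub]
                res = fst_wc(fr, ns)
                theta = np.nan if res.theta is None else res.theta
            rows.append(
                {"locus": locus, "pop_a": pa, "pop_b": pb, "theta": theta,
                 "n_a": ns[0], "n_b": ns[1]}
            )
    return pd.DataFrame(rows)
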