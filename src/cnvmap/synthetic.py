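"""Synthetic multi-population CNV cohorts with full ground truth.

The generator emulates array-based CNV calling output: per-individual call
tables over a set of polymorphic loci with three-allele Hardy-Weinberg
genotype structure, call-boundary jitter across carriers, private singleton
calls, complex regions (one carrier with both a deletion and a duplication),
QC-failing calls, and confidence-flagged missing genotypes. Every draw is
reproducible from the config seed, and a TruthBundle records the generating
genotypes, allele pairs, allele frequencies and F_ST so estimator recovery
can be checked exactly.

Population allele frequencies drift from a shared ancestral frequency down a
nested population hierarchy (Dirichlet drift, Balding-Nichols style), so
distance-based trees have a known generating topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allele_model import fst_wc
from .io_formats import SnpData


@dataclass
class Locus:
    chrom: str
    start: int
    end: int
    freqs: dict[str, np.ndarray]  # population -> (p_l, p_n, p_g)

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.start + 1}-{self.end}"


@dataclass
class SimConfig:
    populations: dict[str, int]  # name -> diploid sample count
    loci: list[Locus]
    boundary_jitter_sd: float = 500.0  # bp; truncated at 40% of locus length
    singleton_rate: float = 0.5  # Poisson mean of private random calls per sample
    complex_rate: float = 0.01  # fraction of loci with an embedded opposite call
    missing_rate: float = 0.01  # chance a carrier's call is confidence-flagged
    qc_noise: float = 0.0  # fraction of calls given sub-threshold metadata
    seed: int = 0


@dataclass
class TruthBundle:
    genotypes: pd.DataFrame  # samples x loci true copy states (NaN = flagged missing)
    alleles: dict[str, np.ndarray]  # locus -> (n_samples, 2) allele copy numbers
    allele_freqs: pd.DataFrame  # (locus, population, p_l, p_n, p_g)
    fst: pd.DataFrame  # (locus, pop_a, pop_b, theta) from generating freqs
    samples: pd.DataFrame  # sample sheet
    loci: list[Locus]
    qc_fail_keys: set  # (sample_id, chrom, start, end) of qc_noise-corrupted calls


def drift_frequencies(p: np.ndarray, c: float, rng: np.random.Generator) -> np.ndarray:
    """One Dirichlet drift step: child ~ Dirichlet(p * (1 - c) / c)."""
    if c <= 0:
        return p.copy()
    out = rng.dirichlet(np.maximum(p, 1e-6) * (1 - c) / c)
    return out / out.sum()


def hierarchical_frequencies(
    tree, p: np.ndarray, rng: np.random.Generator, out: dict | None = None
) -> dict[str, np.ndarray]:
    """Drift ancestral frequencies down a nested population hierarchy.

    ``tree`` is either ``("name", c)`` for a leaf population or
    ``([children...], c)`` where each child is again such a pair; ``c`` is the
    drift intensity on the edge into that node.
    """
    if out is None:
        out = {}
    node, c = tree
    q = drift_frequencies(p, c, rng)
    if isinstance(node, str):
        out[node] = q
    else:
        for child in node:
            hierarchical_frequencies(child, q, rng, out)
    return out


#: population sizes of the study cohort the generator mirrors
STUDY_POPULATIONS = {
    "HAN": 80,
    "TB": 41,
    "DONG": 9,
    "YAO": 8,
    "LI": 8,
    "ZHUANG": 6,
    "UYG": 3,
}

#: generating hierarchy: southern groups (Yao/Zhuang closest, then Dong, Li)
#: form a cluster; Han and Tibetan split off earlier; Uyghur is most diverged
STUDY_HIERARCHY = (
    [
        (
            [
                ([("YAO", 0.005), ("ZHUANG", 0.005)], 0.005),
                ("DONG", 0.01),
                ("LI", 0.01),
            ],
            0.01,
        ),
        ("HAN", 0.015),
        ("TB", 0.02),
        ("UYG", 0.06),
    ],
    0.0,
)


def _ancestral_frequency(rng: np.random.Generator) -> np.ndarray:
    """A low-frequency, loss-biased locus on the (p_l, p_n, p_g) simplex."""
    kind = rng.choice(["deletion", "duplication", "multiallelic"], p=[0.7, 0.2, 0.1])
    f = rng.beta(0.8, 4.0)  # non-normal allele frequency, skewed low
    if kind == "deletion":
        return np.array([f, 1 - f, 0.0])
    if kind == "duplication":
        return np.array([0.0, 1 - f, f])
    g = f * rng.uniform(0.2, 0.8)
    return np.array([f - g, 1 - f, g])


def study_mirror_config(
    n_loci: int = 1440,
    seed: int = 0,
    populations: dict[str, int] | None = None,
    hierarchy=None,
    **overrides,
) -> SimConfig:
    """A config shaped like the study cohort: 7 populations of sizes
    80/41/9/8/8/6/3, loss-dominated low-frequency loci, median length ~15 kb."""
    rng = np.random.default_rng(seed)
    pops = dict(populations or STUDY_POPULATIONS)
    if hierarchy is not None:
        hier = hierarchy
    elif populations is None:
        hier = STUDY_HIERARCHY
    else:  # custom populations without a stated history: star with mild drift
        hier = ([(name, 0.02) for name in pops], 0.0)
    loci = []
    spacing = 2_000_000
    per_chrom = max(1, int(np.ceil(n_loci / 22)))
    for i in range(n_loci):
        chrom = f"chr{i // per_chrom + 1}"
        pos = 1_000_000 + (i % per_chrom) * spacing
        length = int(np.clip(rng.lognormal(np.log(15_000), 0.8), 1_200, 400_000))
        anc = _ancestral_frequency(rng)
        freqs = hierarchical_frequencies(hier, anc, rng)
        freqs = {p: freqs[p] for p in pops}
        loci.append(Locus(chrom=chrom, start=pos, end=pos + length, freqs=freqs))
    return SimConfig(populations=pops, loci=loci, seed=seed, **overrides)


_STATE_OF_PAIR = {
    (0, 0): 0,
    (0, 1): 1,
    (0, 2): 2,  # loss/gain configuration: copy-neutral total
    (1, 1): 2,
    (1, 2): 3,
    (2, 2): 4,
}


def simulate_cohort(config: SimConfig):
    """Draw a cohort and its call table.

    Returns ``(calls, samples, truth)``. Per sample per locus two alleles are
    drawn from the population's frequencies; copy state is their sum. States
    other than 2 are emitted as calls with jittered boundaries; missing-rate
    carriers get confidence > 0.1 (dropped as missing downstream); complex
    loci embed an opposite-sign sub-call for one carrier; singleton calls land
    in reserved empty regions between configured loci so truth regions stay
    identifiable; qc_noise corrupts call metadata below QC thresholds.
    """
    rng = np.random.default_rng(config.seed)
    _check_separable(config.loci)
    sample_ids, sample_pops = [], []
    for pop, n in config.populations.items():
        for k in range(n):
            sample_ids.append(f"{pop}_{k:03d}")
            sample_pops.append(pop)
    samples = pd.DataFrame({"sample_id": sample_ids, "population": sample_pops})
    n_samples = len(sample_ids)

    complex_loci = set(
        rng.choice(
            len(config.loci),
            size=int(round(config.complex_rate * len(config.loci))),
            replace=False,
        )
    ) if config.loci else set()

    calls = []
    truth_geno = np.full((n_samples, len(config.loci)), 2.0)
    alleles: dict[str, np.ndarray] = {}
    freq_rows = []
    for j, locus in enumerate(config.loci):
        length = locus.end - locus.start
        max_jit = 0.4 * length
        pair = np.empty((n_samples, 2), dtype=int)
        row0 = 0
        for pop, n in config.populations.items():
            p = locus.freqs[pop]
            pair[row0 : row0 + n] = rng.choice(3, size=(n, 2), p=p)
            row0 += n
            freq_rows.append(
                {"locus": locus.locus_id, "population": pop,
                 "p_l": p[0], "p_n": p[1], "p_g": p[2]}
            )
        pair.sort(axis=1)
        alleles[locus.locus_id] = pair
        states = pair.sum(axis=1)
        truth_geno[:, j] = states
        carriers = np.flatnonzero(states != 2)
        complex_pick = (
            rng.choice(carriers) if j in complex_loci and len(carriers) else None
        )
        for i in carriers:
            jit = np.clip(
                rng.normal(0, config.boundary_jitter_sd, size=2), -max_jit, max_jit
            )
            s = int(locus.start + jit[0])
            e = int(locus.end + jit[1])
            conf = 0.01
            if rng.random() < config.missing_rate:
                conf = 0.5  # flagged uncertain -> missing genotype downstream
                truth_geno[i, j] = np.nan
            if i == complex_pick:
                # complex carrier: a call over the left part of the locus with
                # the true state and a shorter, non-overlapping opposite-sign
                # call over the right part (so no same-sample state conflict)
                e = locus.start + int(0.45 * length)
                sub_start = locus.start + int(0.60 * length)
                calls.append(
                    {
                        "sample_id": sample_ids[i],
                        "population": sample_pops[i],
                        "chrom": locus.chrom,
                        "start": sub_start,
                        "end": locus.end,
                        "copy_state": 3 if states[i] < 2 else 1,
                        "source": "RARE",
                        "lod": float(rng.uniform(6, 9)),
                        "confidence": np.nan,
                        "n_probes": max(3, (locus.end - sub_start) // 500),
                    }
                )
            calls.append(
                {
                    "sample_id": sample_ids[i],
                    "population": sample_pops[i],
                    "chrom": locus.chrom,
                    "start": max(0, s),
                    "end": max(s + 1000, e),
                    "copy_state": int(states[i]),
                    "source": "CNP",
                    "lod": float(rng.uniform(10, 60)),
                    "confidence": conf,
                    "n_probes": int(max(3, (e - s) // 500)),
                }
            )

    # singletons: private rare calls in reserved space between configured loci
    slot = 0
    for i, sid in enumerate(sample_ids):
        for _ in range(rng.poisson(config.singleton_rate)):
            chrom, pos = _singleton_slot(config.loci, slot)
            slot += 1
            length = int(np.clip(rng.lognormal(np.log(8000), 0.6), 1200, 40_000))
            calls.append(
                {
                    "sample_id": sid,
                    "population": sample_pops[i],
                    "chrom": chrom,
                    "start": pos,
                    "end": pos + length,
                    "copy_state": int(rng.choice([0, 1, 1, 3])),
                    "source": "RARE",
                    "lod": float(rng.uniform(5, 30)),
                    "confidence": np.nan,
                    "n_probes": max(3, length // 500),
                }
            )

    calls = pd.DataFrame(calls)
    qc_fail_keys: set = set()
    if config.qc_noise > 0 and len(calls):
        n_bad = int(round(config.qc_noise * len(calls)))
        bad = rng.choice(len(calls), size=n_bad, replace=False)
        for b in bad:
            mode = rng.integers(3)
            if mode == 0:
                calls.loc[b, "end"] = calls.loc[b, "start"] + int(rng.integers(100, 999))
            elif mode == 1:
                calls.loc[b, "n_probes"] = int(rng.integers(1, 3))
            else:
                calls.loc[b, "lod"] = float(rng.uniform(0.5, 4.9))
            qc_fail_keys.add(
                (
                    calls.loc[b, "sample_id"],
                    calls.loc[b, "chrom"],
                    int(calls.loc[b, "start"]),
                    int(calls.loc[b, "end"]),
                )
            )

    truth = TruthBundle(
        genotypes=pd.DataFrame(
            truth_geno, index=sample_ids, columns=[l.locus_id for l in config.loci]
        ),
        alleles=alleles,
        allele_freqs=pd.DataFrame(freq_rows),
        fst=_true_fst(config),
        samples=samples,
        loci=config.loci,
        qc_fail_keys=qc_fail_keys,
    )
    return calls.reset_index(drop=True), samples, truth


def _check_separable(loci: list[Locus]) -> None:
    by_chrom: dict[str, list[Locus]] = {}
    for l in loci:
        by_chrom.setdefault(l.chrom, []).append(l)
    for chrom, ls in by_chrom.items():
        ls = sorted(ls, key=lambda l: l.start)
        for a, b in zip(ls[:-1], ls[1:]):
            # keep room for 40%-of-length jitter on both sides
            if b.start - 0.4 * (b.end - b.start) <= a.end + 0.4 * (a.end - a.start):
                raise ValueError(
                    f"configured loci too close on {chrom}: "
                    f"{a.locus_id} and {b.locus_id}"
                )


def _singleton_slot(loci: list[Locus], slot: int) -> tuple[str, int]:
    """Deterministic reserved coordinates that cannot merge with truth loci."""
    chrom = f"chr{slot % 22 + 1}"
    return chrom, 200_000_000 + (slot // 22) * 200_000


def _true_fst(config: SimConfig) -> pd.DataFrame:
    names = sorted(config.populations)
    sizes = [config.populations[p] for p in names]
    rows = []
    for locus in config.loci:
        P = [locus.freqs[p] for p in names]
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                res = fst_wc(
                    [locus.freqs[a], locus.freqs[b]],
                    [config.populations[a], config.populations[b]],
                )
                rows.append(
                    {
                        "locus": locus.locus_id,
                        "pop_a": a,
                        "pop_b": b,
                        "theta": np.nan if res.theta is None else res.theta,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Linked SNPs


def simulate_linked_snps(
    truth: TruthBundle,
    plan: pd.DataFrame,
    seed: int = 0,
) -> tuple[SnpData, pd.DataFrame]:
    """Emit unphased SNP genotypes coupled to biallelic CNV loci.

    ``plan`` rows: locus (a truth locus id), n_snps, d_prime, maf, offset
    (bp from the locus end to the first SNP; SNPs step 997 bp apart). For each
    SNP, two-locus haplotype frequencies achieving the requested D' and MAF
    are built against the locus's variant allele, and each individual's SNP
    alleles are drawn conditional on their true CNV alleles. Returns the SNP
    table and the closed-form r^2 per (locus, snp).
    """
    rng = np.random.default_rng(seed)
    loci_by_id = {l.locus_id: l for l in truth.loci}
    sample_ids = list(truth.genotypes.index)
    ids, chroms, poss, cols = [], [], [], []
    true_rows = []
    for row in plan.itertuples():
        locus = loci_by_id[row.locus]
        pair = truth.alleles[row.locus]
        # biallelic requirement: allele set must be {1} plus one variant allele
        others = set(np.unique(pair)) - {1}
        if len(others) != 1:
            raise ValueError(f"locus {row.locus} is not biallelic polymorphic")
        variant = others.pop()
        is_var = pair == variant  # (n, 2) chromosome-level variant indicator
        pA = is_var.mean()
        pB = float(row.maf)
        if not 0 < pA < 1:
            raise ValueError(f"locus {row.locus} monomorphic in the cohort")
        d_max = min(pA * (1 - pB), (1 - pA) * pB) if row.d_prime >= 0 else min(
            pA * pB, (1 - pA) * (1 - pB)
        )
        D = row.d_prime * d_max
        f = {
            (1, 1): pA * pB + D,
            (1, 0): pA * (1 - pB) - D,
            (0, 1): (1 - pA) * pB - D,
            (0, 0): (1 - pA) * (1 - pB) + D,
        }
        p_b_given_a = {
            a: (f[(a, 1)] / (f[(a, 1)] + f[(a, 0)]) if f[(a, 1)] + f[(a, 0)] > 0 else 0.0)
            for a in (0, 1)
        }
        denom = pA * (1 - pA) * pB * (1 - pB)
        r2_true = D * D / denom if denom > 0 else np.nan
        offset = int(getattr(row, "offset", 1000))
        for k in range(int(row.n_snps)):
            pos = locus.end + offset + k * 997 + 1  # 1-based VCF position
            snp_id = f"snp_{row.locus}_{k}"
            b_alleles = np.empty_like(is_var, dtype=float)
            for a_val in (0, 1):
                mask = is_var == bool(a_val)
                b_alleles[mask] = rng.random(mask.sum()) < p_b_given_a[a_val]
            dosage = b_alleles.sum(axis=1)
            ids.append(snp_id)
            chroms.append(locus.chrom)
            poss.append(pos)
            cols.append(dosage)
            true_rows.append(
                {"locus": row.locus, "snp_id": snp_id, "pos": pos, "r2": r2_true}
            )
    dosages = pd.DataFrame(
        np.array(cols).T if cols else np.empty((len(sample_ids), 0)),
        index=sample_ids,
        columns=ids,
    )
    sites = pd.DataFrame({"snp_id": ids, "chrom": chroms, "pos": poss})
    return SnpData(dosages=dosages, sites=sites), pd.DataFrame(true_rows)
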