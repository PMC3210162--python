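"""Population-differentiated CNV ranking and population-exclusive regions.

Frequency comparisons between a test population and each reference population
are Fisher exact tests on 2x2 allele-count tables, one per allele of interest
(loss vs non-loss, gain vs non-gain). Loci are ranked by the number of
Bonferroni-significant comparisons, ties broken by the pooled-reference
("overall") p-value. Copy-state genotypes map to allele counts
deterministically: 0 -> 2 loss, 1 -> loss+normal, 2 -> 2 normal,
3 -> normal+gain, 4 -> 2 gain (the l/g configuration hiding inside state 2 is
counted as normal/normal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .cnv_map import CNVR

# per-genotype (loss, normal, gain) allele contributions
_ALLELES = np.array(
    [[2, 0, 0], [1, 1, 0], [0, 2, 0], [0, 1, 1], [0, 0, 2]], dtype=int
)


@dataclass
class AlleleCounts:
    loss: int
    normal: int
    gain: int

    @property
    def total(self) -> int:
        return self.loss + self.normal + self.gain


def allele_counts(column: pd.Series, sample_ids=None) -> AlleleCounts:
    """Tally (loss, normal, gain) alleles from a genotype column (NaN skipped)."""
    col = column if sample_ids is None else column.loc[sample_ids]
    g = col.to_numpy(dtype=float)
    g = g[~np.isnan(g)].astype(int)
    tal = _ALLELES[g].sum(axis=0) if len(g) else np.zeros(3, dtype=int)
    return AlleleCounts(loss=int(tal[0]), normal=int(tal[1]), gain=int(tal[2]))


def freq_diff_test(test: AlleleCounts, ref: AlleleCounts, allele: str) -> float:
    """Two-sided Fisher exact test of allele vs non-allele counts, test vs ref."""
    if test.total == 0 or ref.total == 0:
        raise ValueError("both populations need >= 1 counted allele")
    if allele == "loss":
        a, b = test.loss, ref.loss
    elif allele == "gain":
        a, b = test.gain, ref.gain
    else:
        raise ValueError(f"allele must be 'loss' or 'gain', got {allele!r}")
    table = [[a, test.total - a], [b, ref.total - b]]
    if a + b == 0 or (test.total - a) + (ref.total - b) == 0:
        return 1.0  # zero-margin table carries no information
    return float(fisher_exact(table, alternative="two-sided")[1])


def rank_differentiated(
    genotypes: pd.DataFrame,
    populations: pd.Series,
    test_pop: str,
    ref_pops: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-locus differentiation scan of ``test_pop`` against each reference.

    For each locus and reference, the loss-allele and gain-allele Fisher tests
    are run; a comparison is significant at ``alpha / n_loci`` (Bonferroni over
    loci, within each reference x allele family). The output is sorted by the
    number of significant comparisons (descending), then the pooled-reference
    "overall" p-value (ascending; minimum over the two alleles).
    """
    pops = populations.reindex(genotypes.index)
    test_idx = genotypes.index[pops == test_pop]
    ref_idx = {r: genotypes.index[pops == r] for r in ref_pops}
    pooled_idx = genotypes.index[pops.isin(ref_pops)]
    n_loci = genotypes.shape[1]
    cutoff = alpha / n_loci

    rows = []
    for locus in genotypes.columns:
        col = genotypes[locus]
        tc = allele_counts(col, test_idx)
        rec: dict = {"locus": locus}
        n_sig = 0
        for ref in sorted(ref_pops):
            rc = allele_counts(col, ref_idx[ref])
            for allele in ("loss", "gain"):
                if tc.total and rc.total:
                    p = freq_diff_test(tc, rc, allele)
                else:
                    p = np.nan
                rec[f"p_{allele}_{ref}"] = p
                n_sig += bool(p == p and p < cutoff)
        pc = allele_counts(col, pooled_idx)
        overall = np.nan
        if tc.total and pc.total:
            overall = min(
                freq_diff_test(tc, pc, "loss"), freq_diff_test(tc, pc, "gain")
            )
        rec["overall_p"] = overall
        rec["n_significant"] = n_sig
        rows.append(rec)
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["n_significant", "overall_p", "locus"],
        ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)


def exclusive_cnvrs(
    cnvrs: list[CNVR],
    populations: pd.Series,
    test_pop: str,
    ref_pops: list[str],
    require_non_singleton: bool = True,
) -> pd.DataFrame:
    """CNVRs carried only by the test population among test + references.

    With ``require_non_singleton`` the region must have >= 2 distinct carrier
    samples in the test population. Returns (locus, chrom, start, end,
    n_test_carriers, class).
    """
    pop_of = populations.to_dict()
    scope = {test_pop, *ref_pops}
    rows = []
    for r in cnvrs:
        carriers = {
            s: pop_of.get(s)
            for s in r.members["sample_id"].unique()
            if pop_of.get(s) in scope
        }
        if not carriers:
            continue
        test_carriers = [s for s, p in carriers.items() if p == test_pop]
        if len(test_carriers) != len(carriers):
            continue  # a reference sample carries it
        if require_non_singleton and len(test_carriers) < 2:
            continue
        rows.append(
            {
                "locus": r.locus_id,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_test_carriers": len(test_carriers),
                "class": r.cnv_class,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["locus", "chrom", "start", "end", "n_test_carriers", "class"],
    )
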