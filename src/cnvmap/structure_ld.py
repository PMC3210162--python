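"""Population structure from biallelic CNPs and CNP-SNP taggability.

Only loci whose observed genotypes stay on one side of the copy-neutral state
(within {0,1,2} or within {2,3,4}) have a determinable per-individual allele
configuration; those are recoded as dosages of the non-normal allele
(deletion side: 2 - g; duplication side: g - 2) and fed to a genotype PCA
with Patterson normalization.

Linkage between a CNP and a flanking SNP is r-squared computed from two-locus
haplotype frequencies estimated by EM from unphased dosages (the E-step
splits double heterozygotes between the two phase configurations). A common
CNP (carrier frequency > 10%) is "taggable" when some SNP within 20 kb of
either boundary reaches r^2 >= 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cnv_map import CNVR
from .io_formats import SnpData


def biallelic_filter(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Retain polymorphic loci observed entirely within {0,1,2} or {2,3,4}.

    Returns a table (locus, side) with side in {deletion, duplication}. Loci
    with both deletion and duplication genotypes, or observed only as 2, are
    excluded.
    """
    rows = []
    for locus in genotypes.columns:
        vals = set(genotypes[locus].dropna().astype(int).unique())
        if not vals or vals == {2}:
            continue
        if vals <= {0, 1, 2}:
            rows.append({"locus": locus, "side": "deletion"})
        elif vals <= {2, 3, 4}:
            rows.append({"locus": locus, "side": "duplication"})
    return pd.DataFrame(rows, columns=["locus", "side"])


def encode_dosage(genotypes: pd.DataFrame, loci: pd.DataFrame) -> pd.DataFrame:
    """Dosage of the non-normal allele at each biallelic locus.

    Deletion-side locus: dosage = 2 - genotype; duplication-side: genotype - 2.
    Genotype 2 maps to dosage 0 on either side; missing stays missing.
    """
    out = {}
    for row in loci.itertuples():
        g = genotypes[row.locus].astype(float)
        out[row.locus] = 2.0 - g if row.side == "deletion" else g - 2.0
    return pd.DataFrame(out, index=genotypes.index)


def pca_structure(
    dosages: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Genotype PCA with Patterson normalization.

    Columns are mean-imputed, mean-centered and scaled by sqrt(p(1-p)) with
    p = column mean / 2; the sign of each component is fixed so its
    largest-magnitude loading is positive. Returns (coordinates, eigenvalues).
    """
    X = dosages.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs >= 2 samples and >= 2 loci")
    mu = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mu, X)
    p = mu / 2.0
    scale = np.sqrt(p * (1 - p))
    keep = (scale > 0) & (np.var(X, axis=0) > 0)
    if not keep.any():
        raise ValueError("all loci have zero variance")
    Z = (X[:, keep] - mu[keep]) / scale[keep]
    # eigen-decomposition of the sample covariance via SVD of centered data
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    n_components = min(n_components, len(S))
    eigvals = S**2 / (Z.shape[0] - 1)
    coords = U[:, :n_components] * S[:n_components]
    loadings = Vt[:n_components]
    for k in range(n_components):
        j = np.argmax(np.abs(loadings[k]))
        if loadings[k, j] < 0:
            coords[:, k] *= -1
            loadings[k] *= -1
    return (
        pd.DataFrame(
            coords,
            index=dosages.index,
            columns=[f"PC{k + 1}" for k in range(n_components)],
        ),
        eigvals[:n_components],
    )


@dataclass
class LDRecord:
    cnp_locus: str
    snp_id: str | None
    r2: float
    converged: bool


def two_locus_r2(
    x, y, tol: float = 1e-10, max_iter: int = 10000
) -> LDRecord:
    """r^2 between two unphased biallelic dosage vectors via haplotype EM.

    Estimates the 4 haplotype frequencies (AB, Ab, aB, ab); the only
    ambiguous class is the double heterozygote, split between AB/ab and Ab/aB
    in proportion to the current haplotype products. Initialized at linkage
    equilibrium. Requires >= 5 complete observations and both loci
    polymorphic; otherwise returns NaN flagged unconverged.
    """
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    n = len(a)
    if n < 5 or len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        return LDRecord(cnp_locus="", snp_id=None, r2=np.nan, converged=False)

    # genotype-pair counts n[i, j], i = dosage at locus 1, j = at locus 2
    cnt = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            cnt[i, j] = np.sum((a == i) & (b == j))

    pA = a.mean() / 2.0
    pB = b.mean() / 2.0
    # haplotypes: h[0]=AB h[1]=Ab h[2]=aB h[3]=ab ; A = allele counted by dosage
    h = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    converged = False
    for _ in range(max_iter):
        # expected haplotype counts; only (1,1) genotype-pairs are ambiguous
        e = np.zeros(4)
        e[0] += 2 * cnt[2, 2] + cnt[2, 1] + cnt[1, 2]
        e[1] += 2 * cnt[2, 0] + cnt[2, 1] + cnt[1, 0]
        e[2] += 2 * cnt[0, 2] + cnt[0, 1] + cnt[1, 2]
        e[3] += 2 * cnt[0, 0] + cnt[0, 1] + cnt[1, 0]
        cis = h[0] * h[3]
        trans = h[1] * h[2]
        w = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        e[0] += cnt[1, 1] * w
        e[3] += cnt[1, 1] * w
        e[1] += cnt[1, 1] * (1 - w)
        e[2] += cnt[1, 1] * (1 - w)
        new_h = e / (2 * n)
        if np.max(np.abs(new_h - h)) < tol:
            h = new_h
            converged = True
            break
        h = new_h

    fA = h[0] + h[1]
    fB = h[0] + h[2]
    denom = fA * (1 - fA) * fB * (1 - fB)
    if denom <= 0:
        return LDRecord(cnp_locus="", snp_id=None, r2=np.nan, converged=converged)
    D = h[0] - fA * fB
    return LDRecord(cnp_locus="", snp_id=None, r2=float(D * D / denom), converged=converged)


def taggability(
    cnvrs: list[CNVR],
    genotypes: pd.DataFrame,
    snps: SnpData,
    window: int = 20_000,
    freq_min: float = 0.10,
    r2_min: float = 0.8,
) -> tuple[pd.DataFrame, float]:
    """Per-CNP maximum r^2 with flanking SNPs and the tagged proportion.

    Considers biallelic CNPs with carrier (event) frequency > ``freq_min``;
    candidate SNPs lie within ``window`` bp of either CNVR boundary (1-based
    SNP positions against half-open CNVR intervals). A CNP is tagged when its
    best flanking SNP reaches r^2 >= ``r2_min``. Returns the per-CNP table and
    the tagged proportion among common biallelic CNPs.
    """
    bi = biallelic_filter(genotypes)
    dosages = encode_dosage(genotypes, bi)
    by_id = {r.locus_id: r for r in cnvrs}
    rows = []
    for locus in bi["locus"]:
        r = by_id.get(locus)
        if r is None or r.event_frequency is None or r.event_frequency <= freq_min:
            continue
        near = snps.sites[
            (snps.sites["chrom"] == r.chrom)
            & (snps.sites["pos"] - 1 >= r.start - window)
            & (snps.sites["pos"] - 1 < r.end + window)
        ]
        best_r2, best_snp = np.nan, None
        for snp_id in near["snp_id"]:
            rec = two_locus_r2(
                dosages[locus].reindex(snps.dosages.index),
                snps.dosages[snp_id],
            )
            if rec.r2 == rec.r2 and not (best_r2 == best_r2 and rec.r2 <= best_r2):
                best_r2, best_snp = rec.r2, snp_id
        rows.append(
            {
                "locus": locus,
                "best_snp": best_snp,
                "max_r2": best_r2,
                "n_flanking_snps": len(near),
                "tagged": bool(best_r2 == best_r2 and best_r2 >= r2_min),
            }
        )
    table = pd.DataFrame(
        rows, columns=["locus", "best_snp", "max_r2", "n_flanking_snps", "tagged"]
    )
    prop = float(table["tagged"].mean()) if len(table) else np.nan
    return table, prop
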