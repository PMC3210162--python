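"""Readers and writers for the external formats the pipeline touches.

All genomic intervals are held internally as 0-based half-open ``[start, end)``.
Text output defaults to 1-based inclusive coordinates, the convention in which
array CNV maps are conventionally published; BED input/output is 0-based
half-open. Conversion happens only at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: autosome names accepted on input, with and without the ``chr`` prefix
AUTOSOMES = frozenset(
    [str(i) for i in range(1, 23)] + [f"chr{i}" for i in range(1, 23)]
)

CALL_COLUMNS = [
    "sample_id",
    "population",
    "chrom",
    "start",
    "end",
    "copy_state",
    "source",
    "lod",
    "confidence",
    "n_probes",
]

REQUIRED_CALL_COLUMNS = ["sample_id", "chrom", "start", "end", "copy_state", "source"]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class RecordError(ValueError):
    """A single record violates a field-level invariant."""


def is_autosome(chrom: str) -> bool:
    return str(chrom) in AUTOSOMES


def _to_internal(start, end, dialect: str):
    if dialect == "tsv_1based_inclusive":
        return start - 1, end
    if dialect == "bed_0based_halfopen":
        return start, end
    raise ValueError(f"unknown dialect: {dialect!r}")


def _to_external(start, end, dialect: str):
    if dialect == "tsv_1based_inclusive":
        return start + 1, end
    if dialect == "bed_0based_halfopen":
        return start, end
    raise ValueError(f"unknown dialect: {dialect!r}")


def read_cnv_calls(path, dialect: str = "tsv_1based_inclusive") -> pd.DataFrame:
    """Read a per-individual CNV call table.

    Parameters
    ----------
    path
        TSV file with a header row naming at least ``sample_id``, ``chrom``,
        ``start``, ``end``, ``copy_state`` and ``source``; ``population``,
        ``lod``, ``confidence`` and ``n_probes`` are optional (absent QC
        metadata passes filtering downstream).
    dialect
        ``tsv_1based_inclusive`` or ``bed_0based_halfopen``.

    Returns
    -------
    DataFrame with internal 0-based half-open coordinates, autosomes only.
    Non-autosomal rows are dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in REQUIRED_CALL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column: {col!r}")
    for col in ("population", "lod", "confidence", "n_probes"):
        if col not in df.columns:
            df[col] = np.nan
    df = df[CALL_COLUMNS].copy()

    bad_state = ~df["copy_state"].isin([0, 1, 2, 3, 4])
    if bad_state.any():
        line = int(df.index[bad_state][0]) + 2  # header + 1-based
        raise RecordError(
            f"copy_state outside 0-4 at line {line}: "
            f"{df.loc[df.index[bad_state][0], 'copy_state']!r}"
        )
    # state 2 is the copy-neutral background, never a call
    normal = df["copy_state"] == 2
    if normal.any():
        logger.info("rejected %d rows with copy_state 2 (not a call)", normal.sum())
        df = df[~normal]

    non_auto = ~df["chrom"].map(is_autosome)
    if non_auto.any():
        logger.info("rejected %d non-autosomal rows", int(non_auto.sum()))
        df = df[~non_auto]

    starts, ends = _to_internal(df["start"].to_numpy(), df["end"].to_numpy(), dialect)
    df = df.assign(start=starts, end=ends)
    if len(df) and (df["start"] >= df["end"]).any():
        i = df.index[(df["start"] >= df["end"])][0]
        raise RecordError(f"empty or inverted interval at input row {int(i) + 2}")
    df["copy_state"] = df["copy_state"].astype(int)
    return df.reset_index(drop=True)


def write_cnv_calls(calls: pd.DataFrame, path, dialect: str = "tsv_1based_inclusive") -> None:
    out = calls.copy()
    s, e = _to_external(out["start"].to_numpy(), out["end"].to_numpy(), dialect)
    out["start"], out["end"] = s, e
    out.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the (sample_id, population) sheet that carries population labels."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "population"):
        if col not in df.columns:
            raise FormatError(f"sample sheet missing column: {col!r}")
    return df[["sample_id", "population"]]


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples[["sample_id", "population"]].to_csv(path, sep="\t", index=False)


def read_intervals(path) -> pd.DataFrame:
    """Read a BED file (0-based half-open) into (chrom, start, end, name)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype={0: str}
    )
    if df.shape[1] < 3:
        raise FormatError("BED requires at least chrom, start, end")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.assign(name=".")
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    if "name" not in df.columns:
        df["name"] = "."
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        raise RecordError("BED interval with start < 0 or start >= end")
    return df


# ---------------------------------------------------------------------------
# SNP genotypes


@dataclass
class SnpData:
    """Unphased biallelic SNP dosages with site coordinates.

    Attributes
    ----------
    dosages : DataFrame
        samples x SNP matrix of alt-allele dosages 0/1/2 (NaN missing).
    sites : DataFrame
        one row per SNP: snp_id, chrom, pos (1-based, as in VCF).
    n_skipped : int
        multi-allelic or otherwise unusable records dropped on read.
    """

    dosages: pd.DataFrame
    sites: pd.DataFrame
    n_skipped: int = 0


def read_snp_genotypes(path, format: str = "vcf") -> SnpData:
    if format == "vcf":
        return _read_snp_vcf(path)
    if format == "matrix":
        return _read_snp_matrix(path)
    raise ValueError(f"unknown SNP format: {format!r}")


def _read_snp_vcf(path) -> SnpData:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)  # gt_types: 0/1/2 dosage, 3 unknown
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise FormatError(f"unreadable VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    ids, chroms, poss, rows = [], [], [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            skipped += 1
            continue
        gt = var.gt_types.astype(float)
        dos = np.where(gt == 3, np.nan, gt)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        rows.append(dos)
    dosages = pd.DataFrame(
        np.array(rows).T if rows else np.empty((len(samples), 0)),
        index=samples,
        columns=ids,
    )
    sites = pd.DataFrame({"snp_id": ids, "chrom": chroms, "pos": poss})
    return SnpData(dosages=dosages, sites=sites, n_skipped=skipped)


def _read_snp_matrix(path) -> SnpData:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        chrom_line = fh.readline().rstrip("\n").split("\t")
        pos_line = fh.readline().rstrip("\n").split("\t")
        body = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    if header[0] != "snp_id" or chrom_line[0] != "chrom" or pos_line[0] != "pos":
        raise FormatError("SNP matrix must start with snp_id/chrom/pos rows")
    ids = header[1:]
    body.columns = ids
    body.index.name = None
    sites = pd.DataFrame(
        {"snp_id": ids, "chrom": chrom_line[1:], "pos": [int(p) for p in pos_line[1:]]}
    )
    return SnpData(dosages=body.astype(float), sites=sites, n_skipped=0)


def write_snp_matrix(snps: SnpData, path) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\t" + "\t".join(snps.sites["snp_id"]) + "\n")
        fh.write("chrom\t" + "\t".join(map(str, snps.sites["chrom"])) + "\n")
        fh.write("pos\t" + "\t".join(map(str, snps.sites["pos"])) + "\n")
        snps.dosages.to_csv(fh, sep="\t", header=False, na_rep="nan")


def write_snp_vcf(snps: SnpData, path) -> None:
    """Write unphased biallelic dosages as a minimal VCF (A/C placeholder alleles)."""
    samples = list(snps.dosages.index)
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    sites = snps.sites.sort_values(["chrom", "pos"], kind="stable")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for _, site in sites.iterrows():
            col = snps.dosages[site["snp_id"]]
            gts = [code.get(v, "./.") if v == v else "./." for v in col]
            fh.write(
                f"{site['chrom']}\t{site['pos']}\t{site['snp_id']}\tA\tC\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


# ---------------------------------------------------------------------------
# CNVR map


def write_cnvr_map(cnvrs, path, dialect: str = "tsv_1based_inclusive") -> None:
    """Write a CNVR table (1-based inclusive by default) with class labels."""
    rows = []
    for r in cnvrs:
        s, e = _to_external(r.start, r.end, dialect)
        rows.append(
            {
                "chrom": r.chrom,
                "start": s,
                "end": e,
                "class": r.cnv_class,
                "singleton": int(r.singleton),
                "complex": int(r.complex),
                "n_samples": r.n_samples,
                "event_frequency": (
                    "" if r.event_frequency is None else f"{r.event_frequency:.6g}"
                ),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "class",
            "singleton",
            "complex",
            "n_samples",
            "event_frequency",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_cnvr_map(path, dialect: str = "tsv_1based_inclusive") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    s, e = _to_internal(df["start"].to_numpy(), df["end"].to_numpy(), dialect)
    df["start"], df["end"] = s, e
    return df


def write_genotype_matrix(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, sep="\t", na_rep="nan", index_label="sample_id")


def read_genotype_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


# ---------------------------------------------------------------------------
# Trees


def write_tree_newick(tree, path) -> None:
    """Write a scikit-bio TreeNode to a Newick file."""
    tree.write(str(path), format="newick")


def read_tree_newick(path):
    from skbio import TreeNode

    return TreeNode.read(str(path), format="newick")
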