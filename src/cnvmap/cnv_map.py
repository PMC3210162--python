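"""From filtered per-individual calls to the CNV map.

The map has two granularities:

* **CNVR** — the union of all calls that overlap transitively (connected
  component of the >=1 bp overlap graph, per chromosome).
* **CNVseg** — the minimal sub-segments of a CNVR obtained by cutting at every
  member call's breakpoints; segments tile the CNVR and never cross a member
  boundary, so per-sample copy state on a segment is unambiguous except in
  complex regions.

Per-sample genotypes at a locus are copy states 0-4; a sample with no call is
copy-neutral (2). A sample with several overlapping calls in one CNVR takes
the state of the longest call (ties: lower state, then leftmost start).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class CNVR:
    """A copy-number variable region: the union of overlapping calls."""

    chrom: str
    start: int
    end: int
    members: pd.DataFrame  # the member calls (internal coordinates)
    cnv_class: str = ""  # deletion | duplication | multiallelic
    singleton: bool = False
    complex: bool = False
    event_frequency: float | None = None
    n_samples: int = 0
    overlaps_reference: bool | None = None

    @property
    def locus_id(self) -> str:
        # 1-based inclusive label, the published convention
        return f"{self.chrom}:{self.start + 1}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CNVseg:
    chrom: str
    start: int
    end: int
    parent: CNVR

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.start + 1}-{self.end}"


# ---------------------------------------------------------------------------
# QC


def qc_filter_calls(
    calls: pd.DataFrame,
    min_len: int = 1000,
    min_probes: int = 3,
    min_lod: float = 5.0,
) -> pd.DataFrame:
    """Drop low-quality calls.

    A call is removed when its length, probe count or LOD falls *below* the
    threshold; equality survives. Absent metadata (NaN lod / n_probes) passes.
    Per-criterion removal counts are logged.
    """
    if min_len <= 0 or min_probes <= 0 or min_lod <= 0:
        raise ValueError("QC thresholds must be positive")
    length = calls["end"] - calls["start"]
    short = length < min_len
    few = calls["n_probes"].notna() & (calls["n_probes"] < min_probes)
    weak = calls["lod"].notna() & (calls["lod"] < min_lod)
    logger.info(
        "QC removed %d short, %d few-probe, %d low-LOD calls",
        int(short.sum()),
        int(few.sum()),
        int(weak.sum()),
    )
    return calls[~(short | few | weak)].reset_index(drop=True)


def qc_filter_samples(
    calls: pd.DataFrame, samples: pd.DataFrame, k_sd: float = 5.0
) -> tuple[list[str], list[str]]:
    """Exclude samples with an excessive number of deletion OR duplication events.

    The threshold is mean + k_sd * sd of the per-sample count over *all*
    samples (computed before any exclusion), separately for deletions and
    duplications; exceeding either excludes the sample. Samples with zero
    calls count as zero.
    """
    all_samples = list(samples["sample_id"])
    if len(all_samples) < 2:
        raise ValueError("sample QC requires at least 2 samples")
    is_del = calls["copy_state"] < 2
    counts = {}
    for label, mask in (("del", is_del), ("dup", ~is_del)):
        c = calls[mask].groupby("sample_id").size()
        counts[label] = np.array([c.get(s, 0) for s in all_samples], dtype=float)
    excluded = set()
    for label in ("del", "dup"):
        c = counts[label]
        thresh = c.mean() + k_sd * c.std(ddof=1)
        for s, n in zip(all_samples, c):
            if n > thresh:
                excluded.add(s)
    retained = [s for s in all_samples if s not in excluded]
    return retained, [s for s in all_samples if s in excluded]


def resolve_call_conflicts(
    calls: pd.DataFrame, max_confidence: float = 0.1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the CNP confidence filter and resolve CNP/rare-call conflicts.

    Returns ``(calls, missing_markers)``:

    * CNP-source calls with confidence > ``max_confidence`` are dropped and the
      (sample, interval) recorded as a missing marker — the sample's genotype
      at any locus covering the interval becomes missing, not copy-neutral.
    * Where one sample's overlapping calls disagree in copy state, only the
      highest-LOD call survives; an absent LOD counts as -inf. Equal LOD keeps
      the CNP-source call (genotyped at a predefined locus). Overlapping calls
      with the *same* state are all kept (they merge at CNVR construction).
    """
    conf = (
        (calls["source"] == "CNP")
        & calls["confidence"].notna()
        & (calls["confidence"] > max_confidence)
    )
    missing_markers = calls.loc[conf, ["sample_id", "chrom", "start", "end"]].reset_index(
        drop=True
    )
    kept = calls[~conf].reset_index(drop=True)

    drop = set()
    lod = kept["lod"].fillna(-np.inf)
    for (_, _), idx in kept.groupby(["sample_id", "chrom"]).groups.items():
        sub = kept.loc[idx].sort_values(["start", "end"], kind="stable")
        rows = list(sub.itertuples())
        for i, a in enumerate(rows):
            for b in rows[i + 1 :]:
                if b.start >= a.end:
                    break
                if a.copy_state == b.copy_state:
                    continue
                la, lb = lod[a.Index], lod[b.Index]
                if la > lb:
                    drop.add(b.Index)
                elif lb > la:
                    drop.add(a.Index)
                else:  # tie on LOD: the CNP call wins; tie again keeps the first
                    if a.source == b.source:
                        drop.add(b.Index)
                    elif a.source == "CNP":
                        drop.add(b.Index)
                    else:
                        drop.add(a.Index)
                    logger.info(
                        "equal-LOD conflict for %s at %s:%d-%d",
                        a.sample_id,
                        a.chrom,
                        min(a.start, b.start),
                        max(a.end, b.end),
                    )
    resolved = kept.drop(index=list(drop)).reset_index(drop=True)
    return resolved, missing_markers


# ---------------------------------------------------------------------------
# Map construction


def build_cnvrs(calls: pd.DataFrame) -> list[CNVR]:
    """Merge calls with any positive overlap into CNVRs.

    Connected components of the >=1 bp overlap graph per chromosome; the CNVR
    extent is the union of its members. Abutting calls (zero shared bp) do
    not merge. Output sorted by (chrom, start).
    """
    cnvrs: list[CNVR] = []
    for chrom, sub in calls.groupby("chrom"):
        sub = sub.sort_values(["start", "end"], kind="stable")
        cur_idx: list = []
        cur_end = -1
        for row in sub.itertuples():
            if cur_idx and row.start < cur_end:
                cur_idx.append(row.Index)
                cur_end = max(cur_end, row.end)
            else:
                if cur_idx:
                    cnvrs.append(_make_cnvr(chrom, calls.loc[cur_idx]))
                cur_idx = [row.Index]
                cur_end = row.end
        if cur_idx:
            cnvrs.append(_make_cnvr(chrom, calls.loc[cur_idx]))
    cnvrs.sort(key=lambda r: (r.chrom, r.start, r.end))
    return cnvrs


def _make_cnvr(chrom: str, members: pd.DataFrame) -> CNVR:
    r = CNVR(
        chrom=str(chrom),
        start=int(members["start"].min()),
        end=int(members["end"].max()),
        members=members.reset_index(drop=True),
    )
    states = r.members["copy_state"]
    if (states < 2).all():
        r.cnv_class = "deletion"
    elif (states > 2).all():
        r.cnv_class = "duplication"
    else:
        r.cnv_class = "multiallelic"
    r.n_samples = r.members["sample_id"].nunique()
    r.singleton = r.n_samples == 1
    per_sample = r.members.groupby("sample_id")["copy_state"]
    r.complex = bool(((per_sample.min() < 2) & (per_sample.max() > 2)).any())
    return r


def dissect_cnvsegs(cnvr: CNVR) -> list[CNVseg]:
    """Cut the CNVR at every member breakpoint into tiling segments."""
    bounds = sorted(set(cnvr.members["start"]) | set(cnvr.members["end"]))
    return [
        CNVseg(chrom=cnvr.chrom, start=int(a), end=int(b), parent=cnvr)
        for a, b in zip(bounds[:-1], bounds[1:])
    ]


def assign_genotypes(
    calls: pd.DataFrame,
    loci,
    samples,
    missing_markers: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Samples x loci matrix of copy-state genotypes.

    ``loci`` is a list of CNVR or CNVseg. No overlapping call -> 2; one call
    -> its state; several -> the state of the longest overlapping call, ties
    broken toward the lower state then the leftmost start. A sample whose
    confidence-dropped CNP call overlaps the locus is missing (NaN) there
    unless a surviving call genotypes it.
    """
    sample_ids = list(samples["sample_id"]) if isinstance(samples, pd.DataFrame) else list(samples)
    order = {s: i for i, s in enumerate(sample_ids)}
    mat = np.full((len(sample_ids), len(loci)), 2.0)

    by_chrom = {c: g.sort_values("start", kind="stable") for c, g in calls.groupby("chrom")}
    miss_by_chrom = (
        {c: g for c, g in missing_markers.groupby("chrom")}
        if missing_markers is not None and len(missing_markers)
        else {}
    )

    for j, locus in enumerate(loci):
        sub = by_chrom.get(locus.chrom)
        best: dict[str, tuple] = {}
        if sub is not None:
            hit = sub[(sub["start"] < locus.end) & (sub["end"] > locus.start)]
            for row in hit.itertuples():
                if row.sample_id not in order:
                    continue
                # rank by (longer, lower state, leftmost); max() picks the winner
                key = (row.end - row.start, -row.copy_state, -row.start)
                if row.sample_id not in best or key > best[row.sample_id][0]:
                    best[row.sample_id] = (key, row.copy_state)
        mm = miss_by_chrom.get(locus.chrom)
        if mm is not None:
            miss_hit = mm[(mm["start"] < locus.end) & (mm["end"] > locus.start)]
            for row in miss_hit.itertuples():
                if row.sample_id in order and row.sample_id not in best:
                    mat[order[row.sample_id], j] = np.nan
        for s, (_, state) in best.items():
            mat[order[s], j] = state

    return pd.DataFrame(mat, index=sample_ids, columns=[l.locus_id for l in loci])


def classify_cnvr(cnvr: CNVR, genotype_column: pd.Series) -> CNVR:
    """Fill event frequency from assigned genotypes; class/singleton/complex
    are structural and already set at construction."""
    non_missing = genotype_column.notna()
    carriers = non_missing & (genotype_column != 2)
    n = int(non_missing.sum())
    cnvr.event_frequency = float(carriers.sum()) / n if n else None
    return cnvr


def compare_reference(cnvrs: list[CNVR], reference: pd.DataFrame) -> int:
    """Flag each CNVR known iff it shares >=1 bp with any reference interval;
    return the number of novel CNVRs."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for row in reference.itertuples():
        trees.setdefault(str(row.chrom), IntervalTree()).addi(row.start, row.end)
    novel = 0
    for r in cnvrs:
        t = trees.get(r.chrom)
        r.overlaps_reference = bool(t.overlap(r.start, r.end)) if t is not None else False
        novel += not r.overlaps_reference
    return novel


def build_map(
    calls: pd.DataFrame,
    samples: pd.DataFrame,
    missing_markers: pd.DataFrame | None = None,
    with_segments: bool = False,
):
    """Convenience: CNVRs (+ optionally segments) and their genotype matrices."""
    cnvrs = build_cnvrs(calls)
    genotypes = assign_genotypes(calls, cnvrs, samples, missing_markers)
    for r in cnvrs:
        classify_cnvr(r, genotypes[r.locus_id])
    if not with_segments:
        return cnvrs, genotypes
    segs = [s for r in cnvrs for s in dissect_cnvsegs(r)]
    seg_genotypes = assign_genotypes(calls, segs, samples, missing_markers)
    return cnvrs, genotypes, segs, seg_genotypes
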