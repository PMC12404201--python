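"""Back-splice junction calling and quantification.

A back-splice read is a split read whose two segments map to the same
chromosome and strand but out of transcriptional order: on the plus strand
the second segment lies genomically upstream of the first (the read runs off
the circle's donor and re-enters at the acceptor).  Candidate junctions are
kept only when the intronic dinucleotides flanking the junction are the
canonical GT (donor side) / AG (acceptor side) on the transcribed strand.
Counts are aggregated at exact coordinates; fuzzy collapsing belongs to the
annotation layer.

The circular-to-linear junction ratio is 2*bsj / (2*bsj + fsj): each
back-spliced molecule contributes two junction-crossing opportunities
(acceptor and donor) whereas each linear molecule contributes one per
boundary crossed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._util import child_rng


@dataclass
class CircRNA:
    circ_id: str
    chrom: str
    strand: str
    start: int  # acceptor boundary on '+' genes; genomic leftmost always
    end: int  # donor boundary on '+' genes; genomic rightmost (half-open)
    host_gene_id: Optional[str] = None
    canonical: bool = True
    bsj: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.circ_id}: start must precede end")


def circ_key(chrom: str, strand: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}:{strand}"


def canonical_flanks(genome: dict[str, str], chrom: str, strand: str, start: int, end: int) -> bool:
    """GT just past the donor and AG just before the acceptor, on the
    transcribed strand (genomic complements on the minus strand)."""
    seq = genome[chrom]
    if start - 2 < 0 or end + 2 > len(seq):
        return False
    left = seq[start - 2 : start]
    right = seq[end : end + 2]
    if strand == "+":
        return right == "GT" and left == "AG"
    return left == "AC" and right == "CT"


def detect_bsj_reads(reads: pd.DataFrame, genome: dict[str, str]) -> pd.DataFrame:
    """Per-read back-splice candidates that pass the canonical GT/AG check.

    Returns one row per accepted read with the junction coordinates
    (``start`` = genomic acceptor-side boundary, ``end`` = donor-side).
    """
    rows = []
    for r in reads.itertuples(index=False):
        if r.seg2_start < 0:  # contiguous read, cannot be a back-splice
            continue
        if r.chrom not in genome:
            raise ValueError(f"unknown chromosome {r.chrom!r}")
        clen = len(genome[r.chrom])
        for s, e in ((r.seg1_start, r.seg1_end), (r.seg2_start, r.seg2_end)):
            if s < 0 or e > clen:
                raise ValueError(f"read {r.read_id}: segment [{s},{e}) beyond chromosome end")
        if r.strand == "+":
            backsplice = r.seg2_start < r.seg1_start
            start, end = r.seg2_start, r.seg1_end
        else:
            backsplice = r.seg2_start > r.seg1_start
            start, end = r.seg1_start, r.seg2_end
        if not backsplice or start >= end:
            continue
        if not canonical_flanks(genome, r.chrom, r.strand, start, end):
            continue
        rows.append((r.read_id, r.chrom, r.strand, start, end))
    return pd.DataFrame(rows, columns=["read_id", "chrom", "strand", "start", "end"])


def call_bsj(reads: pd.DataFrame, genome: dict[str, str]) -> list[CircRNA]:
    """Aggregate accepted back-splice reads into circRNA calls."""
    accepted = detect_bsj_reads(reads, genome)
    if accepted.empty:
        return []
    counts = (
        accepted.groupby(["chrom", "strand", "start", "end"]).size().reset_index(name="bsj")
    )
    circs = []
    for r in counts.itertuples(index=False):
        circs.append(
            CircRNA(
                circ_id=circ_key(r.chrom, r.strand, r.start, r.end),
                chrom=r.chrom,
                strand=r.strand,
                start=int(r.start),
                end=int(r.end),
                canonical=True,
                bsj=int(r.bsj),
            )
        )
    return sorted(circs, key=lambda c: (c.chrom, c.start, c.end, c.strand))


def count_fsj(reads: pd.DataFrame, circs: Sequence[CircRNA]) -> pd.DataFrame:
    """Reads colinearly spanning either circle boundary, deduplicated per read.

    A colinear read spans a boundary b when a contiguous segment crosses it
    (seg_start < b < seg_end) or when its splice junction coincides with the
    boundary's linear junction (intron ending at the acceptor or starting at
    the donor).
    """
    out = []
    for c in circs:
        sub = reads[(reads["chrom"] == c.chrom) & (reads["strand"] == c.strand)]
        n = 0
        for r in sub.itertuples(index=False):
            segs = [(r.seg1_start, r.seg1_end)]
            junction = None
            if r.seg2_start >= 0:
                segs.append((r.seg2_start, r.seg2_end))
                # colinear means transcript order == genomic order; skip back-splices
                if r.strand == "+" and r.seg2_start < r.seg1_start:
                    continue
                if r.strand == "-" and r.seg2_start > r.seg1_start:
                    continue
                lo_end = min(r.seg1_end, r.seg2_end)
                hi_start = max(r.seg1_start, r.seg2_start)
                junction = (lo_end, hi_start)
            crosses = any(s < b < e for s, e in segs for b in (c.start, c.end))
            if junction is not None:
                jlo, jhi = junction
                crosses = crosses or jlo == c.end or jhi == c.start
            if crosses:
                n += 1
        out.append({"circ_id": c.circ_id, "fsj": n})
    return pd.DataFrame(out)


def junction_ratio(bsj, fsj):
    """2*bsj / (2*bsj + fsj); NaN when both counts are zero."""
    bsj_arr = np.asarray(bsj, dtype=float)
    fsj_arr = np.asarray(fsj, dtype=float)
    if np.any(bsj_arr < 0) or np.any(fsj_arr < 0):
        raise ValueError("counts must be non-negative")
    denom = 2.0 * bsj_arr + fsj_arr
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(denom > 0, 2.0 * bsj_arr / denom, np.nan)
    if np.isscalar(bsj) and np.isscalar(fsj):
        return float(ratio)
    return ratio


def junction_counts(
    reads: pd.DataFrame, genome: dict[str, str], sample_id: str = "s1"
) -> pd.DataFrame:
    """Convenience: call BSJs, count FSJs, compute the junction ratio."""
    circs = call_bsj(reads, genome)
    fsj = count_fsj(reads, circs).set_index("circ_id")["fsj"]
    rows = []
    for c in circs:
        f = int(fsj.get(c.circ_id, 0))
        rows.append(
            {
                "circ_id": c.circ_id,
                "sample_id": sample_id,
                "bsj": c.bsj,
                "fsj": f,
                "junction_ratio": junction_ratio(c.bsj, f),
            }
        )
    return pd.DataFrame(rows)


def filter_reference(counts: pd.DataFrame, min_bsj: int = 5) -> pd.DataFrame:
    """Keep circRNAs with >= ``min_bsj`` pooled BSJ reads in at least one
    population; the qualifying population(s) are recorded as provenance.

    ``counts`` needs columns circ_id, population, bsj (replicates may appear
    as multiple rows; they are pooled within population).
    """
    pooled = counts.groupby(["circ_id", "population"], as_index=False)["bsj"].sum()
    ok = pooled[pooled["bsj"] >= min_bsj]
    if ok.empty:
        return pd.DataFrame(columns=["circ_id", "populations", "max_bsj"])
    prov = ok.groupby("circ_id").agg(
        populations=("population", lambda p: ",".join(sorted(p))),
        max_bsj=("bsj", "max"),
    )
    return prov.reset_index()


def saturation_curve(
    bsj_reads: pd.DataFrame,
    fractions: Sequence[float] = (1, 5, 10, 25, 50, 75, 100),
    n_reps: int = 3,
    seed: int = 0,
    min_bsj: int = 5,
) -> pd.DataFrame:
    """Detection saturation under read subsampling without replacement.

    ``bsj_reads`` is the per-read table from :func:`detect_bsj_reads`
    (pooled over replicates).  For each fraction the accepted reads are
    subsampled, detection at >= ``min_bsj`` recomputed, and recovery
    expressed against the full-set detections, averaged over replicates.
    """
    if bsj_reads.empty:
        raise ValueError("no back-splice reads to subsample")
    for f in fractions:
        if not (0 < f <= 100):
            raise ValueError(f"fraction {f} outside (0, 100]")
    keys = bsj_reads[["chrom", "strand", "start", "end"]].apply(tuple, axis=1).to_numpy()
    full_counts = pd.Series(keys).value_counts()
    full_set = set(full_counts[full_counts >= min_bsj].index)
    if not full_set:
        raise ValueError(f"no circRNA reaches {min_bsj} reads in the full set")
    rng = child_rng(seed, 97)
    n = len(keys)
    rows = []
    for f in fractions:
        take = int(np.floor(f / 100.0 * n + 0.5))
        recs, dets = [], []
        reps = 1 if f == 100 else n_reps
        for _ in range(reps):
            idx = rng.choice(n, size=take, replace=False)
            counts = pd.Series(keys[idx]).value_counts()
            detected = set(counts[counts >= min_bsj].index) & full_set
            dets.append(len(detected))
            recs.append(len(detected) / len(full_set))
        rows.append(
            {"fraction": f, "n_detected": float(np.mean(dets)), "recovery": float(np.mean(recs))}
        )
    return pd.DataFrame(rows)
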