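"""Intron database construction and circRNA-relative intron classification.

circRNA biogenesis is shaped by the introns that flank the back-splice
boundaries, so the central bookkeeping object here is an intron database
derived from protein-coding gene models: terminal exons belonging to
alternative transcription starts/ends are excluded, optionally non-expressed
exons are dropped, and the union of the remaining exons is subtracted from
the gene span.  Introns are then classified relative to (collapsed) circRNAs
as flanking (immediately upstream/downstream of a back-splice boundary in
transcription direction), nonflanking (other introns of a circRNA-hosting
gene), or belonging to other genes.

All coordinates are 0-based half-open on the genomic forward strand;
"upstream"/"downstream" follow the direction of transcription.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

#: shortest gap between retained exons that still counts as an intron (nt)
MIN_INTRON_LEN = 10

#: maximum distance (nt, inclusive) for circRNA collapse and flank assignment
DEFAULT_TOL = 10


@dataclass
class GeneModel:
    """A gene with one or more transcripts, each a sorted list of exons."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: list  # list of lists of (start, end) tuples
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        for t in self.transcripts:
            if len(t) < 1:
                raise ValueError(f"{self.gene_id}: transcript with no exons")
            ordered = sorted(t)
            for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
                if e1 > s2:
                    raise ValueError(f"{self.gene_id}: overlapping exons in one transcript")

    @property
    def span(self) -> tuple[int, int]:
        starts = [e[0] for t in self.transcripts for e in t]
        ends = [e[1] for t in self.transcripts for e in t]
        return min(starts), max(ends)


@dataclass
class IntronRecord:
    intron_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    klass: str = "other_gene"  # flank_up | flank_down | nonflanking | other_gene
    circ_ids: list = field(default_factory=list)
    double_flank: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CircCluster:
    """CircRNAs whose 5' and 3' ends chain together within the tolerance."""

    cluster_id: str
    chrom: str
    strand: str
    start: int  # leftmost member start
    end: int  # rightmost member end
    members: list  # member circ_ids
    host_gene_ids: set = field(default_factory=set)


def build_intron_db(
    genes: Iterable[GeneModel],
    expressed_exons: Optional[set] = None,
    min_intron_len: int = MIN_INTRON_LEN,
) -> list[IntronRecord]:
    """Subtract retained exons from protein-coding gene spans.

    Per transcript the first/last exon is dropped when its outer boundary
    differs from the gene-level outermost boundary (alternative TSS/TES).
    ``expressed_exons``, when given, is a whitelist of ``(chrom, start, end)``
    tuples; exons absent from it are dropped before subtraction.  Gaps
    shorter than ``min_intron_len`` are discarded.
    """
    records: list[IntronRecord] = []
    for gene in genes:
        if gene.biotype != "protein_coding":
            continue
        gmin, gmax = gene.span
        retained: set[tuple[int, int]] = set()
        for t in gene.transcripts:
            exons = sorted(t)
            drop_first = exons[0][0] != gmin
            drop_last = exons[-1][1] != gmax
            keep = list(exons)
            if drop_last:
                keep = keep[:-1]
            if drop_first and keep and keep[0] == exons[0]:
                keep = keep[1:]
            retained.update(keep)
        if expressed_exons is not None:
            retained = {
                e for e in retained if (gene.chrom, e[0], e[1]) in expressed_exons
            }
        merged = _merge_intervals(sorted(retained))
        gaps = _complement(merged, gmin, gmax)
        k = 0
        for s, e in gaps:
            if e - s < min_intron_len:
                continue
            records.append(
                IntronRecord(
                    intron_id=f"{gene.gene_id}_I{k}",
                    gene_id=gene.gene_id,
                    chrom=gene.chrom,
                    strand=gene.strand,
                    start=s,
                    end=e,
                )
            )
            k += 1
    return records


def _merge_intervals(ivs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _complement(ivs: Sequence[tuple[int, int]], lo: int, hi: int) -> list[tuple[int, int]]:
    gaps = []
    cursor = lo
    for s, e in ivs:
        if s > cursor:
            gaps.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < hi:
        gaps.append((cursor, hi))
    return gaps


def collapse_circrnas(circs: Sequence, tol: int = DEFAULT_TOL) -> list[CircCluster]:
    """Single-linkage collapse of circRNAs with both ends within ``tol`` nt.

    Two circRNAs link iff they share chrom and strand and both their 5' and
    3' genomic boundaries differ by at most ``tol``; clusters are the
    connected components (so chains merge transitively).
    """
    circs = list(circs)
    n = len(circs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    order = sorted(range(n), key=lambda i: (circs[i].chrom, circs[i].strand, circs[i].start))
    for a in range(n):
        i = order[a]
        for b in range(a + 1, n):
            j = order[b]
            if (circs[j].chrom, circs[j].strand) != (circs[i].chrom, circs[i].strand):
                break
            if circs[j].start - circs[i].start > tol:
                break
            if abs(circs[i].start - circs[j].start) <= tol and abs(circs[i].end - circs[j].end) <= tol:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    clusters = []
    for k, idxs in enumerate(sorted(groups.values(), key=lambda g: min(circs[i].start for i in g))):
        members = [circs[i] for i in idxs]
        hosts = {c.host_gene_id for c in members if getattr(c, "host_gene_id", None)}
        clusters.append(
            CircCluster(
                cluster_id=f"cc{k}",
                chrom=members[0].chrom,
                strand=members[0].strand,
                start=min(c.start for c in members),
                end=max(c.end for c in members),
                members=[c.circ_id for c in members],
                host_gene_ids=hosts,
            )
        )
    return clusters


def assign_flanking_introns(
    clusters: Sequence[CircCluster],
    introns: Sequence[IntronRecord],
    tol: int = DEFAULT_TOL,
) -> list[IntronRecord]:
    """Label introns relative to collapsed circRNAs.

    An intron abutting (within ``tol`` nt) the circRNA's 5' back-splice
    boundary is ``flank_up``; one abutting the 3' boundary is ``flank_down``.
    Labels follow transcription direction, so on the minus strand the genomic
    relations swap.  Remaining introns of circRNA-hosting genes become
    ``nonflanking``; introns of all other genes become ``other_gene``.
    A single-intron circle geometry (both boundaries hit by the same intron)
    is flagged via ``double_flank`` and keeps both links.
    """
    # genes hosting a cluster: explicit membership, else cluster within the
    # gene's intron hull (multi-gene loci disambiguation is out of scope)
    hull: dict[str, tuple[str, str, int, int]] = {}
    for i in introns:
        c, st, s, e = hull.get(i.gene_id, (i.chrom, i.strand, i.start, i.end))
        hull[i.gene_id] = (i.chrom, i.strand, min(s, i.start), max(e, i.end))
    hosting: set[str] = set()
    for cl in clusters:
        hosting |= cl.host_gene_ids
        for g, (c, st, s, e) in hull.items():
            if (c, st) == (cl.chrom, cl.strand) and s - tol <= cl.start and cl.end <= e + tol:
                hosting.add(g)

    out: list[IntronRecord] = []
    for i in introns:
        up_links: list[str] = []
        down_links: list[str] = []
        for cl in clusters:
            if (cl.chrom, cl.strand) != (i.chrom, i.strand):
                continue
            if i.strand == "+":
                is_up = abs(i.end - cl.start) <= tol
                is_down = abs(i.start - cl.end) <= tol
            else:
                is_up = abs(i.start - cl.end) <= tol
                is_down = abs(i.end - cl.start) <= tol
            if is_up:
                up_links.append(cl.cluster_id)
            if is_down:
                down_links.append(cl.cluster_id)
        if up_links and down_links:
            klass, double = "flank_up", True
        elif up_links:
            klass, double = "flank_up", False
        elif down_links:
            klass, double = "flank_down", False
        elif i.gene_id in hosting:
            klass, double = "nonflanking", False
        else:
            klass, double = "other_gene", False
        out.append(
            IntronRecord(
                intron_id=i.intron_id,
                gene_id=i.gene_id,
                chrom=i.chrom,
                strand=i.strand,
                start=i.start,
                end=i.end,
                klass=klass,
                circ_ids=sorted(set(up_links + down_links)),
                double_flank=double,
            )
        )
    return out


def introns_to_frame(introns: Sequence[IntronRecord]) -> pd.DataFrame:
    """Intron DB as a BED6-plus table (score column carries length)."""
    return pd.DataFrame(
        {
            "chrom": [i.chrom for i in introns],
            "start": [i.start for i in introns],
            "end": [i.end for i in introns],
            "name": [i.intron_id for i in introns],
            "score": [i.length for i in introns],
            "strand": [i.strand for i in introns],
            "gene_id": [i.gene_id for i in introns],
            "klass": [i.klass for i in introns],
            "circ_ids": [",".join(i.circ_ids) for i in introns],
            "double_flank": [i.double_flank for i in introns],
        }
    )


def frame_to_introns(df: pd.DataFrame) -> list[IntronRecord]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            IntronRecord(
                intron_id=row.name,
                gene_id=row.gene_id,
                chrom=row.chrom,
                strand=row.strand,
                start=int(row.start),
                end=int(row.end),
                klass=row.klass,
                circ_ids=[c for c in str(row.circ_ids).split(",") if c and c != "nan"],
                double_flank=bool(row.double_flank),
            )
        )
    return out
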