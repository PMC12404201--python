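"""Cotranscriptional splicing efficiency from nascent read counts.

Per intron, nascent signal in the last (3') 30% of the intron is compared
with signal in the first (5') 30% of the downstream exon, both taken in
transcription direction.  Efficiency is 1 minus the ratio of the two per-nt
densities, clamped to [0, 1]: values near 1 mean the intron is removed
quickly relative to transcription, values near 0 mean it lingers.

Window lengths use round-half-up and must be at least 1 nt; a feature whose
window would round to zero raises.  Library scaling cancels in the ratio but
is accepted for interface symmetry.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_up
from .annotation import GeneModel, IntronRecord

WINDOW_FRACTION = 0.3


def make_windows(
    intron_start: int,
    intron_end: int,
    strand: str,
    exon_start: int,
    exon_end: int,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """(intron window, exon window) in genomic coordinates.

    The intron window is the transcribed-strand last 30% of the intron; the
    exon window is the first 30% of the downstream exon.  On the minus
    strand those are the genomically leftmost/rightmost segments.
    """
    ilen = intron_end - intron_start
    elen = exon_end - exon_start
    wi = round_half_up(WINDOW_FRACTION * ilen)
    we = round_half_up(WINDOW_FRACTION * elen)
    if wi < 1 or we < 1:
        raise ValueError("feature too short: 30% window rounds to 0 nt")
    if strand == "+":
        return (intron_end - wi, intron_end), (exon_start, exon_start + we)
    return (intron_start, intron_start + wi), (exon_end - we, exon_end)


def splicing_efficiency(
    intron_count: float,
    exon_count: float,
    intron_window_len: int,
    exon_window_len: int,
    lib_size: float = 1.0,
) -> float:
    """1 - (intron density / exon density), clamped to [0, 1]; NaN when the
    exon window is empty."""
    if intron_count < 0 or exon_count < 0:
        raise ValueError("counts must be non-negative")
    if intron_window_len < 1 or exon_window_len < 1:
        raise ValueError("window lengths must be >= 1 nt")
    dens_i = intron_count / intron_window_len / lib_size
    dens_e = exon_count / exon_window_len / lib_size
    if dens_e == 0:
        return float("nan")
    return float(np.clip(1.0 - dens_i / dens_e, 0.0, 1.0))


def intron_downstream_exons(genes: Sequence[GeneModel]) -> dict:
    """Map (chrom, strand, intron_start, intron_end) -> downstream exon.

    The downstream exon is the exon transcribed immediately after the
    intron: genomically right on '+', genomically left on '-'.
    Uses the first transcript of each gene.
    """
    out = {}
    for g in genes:
        exons = sorted(g.transcripts[0])
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            key = (g.chrom, g.strand, e1, s2)
            out[key] = (s2, e2) if g.strand == "+" else (s1, e1)
    return out


def _window_count(track: pd.DataFrame, chrom: str, strand: str, lo: int, hi: int) -> int:
    sel = (
        (track["chrom"] == chrom)
        & (track["strand"] == strand)
        & (track["pos"] >= lo)
        & (track["pos"] < hi)
    )
    return int(track.loc[sel, "count"].sum())


def efficiency_table(
    introns: Sequence[IntronRecord],
    downstream_exons: dict,
    track: pd.DataFrame,
    lib_size: float = 1.0,
) -> pd.DataFrame:
    """Per-intron windows, counts and efficiencies from a position-count track."""
    rows = []
    for i in introns:
        key = (i.chrom, i.strand, i.start, i.end)
        if key not in downstream_exons:
            continue
        ex = downstream_exons[key]
        (iw_lo, iw_hi), (ew_lo, ew_hi) = make_windows(i.start, i.end, i.strand, ex[0], ex[1])
        ic = _window_count(track, i.chrom, i.strand, iw_lo, iw_hi)
        ec = _window_count(track, i.chrom, i.strand, ew_lo, ew_hi)
        rows.append(
            {
                "intron_id": i.intron_id,
                "gene_id": i.gene_id,
                "klass": i.klass,
                "length": i.length,
                "intron_window": f"{iw_lo}-{iw_hi}",
                "exon_window": f"{ew_lo}-{ew_hi}",
                "intron_count": ic,
                "exon_count": ec,
                "efficiency": splicing_efficiency(ic, ec, iw_hi - iw_lo, ew_hi - ew_lo, lib_size),
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    records: pd.DataFrame,
    length_bins: Optional[Sequence[float]] = None,
    group_col: str = "group",
    alternative: str = "less",
) -> pd.DataFrame:
    """Length-binned group comparison of splicing efficiencies.

    ``records`` needs columns intron_id, length, efficiency and a group
    column with exactly two levels.  Within each length bin the second group
    (sorted order) is tested against the first with a one-tailed Welch
    t-test (default alternative: second < first).  Empty bins yield NA rows.
    """
    groups = sorted(records[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError("compare_groups needs exactly two groups")
    if length_bins is None:
        lo = max(1.0, records["length"].min() * 0.999)
        hi = records["length"].max() * 1.001
        length_bins = np.logspace(np.log10(lo), np.log10(hi), 6)
    length_bins = np.asarray(length_bins, dtype=float)
    binned = pd.cut(records["length"], bins=length_bins, include_lowest=True)
    rows = []
    for interval in binned.cat.categories:
        sub = records[binned == interval]
        a = sub.loc[sub[group_col] == groups[0], "efficiency"].dropna()
        b = sub.loc[sub[group_col] == groups[1], "efficiency"].dropna()
        if len(a) >= 2 and len(b) >= 2:
            p = float(stats.ttest_ind(b, a, equal_var=False, alternative=alternative).pvalue)
        else:
            p = np.nan
        for g, vals in ((groups[0], a), (groups[1], b)):
            rows.append(
                {
                    "length_bin": str(interval),
                    group_col: g,
                    "n": len(vals),
                    "median_efficiency": float(vals.median()) if len(vals) else np.nan,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)
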