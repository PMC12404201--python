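"""Cross-link enrichment across intron classes and positional metaprofiles.

Input is a strand-aware position-count track of cross-link sites (iCount
style: 1-nt BED intervals, pile-up count in the score).  Enrichment across
intron classes is tested as a chi-square goodness of fit of raw per-group
counts against a length-proportional expectation — the same normalization
as comparing per-kb densities, but keeping counts integral so the test is
well defined.  Metaprofiles map positions into length-normalized bins in
transcription orientation, either over introns or centered on RCM spans
with fixed-width nucleotide flanks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import IntronRecord

FLANK_CLASSES = ("flank_up", "flank_down")


@dataclass
class EnrichmentResult:
    groups: list
    counts: np.ndarray
    lengths: np.ndarray
    densities_per_kb: np.ndarray
    proportions: np.ndarray  # length-normalized, summing to 1
    chi2: float
    p_value: float
    df: int


def introns_to_groups(
    introns: Sequence[IntronRecord], scheme: str = "three"
) -> dict[str, list[IntronRecord]]:
    """Partition introns into the groups the enrichment test contrasts.

    ``three``: flanking (both orientations pooled) vs nonflanking vs other
    genes; ``flank_vs_nonflank``: the two-group version.
    """
    flank = [i for i in introns if i.klass in FLANK_CLASSES]
    nonfl = [i for i in introns if i.klass == "nonflanking"]
    other = [i for i in introns if i.klass == "other_gene"]
    if scheme == "three":
        return {"flanking": flank, "nonflanking": nonfl, "other": other}
    if scheme == "flank_vs_nonflank":
        return {"flanking": flank, "nonflanking": nonfl}
    raise ValueError(f"unknown scheme {scheme!r}")


def _track_sum(track: pd.DataFrame, intron: IntronRecord) -> int:
    sel = (
        (track["chrom"] == intron.chrom)
        & (track["strand"] == intron.strand)
        & (track["pos"] >= intron.start)
        & (track["pos"] < intron.end)
    )
    return int(track.loc[sel, "count"].sum())


def group_enrichment(
    track: pd.DataFrame, groups: dict[str, Sequence[IntronRecord]]
) -> EnrichmentResult:
    """Chi-square test of cross-link counts vs length-proportional expectation."""
    names = [g for g in groups if len(groups[g]) > 0]
    if len(names) < 2:
        raise ValueError("need at least two non-empty groups")
    counts = np.array(
        [sum(_track_sum(track, i) for i in groups[g]) for g in names], dtype=float
    )
    lengths = np.array([sum(i.length for i in groups[g]) for g in names], dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("every group needs positive total length")
    total = counts.sum()
    dens = counts / lengths * 1000.0
    if total == 0:
        warnings.warn("no cross-link sites in any group; returning NA result")
        return EnrichmentResult(
            names, counts, lengths, dens, np.full(len(names), np.nan),
            float("nan"), float("nan"), len(names) - 1,
        )
    with np.errstate(invalid="ignore"):
        props = (counts / lengths) / (counts / lengths).sum()
    expected = total * lengths / lengths.sum()
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    dof = len(names) - 1
    p = float(stats.chi2.sf(chi2, dof))
    return EnrichmentResult(names, counts, lengths, dens, props, chi2, p, dof)


def intron_metaprofile(
    track: pd.DataFrame,
    introns: Sequence[IntronRecord],
    n_bins: int = 100,
    per_intron_norm: bool = False,
) -> np.ndarray:
    """Summed cross-link pile-up over length-normalized introns.

    Bin 0 is the transcribed 5' end of the intron; on minus-strand introns
    the genomic right end maps to bin 0.  Positions map to bins by
    floor(position_fraction * n_bins).
    """
    if not introns:
        raise ValueError("no introns to profile")
    profile = np.zeros(n_bins, dtype=float)
    for i in introns:
        sel = (
            (track["chrom"] == i.chrom)
            & (track["strand"] == i.strand)
            & (track["pos"] >= i.start)
            & (track["pos"] < i.end)
        )
        sub = track.loc[sel]
        if sub.empty:
            continue
        rel = sub["pos"].to_numpy() - i.start
        if i.strand == "-":
            rel = (i.length - 1) - rel
        bins = np.minimum(rel * n_bins // i.length, n_bins - 1)
        w = sub["count"].to_numpy().astype(float)
        if per_intron_norm and w.sum() > 0:
            w = w / w.sum()
        np.add.at(profile, bins, w)
    return profile


def rcm_metaprofile(
    track: pd.DataFrame,
    rcm_regions: pd.DataFrame,
    flank: int = 1000,
    n_interior_bins: int = 50,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> dict[str, np.ndarray]:
    """Cross-link pile-up at RCM spans and their surrounding flanks.

    ``rcm_regions`` needs chrom, strand, start, end and a ``side`` column
    ('up' for upstream-intron spans, 'down' for downstream).  Each profile
    has ``flank`` 1-nt upstream bins, ``n_interior_bins`` length-normalized
    interior bins, and ``flank`` downstream bins, oriented in transcription
    direction.  Flanks running past a chromosome end are truncated when
    ``chrom_sizes`` is given.
    """
    width = flank + n_interior_bins + flank
    profiles = {"up": np.zeros(width), "down": np.zeros(width)}
    for r in rcm_regions.itertuples(index=False):
        side = r.side
        length = r.end - r.start
        lo = r.start - flank
        hi = r.end + flank
        if chrom_sizes is not None:
            size = chrom_sizes[r.chrom]
            lo, hi = max(0, lo), min(size, hi)
        sel = (
            (track["chrom"] == r.chrom)
            & (track["strand"] == r.strand)
            & (track["pos"] >= lo)
            & (track["pos"] < hi)
        )
        sub = track.loc[sel]
        for pos, cnt in zip(sub["pos"].to_numpy(), sub["count"].to_numpy()):
            if r.strand == "+":
                if pos < r.start:
                    idx = pos - (r.start - flank)
                elif pos < r.end:
                    idx = flank + (pos - r.start) * n_interior_bins // length
                else:
                    idx = flank + n_interior_bins + (pos - r.end)
            else:
                if pos >= r.end:
                    idx = (r.end + flank - 1) - pos
                elif pos >= r.start:
                    idx = flank + (r.end - 1 - pos) * n_interior_bins // length
                else:
                    idx = flank + n_interior_bins + (r.start - 1 - pos)
            if 0 <= idx < width:
                profiles[side][idx] += cnt
    return profiles
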