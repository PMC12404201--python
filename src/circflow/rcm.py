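"""Reverse complementary matches between circRNA-flanking introns.

A reverse complementary match (RCM) is a span in the upstream flanking
intron whose sequence equals the reverse complement of a span in the
downstream flanking intron; such pairs can base-pair in the nascent
transcript, looping the back-splice sites together.  The default detector
reports all *maximal exact* matches of at least ``min_len`` nt, found by
k-mer seeding (word size 7, the minus-strand BLAST word size) and
bidirectional extension.  An optional greedy mode tolerates mismatches with
BLAST-like X-drop extension (+1 match, -2 mismatch, drop 6).

All sequences are taken on the genomic forward strand: RNA-level pairing
between two introns of one gene reduces to forward == revcomp(forward)
regardless of the gene's strand.  Downstream spans are likewise reported in
forward-strand coordinates.

The module also summarizes RCM density per circRNA class, GC content, and
overlap of RCM spans with repeat regions via a length-preserving
permutation test (observed number of RCM regions overlapping a repeat vs
uniform re-placement in a placement space; empirical p with add-one
smoothing and a z-score against the null distribution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._util import child_rng, revcomp

DEFAULT_WORD_SIZE = 7
DEFAULT_MIN_LEN = 21  # "longer than 20 nt"

_VALID = set("ACGTN")


@dataclass
class RCMPair:
    up_start: int
    up_end: int
    down_start: int  # forward-strand coordinates within the downstream sequence
    down_end: int
    length: int
    n_mismatches: int = 0
    gc_content: float = 0.0
    circ_id: Optional[str] = None
    up_intron_id: Optional[str] = None
    down_intron_id: Optional[str] = None


@dataclass
class PermutationResult:
    observed: int
    null_overlaps: np.ndarray
    p_empirical: float
    z_score: float


def _check_alphabet(seq: str, name: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{name} sequence is empty")
    if set(seq) - _VALID:
        raise ValueError(f"{name} contains non-ACGTN symbols")
    return seq


def find_rcms(
    up_seq: str,
    down_seq: str,
    word_size: int = DEFAULT_WORD_SIZE,
    min_len: int = DEFAULT_MIN_LEN,
    mode: str = "exact",
    x_drop: int = 6,
    match_score: int = 1,
    mismatch_score: int = -2,
) -> list[RCMPair]:
    """All RCMs between an upstream and a downstream intron sequence.

    Exact mode reports every maximal run where ``up_seq`` equals the
    reverse complement of ``down_seq`` with length >= ``min_len`` (N never
    matches).  Greedy mode extends seeds with mismatches under an X-drop
    rule and suppresses hits contained in longer ones.
    """
    up = _check_alphabet(up_seq, "up")
    down = _check_alphabet(down_seq, "down")
    v = revcomp(down)  # match up against this left-to-right
    if mode == "exact":
        hits = _exact_maximal_matches(up, v, word_size, min_len)
    elif mode == "greedy":
        hits = _greedy_matches(up, v, word_size, min_len, x_drop, match_score, mismatch_score)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    pairs = []
    for (us, ue, vs, ve, mism) in hits:
        ds, de = len(down) - ve, len(down) - vs
        pairs.append(
            RCMPair(
                up_start=us,
                up_end=ue,
                down_start=ds,
                down_end=de,
                length=ue - us,
                n_mismatches=mism,
                gc_content=gc_content(up[us:ue]),
            )
        )
    return sorted(pairs, key=lambda p: (p.up_start, p.down_start))


def _chars_match(a: str, b: str) -> bool:
    return a == b and a != "N"


def _exact_maximal_matches(u: str, v: str, word_size: int, min_len: int):
    index: dict[str, list[int]] = {}
    for j in range(len(v) - word_size + 1):
        w = v[j : j + word_size]
        if "N" in w:
            continue
        index.setdefault(w, []).append(j)
    seen: set[tuple[int, int]] = set()  # (diagonal, run start in u)
    hits = []
    for i in range(len(u) - word_size + 1):
        w = u[i : i + word_size]
        if "N" in w:
            continue
        for j in index.get(w, ()):
            d = i - j
            # extend to maximal run on this diagonal
            a, b = i, i + word_size
            while a > 0 and a - d > 0 and _chars_match(u[a - 1], v[a - 1 - d]):
                a -= 1
            while b < len(u) and b - d < len(v) and _chars_match(u[b], v[b - d]):
                b += 1
            if (d, a) in seen:
                continue
            seen.add((d, a))
            if b - a >= min_len:
                hits.append((a, b, a - d, b - d, 0))
    return hits


def _greedy_matches(u, v, word_size, min_len, x_drop, match_score, mismatch_score):
    index: dict[str, list[int]] = {}
    for j in range(len(v) - word_size + 1):
        w = v[j : j + word_size]
        if "N" not in w:
            index.setdefault(w, []).append(j)
    raw = []
    covered: set[tuple[int, int]] = set()  # (diagonal, u position) already inside a hit
    for i in range(len(u) - word_size + 1):
        w = u[i : i + word_size]
        if "N" in w:
            continue
        for j in index.get(w, ()):
            d = i - j
            if (d, i) in covered:
                continue
            a = _xdrop_extend(u, v, i, d, -1, x_drop, match_score, mismatch_score)
            b = _xdrop_extend(u, v, i + word_size - 1, d, +1, x_drop, match_score, mismatch_score) + 1
            mism = sum(1 for k in range(a, b) if not _chars_match(u[k], v[k - d]))
            for k in range(a, b):
                covered.add((d, k))
            if b - a >= min_len:
                raw.append((a, b, a - d, b - d, mism))
    # suppress hits contained in a longer hit
    raw.sort(key=lambda h: h[1] - h[0], reverse=True)
    kept = []
    for h in raw:
        if any(k[0] <= h[0] and h[1] <= k[1] and k[2] <= h[2] and h[3] <= k[3] for k in kept):
            continue
        kept.append(h)
    return kept


def _xdrop_extend(u, v, start, d, step, x_drop, match_score, mismatch_score):
    """Best-scoring extension endpoint from ``start`` along ``step``."""
    best, best_pos = 0, start
    score = 0
    k = start + step
    while 0 <= k < len(u) and 0 <= k - d < len(v):
        score += match_score if _chars_match(u[k], v[k - d]) else mismatch_score
        if score > best:
            best, best_pos = score, k
        if best - score >= x_drop:
            break
        k += step
    return best_pos


def gc_content(seq: str) -> float:
    """(G+C) / (A+C+G+T); N excluded from both sides; NaN for all-N."""
    seq = _check_alphabet(seq, "span")
    acgt = sum(seq.count(c) for c in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


def find_rcms_for_circs(
    circ_flanks: Sequence[dict],
    genome: dict[str, str],
    **kwargs,
) -> pd.DataFrame:
    """Run the detector over per-circRNA flanking intron pairs.

    Each entry of ``circ_flanks`` needs circ_id, chrom and genomic
    (start, end) spans ``up`` and ``down`` for the upstream/downstream
    flanking introns (transcription direction).  Spans in the output are
    genomic forward-strand coordinates.
    """
    rows = []
    for fl in circ_flanks:
        seq = genome[fl["chrom"]]
        u_lo, u_hi = fl["up"]
        d_lo, d_hi = fl["down"]
        pairs = find_rcms(seq[u_lo:u_hi], seq[d_lo:d_hi], **kwargs)
        for p in pairs:
            rows.append(
                {
                    "circ_id": fl["circ_id"],
                    "chrom": fl["chrom"],
                    "up_start": u_lo + p.up_start,
                    "up_end": u_lo + p.up_end,
                    "down_start": d_lo + p.down_start,
                    "down_end": d_lo + p.down_end,
                    "length": p.length,
                    "n_mismatches": p.n_mismatches,
                    "gc_content": p.gc_content,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "circ_id",
            "chrom",
            "up_start",
            "up_end",
            "down_start",
            "down_end",
            "length",
            "n_mismatches",
            "gc_content",
        ],
    )


def rcm_density(
    rcms: pd.DataFrame,
    circ_meta: pd.DataFrame,
    length_bins: Sequence[float] = (21, 30, 50, 100, 200, 1000),
) -> pd.DataFrame:
    """circRNAs with at least one RCM per pairing-length bin, per kb of
    flanking intron, by circRNA class.

    ``rcms`` needs circ_id and length; ``circ_meta`` needs circ_id,
    circ_class and flank_len (total flanking-intron nt).  Multiple RCMs of
    one circRNA falling in the same bin count once.
    """
    bins = np.asarray(length_bins, dtype=float)
    meta = circ_meta.set_index("circ_id")
    rows = []
    for klass, sub_meta in meta.groupby("circ_class"):
        total_kb = sub_meta["flank_len"].sum() / 1000.0
        class_rcms = rcms[rcms["circ_id"].isin(sub_meta.index)]
        binned = pd.cut(class_rcms["length"], bins=bins, include_lowest=True)
        for interval in binned.cat.categories:
            n_circ = class_rcms.loc[binned == interval, "circ_id"].nunique()
            rows.append(
                {
                    "circ_class": klass,
                    "length_bin": str(interval),
                    "n_circ": int(n_circ),
                    "per_kb": n_circ / total_kb if total_kb > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _merge(ivs):
    out = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _repeat_index(repeats: pd.DataFrame) -> dict:
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in repeats.groupby("chrom"):
        merged = _merge(zip(sub["start"], sub["end"]))
        starts = np.array([s for s, _ in merged])
        # merged intervals are disjoint, so a cumulative max is just the ends
        ends = np.array([e for _, e in merged])
        by_chrom[chrom] = (starts, ends)
    return by_chrom


def _count_overlapping_indexed(
    chroms: Sequence[str], starts: np.ndarray, ends: np.ndarray, index: dict
) -> int:
    n = 0
    order = pd.Series(range(len(chroms))).groupby(list(chroms)).groups
    for chrom, idx in order.items():
        if chrom not in index:
            continue
        rs, re = index[chrom]
        qs = starts[list(idx)]
        qe = ends[list(idx)]
        # overlap iff some merged repeat starts before the query end and the
        # repeat immediately left of the query end runs past the query start
        k = np.searchsorted(rs, qe, side="left")
        has = k > 0
        n += int(np.sum(has & (re[np.maximum(k, 1) - 1] > qs)))
    return n


def _count_overlapping(query: pd.DataFrame, repeats: pd.DataFrame) -> int:
    return _count_overlapping_indexed(
        list(query["chrom"]),
        query["start"].to_numpy(),
        query["end"].to_numpy(),
        _repeat_index(repeats),
    )


def permutation_overlap(
    query: pd.DataFrame,
    repeats: pd.DataFrame,
    placement_space: pd.DataFrame,
    ntimes: int = 500,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of query-region overlap with repeats.

    The observed statistic is the number of query regions overlapping at
    least one repeat.  The null re-places each query region, length
    preserved, uniformly over the placement space (an interval is chosen
    with probability proportional to its number of valid start positions);
    p_empirical = (1 + #{null >= observed}) / (ntimes + 1).
    """
    if ntimes < 1:
        raise ValueError("ntimes must be >= 1")
    index = _repeat_index(repeats)
    observed = _count_overlapping_indexed(
        list(query["chrom"]),
        query["start"].to_numpy(),
        query["end"].to_numpy(),
        _repeat_index(repeats),
    )
    space = [
        (r.chrom, int(r.start), int(r.end)) for r in placement_space.itertuples(index=False)
    ]
    lengths = (query["end"] - query["start"]).to_numpy()
    # per region length: cumulative count of valid start positions over the
    # placement intervals, so one uniform integer maps to a placement
    placements = {}
    for L in np.unique(lengths):
        valid = np.array([max(0, e - s - int(L) + 1) for _, s, e in space], dtype=np.int64)
        total = int(valid.sum())
        if total <= 0:
            raise ValueError(f"no placement interval can hold a region of length {L}")
        placements[int(L)] = (np.cumsum(valid), total)
    rng = child_rng(seed, 53)
    null = np.zeros(ntimes, dtype=int)
    chrom_arr = [c for c, _, _ in space]
    start_arr = np.array([s for _, s, _ in space])
    totals = np.array([placements[int(L)][1] for L in lengths])
    for t in range(ntimes):
        xs = rng.integers(0, totals)
        if len(space) == 1:
            starts = start_arr[0] + xs
            chroms = chrom_arr * len(lengths)
        else:
            starts = np.empty(len(lengths), dtype=np.int64)
            chroms = []
            for i, L in enumerate(lengths):
                cum, _ = placements[int(L)]
                k = int(np.searchsorted(cum, xs[i], side="right"))
                starts[i] = start_arr[k] + xs[i] - (cum[k - 1] if k > 0 else 0)
                chroms.append(chrom_arr[k])
        null[t] = _count_overlapping_indexed(chroms, starts, starts + lengths, index)
    p_emp = (1 + int(np.sum(null >= observed))) / (ntimes + 1)
    sd = float(np.std(null, ddof=1)) if ntimes > 1 else 0.0
    z = (observed - float(np.mean(null))) / sd if sd > 0 else float("nan")
    return PermutationResult(
        observed=observed, null_overlaps=null, p_empirical=p_emp, z_score=z
    )
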