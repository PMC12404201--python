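"""PWM scanning and enrichment statistics at back-splice junction windows.

The sequence reading across a back-splice junction — the last ``half_width``
nt of the circle joined to its first ``half_width`` nt — is unique to the
circular transcript, so RNA-binding-protein motifs enriched or positionally
centered there mark circle-specific regulation.  Windows are built on the
spliced (exonic) circle sequence and wrap for circles shorter than the
window.  Motifs are position weight matrices scored as log-odds against a
background; set enrichment is a Fisher exact test on windows-with-hit
counts, and positional (central) enrichment is an upper-tail binomial test
on the fraction of hit centers falling in the middle of the window.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import ALPHABET, encode_seq, revcomp

DEFAULT_HALF_WIDTH = 25
DEFAULT_CENTRAL_WIDTH = 20


@dataclass
class PWM:
    motif_id: str
    matrix: np.ndarray  # L x 4 position probabilities (A,C,G,T)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold: float = 0.0  # minimum log-odds for a hit

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must be L x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-3):
            raise ValueError("each PWM position must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-3):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        eps = 1e-9
        return np.log2((self.matrix + eps) / (self.background + eps))

    @classmethod
    def from_consensus(cls, consensus: str, motif_id: Optional[str] = None, major: float = 0.91):
        """Near-deterministic PWM from a consensus string."""
        idx = {c: i for i, c in enumerate(ALPHABET)}
        mat = np.full((len(consensus), 4), (1.0 - major) / 3.0)
        for p, c in enumerate(consensus.upper()):
            if c not in idx:
                raise ValueError(f"consensus must be over ACGT, got {c!r}")
            mat[p, idx[c]] = major
        return cls(motif_id=motif_id or consensus, matrix=mat)


def read_meme(path) -> list[PWM]:
    """Minimal MEME-format motif reader (letter-probability matrices)."""
    pwms = []
    background = np.full(4, 0.25)
    name = None
    rows: list[list[float]] = []
    expecting = 0
    with open(path) as fh:
        lines = iter(fh.read().splitlines())
    for line in lines:
        s = line.strip()
        if s.startswith("Background letter frequencies"):
            nxt = next(lines).split()
            background = np.array([float(nxt[i]) for i in (1, 3, 5, 7)])
        elif s.startswith("MOTIF"):
            name = s.split()[1]
        elif s.startswith("letter-probability matrix"):
            m = re.search(r"w=\s*(\d+)", s)
            expecting = int(m.group(1)) if m else 0
            rows = []
        elif expecting and s and s[0].isdigit() or (expecting and s.startswith("0.")):
            rows.append([float(x) for x in s.split()[:4]])
            if len(rows) == expecting:
                pwms.append(PWM(motif_id=name, matrix=np.array(rows), background=background))
                expecting = 0
    return pwms


def write_meme(pwms: Sequence[PWM], path) -> None:
    out = ["MEME version 4", "", "ALPHABET= ACGT", ""]
    bg = pwms[0].background if pwms else np.full(4, 0.25)
    out += [
        "Background letter frequencies",
        " ".join(f"{c} {f:.5f}" for c, f in zip(ALPHABET, bg)),
        "",
    ]
    for p in pwms:
        out.append(f"MOTIF {p.motif_id}")
        out.append(f"letter-probability matrix: alength= 4 w= {len(p)} nsites= 20 E= 0")
        for row in p.matrix:
            out.append(" ".join(f"{x:.6f}" for x in row))
        out.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(out))


def junction_window(circle_seq: str, half_width: int = DEFAULT_HALF_WIDTH) -> str:
    """The 2*half_width nt read across the back-splice junction.

    Built from the spliced circle sequence in transcript orientation: the
    last half_width nt joined to the first half_width nt, wrapping
    circularly when the circle is shorter than the window.
    """
    L = len(circle_seq)
    if L == 0:
        raise ValueError("circle sequence is empty")
    return "".join(circle_seq[(L - half_width + i) % L] for i in range(2 * half_width))


def circle_sequence(circ, exons: Sequence[tuple[int, int]], genome: dict[str, str]) -> str:
    """Spliced exonic sequence of a circRNA in transcript orientation.

    ``exons`` are the host transcript's exons; those within [start, end) are
    concatenated and reverse-complemented for minus-strand circles.
    """
    inside = [e for e in sorted(exons) if e[0] >= circ.start and e[1] <= circ.end]
    if not inside:
        inside = [(circ.start, circ.end)]  # genomic fallback (single-exon circle)
    seq = "".join(genome[circ.chrom][s:e] for s, e in inside)
    return revcomp(seq) if circ.strand == "-" else seq


def scan_pwm(seq: str, pwm: PWM, threshold: Optional[float] = None) -> pd.DataFrame:
    """Log-odds scan at every offset; rows where score >= threshold.

    Overlapping hits are allowed; offsets containing N never score.
    """
    if threshold is None:
        threshold = pwm.threshold
    L = len(pwm)
    if len(seq) < L:
        raise ValueError("sequence shorter than motif")
    enc = encode_seq(seq)
    if np.any(enc == 4) and set(seq.upper()) - set("ACGTN"):
        raise ValueError("sequence contains non-ACGTN symbols")
    lo = pwm.log_odds
    n_off = len(seq) - L + 1
    scores = np.full(n_off, -np.inf)
    for off in range(n_off):
        window = enc[off : off + L]
        if np.any(window == 4):
            continue
        scores[off] = lo[np.arange(L), window].sum()
    hits = np.where(scores >= threshold)[0]
    return pd.DataFrame({"offset": hits, "score": scores[hits]})


def motif_enrichment(
    target_windows: Sequence[str], control_windows: Sequence[str], pwm: PWM
) -> tuple[float, float]:
    """Fisher exact test of windows-with-hit between target and control.

    Returns (odds ratio with Haldane 0.5 correction, two-sided p).
    """
    if not target_windows or not control_windows:
        raise ValueError("both window sets must be non-empty")
    a = sum(1 for w in target_windows if len(scan_pwm(w, pwm)) > 0)
    b = len(target_windows) - a
    c = sum(1 for w in control_windows if len(scan_pwm(w, pwm)) > 0)
    d = len(control_windows) - c
    _, p = stats.fisher_exact([[a, b], [c, d]])
    orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return float(orr), float(p)


def central_enrichment(
    offsets: Sequence[int],
    motif_len: int,
    window_len: int = 2 * DEFAULT_HALF_WIDTH,
    central_width: int = DEFAULT_CENTRAL_WIDTH,
) -> float:
    """Upper-tail binomial p for hits concentrating at the window center.

    A hit is central when its motif midpoint (rounded down) lies within the
    ``central_width`` region around the window midpoint.  The null central
    probability is central_width over the number of available motif
    placements.
    """
    if central_width >= window_len:
        raise ValueError("central_width must be smaller than window_len")
    offsets = list(offsets)
    n = len(offsets)
    if n == 0:
        return 1.0
    n_avail = window_len - motif_len + 1
    p0 = min(1.0, central_width / n_avail)
    mid = window_len // 2
    lo = mid - central_width // 2
    hi = lo + central_width
    centers = [off + motif_len // 2 for off in offsets]
    c = sum(1 for x in centers if lo <= x < hi)
    return float(stats.binom.sf(c - 1, n, p0))
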