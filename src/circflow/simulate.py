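"""Synthetic genomes, circRNA truth sets, and read/track generators.

Everything downstream — back-splice calling, intron classification, EISA,
splicing efficiency, RCM detection, cross-link enrichment, BSJ motif
statistics — is exercised on data produced here, with planted ground truth:
multi-exon protein-coding genes on both strands with canonical GT/AG intron
boundaries; a subset of genes hosting one circRNA over internal exons; an
exact reverse-complementary match planted in each circle's flanking intron
pair, carrying the configured binding-motif consensus on the transcribed
strand; split reads across back-splice and forward junctions at configured
circular:linear ratios and group fold changes; cross-link tracks with
configurable flanking-intron enrichment; and nascent position counts with
per-intron spliced fractions.

The read model is idealized: two 30-nt segments per junction read, no
mismatches, CIGAR ``30M`` per segment — the statistics downstream, not
aligner behavior, are the target.  One top-level seed drives the whole
simulation; each generator derives an independent child stream by a fixed
offset, so outputs are byte-identical across runs at fixed config.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._util import ALPHABET, child_rng, revcomp
from .annotation import GeneModel, IntronRecord
from .io import READS_COLUMNS
from .quantify import CircRNA, canonical_flanks, circ_key

# fixed child-stream offsets, one per generator stage
_STREAM_GENOME = 1
_STREAM_CIRC = 2
_STREAM_READS = 3
_STREAM_CLIP = 4
_STREAM_NASCENT = 5
_STREAM_EISA = 6


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic data generators.

    Ranges are inclusive (lo, hi) tuples in nt or counts.  ``bsj_depth`` is
    the mean back-splice read count per circRNA per sample;
    ``circular_fraction`` the fraction of junction-spanning reads at circle
    boundaries that are back-spliced; ``fold_change`` the group-B over
    group-A abundance multiplier for circRNAs; ``motif`` the consensus
    planted (transcribed strand) inside every RCM; ``clip_enrichment`` the
    cross-link density multiplier in flanking introns over the base density
    of ``clip_base_density`` sites/nt; ``spliced_fraction`` the per-intron
    probability that a nascent read is already spliced.
    """

    seed: int = 0
    n_genes: int = 20
    exons_per_gene: tuple = (4, 6)
    exon_len: tuple = (80, 200)
    intron_len: tuple = (150, 600)
    n_circ_genes: int = 10
    circ_exon_span: tuple = (1, 3)
    bsj_depth: float = 50.0
    circular_fraction: float = 0.5
    fold_change: float = 4.0
    rcm_len: tuple = (25, 40)
    motif: str = "TTTTTTT"
    clip_base_density: float = 0.05
    clip_enrichment: float = 3.0
    spliced_fraction: float = 0.5
    nascent_depth: float = 5000.0
    seg_len: int = 30
    intergenic: int = 200
    alt_terminal_exons: bool = False

    def __post_init__(self) -> None:
        for name in ("exons_per_gene", "exon_len", "intron_len", "circ_exon_span", "rcm_len"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a nonempty positive range, got {(lo, hi)}")
        for name in ("circular_fraction", "spliced_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if set(self.motif.upper()) - set(ALPHABET):
            raise ValueError("motif must be over ACGT")
        if self.exon_len[0] < self.seg_len:
            raise ValueError("exons must be at least one read segment long")
        if self.exons_per_gene[0] < 1:
            raise ValueError("genes need at least one exon")


@dataclass
class TruthSet:
    """Planted ground truth shared by all generators."""

    genome: dict[str, str]
    genes: list[GeneModel]
    circrnas: list[CircRNA] = field(default_factory=list)
    rcm_pairs: list[dict] = field(default_factory=list)
    clip_sites: Optional[pd.DataFrame] = None
    spliced_fractions: dict = field(default_factory=dict)

    def gene(self, gene_id: str) -> GeneModel:
        return next(g for g in self.genes if g.gene_id == gene_id)

    def intron_records(self) -> list[IntronRecord]:
        """Truth-level intron classification, derived from the planted
        circles rather than from the annotation module under test."""
        circ_by_gene = {c.host_gene_id: c for c in self.circrnas}
        records = []
        for g in self.genes:
            exons = sorted(g.transcripts[0])
            circ = circ_by_gene.get(g.gene_id)
            for k, ((s1, e1), (s2, e2)) in enumerate(zip(exons, exons[1:])):
                start, end = e1, s2
                klass = "other_gene"
                circ_ids: list[str] = []
                if circ is not None:
                    klass = "nonflanking"
                    if g.strand == "+":
                        if end == circ.start:
                            klass = "flank_up"
                        elif start == circ.end:
                            klass = "flank_down"
                    else:
                        if start == circ.end:
                            klass = "flank_up"
                        elif end == circ.start:
                            klass = "flank_down"
                    if klass.startswith("flank"):
                        circ_ids = [circ.circ_id]
                records.append(
                    IntronRecord(
                        intron_id=f"{g.gene_id}_I{k}",
                        gene_id=g.gene_id,
                        chrom=g.chrom,
                        strand=g.strand,
                        start=start,
                        end=end,
                        klass=klass,
                        circ_ids=circ_ids,
                    )
                )
        return records

    def flank_pairs(self) -> list[dict]:
        """Per-circRNA upstream/downstream flanking intron spans
        (transcription direction), as consumed by the RCM detector."""
        introns = self.intron_records()
        out = []
        for c in self.circrnas:
            up = next(
                i for i in introns if i.klass == "flank_up" and c.circ_id in i.circ_ids
            )
            down = next(
                i for i in introns if i.klass == "flank_down" and c.circ_id in i.circ_ids
            )
            out.append(
                {
                    "circ_id": c.circ_id,
                    "chrom": c.chrom,
                    "up": (up.start, up.end),
                    "down": (down.start, down.end),
                }
            )
        return out


def generate_genome(config: SimulationConfig) -> TruthSet:
    """One chromosome of multi-exon genes, alternating strands, with GT/AG
    written at every intron's transcribed-strand boundaries."""
    rng = child_rng(config.seed, _STREAM_GENOME)
    genes: list[GeneModel] = []
    cursor = config.intergenic
    layouts = []
    for k in range(config.n_genes):
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_len[0], config.exon_len[1] + 1, n_ex)
        intron_lens = rng.integers(config.intron_len[0], config.intron_len[1] + 1, max(0, n_ex - 1))
        strand = "+" if k % 2 == 0 else "-"
        exons = []
        pos = cursor
        for j in range(n_ex):
            exons.append((pos, pos + int(exon_lens[j])))
            pos += int(exon_lens[j])
            if j < n_ex - 1:
                pos += int(intron_lens[j])
        layouts.append((f"g{k}", strand, exons))
        cursor = pos + config.intergenic
    chrom_len = cursor
    if chrom_len > 50_000_000:
        raise ValueError("requested geometry exceeds the chromosome budget")
    seq = rng.choice(list(ALPHABET), size=chrom_len)
    for gene_id, strand, exons in layouts:
        transcripts = [list(exons)]
        if config.alt_terminal_exons and len(exons) >= 3:
            alt = list(exons)
            s0, e0 = alt[0]
            alt[0] = (min(s0 + 10, e0 - 1), e0)  # alternative TSS-side exon
            transcripts.append(alt)
        genes.append(
            GeneModel(gene_id=gene_id, chrom="chr1", strand=strand, transcripts=transcripts)
        )
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if strand == "+":
                seq[e1 : e1 + 2] = list("GT")
                seq[s2 - 2 : s2] = list("AG")
            else:
                seq[e1 : e1 + 2] = list("CT")  # revcomp(AG)
                seq[s2 - 2 : s2] = list("AC")  # revcomp(GT)
    return TruthSet(genome={"chr1": "".join(seq)}, genes=genes)


def plant_circrnas(truth: TruthSet, config: SimulationConfig) -> TruthSet:
    """Plant one circRNA per selected gene plus an exact RCM pair carrying
    the motif consensus in its upstream span (transcribed strand)."""
    rng = child_rng(config.seed, _STREAM_CIRC)
    eligible = [g for g in truth.genes if len(g.transcripts[0]) >= 3]
    if config.n_circ_genes > len(eligible):
        raise ValueError(
            f"cannot place {config.n_circ_genes} circRNAs: only {len(eligible)} genes "
            "have an internal exon"
        )
    if config.rcm_len[0] < len(config.motif):
        raise ValueError("rcm_len must accommodate the motif consensus")
    chosen_idx = sorted(rng.choice(len(eligible), size=config.n_circ_genes, replace=False))
    genome = {c: list(s) for c, s in truth.genome.items()}
    for gi in chosen_idx:
        gene = eligible[gi]
        exons = sorted(gene.transcripts[0])
        n_int = len(exons) - 2
        span = int(rng.integers(config.circ_exon_span[0], config.circ_exon_span[1] + 1))
        span = min(span, n_int)
        first = int(rng.integers(1, len(exons) - span))
        circ_start = exons[first][0]
        circ_end = exons[first + span - 1][1]
        circ = CircRNA(
            circ_id=circ_key(gene.chrom, gene.strand, circ_start, circ_end),
            chrom=gene.chrom,
            strand=gene.strand,
            start=circ_start,
            end=circ_end,
            host_gene_id=gene.gene_id,
        )
        assert canonical_flanks(truth.genome, circ.chrom, circ.strand, circ.start, circ.end)
        truth.circrnas.append(circ)
        # flanking introns in genomic coordinates
        left = (exons[first - 1][1], circ_start)
        right = (circ_end, exons[first + span][0])
        up, down = (left, right) if gene.strand == "+" else (right, left)
        L = int(rng.integers(config.rcm_len[0], config.rcm_len[1] + 1))
        margin = 4
        for iv in (up, down):
            if iv[1] - iv[0] < L + 2 * margin:
                raise ValueError("flanking intron too short for the requested RCM length")
        core = rng.choice(list(ALPHABET), size=L)
        moff = int(rng.integers(0, L - len(config.motif) + 1))
        core[moff : moff + len(config.motif)] = list(config.motif.upper())
        core_rna = "".join(core)
        up_fwd = core_rna if gene.strand == "+" else revcomp(core_rna)
        down_fwd = revcomp(up_fwd)
        u_pos = int(rng.integers(up[0] + margin, up[1] - margin - L + 1))
        d_pos = int(rng.integers(down[0] + margin, down[1] - margin - L + 1))
        genome[circ.chrom][u_pos : u_pos + L] = list(up_fwd)
        genome[circ.chrom][d_pos : d_pos + L] = list(down_fwd)
        truth.rcm_pairs.append(
            {
                "circ_id": circ.circ_id,
                "chrom": circ.chrom,
                "strand": circ.strand,
                "up_start": u_pos,
                "up_end": u_pos + L,
                "down_start": d_pos,
                "down_end": d_pos + L,
                "length": L,
                "rna_seq": core_rna,
            }
        )
    truth.genome = {c: "".join(s) for c, s in genome.items()}
    return truth


def _neighbor_exons(gene: GeneModel, circ: CircRNA) -> tuple[tuple[int, int], tuple[int, int]]:
    """(exon genomically left of the circle, exon genomically right)."""
    exons = sorted(gene.transcripts[0])
    left = max((e for e in exons if e[1] <= circ.start), key=lambda e: e[1])
    right = min((e for e in exons if e[0] >= circ.end), key=lambda e: e[0])
    return left, right


def simulate_reads(
    truth: TruthSet,
    config: SimulationConfig,
    group: str = "A",
    sample_index: int = 0,
    sample_id: Optional[str] = None,
    fc_circs: Optional[set] = None,
    depth_overrides: Optional[dict] = None,
    fixed_counts: Optional[dict] = None,
    decoy_reads: int = 0,
) -> pd.DataFrame:
    """One sample of split reads across back-splice and forward junctions.

    Per circRNA, back-splice reads are Poisson around ``bsj_depth`` (times
    ``fold_change`` for group B circles in ``fc_circs``, default all) and
    forward-junction reads are Poisson with mean scaled so the back-spliced
    fraction of junction reads equals ``circular_fraction``.
    ``fixed_counts`` maps circ_id -> (bsj, fsj) to bypass sampling;
    ``decoy_reads`` adds per circle that many back-splice-shaped reads at a
    shifted junction without canonical splice signals.
    """
    if sample_id is None:
        sample_id = f"{group}{sample_index}"
    rng = child_rng(config.seed, _STREAM_READS, 0 if group == "A" else 1, sample_index)
    seg = config.seg_len
    cf = config.circular_fraction
    if config.bsj_depth == 0 and not fixed_counts:
        warnings.warn("zero depth: returning an empty sample")
        return pd.DataFrame(columns=READS_COLUMNS)
    rows: list[tuple] = []
    k = 0

    def emit(chrom, strand, s1, e1, s2, e2, jt):
        nonlocal k
        cigar = f"{seg}M,{seg}M" if s2 >= 0 else f"{e1 - s1}M"
        rows.append((f"{sample_id}_r{k}", chrom, strand, s1, e1, s2, e2, cigar, jt))
        k += 1

    for circ in truth.circrnas:
        gene = truth.gene(circ.host_gene_id)
        mult = 1.0
        if group == "B" and (fc_circs is None or circ.circ_id in fc_circs):
            mult = config.fold_change
        if fixed_counts and circ.circ_id in fixed_counts:
            n_bsj, n_fsj = fixed_counts[circ.circ_id]
        else:
            mean = (depth_overrides or {}).get(circ.circ_id, config.bsj_depth) * mult
            n_bsj = int(rng.poisson(mean)) if cf > 0 else 0
            if cf == 1.0:
                n_fsj = 0
            elif cf == 0.0:
                n_fsj = int(rng.poisson(mean))
            else:
                n_fsj = int(rng.poisson(mean * (1.0 - cf) / cf))
        s, e = circ.start, circ.end
        for _ in range(n_bsj):
            if circ.strand == "+":
                emit(circ.chrom, "+", e - seg, e, s, s + seg, "bsj")
            else:
                emit(circ.chrom, "-", s, s + seg, e - seg, e, "bsj")
        left, right = _neighbor_exons(gene, circ)
        for _ in range(n_fsj):
            at_left = bool(rng.integers(0, 2))
            if circ.strand == "+":
                if at_left:  # forward junction into the acceptor
                    emit(circ.chrom, "+", left[1] - seg, left[1], s, s + seg, "fsj")
                else:  # forward junction off the donor
                    emit(circ.chrom, "+", e - seg, e, right[0], right[0] + seg, "fsj")
            else:
                if at_left:  # junction across the circle's genomic start
                    emit(circ.chrom, "-", s, s + seg, left[1] - seg, left[1], "fsj")
                else:  # junction across the circle's genomic end
                    emit(circ.chrom, "-", right[0], right[0] + seg, e - seg, e, "fsj")
        for _ in range(decoy_reads):
            ds, de = _decoy_junction(truth.genome, circ)
            if circ.strand == "+":
                emit(circ.chrom, "+", de - seg, de, ds, ds + seg, "decoy")
            else:
                emit(circ.chrom, "-", ds, ds + seg, de - seg, de, "decoy")
    return pd.DataFrame(rows, columns=READS_COLUMNS)


def _decoy_junction(genome: dict[str, str], circ: CircRNA) -> tuple[int, int]:
    """A shifted junction near the circle that fails the canonical check."""
    for shift in range(3, 40):
        ds, de = circ.start + shift, circ.end + shift
        if not canonical_flanks(genome, circ.chrom, circ.strand, ds, de):
            return ds, de
    raise RuntimeError("could not find a non-canonical decoy junction")


def crosslink_track(
    introns: Sequence[IntronRecord],
    base_density: float,
    enrichment: float,
    rng: np.random.Generator,
    enriched_classes: tuple = ("flank_up", "flank_down"),
) -> pd.DataFrame:
    """Uniform per-intron cross-link sites; enriched classes get
    ``enrichment`` times the base per-nt density."""
    chroms, strands, positions = [], [], []
    for i in introns:
        mult = enrichment if i.klass in enriched_classes else 1.0
        n = int(rng.poisson(base_density * i.length * mult))
        if n == 0:
            continue
        pos = rng.integers(i.start, i.end, n)
        positions.extend(int(p) for p in pos)
        chroms.extend([i.chrom] * n)
        strands.extend([i.strand] * n)
    if not positions:
        return pd.DataFrame(columns=["chrom", "strand", "pos", "count"])
    df = pd.DataFrame({"chrom": chroms, "strand": strands, "pos": positions})
    out = df.groupby(["chrom", "strand", "pos"], as_index=False).size()
    return out.rename(columns={"size": "count"}).sort_values(
        ["chrom", "strand", "pos"], ignore_index=True
    )


def simulate_crosslinks(truth: TruthSet, config: SimulationConfig) -> pd.DataFrame:
    rng = child_rng(config.seed, _STREAM_CLIP)
    track = crosslink_track(
        truth.intron_records(), config.clip_base_density, config.clip_enrichment, rng
    )
    truth.clip_sites = track
    return track


def simulate_nascent(
    truth: TruthSet,
    config: SimulationConfig,
    spliced_fractions: Optional[dict] = None,
) -> pd.DataFrame:
    """Nascent position counts over introns and their downstream exons.

    Reads cover the downstream exon at the full per-intron depth and the
    intron at (1 - spliced_fraction) times the exon's per-nt density, both
    uniformly, so any sub-window measures the same density ratio.
    """
    rng = child_rng(config.seed, _STREAM_NASCENT)
    rows = []
    for g in truth.genes:
        exons = sorted(g.transcripts[0])
        for k, ((s1, e1), (s2, e2)) in enumerate(zip(exons, exons[1:])):
            intron_id = f"{g.gene_id}_I{k}"
            f = config.spliced_fraction
            if spliced_fractions and intron_id in spliced_fractions:
                f = spliced_fractions[intron_id]
            truth.spliced_fractions[intron_id] = f
            i_lo, i_hi = e1, s2
            ex = (s2, e2) if g.strand == "+" else (s1, e1)
            elen = ex[1] - ex[0]
            ilen = i_hi - i_lo
            n_e = int(rng.poisson(config.nascent_depth))
            n_i = int(rng.poisson(config.nascent_depth * (1.0 - f) * ilen / elen))
            for n, (lo, hi) in ((n_e, ex), (n_i, (i_lo, i_hi))):
                if n == 0:
                    continue
                pos = rng.integers(lo, hi, n)
                vals, counts = np.unique(pos, return_counts=True)
                for p, c in zip(vals, counts):
                    rows.append((g.chrom, g.strand, int(p), int(c)))
    df = pd.DataFrame(rows, columns=["chrom", "strand", "pos", "count"])
    return (
        df.groupby(["chrom", "strand", "pos"], as_index=False)["count"]
        .sum()
        .sort_values(["chrom", "strand", "pos"], ignore_index=True)
    )


def simulate_eisa(
    truth: TruthSet,
    config: SimulationConfig,
    enriched_genes: Optional[set] = None,
    boundary_multiplier: float = 8.0,
    eej_mean: float = 100.0,
    eib_mean: float = 30.0,
    low_eej_genes: Optional[set] = None,
    low_eej_mean: float = 4.0,
) -> dict[str, pd.DataFrame]:
    """IP and input read sets for exon-intron split analysis.

    Genes in ``enriched_genes`` carry ``boundary_multiplier`` times more
    exon-intron-boundary reads in the IP (pre-mRNA binding); exon-exon
    junction reads are matched between samples.  ``low_eej_genes`` get
    ``low_eej_mean`` junction reads to exercise the expression filter.
    """
    rng = child_rng(config.seed, _STREAM_EISA)
    enriched = enriched_genes or set()
    low = low_eej_genes or set()
    seg = config.seg_len
    samples: dict[str, list] = {"ip": [], "input": []}
    counters = {"ip": 0, "input": 0}

    def emit(sample, chrom, strand, s1, e1, s2, e2, jt):
        cigar = f"{seg}M,{seg}M" if s2 >= 0 else f"{e1 - s1}M"
        samples[sample].append(
            (f"{sample}_r{counters[sample]}", chrom, strand, s1, e1, s2, e2, cigar, jt)
        )
        counters[sample] += 1

    for g in truth.genes:
        exons = sorted(g.transcripts[0])
        if len(exons) < 2:
            continue
        junctions = [(e1, s2) for (s1, e1), (s2, e2) in zip(exons, exons[1:])]
        boundaries = [j[0] for j in junctions] + [j[1] for j in junctions]
        gene_eej = low_eej_mean if g.gene_id in low else eej_mean
        for sample in ("ip", "input"):
            n_eej = int(rng.poisson(gene_eej))
            for _ in range(n_eej):
                jlo, jhi = junctions[int(rng.integers(0, len(junctions)))]
                if g.strand == "+":
                    emit(sample, g.chrom, "+", jlo - seg, jlo, jhi, jhi + seg, "fsj")
                else:
                    emit(sample, g.chrom, "-", jhi, jhi + seg, jlo - seg, jlo, "fsj")
            mult = boundary_multiplier if (sample == "ip" and g.gene_id in enriched) else 1.0
            n_eib = int(rng.poisson(eib_mean * mult))
            for _ in range(n_eib):
                b = boundaries[int(rng.integers(0, len(boundaries)))]
                emit(sample, g.chrom, g.strand, b - seg, b + seg, -1, -1, "contig")
    return {
        s: pd.DataFrame(rows, columns=READS_COLUMNS) for s, rows in samples.items()
    }


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    """Build a config from a plain mapping (YAML-friendly; lists become tuples)."""
    kwargs = {}
    for key, val in d.items():
        kwargs[key] = tuple(val) if isinstance(val, list) else val
    return SimulationConfig(**kwargs)
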