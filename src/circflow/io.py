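"""Readers and writers for the on-disk formats the pipeline exchanges.

Conventions: FASTA via Biopython; GTF 1-based inclusive at the boundary,
converted to the 0-based half-open internal representation; BED 0-based
half-open.  Split reads travel as a TSV with one row per read and up to two
aligned segments (single-segment rows leave seg2 at -1); cross-link tracks
are 1-nt BED6 intervals with the pile-up count in the score column.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import GeneModel, IntronRecord, frame_to_introns, introns_to_frame

READS_COLUMNS = [
    "read_id",
    "chrom",
    "strand",
    "seg1_start",
    "seg1_end",
    "seg2_start",
    "seg2_end",
    "cigar",
    "junction_type",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(recs, str(path), "fasta")


def write_gtf(genes: Iterable[GeneModel], path) -> None:
    lines = []
    for g in genes:
        gmin, gmax = g.span
        attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
        lines.append(_gtf_line(g.chrom, "gene", gmin, gmax, g.strand, attrs))
        for ti, exons in enumerate(g.transcripts):
            tid = f"{g.gene_id}.t{ti}"
            tattrs = f'gene_id "{g.gene_id}"; transcript_id "{tid}"; gene_biotype "{g.biotype}";'
            tmin = min(e[0] for e in exons)
            tmax = max(e[1] for e in exons)
            lines.append(_gtf_line(g.chrom, "transcript", tmin, tmax, g.strand, tattrs))
            for s, e in sorted(exons):
                lines.append(_gtf_line(g.chrom, "exon", s, e, g.strand, tattrs))
    Path(path).write_text("\n".join(lines) + "\n")


def _gtf_line(chrom: str, feature: str, start0: int, end0: int, strand: str, attrs: str) -> str:
    return "\t".join(
        [chrom, "circflow", feature, str(start0 + 1), str(end0), ".", strand, ".", attrs]
    )


def read_gtf(path) -> list[GeneModel]:
    """Parse exon features into gene models (one exon list per transcript)."""
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "exon":
                continue
            attrs = _parse_attrs(f[8])
            gid = attrs["gene_id"]
            tid = attrs.get("transcript_id", gid)
            g = genes.setdefault(
                gid,
                {
                    "chrom": f[0],
                    "strand": f[6],
                    "biotype": attrs.get("gene_biotype", "protein_coding"),
                    "transcripts": {},
                },
            )
            g["transcripts"].setdefault(tid, []).append((int(f[3]) - 1, int(f[4])))
    out = []
    for gid, g in genes.items():
        transcripts = [sorted(ex) for _, ex in sorted(g["transcripts"].items())]
        out.append(
            GeneModel(
                gene_id=gid,
                chrom=g["chrom"],
                strand=g["strand"],
                transcripts=transcripts,
                biotype=g["biotype"],
            )
        )
    return sorted(out, key=lambda x: (x.chrom, x.span[0]))


def _parse_attrs(s: str) -> dict[str, str]:
    out = {}
    for part in s.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def write_reads_tsv(reads: pd.DataFrame, path) -> None:
    reads.to_csv(path, sep="\t", index=False, columns=READS_COLUMNS)


def read_reads_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str, "cigar": str})
    for c in ("seg1_start", "seg1_end", "seg2_start", "seg2_end"):
        df[c] = df[c].astype(int)
    return df


def write_crosslinks_bed(track: pd.DataFrame, path) -> None:
    """1-nt BED6 intervals; count in the score column."""
    bed = pd.DataFrame(
        {
            "chrom": track["chrom"],
            "start": track["pos"],
            "end": track["pos"] + 1,
            "name": "xl",
            "score": track["count"],
            "strand": track["strand"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_crosslinks_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "strand": str},
    )
    return pd.DataFrame(
        {
            "chrom": bed["chrom"],
            "strand": bed["strand"],
            "pos": bed["start"].astype(int),
            "count": bed["score"].astype(int),
        }
    )


def read_bed_regions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df[["chrom", "start", "end"]]


def write_intron_db(introns: Sequence[IntronRecord], path) -> None:
    introns_to_frame(introns).to_csv(path, sep="\t", index=False)


def read_intron_db(path) -> list[IntronRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str, "circ_ids": str})
    df["circ_ids"] = df["circ_ids"].fillna("")
    return frame_to_introns(df)


def write_circs_bed(circs: Sequence, path) -> None:
    """circRNAs as BED6; name = circ_id, score = BSJ count when present."""
    rows = []
    for c in circs:
        rows.append(
            [c.chrom, c.start, c.end, c.circ_id, getattr(c, "bsj", 0), c.strand]
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
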