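"""Readers and writers for the pipeline's on-disk formats.

Internal coordinates are 0-based half-open everywhere; GFF3's 1-based
closed intervals are converted at this boundary only. BED and bedGraph go
through pandas, FASTA through Bio.SeqIO, JASPAR count matrices through
Bio.motifs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetargets import GeneAnnotation, GeneModel
from .intervals import Peak, PeakSet
from .motifscan import PWM
from .tracks import IntervalTrack, ProbeTrack

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path, label=("na", "na")) -> PeakSet:
    """BED3/BED6(+center) -> PeakSet; 0-based half-open.

    An optional 7th column is the peak center; otherwise the interval
    midpoint (floor) is used. Malformed lines raise with their number.
    """
    peaks = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                if start < 0 or end <= start:
                    raise ValueError("invalid interval")
                name = f[3] if len(f) > 3 else "."
                score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
                center = int(f[6]) if len(f) > 6 else (start + end) // 2
                peaks.append(Peak(chrom, start, end, center, score=score, name=name))
            except (IndexError, ValueError) as e:
                raise ValueError(f"{path}:{ln}: malformed BED line ({e})") from e
    return PeakSet(label, peaks)


def write_bed(peaks: PeakSet, path) -> None:
    """PeakSet -> BED6 + center column; sorted, round-trip stable."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t.\t{p.center}\n"
            )


def read_gff3(path) -> GeneAnnotation:
    """Gene-only GFF3 -> GeneAnnotation; 1-based closed -> 0-based half-open."""
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}:{ln}: expected 9 GFF3 columns, got {len(f)}")
            if f[2] != "gene":
                continue
            start1, end1 = int(f[3]), int(f[4])
            if start1 < 1 or end1 < start1:
                raise ValueError(f"{path}:{ln}: invalid GFF3 coordinates")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gid = attrs.get("ID", f"gene{ln}")
            genes.append(GeneModel(gid, f[0], start1 - 1, end1, f[6]))
    return GeneAnnotation(genes)


def write_gff3(annotation: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(annotation.genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(
                f"{g.chrom}\tdiscbind\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sorted(seqs.items())]
    SeqIO.write(records, str(path), "fasta")


def read_bedgraph_probes(path) -> ProbeTrack:
    """bedGraph -> ProbeTrack, one probe per interval at its start."""
    df = pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "value"], comment="#"
    )
    track = ProbeTrack()
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        track.add(str(chrom), sub["start"].to_numpy(), sub["value"].to_numpy())
    return track


def write_bedgraph_probes(track: ProbeTrack, path, span: int | None = None) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            pos, val = track[chrom]
            if span is None:
                spans = np.diff(pos, append=pos[-1] + (pos[-1] - pos[-2] if pos.size > 1 else 1))
            else:
                spans = np.full(pos.size, span)
            for p, s, v in zip(pos, spans, val):
                fh.write(f"{chrom}\t{p}\t{p + s}\t{v:.6g}\n")


def read_bedgraph_intervals(path) -> IntervalTrack:
    df = pd.read_csv(path, sep="\t", names=["chrom", "start", "end", "value"], comment="#")
    track = IntervalTrack()
    for chrom, sub in df.groupby("chrom", sort=True):
        track.add(str(chrom), sub["start"].to_numpy(), sub["end"].to_numpy(), sub["value"].to_numpy())
    return track


def read_jaspar(path) -> list[PWM]:
    """JASPAR-format count matrices -> PWMs (pseudocount 0.5, uniform background)."""
    out = []
    with open(path) as fh:
        for m in motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float).T
            name = m.name or m.matrix_id or "motif"
            out.append(PWM.from_counts(name, counts))
    return out


def write_jaspar(pwms: list[PWM], path, scale: int = 100) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            counts = np.round(pwm.matrix * scale).astype(int)
            for i, b in enumerate("ACGT"):
                row = " ".join(str(int(c)) for c in counts[:, i])
                fh.write(f"{b} [ {row} ]\n")


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise ValueError("expression table must have a 'gene' column")
    return df


def read_term_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "term"} <= set(df.columns):
        raise ValueError("term annotation must have 'gene' and 'term' columns")
    return df
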