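"""Readers and writers for the plain-text formats the pipeline consumes.

BED, bedGraph, BEDPE and the differential-expression TSVs are parsed with
pandas; GTF goes through :func:`pyranges.read_gtf` (which already converts to
0-based half-open coordinates).  All writers emit tab-separated text with
deterministic formatting so that fixed-seed synthetic bundles are
byte-identical across runs.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pyranges

from .intervals import (
    BindingSite,
    GeneRecord,
    GenomicInterval,
    InteractionPair,
    SignalTrack,
    tss_from_interval,
)


class BedParseError(ValueError):
    """Malformed BED/bedGraph/BEDPE record; message names the line number."""


def _parse_coords(chrom: str, start_s: str, end_s: str, path, lineno: int):
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise BedParseError(
            f"{path}:{lineno}: non-integer coordinates ({start_s!r}, {end_s!r})"
        ) from exc
    try:
        return GenomicInterval(chrom, start, end)
    except ValueError as exc:
        raise BedParseError(f"{path}:{lineno}: {exc}") from exc


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/4/6 into intervals, preserving file order.

    Strand is taken from column 6 when present, else ".".  Malformed lines
    (non-integer coordinates, empty intervals) raise :class:`BedParseError`
    naming the offending line.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            iv = _parse_coords(fields[0], fields[1], fields[2], path, lineno)
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            out.append(
                GenomicInterval(iv.chrom, iv.start, iv.end, strand)
            )
    return out


def read_bed_names(path) -> list[str | None]:
    """Name column (4) of a BED file, parallel to :func:`read_bed` output."""
    names: list[str | None] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            names.append(fields[3] if len(fields) >= 4 and fields[3] != "." else None)
    return names


def write_bed(path, intervals: Iterable[GenomicInterval], names: Sequence[str] | None = None) -> None:
    """BED writer; emits BED6 whenever any strand or name is present, else BED3."""
    intervals = list(intervals)
    six_cols = names is not None or any(iv.strand != "." for iv in intervals)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for i, iv in enumerate(intervals):
            row = [iv.chrom, iv.start, iv.end]
            if six_cols:
                row.extend(
                    [names[i] if names is not None else ".", 0, iv.strand]
                )
            w.writerow(row)


def read_aerbs(path) -> list[BindingSite]:
    """Binding sites from BED; column 4, when present, is the epigenetic class."""
    ivs = read_bed(path)
    names = read_bed_names(path)
    return [BindingSite(iv, name) for iv, name in zip(ivs, names)]


def read_bedgraph(path) -> SignalTrack:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
            iv = _parse_coords(fields[0], fields[1], fields[2], path, lineno)
            try:
                value = float(fields[3])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-numeric value") from exc
            records.append((iv.chrom, iv.start, iv.end, value))
    return SignalTrack.from_records(records)


def write_bedgraph(path, track: SignalTrack) -> None:
    with open(path, "w", newline="") as fh:
        for chrom, start, end, value in track.to_records():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_gtf_genes(path) -> list[GeneRecord]:
    """Gene records from a GTF annotation (Gencode-style).

    The gene body comes from ``gene`` features; ``longest_isoform_length`` and
    the TSS come from the longest ``transcript`` feature of each gene (falling
    back to the gene body itself when no transcripts are annotated).
    """
    df = pyranges.read_gtf(str(path)).df
    if df.empty:
        return []
    genes = df[df.Feature == "gene"]
    tx = df[df.Feature == "transcript"]
    longest: dict[str, tuple[int, int, int]] = {}  # gene_id -> (len, start, end)
    for row in tx.itertuples():
        length = int(row.End) - int(row.Start)
        prev = longest.get(row.gene_id)
        if prev is None or length > prev[0]:
            longest[row.gene_id] = (length, int(row.Start), int(row.End))
    out = []
    for row in genes.itertuples():
        iv = GenomicInterval(row.Chromosome, int(row.Start), int(row.End), row.Strand)
        biotype = getattr(row, "gene_biotype", None) or getattr(
            row, "gene_type", None
        )
        iso = longest.get(row.gene_id)
        if iso is not None:
            iso_len = iso[0]
            tss_iv = GenomicInterval(row.Chromosome, iso[1], iso[2], row.Strand)
            tss = tss_from_interval(tss_iv)
        else:
            iso_len = iv.length
            tss = tss_from_interval(iv)
        out.append(
            GeneRecord(
                gene_id=row.gene_id,
                gene_name=getattr(row, "gene_name", None) or row.gene_id,
                interval=iv,
                tss=tss,
                biotype=biotype if isinstance(biotype, str) else "unknown",
                longest_isoform_length=iso_len,
            )
        )
    return out


def write_gtf_genes(path, genes: Iterable[GeneRecord], source: str = "aposenet") -> None:
    """Write genes as GTF ``gene`` + single ``transcript`` (longest isoform) lines.

    Internal half-open coordinates are converted back to GTF 1-based
    inclusive.  The transcript shares the gene's 5' end and spans the longest
    isoform length, so a round-trip preserves TSS and isoform length.
    """
    with open(path, "w", newline="") as fh:
        for g in genes:
            iv = g.interval
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; '
                f'gene_biotype "{g.biotype}";'
            )
            fh.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )
            if iv.strand == "-":
                t_start, t_end = iv.end - g.longest_isoform_length, iv.end
            else:
                t_start, t_end = iv.start, iv.start + g.longest_isoform_length
            t_attrs = attrs + f' transcript_id "{g.gene_id}.1";'
            fh.write(
                f"{iv.chrom}\t{source}\ttranscript\t{t_start + 1}\t{t_end}\t.\t"
                f"{iv.strand}\t.\t{t_attrs}\n"
            )


def read_bedpe(path, experiment_id: str | None = None) -> list[InteractionPair]:
    """BEDPE interaction pairs.

    Expected columns: chrom1 start1 end1 chrom2 start2 end2 [name] [score].
    ``score`` is the pair count (default 1); ``name`` is used as the
    experiment id unless ``experiment_id`` overrides it.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise BedParseError(f"{path}:{lineno}: BEDPE needs >= 6 columns")
            a1 = _parse_coords(fields[0], fields[1], fields[2], path, lineno)
            a2 = _parse_coords(fields[3], fields[4], fields[5], path, lineno)
            name = fields[6] if len(fields) >= 7 else "."
            count = 1
            if len(fields) >= 8 and fields[7] not in (".", ""):
                count = int(round(float(fields[7])))
            exp = experiment_id if experiment_id is not None else (
                name if name != "." else "experiment_1"
            )
            out.append(InteractionPair(a1, a2, exp, count))
    return out


def write_bedpe(path, pairs: Iterable[InteractionPair]) -> None:
    with open(path, "w", newline="") as fh:
        for p in pairs:
            fh.write(
                f"{p.anchor1.chrom}\t{p.anchor1.start}\t{p.anchor1.end}\t"
                f"{p.anchor2.chrom}\t{p.anchor2.start}\t{p.anchor2.end}\t"
                f"{p.experiment_id}\t{p.count}\n"
            )


DE_COLUMNS = ("gene_id", "log2fc", "adj_p")


def read_de_table(path) -> pd.DataFrame:
    """Differential-expression TSV with header gene_id / log2fc / adj_p."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing DE columns {missing}")
    bad = df["adj_p"].dropna()
    if ((bad < 0) | (bad > 1)).any():
        raise ValueError(f"{path}: adjusted p-values outside [0, 1]")
    return df


def write_tsv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
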