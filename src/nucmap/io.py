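"""Readers and writers for the standard formats at the pipeline boundary.

All in-memory coordinates are 0-based half-open; SAM (1-based) and GFF
(1-based closed) conventions are converted here and nowhere else.  bedGraph
is the canonical on-disk track format (text, diffable); bigWig is emitted
only when pyBigWig is importable.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from .coverage import CoverageTrack
from .dedup import parse_umi_suffix, umi_name_suffix
from .ndr import NdrRecord, OccupancyMatrix
from .nucleosomes import NucleosomeCall
from .records import AlignmentRecord

__all__ = [
    "write_sam",
    "read_alignments",
    "write_alignments_tsv",
    "write_fastq",
    "read_fastq",
    "read_annotation",
    "write_annotation_bed",
    "write_bedgraph",
    "read_bedgraph",
    "write_wiggle",
    "write_bigwig",
    "write_nucleosome_calls",
    "write_ndrs",
    "write_matrix_tsv",
    "load_config",
    "dump_config",
    "config_hash",
]

ALIGN_TSV_COLS = ["chrom", "pos5", "strand", "length", "name", "umi", "is_dup"]


# --------------------------------------------------------------------------
# alignments
# --------------------------------------------------------------------------


def write_sam(
    records: Sequence[AlignmentRecord],
    path: str | Path,
    chrom_sizes: Mapping[str, int],
) -> None:
    """Write single-end records as minimal SAM (@SQ from chrom_sizes)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": int(n)} for c, n in chrom_sizes.items()],
    }
    tid = {c: i for i, c in enumerate(chrom_sizes)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in records:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = rec.name + (
                umi_name_suffix(rec.umi) if rec.umi and umi_name_suffix(rec.umi)
                not in rec.name else ""
            )
            a.flag = (16 if rec.strand == "-" else 0) | (
                1024 if rec.is_dup else 0
            )
            a.reference_id = tid[rec.chrom]
            a.reference_start = rec.start
            a.mapping_quality = 60
            a.cigarstring = f"{rec.length}M"
            if rec.umi:
                a.set_tag("RX", rec.umi)
            fh.write(a)


def read_alignments(path: str | Path, format: str | None = None) -> list[AlignmentRecord]:
    """Read SAM/BAM or the package's alignment TSV into records.

    SAM positions are converted 1-based -> 0-based by pysam; the 5' position
    of a reverse-strand record is the last aligned base.  Unmapped and
    secondary/supplementary records are skipped.  A UMI is taken from a
    ``:UMI:`` read-name suffix or an RX tag when present.
    """
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix in (".tsv", ".txt") else "sam"
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        return [
            AlignmentRecord(
                str(r.chrom), int(r.pos5), str(r.strand), int(r.length),
                str(r.name), (str(r.umi) or None),
                str(r.is_dup) in ("True", "true", "1"),
            )
            for r in df.itertuples(index=False)
        ]
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                continue
            strand = "-" if a.is_reverse else "+"
            length = a.reference_length or a.query_length
            pos5 = a.reference_end - 1 if a.is_reverse else a.reference_start
            name, umi = parse_umi_suffix(a.query_name)
            if umi is None and a.has_tag("RX"):
                umi = str(a.get_tag("RX"))
            out.append(
                AlignmentRecord(a.reference_name, pos5, strand, length,
                                a.query_name, umi, a.is_duplicate)
            )
    return out


def write_alignments_tsv(
    records: Sequence[AlignmentRecord], path: str | Path
) -> None:
    df = pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "pos5": [r.pos5 for r in records],
            "strand": [r.strand for r in records],
            "length": [r.length for r in records],
            "name": [r.name for r in records],
            "umi": [r.umi or "" for r in records],
            "is_dup": [r.is_dup for r in records],
        },
        columns=ALIGN_TSV_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# FASTQ
# --------------------------------------------------------------------------


def write_fastq(
    reads: Iterable[tuple[str, str, str]] | Iterable, path: str | Path
) -> None:
    """Write (name, sequence, quality) triples or ProtectionRead objects."""
    with open(path, "w") as fh:
        for r in reads:
            if isinstance(r, tuple):
                name, seq, qual = r
            else:
                name, seq, qual = r.name, r.sequence, r.quality
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    out = []
    with open(path) as fh:
        while True:
            header = fh.readline().strip()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            out.append((header[1:], seq, qual))
    return out


# --------------------------------------------------------------------------
# annotation
# --------------------------------------------------------------------------


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene table from BED6+biotype or GFF3 into (id, chrom, tss, strand, biotype).

    TSS = start for + strand genes, end-1 for - strand (0-based).  BED rows
    carry the biotype in column 7; GFF3 records need ``ID`` (or ``Name``) and
    ``biotype`` attributes.
    """
    path = Path(path)
    rows = []
    if path.suffix in (".gff", ".gff3"):
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9:
                    raise ValueError(f"{path}:{ln}: not a GFF3 record")
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                if "biotype" not in attrs:
                    raise ValueError(f"{path}:{ln}: missing biotype attribute")
                strand = f[6]
                if strand not in "+-":
                    raise ValueError(f"{path}:{ln}: missing strand")
                start0, end0 = int(f[3]) - 1, int(f[4])  # GFF is 1-based closed
                rows.append(
                    {
                        "id": attrs.get("ID", attrs.get("Name", f"row{ln}")),
                        "chrom": f[0],
                        "tss": start0 if strand == "+" else end0 - 1,
                        "strand": strand,
                        "biotype": attrs["biotype"],
                    }
                )
    else:
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 7:
                    raise ValueError(
                        f"{path}:{ln}: need BED6 + biotype column"
                    )
                strand = f[5]
                if strand not in "+-":
                    raise ValueError(f"{path}:{ln}: missing strand")
                start, end = int(f[1]), int(f[2])
                rows.append(
                    {
                        "id": f[3],
                        "chrom": f[0],
                        "tss": start if strand == "+" else end - 1,
                        "strand": strand,
                        "biotype": f[6],
                    }
                )
    return pd.DataFrame(rows, columns=["id", "chrom", "tss", "strand", "biotype"])


def write_annotation_bed(
    genes: pd.DataFrame, path: str | Path, gene_span: int = 500
) -> None:
    """Write the gene table as BED6+biotype; the TSS defines the 5' end."""
    with open(path, "w") as fh:
        for r in genes.itertuples(index=False):
            if r.strand == "+":
                start, end = r.tss, r.tss + gene_span
            else:
                start, end = r.tss + 1 - gene_span, r.tss + 1
            fh.write(
                f"{r.chrom}\t{max(0, start)}\t{end}\t{r.id}\t0\t{r.strand}"
                f"\t{r.biotype}\n"
            )


# --------------------------------------------------------------------------
# tracks
# --------------------------------------------------------------------------


def write_bedgraph(track: CoverageTrack, path: str | Path, digits: int = 6) -> None:
    """Run-length-compressed bedGraph (0-based half-open, 4 columns)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            a = np.round(track.data[chrom], digits)
            if len(a) == 0:
                continue
            change = np.flatnonzero(np.diff(a)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(a)]))
            for s, e in zip(starts, ends):
                v = a[s]
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(
    path: str | Path, chrom_sizes: Mapping[str, int], norm_state: str = "raw"
) -> CoverageTrack:
    data = {c: np.zeros(n) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, s, e, v = line.split()
            data[chrom][int(s):int(e)] = float(v)
    return CoverageTrack(data, norm_state, 0)


def write_wiggle(track: CoverageTrack, path: str | Path) -> None:
    """Fixed-step wiggle at 1 bp step (1-based starts, per format spec)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
            fh.write("\n".join(f"{v:g}" for v in track.data[chrom]))
            fh.write("\n")


def write_bigwig(track: CoverageTrack, path: str | Path) -> bool:
    """Write bigWig if pyBigWig is available; returns False otherwise."""
    try:
        import pyBigWig
    except ImportError:
        return False
    bw = pyBigWig.open(str(path), "w")
    sizes = [(c, len(a)) for c, a in sorted(track.data.items())]
    bw.addHeader(sizes)
    for chrom, _ in sizes:
        a = track.data[chrom]
        bw.addEntries(chrom, 0, values=a.astype(float).tolist(),
                      span=1, step=1)
    bw.close()
    return True


# --------------------------------------------------------------------------
# tables
# --------------------------------------------------------------------------


def write_nucleosome_calls(
    calls: Sequence[NucleosomeCall], path: str | Path
) -> None:
    """BED-like TSV: chrom, footprint start/end, id, occupancy, dyad, fuzziness."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tid\toccupancy_score\tdyad\tfuzziness\n")
        for i, c in enumerate(calls):
            s, e = c.footprint
            fh.write(
                f"{c.chrom}\t{s}\t{e}\tnuc{i:05d}\t{c.occupancy_score:.6f}"
                f"\t{c.dyad}\t{c.fuzziness:.6f}\n"
            )


def write_ndrs(ndrs: Sequence[NdrRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tid\tlength\tanchor\tanchor_side"
            "\torientation\tlength_class\ttss_ids\n"
        )
        for r in ndrs:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\t{r.length}"
                f"\t{r.anchor}\t{r.anchor_side}\t{r.orientation}"
                f"\t{r.length_class if r.length_class is not None else ''}"
                f"\t{','.join(r.tss_ids)}\n"
            )


def write_matrix_tsv(matrix: OccupancyMatrix, path: str | Path) -> None:
    """Occupancy matrix as TSV with a header row of bin offsets."""
    matrix.to_dataframe().to_csv(path, sep="\t", index_label="id",
                                 float_format="%.6f")


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


def dump_config(config: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def config_hash(config: Mapping) -> str:
    canon = yaml.safe_dump(dict(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
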