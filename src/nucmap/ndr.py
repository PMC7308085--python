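"""Promoter NDR extraction and occupancy aggregation.

NDRs are extracted as inter-nucleosomal intervals (between adjacent called
footprint edges), kept when 75-600 bp long and lying over or adjacent to a
protein-coding TSS, represented once per divergent promoter pair, sorted by
decreasing length and aligned on the edge closest to the TSS.  Occupancy is
aggregated as per-region means and as TSS-oriented, anchor-relative binned
matrices (heat-map rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack
from .nucleosomes import HALF_LEFT, HALF_RIGHT, NucleosomeCall

__all__ = [
    "NdrRecord",
    "AnchoredFeature",
    "OccupancyMatrix",
    "internucleosomal_intervals",
    "extract_ndrs",
    "anchor_sort",
    "length_classes",
    "region_means",
    "relative_matrix",
    "tdna_features",
]


@dataclass
class NdrRecord:
    chrom: str
    start: int
    end: int  # 0-based half-open
    tss_ids: list[str]  # 1 gene, or 2 for a divergent pair
    anchor: int  # edge coordinate closest to the nearest TSS
    anchor_side: str  # left | right
    orientation: str  # strand of the nearest TSS (+ / -)
    length_class: int | None = None  # 1 = shortest tertile

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def id(self) -> str:
        return "|".join(self.tss_ids)


@dataclass
class AnchoredFeature:
    """Generic anchored, oriented feature (e.g. a tDNA) for matrix rows."""

    id: str
    chrom: str
    anchor: int
    orientation: str


def tdna_features(genes: pd.DataFrame) -> list[AnchoredFeature]:
    """tDNA rows anchored at their TSS, oriented by gene strand."""
    sub = genes[genes["biotype"] == "tDNA"]
    return [
        AnchoredFeature(str(r.id), str(r.chrom), int(r.tss), str(r.strand))
        for r in sub.itertuples()
    ]


def internucleosomal_intervals(
    calls: Sequence[NucleosomeCall],
) -> list[tuple[str, int, int]]:
    """Intervals between adjacent called footprints: [dyad1+74, dyad2-73).

    Requires calls sorted by (chrom, dyad); zero/negative-width intervals
    (abutting or overlapping footprints) are discarded.
    """
    key = [(c.chrom, c.dyad) for c in calls]
    if key != sorted(key):
        raise ValueError("calls must be sorted by (chrom, dyad)")
    out = []
    for a, b in zip(calls, calls[1:]):
        if a.chrom != b.chrom:
            continue
        start = a.dyad + HALF_RIGHT
        end = b.dyad - HALF_LEFT
        if end > start:
            out.append((a.chrom, start, end))
    return out


def _qualifies(tss: int, start: int, end: int, adjacency: int) -> bool:
    return start - adjacency <= tss <= end - 1 + adjacency


def extract_ndrs(
    intervals: Sequence[tuple[str, int, int]],
    genes: pd.DataFrame,
    min_len: int = 75,
    max_len: int = 600,
    adjacency: int = 73,
) -> list[NdrRecord]:
    """Select promoter NDRs among inter-nucleosomal intervals.

    Keeps intervals of min_len..max_len bp with at least one protein-coding
    TSS inside or within ``adjacency`` bp of an edge (default 73, half a
    nucleosome footprint).  An interval claimed by two TSSs — a divergent
    promoter pair — yields exactly one record carrying both gene ids.  The
    anchor is the interval edge nearest to the closest qualifying TSS, and
    the record is oriented by that TSS's strand.
    """
    pc = genes[genes["biotype"] == "protein_coding"]
    by_chrom: dict[str, pd.DataFrame] = {
        str(c): g.sort_values("tss") for c, g in pc.groupby("chrom")
    }
    out: list[NdrRecord] = []
    for chrom, start, end in intervals:
        length = end - start
        if not min_len <= length <= max_len:
            continue
        g = by_chrom.get(chrom)
        if g is None:
            continue
        tss = g["tss"].to_numpy()
        mask = (tss >= start - adjacency) & (tss <= end - 1 + adjacency)
        if not mask.any():
            continue
        hits = g[mask]
        # nearest qualifying TSS decides the anchor edge and orientation
        d_left = np.abs(hits["tss"].to_numpy() - start)
        d_right = np.abs(end - hits["tss"].to_numpy())
        best = int(np.argmin(np.minimum(d_left, d_right)))
        if d_left[best] <= d_right[best]:
            anchor, side = start, "left"
        else:
            anchor, side = end, "right"
        out.append(
            NdrRecord(
                chrom=chrom,
                start=start,
                end=end,
                tss_ids=[str(i) for i in hits["id"]],
                anchor=anchor,
                anchor_side=side,
                orientation=str(hits["strand"].iloc[best]),
            )
        )
    return out


def anchor_sort(ndrs: Sequence[NdrRecord]) -> list[NdrRecord]:
    """Stable sort by decreasing length; ties by (chrom, start)."""
    return sorted(ndrs, key=lambda r: (-r.length, r.chrom, r.start))


def length_classes(ndrs: Sequence[NdrRecord], k: int = 3) -> list[int]:
    """Assign equal-count length classes (1 = shortest) in place.

    Ranks break ties by genomic order, so assignment is deterministic even
    with equal lengths.  Returns the class boundaries (max length per class).
    """
    if len(ndrs) < k:
        raise ValueError(f"need at least k={k} records, have {len(ndrs)}")
    order = sorted(range(len(ndrs)),
                   key=lambda i: (ndrs[i].length, ndrs[i].chrom, ndrs[i].start))
    boundaries = []
    splits = np.array_split(np.array(order), k)
    for cls, idxs in enumerate(splits, start=1):
        for i in idxs:
            ndrs[i].length_class = cls
        boundaries.append(max(ndrs[i].length for i in idxs))
    return boundaries


def region_means(
    track: CoverageTrack, regions: Sequence[tuple[str, int, int]]
) -> np.ndarray:
    """Arithmetic mean of per-base values over each [start, end) region."""
    if track.norm_state == "raw":
        raise ValueError("region_means expects a normalised track")
    out = np.empty(len(regions))
    for i, (chrom, start, end) in enumerate(regions):
        a = track.data[chrom]
        lo, hi = max(0, start), min(len(a), end)
        out[i] = float(a[lo:hi].mean()) if hi > lo else np.nan
    return out


@dataclass
class OccupancyMatrix:
    ids: list[str]
    offsets: np.ndarray  # bin start offsets relative to anchor, oriented
    values: np.ndarray  # rows = features in sort order, cols = bins
    bin_width: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids,
                            columns=[int(o) for o in self.offsets])


def relative_matrix(
    track: CoverageTrack,
    features: Sequence[NdrRecord | AnchoredFeature],
    window: int = 500,
    bin_width: int = 25,
) -> OccupancyMatrix:
    """Mean signal in fixed bins around each feature's anchor, oriented.

    Bins tile [anchor-window, anchor+window); for ``-`` oriented features the
    bin order is reversed so transcription runs rightward in every row.
    Rows follow the order of ``features`` (callers pass anchor_sort output).
    Bins falling outside the chromosome are NaN.
    """
    if window % bin_width != 0:
        raise ValueError("window must be a multiple of bin_width")
    n_bins = 2 * window // bin_width
    values = np.full((len(features), n_bins), np.nan)
    for i, f in enumerate(features):
        a = track.data[f.chrom]
        row = np.full(n_bins, np.nan)
        for j in range(n_bins):
            lo = f.anchor - window + j * bin_width
            hi = lo + bin_width
            clo, chi = max(0, lo), min(len(a), hi)
            if chi > clo:
                row[j] = float(a[clo:chi].mean())
        if f.orientation == "-":
            row = row[::-1]
        values[i] = row
    offsets = np.arange(-window, window, bin_width)
    ids = [f.id for f in features]
    return OccupancyMatrix(ids, offsets, values, bin_width)
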