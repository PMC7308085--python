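"""Per-base coverage tracks: extension transforms, normalisation, enrichment.

Two 5'-anchored transforms are used throughout:

* ``fragment`` — extend each alignment 160 bp in the 3' direction, the
  approximate MNase mononucleosome fragment;
* ``skinny`` — shift the 5' coordinate 37 bp in the 3' direction and extend
  74 bp, recording only the predicted central portion of the nucleosome,
  which sharpens dyad signal for position calling.

Tracks carry an explicit normalisation state (raw / rpm / scaled:<N> /
log2fe) so invalid compositions (e.g. scaling twice, averaging mixed states)
fail loudly instead of silently producing wrong numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .records import AlignmentRecord

__all__ = [
    "CoverageTrack",
    "CoverageParams",
    "PRESETS",
    "filter_excluded",
    "shifted_coverage",
    "scale_track",
    "mean_tracks",
    "log2_enrichment",
]


@dataclass
class CoverageParams:
    shift: int = 0
    extend: int = 160

    def __post_init__(self) -> None:
        if self.extend < 1:
            raise ValueError("extend must be >= 1")
        if self.shift < 0:
            raise ValueError("shift must be >= 0")


PRESETS: dict[str, CoverageParams] = {
    "fragment": CoverageParams(shift=0, extend=160),
    "skinny": CoverageParams(shift=37, extend=74),
}


@dataclass
class CoverageTrack:
    data: dict[str, np.ndarray]
    norm_state: str = "raw"
    n_alignments_used: int = 0

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.data.items()}

    def total(self) -> float:
        return float(sum(a.sum() for a in self.data.values()))

    def mean(self) -> float:
        n = sum(len(a) for a in self.data.values())
        return self.total() / n if n else 0.0

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(
            {c: a.copy() for c, a in self.data.items()},
            self.norm_state,
            self.n_alignments_used,
        )

    def same_genome(self, other: "CoverageTrack") -> bool:
        return self.chrom_sizes == other.chrom_sizes


def filter_excluded(
    records: Sequence[AlignmentRecord],
    exclusion_intervals: Mapping[str, Sequence[tuple[int, int]]],
    chrom_sizes: Mapping[str, int],
) -> tuple[list[AlignmentRecord], int]:
    """Drop records whose 5' coordinate falls in an exclusion interval.

    Mirrors the masking of rDNA/telomere/mitochondrial and other high-copy
    regions before track building.  Intervals are 0-based half-open per
    chromosome; an interval naming an unknown chromosome is an error.
    Returns (kept records, number dropped).
    """
    for chrom in exclusion_intervals:
        if chrom not in chrom_sizes:
            raise ValueError(f"exclusion chromosome {chrom!r} not in genome")
    bounds: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivals in exclusion_intervals.items():
        if not ivals:
            continue
        arr = np.array(sorted(ivals))
        bounds[chrom] = (arr[:, 0], arr[:, 1])
    kept: list[AlignmentRecord] = []
    n_dropped = 0
    for rec in records:
        b = bounds.get(rec.chrom)
        if b is not None:
            i = int(np.searchsorted(b[0], rec.pos5, side="right")) - 1
            if i >= 0 and rec.pos5 < b[1][i]:
                n_dropped += 1
                continue
        kept.append(rec)
    return kept, n_dropped


def shifted_coverage(
    records: Sequence[AlignmentRecord],
    params: CoverageParams | str,
    chrom_sizes: Mapping[str, int],
) -> CoverageTrack:
    """Build a raw per-base track from 5'-shifted, extended footprints.

    A ``+`` strand record adds 1.0 over [pos5+shift, pos5+shift+extend); a
    ``-`` strand record over [pos5-shift-extend+1, pos5-shift+1).  Footprints
    are clipped at chromosome bounds (mass near edges is kept, not dropped).
    """
    if isinstance(params, str):
        params = PRESETS[params]
    # difference-array accumulation: O(records + genome)
    diffs = {c: np.zeros(size + 1) for c, size in chrom_sizes.items()}
    n_used = 0
    for rec in records:
        d = diffs.get(rec.chrom)
        if d is None:
            raise ValueError(f"record chromosome {rec.chrom!r} not in genome")
        if rec.strand == "+":
            start = rec.pos5 + params.shift
        else:
            start = rec.pos5 - params.shift - params.extend + 1
        end = start + params.extend
        start = max(start, 0)
        end = min(end, len(d) - 1)
        if end > start:
            d[start] += 1.0
            d[end] -= 1.0
        n_used += 1
    data = {c: np.cumsum(d[:-1]) for c, d in diffs.items()}
    return CoverageTrack(data, "raw", n_used)


def scale_track(
    track: CoverageTrack, mode: str = "rpm", total: int | None = None
) -> CoverageTrack:
    """Depth-normalise a raw track.

    ``rpm`` multiplies by 1e6 / n_alignments_used (reads per million);
    ``to_total`` multiplies by total / n_alignments_used, e.g. scaling to an
    equivalent of 100K reads.  Only raw tracks may be scaled.
    """
    if track.norm_state != "raw":
        raise ValueError(f"cannot scale a {track.norm_state!r} track")
    if track.n_alignments_used <= 0:
        raise ValueError("track built from zero alignments")
    if mode == "rpm":
        factor = 1e6 / track.n_alignments_used
        state = "rpm"
    elif mode == "to_total":
        if total is None or total <= 0:
            raise ValueError("to_total scaling needs a positive total")
        factor = total / track.n_alignments_used
        state = f"scaled:{total}"
    else:
        raise ValueError(f"unknown scaling mode {mode!r}")
    return CoverageTrack(
        {c: a * factor for c, a in track.data.items()},
        state,
        track.n_alignments_used,
    )


def mean_tracks(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Element-wise mean of depth-normalised replicate tracks."""
    if not tracks:
        raise ValueError("no tracks to average")
    first = tracks[0]
    for t in tracks[1:]:
        if t.norm_state != first.norm_state:
            raise ValueError("mixed normalisation states in mean_tracks")
        if not t.same_genome(first):
            raise ValueError("mismatched genomes in mean_tracks")
    if first.norm_state != "rpm":
        raise ValueError("replicates must be rpm-normalised before averaging")
    data = {
        c: np.mean([t.data[c] for t in tracks], axis=0) for c in first.data
    }
    n = int(round(np.mean([t.n_alignments_used for t in tracks])))
    return CoverageTrack(data, "rpm", n)


def log2_enrichment(
    chip: CoverageTrack, control: CoverageTrack, pseudocount: float = 0.1
) -> CoverageTrack:
    """Per-base log2((chip+p)/(control+p)) of two rpm tracks.

    This is ChIP fold enrichment over the non-enriched nucleosome (input)
    signal without any background-lambda correction, so it reduces to a plain
    pseudocounted ratio of depth-normalised pileups.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if chip.norm_state != "rpm" or control.norm_state != "rpm":
        raise ValueError("log2_enrichment needs two rpm tracks")
    if not chip.same_genome(control):
        raise ValueError("mismatched genomes in log2_enrichment")
    data = {
        c: np.log2((chip.data[c] + pseudocount)
                   / (control.data[c] + pseudocount))
        for c in chip.data
    }
    return CoverageTrack(data, "log2fe", chip.n_alignments_used)
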