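"""Length-resolved analysis of ExoIII-S1 protected fragments.

Sequential ExoIII/S1 digestion trims DNA not bound by the histone octamer,
so the endpoints of the protected fragment report how far the nucleosome is
wrapped on each side.  After UMI deduplication, fragments are binned into a
(5' start position x fragment length) count matrix at 1 bp resolution over
the template, depth-normalised to an equivalent of 100K reads (computed from
the total alignment count without regard to length), and summarised as
discrete protected species (cells holding >= 5% of the normalised signal),
the largely-wrapped fraction (fragments >= 135 bp), and per-side end
profiles that identify a fixed (fully wrapped) boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .records import AlignmentRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ProtectionMatrix",
    "ProtectedSpecies",
    "EndProfile",
    "protection_matrix",
    "scale_matrix",
    "call_species",
    "wrapped_fraction",
    "end_profile",
]

DEFAULT_LENGTH_RANGE = (92, 169)


@dataclass
class ProtectionMatrix:
    template_len: int
    length_range: tuple[int, int]  # inclusive
    counts: np.ndarray  # shape (template_len, n_lengths)
    norm_state: str = "raw"
    n_fragments_total: int = 0  # all fragments, before length filtering

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(self.length_range[0], self.length_range[1] + 1)

    def total(self) -> float:
        return float(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        """Rows = fragment lengths min..max, columns = template positions."""
        return pd.DataFrame(
            self.counts.T,
            index=self.lengths,
            columns=np.arange(self.template_len),
        )


@dataclass
class ProtectedSpecies:
    start: int
    length: int
    fraction: float

    @property
    def end(self) -> int:  # 0-based half-open
        return self.start + self.length

    @property
    def end_1based(self) -> int:  # 1-based last protected base
        return self.start + self.length


def protection_matrix(
    fragments: Sequence[AlignmentRecord | tuple[int, int]],
    template_len: int,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
) -> ProtectionMatrix:
    """Bin deduplicated template fragments by (5' start, length).

    Fragments with lengths outside ``length_range`` are excluded from the
    cells but still count toward ``n_fragments_total``, the denominator used
    for depth scaling.  A fragment extending past the template is an error.
    """
    min_len, max_len = length_range
    counts = np.zeros((template_len, max_len - min_len + 1))
    n_total = 0
    n_out_of_range = 0
    for frag in fragments:
        if isinstance(frag, AlignmentRecord):
            start, length = frag.start, frag.length
        else:
            start, length = frag
        if start < 0 or start + length > template_len:
            raise ValueError(
                f"fragment ({start}, len {length}) exceeds template of "
                f"{template_len} bp"
            )
        n_total += 1
        if min_len <= length <= max_len:
            counts[start, length - min_len] += 1.0
        else:
            n_out_of_range += 1
    if n_out_of_range:
        logger.info("%d of %d fragments outside length range %s",
                    n_out_of_range, n_total, length_range)
    return ProtectionMatrix(template_len, (min_len, max_len), counts,
                            "raw", n_total)


def scale_matrix(matrix: ProtectionMatrix, n: int = 100_000) -> ProtectionMatrix:
    """Scale every cell by n / n_fragments_total (raw matrices only).

    When no fragment was length-filtered the scaled matrix sums to exactly n.
    """
    if matrix.norm_state != "raw":
        raise ValueError(f"cannot scale a {matrix.norm_state!r} matrix")
    if matrix.n_fragments_total <= 0:
        raise ValueError("matrix built from zero fragments")
    factor = n / matrix.n_fragments_total
    return ProtectionMatrix(
        matrix.template_len,
        matrix.length_range,
        matrix.counts * factor,
        f"scaled:{n}",
        matrix.n_fragments_total,
    )


def call_species(
    matrix: ProtectionMatrix, cutoff: float = 0.05
) -> list[ProtectedSpecies]:
    """Cells holding >= cutoff of the total matrix signal, as species.

    Sorted by decreasing fraction; ties by (start, length).  The cutoff is
    relative to the matrix total, so the call set is invariant to the
    scaling constant.
    """
    if not matrix.norm_state.startswith("scaled"):
        raise ValueError("call_species expects a scaled matrix")
    total = matrix.total()
    if total <= 0:
        return []
    min_len = matrix.length_range[0]
    rows, cols = np.nonzero(matrix.counts >= cutoff * total)
    species = [
        ProtectedSpecies(int(r), int(c) + min_len,
                         float(matrix.counts[r, c] / total))
        for r, c in zip(rows, cols)
    ]
    species.sort(key=lambda s: (-s.fraction, s.start, s.length))
    return species


def wrapped_fraction(matrix: ProtectionMatrix, min_len: int = 135) -> float:
    """Fraction of matrix signal from largely-wrapped fragments (>= min_len)."""
    total = matrix.total()
    if total <= 0:
        raise ValueError("empty matrix")
    col0 = max(0, min_len - matrix.length_range[0])
    return float(matrix.counts[:, col0:].sum() / total)


@dataclass
class SideProfile:
    mode: int  # modal coordinate (start: 0-based; end: half-open = 1-based last base)
    dispersion: float  # signal-weighted sd, bp
    mode_mass: float  # fraction of total signal within +/- 2 bp of the mode


@dataclass
class EndProfile:
    left: SideProfile  # fragment 5' starts
    right: SideProfile  # fragment ends (start + length)
    fixed_side: str  # left | right | both | neither


def _side(values: np.ndarray, weights: np.ndarray) -> SideProfile:
    total = weights.sum()
    mode_i = int(np.argmax(weights))
    mode = int(values[mode_i])
    mu = float((values * weights).sum() / total)
    sd = float(np.sqrt((weights * (values - mu) ** 2).sum() / total))
    near = np.abs(values - mode) <= 2
    return SideProfile(mode, sd, float(weights[near].sum() / total))


def end_profile(matrix: ProtectionMatrix, fixed_mass: float = 0.5) -> EndProfile:
    """Marginal start/end distributions and fixed-boundary classification.

    A side is "fixed" when a strict majority (> ``fixed_mass``) of the total
    signal lies within +/- 2 bp of that side's modal coordinate, so a side
    split evenly between two distant boundaries is never called fixed.  End coordinates are
    half-open, which equals the 1-based index of the last protected base
    (a 147-mer starting at offset 11 ends at 158).
    """
    total = matrix.total()
    if total <= 0:
        raise ValueError("empty matrix")
    starts = matrix.counts.sum(axis=1)
    pos = np.arange(matrix.template_len)
    rows, cols = np.nonzero(matrix.counts)
    ends = rows + cols + matrix.length_range[0]
    end_weights = np.zeros(matrix.template_len + 1)
    np.add.at(end_weights, ends, matrix.counts[rows, cols])
    left = _side(pos, starts)
    right = _side(np.arange(matrix.template_len + 1), end_weights)
    l_fixed = left.mode_mass > fixed_mass
    r_fixed = right.mode_mass > fixed_mass
    fixed = {(True, True): "both", (True, False): "left",
             (False, True): "right", (False, False): "neither"}[
        (l_fixed, r_fixed)
    ]
    return EndProfile(left, right, fixed)
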