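"""Shared light-weight record types.

All coordinates in this package are 0-based, half-open; conversion to the
1-based conventions of SAM/GFF happens only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class AlignmentRecord:
    """One single-end-style alignment.

    ``pos5`` is the 5' coordinate of the read: the leftmost aligned base for a
    ``+`` strand read, the rightmost for a ``-`` strand read. MNase fragments
    are intrinsically unstranded, but the strand decides the direction of all
    5'-anchored coverage transforms downstream.
    """

    chrom: str
    pos5: int
    strand: str  # '+' or '-'
    length: int
    name: str
    umi: str | None = None
    is_dup: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} on {self.name}")
        if self.length < 1:
            raise ValueError(f"non-positive length on {self.name}")

    @property
    def start(self) -> int:
        """Leftmost coordinate of the aligned fragment (0-based)."""
        return self.pos5 if self.strand == "+" else self.pos5 - self.length + 1

    @property
    def end(self) -> int:
        """One past the rightmost aligned base."""
        return self.start + self.length
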