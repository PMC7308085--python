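"""Independent oracles used by the tests.

These re-derive expected values by brute force or direct Monte-Carlo on the
generative rules, without calling the implementation paths they check.
"""

from __future__ import annotations

import numpy as np


def brute_force_duplicate_count(records, mode: str = "coordinate") -> int:
    """O(n^2) pairwise duplicate count: a record is a duplicate if any
    earlier-named record matches it on (chrom, pos5, strand[, umi])."""
    n_dup = 0
    for a in records:
        for b in records:
            if b.name >= a.name:
                continue
            same = (a.chrom, a.pos5, a.strand) == (b.chrom, b.pos5, b.strand)
            if mode == "umi":
                same = same and a.umi == b.umi
            if same:
                n_dup += 1
                break
    return n_dup


def mc_protected_lengths(pcfg, n_draws: int, seed: int) -> np.ndarray:
    """Vectorised Monte-Carlo of protected-fragment lengths.

    Mirrors the stated generative rules directly: per end, fully wrapped
    with probability p_wrap else ceil(Exponential(mean)) bp unwrapped;
    round(Normal(0, jitter_sd)) digestion jitter on each boundary; clipped
    to the template; degenerate draws discarded.
    """
    rng = np.random.default_rng(seed)
    u_l = np.where(
        rng.random(n_draws) < pcfg.p_wrap_left,
        0,
        np.ceil(rng.exponential(pcfg.unwrap_mean_left, n_draws)),
    )
    u_r = np.where(
        rng.random(n_draws) < pcfg.p_wrap_right,
        0,
        np.ceil(rng.exponential(pcfg.unwrap_mean_right, n_draws)),
    )
    start = pcfg.octamer_start + u_l
    end = pcfg.octamer_start + pcfg.core_len - u_r
    if pcfg.jitter_sd > 0:
        start = start + np.rint(rng.normal(0, pcfg.jitter_sd, n_draws))
        end = end + np.rint(rng.normal(0, pcfg.jitter_sd, n_draws))
    start = np.maximum(start, 0)
    end = np.minimum(end, pcfg.template_len)
    lengths = end - start
    return lengths[lengths >= 1]


def mc_wrapped_fraction(
    pcfg,
    n_draws: int,
    seed: int,
    min_len: int = 135,
    length_range: tuple[int, int] | None = None,
) -> float:
    """Monte-Carlo expectation of the largely-wrapped (>= min_len) fraction,
    optionally conditioned on the analysed fragment-length range."""
    lengths = mc_protected_lengths(pcfg, n_draws, seed)
    if length_range is not None:
        lengths = lengths[
            (lengths >= length_range[0]) & (lengths <= length_range[1])
        ]
    return float((lengths >= min_len).mean())
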