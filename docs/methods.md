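# Methods

## Scope and model

The package implements two post-alignment analyses of nucleosome
organisation and the synthetic data generator used to validate them in a
closed loop. All internal coordinates are 0-based, half-open; SAM and GFF
conventions (1-based) are converted only at the I/O boundary. A nucleosome
core is 147 bp; its footprint around a dyad `d` is `[d−73, d+74)` (the odd
split is fixed once so inter-nucleosomal interval arithmetic is exact).

## Synthetic chromatin (`nucmap.simulate`)

The generator emulates the statistical structure the analyses assume, not
sequence-level realism: records are born aligned, there is no base
composition or sequencing-error model.

**Genome layout.** Genes are laid out sequentially on `n_chroms`
chromosomes with 1 kb bare margins. A promoter unit is
`[−1 nucleosome][NDR][+1 nucleosome][gene-body array]`; divergent units
mirror a second gene body leftward off a shared NDR; tDNA units are two
flanking nucleosomes around a nucleosome-free gap (160 bp). −1/+1 dyads
sit half a footprint outside the NDR edges, so the interval between their
footprints equals the planted NDR exactly. NDR widths are a two-class
mixture — narrow N(120, 20) and wide N(330, 50) bp, 30% wide — matching
the two promoter architectures seen in budding yeast, where the wide class
(ribosomal-protein-gene-like promoters) has a mean size in the low 300s.
Successive dyads are ≥147 bp apart by construction; nucleosome spacing is
N(165, 10) bp.

**Occupancy and fragility.** −1/+1 and tDNA-flanking nucleosomes draw
occupancy from U(0.8, 1.0) (they are the best-positioned nucleosomes in
vivo), gene-body nucleosomes from U(0.6, 1.0). Wide promoters additionally
carry an *interposed* nucleosome at the NDR midpoint with occupancy
U(0.2, 0.4) and a larger positional fuzz (25 bp vs the global 10 bp):
a partially-unwrapped, fragile nucleosome that standard MNase analysis
reads as part of the NDR — the reason wide NDRs appear wide. The 0.2–0.4
range is a fixture choice (no measured value exists for it), made once.

**Fragment sampling.** Each fragment picks a nucleosome with probability
∝ occupancy (× the factor's affinity weight for ChIP), centres on the
dyad + N(0, fuzz), draws length from N(147, 5) truncated to [100, 200],
and gets a uniformly random strand (MNase fragments are unstranded; the
random strand exercises 5'-anchored transforms on both orientations).
Coordinate PCR duplicates are injected by resampling records with
replacement — exact clones under fresh names — to a 65% duplicate
fraction, the observed mean for MNase libraries.

**Factor affinity rules.** The RSC-like factor has weight 4 at wide-NDR
−1/+1 and tDNA-flanking nucleosomes, 1 elsewhere. The Hmo1-like factor's
weight at promoter nucleosomes is NDR width / 150 bp (occupancy tracks NDR
width), 0 at tDNAs, 0.25 in gene bodies. Rules are configurable per
factor.

**Protection assay.** On a 174 bp template with the octamer core at
offset 11, each molecule's end is fully wrapped with probability
`p_wrap_{left,right}` or unwrapped by `ceil(Exp(mean))` bp; boundaries
get round(N(0, jitter_sd)) digestion jitter and are clipped to the
template; degenerate molecules are redrawn and counted. Defaults
(`p_wrap_right = 0.95`, `p_wrap_left = 0.4`, unwrap means 5/15 bp,
jitter 1 bp) describe a template wrapped tightly on one side and
breathing on the other, the known asymmetric behaviour of 5S positioning
sequences. Each molecule gets one random 8-mer UMI and 1 + Poisson(2)
read copies. Distinct molecules can collide on (position, UMI) with
probability 4⁻⁸ per pair; at 20,000 molecules this loses ~1% of
molecules at dedup, exactly as a real position+UMI dedup would.

## Duplicate handling (`nucmap.dedup`)

Duplicates share (chrom, 5' position, strand) and, in UMI mode, the UMI —
exact string match, no mismatch tolerance (the conservative, reproducible
choice; error-corrected UMI collapsing is deliberately out of scope). The
keeper in each group is the lexicographically smallest read name, so
marking is order-independent and deterministic. Subsampling retains a
seeded simple random sample of `round(t·U/(1−t))` duplicates when the
observed fraction exceeds the target `t` (default 0.40) and is a no-op at
or below it; non-duplicates are never dropped.

## Coverage and enrichment (`nucmap.covtrack` = `coverage.py`)

Tracks are dense per-base float arrays (genomes here are ≤ a few Mb) with
an explicit normalisation state; run-length bedGraph is used only on
disk. A `+` record's footprint is `[pos5+shift, pos5+shift+extend)`; a
`−` record's is `[pos5−shift−extend+1, pos5−shift+1)` — width always
equals `extend`, and footprints are clipped (not dropped) at chromosome
ends. Fold enrichment is computed directly as
`log2((chip+p)/(input+p))` on RPM tracks: without background-lambda
correction the computation is a plain pseudocounted ratio, so no external
peak caller is involved and bit-parity with one is a non-goal. The
pseudocount default 0.1 RPM is a declared choice (no published value);
it only matters where both tracks are near zero.

## Nucleosome calling (`nucmap.nuccall` = `nucleosomes.py`)

The caller is this package's own design, validated purely by recovery on
planted truth. Skinny coverage is smoothed with a centred 31 bp moving
average (edges average the available span), then peaks are picked
greedily: the highest remaining *local maximum* at or above
`threshold_factor ×` the genome-wide mean of the smoothed track, masking
±(min_spacing−1) = ±146 bp after each call. Ties at equal smoothed height
resolve to the centre of the tied plateau, so noise-free symmetric
coverage recovers the planted dyad exactly. The threshold is
genome-relative, making calls invariant to sequencing depth.

`threshold_factor` defaults to 1.5. With nucleosome footprints covering
~37% of the genome at mean occupancy ~0.8, a nucleosome of occupancy `q`
peaks near `q / (0.37 × 0.8)` × the genome mean; 1.5× the mean therefore
sits at an effective occupancy of ~0.45 — between fragile interposed
nucleosomes (≤0.4) and canonical ones (≥0.6). This is the intended
discrimination: fragile promoter nucleosomes stay below threshold and
read out as NDR.

Occupancy score is the summed unsmoothed skinny signal in dyad±37.
Fuzziness is the signal-weighted positional sd in dyad±73: the 74 bp
skinny footprint is itself as wide as a ±37 window, so a ±37 metric
saturates at the boxcar sd (~21 bp) regardless of positioning spread;
over ±73 the metric increases monotonically with planted fuzz (medians
21.6/22.1/26.0/32.6 bp at fuzz 2/5/15/30).

## NDR extraction and aggregation (`nucmap.ndrmap` = `ndr.py`)

Inter-nucleosomal intervals are `[dyad₁+74, dyad₂−73)` between adjacent
calls (footprint-edge arithmetic; measuring between dyads instead would
shift every length by 147 bp — the footprint convention is declared
here). Kept NDRs are 75–600 bp with ≥1 protein-coding TSS inside or
within 73 bp (half a footprint — the quantification of "adjacent", which
has no published value) of an edge. Two qualifying TSSs mean a divergent
pair and yield exactly one record with both gene ids; the anchor is the
edge nearest whichever TSS is closest to any edge, with ties to the left
edge. Length classes are equal-count tertiles (the published three-way
split has unprinted boundaries; tertiles are a declared stand-in), with
rank ties broken by genomic order. Aggregation matrices are mean signal
in 25 bp bins over anchor ±500 bp, rows in decreasing-length order,
columns reversed for `−`-oriented features so transcription runs
rightward; bins off the chromosome end are NaN.

## Wrapping analysis (`nucmap.wrapmap` = `wrapping.py`)

The matrix counts deduplicated fragments per (5' start, length) cell for
lengths 92–169 bp; fragments outside the range are excluded from cells
but counted in the scaling denominator, which is the total alignment
count without regard to length (so the scaled matrix sums to exactly
100,000 only when nothing was filtered). The species cutoff (5%) is
applied per cell against the total matrix signal — the denominator choice
is declared here (per-length or per-position alternatives are not used)
and configurable. The largely-wrapped fraction is the signal share of
cells with length ≥135 bp. End profiles take the marginal start and end
(= start+length) distributions; a side is *fixed* when a strict majority
(>50%) of total signal lies within ±2 bp of its mode — strict, so a side
split evenly between two distant boundaries is never called fixed. End
coordinates are half-open internally, which equals the 1-based index of
the last protected base in reports (offset-11 147-mer → 158).

## Problem sizes and numerics

The analysis scripts and tests run a two-chromosome ~190 kb genome with
130 genes / ~1,040 nucleosomes at 30× fragment coverage per sample, and
20,000 protection molecules — sizes chosen so every recovery statistic is
estimated with comfortable margins while a full run stays in the minutes
range on one core. Monte-Carlo oracles in the tests use 10⁶ draws.
Determinism: every stochastic step takes an explicit seed
(`numpy.random.default_rng`), identical (config, seed) reruns are
byte-identical, and the pipeline manifest records the config hash and
seed.

## What passing tests do and do not show

The generator reproduces the features the analyses rely on — occupancy-
proportional sampling, positioning fuzz, coordinate PCR duplication,
factor-weighted enrichment, per-molecule unwrapping with digestion
jitter — but not sequence bias, MNase sequence preference, mappability,
or inter-sample fragment-length bias. Recovery rates on these data
therefore validate the transforms, the bookkeeping, and the calling
logic under the stated noise model; they are not performance estimates
for real libraries. Known limitations: no paired-end-aware dedup, no UMI
error correction, no deconvolution of overlapping nucleosomes, no
statistical testing of occupancy differences between factors.
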