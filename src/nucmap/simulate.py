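"""Synthetic chromatin, ChIP alignments, and nuclease-protection reads.

The generator plants a fully known chromatin landscape — gene promoters with
nucleosome-deficient regions (NDRs) of a narrow/wide two-class mixture,
well-positioned -1/+1 flanking nucleosomes, phased gene-body arrays, tDNAs
with flanking nucleosomes and a nucleosome-free body, and a low-occupancy
"fragile" nucleosome interposed mid-NDR at wide promoters — then samples
MNase-style fragments from it, optionally weighted by per-factor binding
affinities (ChIP), and injects coordinate PCR duplicates at a configurable
rate.  A second branch emulates the ExoIII-S1 protection assay on a 174 bp
mononucleosome template: per-molecule entry/exit unwrapping, digestion
jitter, PCR amplification and 8 bp UMIs.

Every output comes with a truth table, so downstream recovery is closed-loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .records import AlignmentRecord

__all__ = [
    "SimConfig",
    "ProtectionSimConfig",
    "Gene",
    "Nucleosome",
    "GenomeModel",
    "ProtectionRead",
    "SizingError",
    "build_genome_model",
    "simulate_alignments",
    "inject_duplicates",
    "simulate_protection_reads",
    "default_factor_rules",
]


class SizingError(ValueError):
    """Requested genes do not fit in the requested genome."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def default_factor_rules() -> dict[str, dict[str, float]]:
    """Per-factor nucleosome-affinity rules.

    Each rule maps a nucleosome role to a sampling weight; ``base`` applies to
    roles not listed.  ``width_scale`` (bp) switches a factor to
    width-proportional weighting at promoter nucleosomes (weight =
    NDR width / width_scale), the behaviour of an HMGB-family protein whose
    occupancy tracks NDR width.  The RSC-like remodeler is elevated at
    wide-NDR -1/+1 nucleosomes and at tDNA-flanking nucleosomes; the
    Hmo1-like factor is proportional to NDR width at protein-coding promoters
    and absent from tDNAs.
    """
    return {
        "rsc1": {"base": 1.0, "wide_flank": 4.0, "tdna_flank": 4.0},
        "rsc2": {"base": 1.0, "wide_flank": 3.0, "tdna_flank": 2.0},
        "hmo1": {"base": 0.25, "width_scale": 150.0, "tdna_flank": 0.0},
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic genome and MNase fragment sampling.

    Widths and spacings are in bp.  The duplicate-rate default matches the
    observed mean coordinate-duplicate rate of MNase-digested chromatin
    libraries (65%); promoter NDR widths are a narrow/wide mixture with the
    wide class centred near the printed wide-NDR scale (~330 bp).
    """

    seed: int = 0
    n_genes: int = 150
    n_chroms: int = 2
    wide_fraction: float = 0.3
    divergent_fraction: float = 0.2  # fraction of protein-coding genes paired
    tdna_fraction: float = 0.05
    narrow_width_mean: float = 120.0
    narrow_width_sd: float = 20.0
    wide_width_mean: float = 330.0
    wide_width_sd: float = 50.0
    spacing_mean: float = 165.0
    spacing_sd: float = 10.0
    fragment_len_mean: float = 147.0
    fragment_len_sd: float = 5.0
    fuzz_sd: float = 10.0
    interposed_fuzz_sd: float = 25.0  # fragile nucleosomes are poorly phased
    interposed_occ: tuple[float, float] = (0.2, 0.4)
    flank_occ: tuple[float, float] = (0.8, 1.0)
    body_occ: tuple[float, float] = (0.6, 1.0)
    body_nucs: tuple[int, int] = (4, 8)  # inclusive range per gene
    tdna_gap: int = 160  # nucleosome-free span over a tDNA
    margin: int = 1000  # bare chromosome ends
    dup_rate_target: float = 0.65
    chrom_len: int | None = None  # fixed length per chromosome; None = auto
    factor_weight_rules: dict[str, dict[str, float]] = field(
        default_factory=default_factor_rules
    )

    def validate(self) -> None:
        for name in ("narrow_width_sd", "wide_width_sd", "spacing_sd",
                     "fragment_len_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.wide_fraction <= 1.0:
            raise ValueError("wide_fraction must be in [0, 1]")
        if not 0.0 <= self.dup_rate_target < 1.0:
            raise ValueError("dup_rate_target must be in [0, 1)")


@dataclass
class ProtectionSimConfig:
    """Parameters of the ExoIII-S1 protection assay simulation.

    The template is a 174 bp positioning sequence with the histone octamer
    core (147 bp) starting at offset 11, so a fully wrapped protected
    fragment is [11, 158) — last protected base 158 in 1-based coordinates.
    ``p_wrap_left``/``p_wrap_right`` are the per-molecule probabilities that
    an end is fully wrapped; otherwise the end is unwrapped by an
    exponentially distributed number of bp.  Defaults describe a template
    with one fixed (right) side and one partially-unwrapping (left) side.
    """

    template_len: int = 174
    octamer_start: int = 11
    core_len: int = 147
    p_wrap_left: float = 0.4
    p_wrap_right: float = 0.95
    unwrap_mean_left: float = 15.0
    unwrap_mean_right: float = 5.0
    jitter_sd: float = 1.0
    n_molecules: int = 20_000
    pcr_mean_copies: float = 2.0
    umi_len: int = 8
    seed: int = 0

    def validate(self) -> None:
        if self.octamer_start + self.core_len > self.template_len:
            raise ValueError("octamer does not fit on template")
        if self.umi_len < 1:
            raise ValueError("umi_len must be >= 1")
        for p in (self.p_wrap_left, self.p_wrap_right):
            if not 0.0 <= p <= 1.0:
                raise ValueError("wrap probabilities must be in [0, 1]")


# ---------------------------------------------------------------------------
# genome model
# ---------------------------------------------------------------------------


@dataclass
class Gene:
    id: str
    chrom: str
    tss: int  # 0-based
    strand: str
    biotype: str  # protein_coding | tDNA


@dataclass
class Nucleosome:
    chrom: str
    dyad: int  # 0-based
    occupancy: float
    fuzz_sd: float
    role: str  # wide_flank | narrow_flank | interposed | body | tdna_flank
    gene_id: str | None = None
    ndr_width: int | None = None  # width of the promoter NDR it flanks


@dataclass
class GenomeModel:
    chrom_sizes: dict[str, int]
    genes: list[Gene]
    nucleosomes: list[Nucleosome]
    # gene id -> (ndr_start, ndr_end, class); divergent partners share a tuple
    promoter_truth: dict[str, tuple[int, int, str]]
    divergent_pairs: list[tuple[str, str]]
    affinities: dict[str, np.ndarray]
    config: SimConfig

    def nucleosome_table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": [n.chrom for n in self.nucleosomes],
                "dyad": [n.dyad for n in self.nucleosomes],
                "occupancy": [n.occupancy for n in self.nucleosomes],
                "fuzz_sd": [n.fuzz_sd for n in self.nucleosomes],
                "role": [n.role for n in self.nucleosomes],
                "gene_id": [n.gene_id for n in self.nucleosomes],
            }
        )
        for factor, w in self.affinities.items():
            df[f"affinity_{factor}"] = w
        return df

    def gene_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [g.id for g in self.genes],
                "chrom": [g.chrom for g in self.genes],
                "tss": [g.tss for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "biotype": [g.biotype for g in self.genes],
            }
        )

    def promoter_table(self) -> pd.DataFrame:
        rows = [
            {"gene_id": gid, "ndr_start": s, "ndr_end": e, "ndr_class": c}
            for gid, (s, e, c) in sorted(self.promoter_truth.items())
        ]
        return pd.DataFrame(rows)

    def validate(self) -> None:
        by_chrom: dict[str, list[int]] = {}
        for n in self.nucleosomes:
            size = self.chrom_sizes[n.chrom]
            if not 0 < n.dyad < size:
                raise AssertionError(f"dyad {n.dyad} outside {n.chrom}")
            by_chrom.setdefault(n.chrom, []).append(n.dyad)
        for chrom, dyads in by_chrom.items():
            dyads.sort()
            gaps = np.diff(dyads)
            if len(gaps) and gaps.min() < 147:
                raise AssertionError(f"dyads closer than 147 bp on {chrom}")
        tss_of = {g.id: g.tss for g in self.genes}
        for gid, (s, e, _) in self.promoter_truth.items():
            tss = tss_of[gid]
            if not (s - 73 <= tss <= e - 1 + 73):
                raise AssertionError(f"TSS of {gid} not near its NDR")


def _draw_width(rng: np.random.Generator, cfg: SimConfig) -> tuple[int, str]:
    if rng.random() < cfg.wide_fraction:
        lo = max(220.0, cfg.wide_width_mean - 3 * cfg.wide_width_sd)
        w = float(np.clip(rng.normal(cfg.wide_width_mean, cfg.wide_width_sd),
                          lo, 590.0))
        return int(round(w)), "wide"
    w = float(np.clip(rng.normal(cfg.narrow_width_mean, cfg.narrow_width_sd),
                      80.0, 219.0))
    return int(round(w)), "narrow"


def _spacing(rng: np.random.Generator, cfg: SimConfig) -> int:
    return int(round(max(152.0, rng.normal(cfg.spacing_mean, cfg.spacing_sd))))


def build_genome_model(config: SimConfig) -> GenomeModel:
    """Lay out genes and plant the nucleosome/NDR/affinity ground truth.

    Layout is sequential along each chromosome: a promoter unit is
    ``[-1 nucleosome][NDR][+1 nucleosome][gene-body array]``; a divergent
    unit mirrors a second gene body leftward off the same (shared) NDR; a
    tDNA unit is two flanking nucleosomes around a nucleosome-free gap.
    -1/+1 dyads sit half a footprint (73/74 bp) outside the NDR edges so the
    inter-nucleosomal interval between them equals the planted NDR exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes: list[Gene] = []
    nucs: list[Nucleosome] = []
    promoter_truth: dict[str, tuple[int, int, str]] = {}
    divergent_pairs: list[tuple[str, str]] = []
    chrom_sizes: dict[str, int] = {}

    if config.n_genes == 0:
        size = config.chrom_len or 10_000
        return GenomeModel({"chr1": size}, [], [], {}, [], {}, config)

    n_tdna = int(round(config.n_genes * config.tdna_fraction))
    n_pc = config.n_genes - n_tdna
    n_div_pairs = int(round(n_pc * config.divergent_fraction / 2))
    n_single = n_pc - 2 * n_div_pairs

    units = ["single"] * n_single + ["divergent"] * n_div_pairs + ["tdna"] * n_tdna
    rng.shuffle(units)
    unit_chunks = np.array_split(np.array(units, dtype=object), config.n_chroms)

    gene_no = 0
    tdna_no = 0

    def occ(lohi: tuple[float, float]) -> float:
        return float(rng.uniform(*lohi))

    for ci, chunk in enumerate(unit_chunks):
        chrom = f"chr{ci + 1}"
        cursor = config.margin  # leftmost coordinate still free
        for unit in chunk:
            if unit == "tdna":
                tdna_no += 1
                gid = f"t{tdna_no:03d}"
                d1 = cursor + 73
                d2 = d1 + 147 + config.tdna_gap
                tss = d1 + 74 + config.tdna_gap // 2
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(Gene(gid, chrom, tss, strand, "tDNA"))
                for d in (d1, d2):
                    nucs.append(Nucleosome(chrom, d, occ(config.flank_occ),
                                           config.fuzz_sd, "tdna_flank", gid))
                cursor = d2 + _spacing(rng, config) - 73
                continue

            width, klass = _draw_width(rng, config)
            flank_role = f"{klass}_flank"

            if unit == "single":
                gene_no += 1
                gid = f"g{gene_no:04d}"
                d_minus1 = cursor + 73
                owner_left = owner_right = gid
            else:  # divergent pair: left gene body, then the shared NDR
                gene_no += 1
                gid_l = f"g{gene_no:04d}"
                gene_no += 1
                gid_r = f"g{gene_no:04d}"
                d = cursor + 73
                for _ in range(int(rng.integers(config.body_nucs[0],
                                                config.body_nucs[1] + 1))):
                    nucs.append(Nucleosome(chrom, d, occ(config.body_occ),
                                           config.fuzz_sd, "body", gid_l))
                    d += _spacing(rng, config)
                d_minus1 = d
                owner_left, owner_right = gid_l, gid_r

            ndr_start = d_minus1 + 74
            ndr_end = ndr_start + width
            d_plus1 = ndr_end + 73

            if unit == "single":
                tss = ndr_end - int(rng.integers(10, 40))
                genes.append(Gene(gid, chrom, tss, "+", "protein_coding"))
                promoter_truth[gid] = (ndr_start, ndr_end, klass)
            else:
                tss_l = ndr_start + int(rng.integers(10, 40))
                tss_r = ndr_end - int(rng.integers(10, 40))
                genes.append(Gene(gid_l, chrom, tss_l, "-", "protein_coding"))
                genes.append(Gene(gid_r, chrom, tss_r, "+", "protein_coding"))
                promoter_truth[gid_l] = (ndr_start, ndr_end, klass)
                promoter_truth[gid_r] = (ndr_start, ndr_end, klass)
                divergent_pairs.append((gid_l, gid_r))

            nucs.append(Nucleosome(chrom, d_minus1, occ(config.flank_occ),
                                   config.fuzz_sd, flank_role, owner_left, width))
            nucs.append(Nucleosome(chrom, d_plus1, occ(config.flank_occ),
                                   config.fuzz_sd, flank_role, owner_right, width))
            if klass == "wide":
                mid = (ndr_start + ndr_end) // 2
                nucs.append(Nucleosome(chrom, mid, occ(config.interposed_occ),
                                       config.interposed_fuzz_sd, "interposed",
                                       owner_right, width))

            # rightward gene body downstream of +1
            d = d_plus1
            for _ in range(int(rng.integers(config.body_nucs[0],
                                            config.body_nucs[1] + 1))):
                d += _spacing(rng, config)
                nucs.append(Nucleosome(chrom, d, occ(config.body_occ),
                                       config.fuzz_sd, "body", owner_right))
            cursor = d + _spacing(rng, config) - 73

        used = cursor + config.margin
        if config.chrom_len is not None:
            if used > config.chrom_len:
                raise SizingError(
                    f"{chrom}: need {used} bp for requested genes, "
                    f"have {config.chrom_len}"
                )
            chrom_sizes[chrom] = config.chrom_len
        else:
            chrom_sizes[chrom] = used

    nucs.sort(key=lambda n: (n.chrom, n.dyad))
    model = GenomeModel(chrom_sizes, genes, nucs, promoter_truth,
                        divergent_pairs, {}, config)
    model.affinities = {
        factor: _apply_rule(model, rule)
        for factor, rule in config.factor_weight_rules.items()
    }
    model.validate()
    return model


_PROMOTER_ROLES = ("wide_flank", "narrow_flank", "interposed")


def _apply_rule(model: GenomeModel, rule: dict[str, float]) -> np.ndarray:
    w = np.empty(len(model.nucleosomes))
    base = rule.get("base", 1.0)
    scale = rule.get("width_scale")
    for i, n in enumerate(model.nucleosomes):
        if scale is not None and n.role in _PROMOTER_ROLES:
            w[i] = (n.ndr_width or 0) / scale
        else:
            w[i] = rule.get(n.role, base)
    if (w < 0).any():
        raise ValueError("negative affinity weight")
    return w


# ---------------------------------------------------------------------------
# fragment sampling
# ---------------------------------------------------------------------------


def simulate_alignments(
    model: GenomeModel,
    n_fragments: int,
    factor: str = "input",
    seed: int = 0,
) -> list[AlignmentRecord]:
    """Sample MNase-style single-end alignments from the planted landscape.

    Each fragment picks a nucleosome with probability proportional to
    occupancy (times the factor's affinity weight for a ChIP sample), centres
    itself on the dyad plus Normal(0, fuzz) positioning noise, draws its
    length from Normal(fragment_len_mean, sd) truncated to [100, 200], and is
    assigned a uniformly random strand; the 5' coordinate follows from the
    strand.  Records are unique molecules (PCR duplication is a separate,
    explicit step).
    """
    if factor != "input" and factor not in model.affinities:
        raise KeyError(f"unknown factor {factor!r}; "
                       f"known: {sorted(model.affinities)}")
    if not model.nucleosomes:
        raise ValueError("model has no nucleosomes to sample from")
    rng = np.random.default_rng(seed)

    occ = np.array([n.occupancy for n in model.nucleosomes])
    w = occ if factor == "input" else occ * model.affinities[factor]
    total = w.sum()
    if total <= 0:
        raise ValueError(f"all sampling weights are zero for {factor!r}")
    idx = rng.choice(len(w), size=n_fragments, p=w / total)

    dyads = np.array([n.dyad for n in model.nucleosomes])[idx]
    fuzz = np.array([n.fuzz_sd for n in model.nucleosomes])[idx]
    sizes = np.array([model.chrom_sizes[n.chrom] for n in model.nucleosomes])[idx]
    chroms = np.array([n.chrom for n in model.nucleosomes], dtype=object)[idx]

    cfg = model.config
    lengths = np.rint(
        rng.normal(cfg.fragment_len_mean, cfg.fragment_len_sd, n_fragments)
    ).astype(int)
    np.clip(lengths, 100, 200, out=lengths)
    mids = dyads + np.rint(rng.normal(0.0, 1.0, n_fragments) * fuzz).astype(int)
    starts = mids - lengths // 2
    np.clip(starts, 0, sizes - lengths, out=starts)
    minus = rng.random(n_fragments) < 0.5
    pos5 = np.where(minus, starts + lengths - 1, starts)

    return [
        AlignmentRecord(
            chrom=chroms[i],
            pos5=int(pos5[i]),
            strand="-" if minus[i] else "+",
            length=int(lengths[i]),
            name=f"{factor}_{seed}_{i:07d}",
        )
        for i in range(n_fragments)
    ]


def inject_duplicates(
    alignments: Sequence[AlignmentRecord],
    target_dup_fraction: float,
    seed: int = 0,
) -> list[AlignmentRecord]:
    """Append coordinate-identical PCR copies to reach a duplicate fraction.

    With U unique input records, appends D = round(t*U/(1-t)) copies resampled
    with replacement, so duplicates/total hits the target within rounding.
    Copies are exact coordinate clones (same chrom/pos5/strand/length/UMI)
    under fresh read names.
    """
    if not 0.0 <= target_dup_fraction < 1.0:
        raise ValueError("target_dup_fraction must be in [0, 1)")
    if target_dup_fraction == 0.0:
        return list(alignments)
    if not alignments:
        raise ValueError("cannot inject duplicates into an empty record set")
    rng = np.random.default_rng(seed)
    u = len(alignments)
    n_dup = int(round(target_dup_fraction * u / (1.0 - target_dup_fraction)))
    picks = rng.integers(0, u, size=n_dup)
    out = list(alignments)
    for j, i in enumerate(picks):
        src = alignments[int(i)]
        out.append(replace(src, name=f"{src.name}:dup{j:06d}", is_dup=False))
    return out


# ---------------------------------------------------------------------------
# protection assay
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


@dataclass
class ProtectionRead:
    """One sequencing read of a protection-assay molecule (UMI-prefixed)."""

    name: str
    sequence: str
    quality: str
    umi: str
    start: int  # template coordinates of the protected fragment, 0-based
    length: int
    molecule_id: int


def template_sequence(pcfg: ProtectionSimConfig) -> str:
    """Deterministic pseudo-random template sequence for the given seed."""
    rng = np.random.default_rng(pcfg.seed + 104729)
    return "".join(_BASES[rng.integers(0, 4, pcfg.template_len)])


def _draw_unwrap(rng: np.random.Generator, p_wrap: float, mean: float) -> int:
    if rng.random() < p_wrap:
        return 0
    return int(math.ceil(rng.exponential(mean)))


def simulate_protection_reads(
    pcfg: ProtectionSimConfig,
) -> tuple[list[ProtectionRead], pd.DataFrame]:
    """Simulate ExoIII-S1 protected fragments, PCR copies, and UMI reads.

    Per molecule: each octamer end is fully wrapped with probability
    ``p_wrap_*``, else unwrapped by ceil(Exponential(unwrap_mean_*)) bp; the
    protected interval is [octamer_start+u_left, octamer_start+core_len-u_right)
    with each boundary perturbed by round(Normal(0, jitter_sd)) digestion
    jitter and clipped to the template.  Degenerate molecules (empty interval
    after jitter) are redrawn and counted in the truth table attrs.  Each
    molecule gets one random UMI and 1 + Poisson(pcr_mean_copies) read copies
    sharing the UMI and coordinates.

    Returns the reads and a per-molecule truth table
    (molecule_id, u_left, u_right, start, end, length, umi, n_copies).
    """
    pcfg.validate()
    rng = np.random.default_rng(pcfg.seed)
    reads: list[ProtectionRead] = []
    truth_rows = []
    template = template_sequence(pcfg)
    n_redrawn = 0

    for mol in range(pcfg.n_molecules):
        while True:
            u_left = _draw_unwrap(rng, pcfg.p_wrap_left, pcfg.unwrap_mean_left)
            u_right = _draw_unwrap(rng, pcfg.p_wrap_right, pcfg.unwrap_mean_right)
            start = pcfg.octamer_start + u_left
            end = pcfg.octamer_start + pcfg.core_len - u_right
            if pcfg.jitter_sd > 0:
                start += int(round(rng.normal(0.0, pcfg.jitter_sd)))
                end += int(round(rng.normal(0.0, pcfg.jitter_sd)))
            start = max(0, start)
            end = min(pcfg.template_len, end)
            if end - start >= 1:
                break
            n_redrawn += 1
        umi = "".join(_BASES[rng.integers(0, 4, pcfg.umi_len)])
        n_copies = 1 + int(rng.poisson(pcfg.pcr_mean_copies))
        frag = template[start:end]
        for c in range(n_copies):
            name = f"mol{mol:06d}:c{c}"
            seq = umi + frag
            reads.append(
                ProtectionRead(name, seq, "I" * len(seq), umi,
                               start, end - start, mol)
            )
        truth_rows.append(
            {
                "molecule_id": mol,
                "u_left": u_left,
                "u_right": u_right,
                "start": start,
                "end": end,
                "length": end - start,
                "umi": umi,
                "n_copies": n_copies,
            }
        )

    truth = pd.DataFrame(truth_rows)
    truth.attrs["n_redrawn"] = n_redrawn
    return reads, truth


def protection_reads_to_alignments(
    reads: Sequence[ProtectionRead], chrom: str = "template"
) -> list[AlignmentRecord]:
    """View protection reads as template alignments (born aligned, + strand)."""
    return [
        AlignmentRecord(chrom, r.start, "+", r.length, r.name, umi=r.umi)
        for r in reads
    ]
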