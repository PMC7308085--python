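"""End-to-end orchestration of the ChIP and wrapping branches.

ChIP branch: read alignments -> exclusion filter -> coordinate duplicate
marking -> uniform duplicate subsampling (40%) -> fragment coverage -> RPM ->
replicate averaging -> log2 fold enrichment per factor; in parallel the
input sample's skinny coverage feeds nucleosome calling, NDR extraction,
and promoter/tDNA occupancy aggregation.

Wrapping branch (when protection reads are given): UMI extraction ->
position+UMI duplicate marking -> per-length start-position matrix ->
scaling to 100K -> species calling, wrapped fraction, end profile.

Every stage logs its record bookkeeping, every output is written under the
run directory, and a manifest captures the config hash, seed, and counts so
reruns are byte-identical apart from timestamps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import io as nio
from .coverage import (CoverageTrack, filter_excluded, log2_enrichment,
                       mean_tracks, scale_track, shifted_coverage)
from .dedup import extract_umi, mark_duplicates, subsample_duplicates
from .ndr import (NdrRecord, anchor_sort, extract_ndrs,
                  internucleosomal_intervals, length_classes, region_means,
                  relative_matrix, tdna_features)
from .nucleosomes import CallerParams, NucleosomeCall, call_nucleosomes
from .records import AlignmentRecord
from .wrapping import (ProtectionMatrix, call_species, end_profile,
                       protection_matrix, scale_matrix, wrapped_fraction)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All tunable parameters in one place, serialisable to YAML.

    Defaults are the values the analysis is defined with: 8 bp UMIs, a 40%
    uniform duplicate rate, 160 bp fragment extension, the (37, 74) skinny
    transform, NDR length bounds 75-600 bp with 73 bp TSS adjacency,
    +/-500 bp aggregation windows at 25 bp bins, protection fragment lengths
    92-169 bp scaled to 100K reads with a 5% species cutoff, and a 0.1 RPM
    enrichment pseudocount.
    """

    # inputs (any may be empty/None when a branch is not run)
    input_paths: list[str] = field(default_factory=list)  # MNase input reps
    chip_paths: dict[str, list[str]] = field(default_factory=dict)
    annotation_path: str | None = None
    exclusion_path: str | None = None
    protection_fastq: str | None = None
    protection_spans: str | None = None  # TSV of template alignments
    out_dir: str = "results/run"

    # parameters
    umi_len: int = 8
    dup_target: float = 0.40
    pseudocount: float = 0.1
    caller: CallerParams = field(default_factory=CallerParams)
    ndr_min_len: int = 75
    ndr_max_len: int = 600
    adjacency: int = 73
    window: int = 500
    bin_width: int = 25
    template_len: int = 174
    length_range: tuple[int, int] = (92, 169)
    scale_n: int = 100_000
    species_cutoff: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["length_range"] = list(self.length_range)
        return d


@dataclass
class PipelineResult:
    input_track_rpm: CoverageTrack | None = None
    enrichment: dict[str, CoverageTrack] = field(default_factory=dict)
    calls: list[NucleosomeCall] = field(default_factory=list)
    ndrs: list[NdrRecord] = field(default_factory=list)
    ndr_means: dict[str, np.ndarray] = field(default_factory=dict)
    matrices: dict[str, object] = field(default_factory=dict)
    protection: ProtectionMatrix | None = None
    wrapped_fraction: float | None = None
    species: list = field(default_factory=list)
    end_profile: object | None = None
    manifest: dict = field(default_factory=dict)


def _read_exclusion(path: str) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split()
            out.setdefault(f[0], []).append((int(f[1]), int(f[2])))
    return out


def _chrom_sizes_from_records(
    recs: Sequence[AlignmentRecord],
) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for r in recs:
        sizes[r.chrom] = max(sizes.get(r.chrom, 0), r.end + 1)
    return sizes


def _prep_sample(
    path: str,
    exclusions: Mapping[str, Sequence[tuple[int, int]]],
    chrom_sizes: Mapping[str, int],
    cfg: PipelineConfig,
    stage_log: list[dict],
    label: str,
) -> list[AlignmentRecord]:
    recs = nio.read_alignments(path)
    n_in = len(recs)
    recs, n_excluded = filter_excluded(recs, exclusions, chrom_sizes)
    recs, stats = mark_duplicates(recs, mode="coordinate")
    recs = subsample_duplicates(recs, cfg.dup_target, seed=cfg.seed)
    stage_log.append(
        {
            "sample": label,
            "records_in": n_in,
            "excluded": n_excluded,
            "duplicate_fraction_observed": round(stats.duplicate_fraction, 4),
            "records_out": len(recs),
            "dropped": n_in - len(recs),
        }
    )
    logger.info("%s: %d in, %d excluded, %.1f%% dups, %d out", label, n_in,
                n_excluded, 100 * stats.duplicate_fraction, len(recs))
    return recs


def run_pipeline(
    config: PipelineConfig,
    chrom_sizes: Mapping[str, int] | None = None,
) -> PipelineResult:
    """Run every configured stage and write outputs plus a manifest.

    ``chrom_sizes`` may be omitted, in which case the genome extent is taken
    from the input alignments themselves.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()
    stage_log: list[dict] = []
    cfg_dict = config.to_dict()

    exclusions = (
        _read_exclusion(config.exclusion_path)
        if config.exclusion_path
        else {}
    )

    genes = (
        nio.read_annotation(config.annotation_path)
        if config.annotation_path
        else None
    )

    # ---------------- ChIP / nucleosome branch ----------------
    if config.input_paths:
        if chrom_sizes is None:
            probe = []
            for p in config.input_paths:
                probe.extend(nio.read_alignments(p))
            chrom_sizes = _chrom_sizes_from_records(probe)
        input_reps = [
            _prep_sample(p, exclusions, chrom_sizes, config, stage_log,
                         f"input_rep{i + 1}")
            for i, p in enumerate(config.input_paths)
        ]
        input_rpm = mean_tracks(
            [
                scale_track(shifted_coverage(r, "fragment", chrom_sizes))
                for r in input_reps
            ]
        )
        result.input_track_rpm = input_rpm
        nio.write_bedgraph(input_rpm, out_dir / "input_fragment_rpm.bedgraph")

        for factor, paths in config.chip_paths.items():
            reps = [
                _prep_sample(p, exclusions, chrom_sizes, config, stage_log,
                             f"{factor}_rep{i + 1}")
                for i, p in enumerate(paths)
            ]
            chip_rpm = mean_tracks(
                [
                    scale_track(shifted_coverage(r, "fragment", chrom_sizes))
                    for r in reps
                ]
            )
            fe = log2_enrichment(chip_rpm, input_rpm, config.pseudocount)
            result.enrichment[factor] = fe
            nio.write_bedgraph(fe, out_dir / f"{factor}_log2fe.bedgraph")

        # nucleosome calling on pooled input skinny coverage
        pooled = [r for rep in input_reps for r in rep]
        skinny = shifted_coverage(pooled, "skinny", chrom_sizes)
        result.calls = call_nucleosomes(skinny, config.caller)
        nio.write_nucleosome_calls(result.calls,
                                   out_dir / "nucleosome_calls.tsv")
        stage_log.append({"stage": "call_nucleosomes",
                          "n_calls": len(result.calls)})

        if genes is not None and len(result.calls) >= 2:
            intervals = internucleosomal_intervals(result.calls)
            ndrs = extract_ndrs(intervals, genes, config.ndr_min_len,
                                config.ndr_max_len, config.adjacency)
            ndrs = anchor_sort(ndrs)
            if len(ndrs) >= 3:
                length_classes(ndrs, k=3)
            result.ndrs = ndrs
            nio.write_ndrs(ndrs, out_dir / "ndrs.tsv")
            stage_log.append({"stage": "extract_ndrs", "n_ndrs": len(ndrs)})

            regions = [(r.chrom, r.start, r.end) for r in ndrs]
            for factor, fe in result.enrichment.items():
                result.ndr_means[factor] = region_means(fe, regions)
                mat = relative_matrix(fe, ndrs, config.window,
                                      config.bin_width)
                result.matrices[f"{factor}_ndr"] = mat
                nio.write_matrix_tsv(mat, out_dir / f"{factor}_ndr_matrix.tsv")
                tfeats = tdna_features(genes)
                if tfeats:
                    tmat = relative_matrix(fe, tfeats, config.window,
                                           config.bin_width)
                    result.matrices[f"{factor}_tdna"] = tmat
                    nio.write_matrix_tsv(
                        tmat, out_dir / f"{factor}_tdna_matrix.tsv"
                    )

    # ---------------- wrapping branch ----------------
    if config.protection_fastq or config.protection_spans:
        frags = _wrapping_inputs(config, stage_log)
        matrix = protection_matrix(frags, config.template_len,
                                   config.length_range)
        scaled = scale_matrix(matrix, config.scale_n)
        result.protection = scaled
        result.wrapped_fraction = wrapped_fraction(scaled)
        result.species = call_species(scaled, config.species_cutoff)
        result.end_profile = end_profile(scaled)
        scaled.to_dataframe().to_csv(out_dir / "protection_matrix.tsv",
                                     sep="\t")
        with open(out_dir / "protection_report.json", "w") as fh:
            json.dump(
                {
                    "n_molecules": matrix.n_fragments_total,
                    "wrapped_fraction_ge135": result.wrapped_fraction,
                    "species": [
                        {"start": s.start, "length": s.length,
                         "end_1based": s.end_1based,
                         "fraction": round(s.fraction, 6)}
                        for s in result.species
                    ],
                    "fixed_side": result.end_profile.fixed_side,
                    "modal_end_1based": result.end_profile.right.mode,
                    "modal_start": result.end_profile.left.mode,
                },
                fh, indent=2,
            )
        stage_log.append({"stage": "wrapping",
                          "n_molecules": matrix.n_fragments_total,
                          "n_species": len(result.species)})
    else:
        logger.info("no protection inputs; wrapping branch skipped")
        stage_log.append({"stage": "wrapping", "skipped": True})

    result.manifest = {
        "config": cfg_dict,
        "config_hash": nio.config_hash(cfg_dict),
        "seed": config.seed,
        "stages": stage_log,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
    return result


def _wrapping_inputs(
    config: PipelineConfig, stage_log: list[dict]
) -> list[AlignmentRecord]:
    """Protection fragments after UMI extraction and position+UMI dedup.

    The spans table carries the template alignments; when a FASTQ is also
    given, embedded UMIs are extracted from the read sequences and attached
    to the matching alignments by read name (records already carrying a UMI
    keep it).
    """
    if not config.protection_spans:
        raise ValueError(
            "wrapping branch needs protection_spans (template-aligned "
            "fragments); a FASTQ alone carries no coordinates"
        )
    recs = nio.read_alignments(config.protection_spans, format="tsv")
    if config.protection_fastq:
        umis: dict[str, str] = {}
        n_rejected = 0
        for name, seq, qual in nio.read_fastq(config.protection_fastq):
            try:
                umi, _, _, _ = extract_umi(seq, qual, config.umi_len)
            except ValueError:
                n_rejected += 1
                continue
            umis[name] = umi
        recs = [
            dataclasses.replace(r, umi=r.umi or umis.get(r.name))
            for r in recs
        ]
        if n_rejected:
            stage_log.append({"stage": "umi_extraction",
                              "rejected_reads": n_rejected})
    recs, stats = mark_duplicates(recs, mode="umi")
    kept = [r for r in recs if not r.is_dup]
    stage_log.append(
        {
            "stage": "protection_dedup",
            "reads": stats.n_records,
            "molecules": len(kept),
            "duplicate_fraction": round(stats.duplicate_fraction, 4),
        }
    )
    return kept
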