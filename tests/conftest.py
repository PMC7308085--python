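"""Shared fixtures: simulated datasets reused across test modules.

The deep ChIP simulation (a ~200 kb genome with ~1,000 planted nucleosomes
at ~30x fragment coverage) is session-scoped because several recovery tests
interrogate the same closed-loop dataset.
"""

from __future__ import annotations

import numpy as np
import pytest

import nucmap as nm


@pytest.fixture(scope="session")
def chip_sim():
    """Genome model + input-sample skinny coverage + nucleosome calls."""
    cfg = nm.SimConfig(seed=7, n_genes=130)
    model = nm.build_genome_model(cfg)
    genome = sum(model.chrom_sizes.values())
    n_fragments = int(30 * genome / cfg.fragment_len_mean)
    records = nm.simulate_alignments(model, n_fragments, "input", seed=1)
    skinny = nm.shifted_coverage(records, "skinny", model.chrom_sizes)
    calls = nm.call_nucleosomes(skinny)
    return {
        "model": model,
        "n_fragments": n_fragments,
        "records": records,
        "skinny": skinny,
        "calls": calls,
    }


@pytest.fixture(scope="session")
def enrichment_sim(chip_sim):
    """RPM input track plus log2 fold-enrichment tracks for two factors."""
    model = chip_sim["model"]
    n = chip_sim["n_fragments"]
    input_rpm = nm.scale_track(
        nm.shifted_coverage(chip_sim["records"], "fragment",
                            model.chrom_sizes)
    )
    tracks = {}
    for seed, factor in ((2, "rsc1"), (3, "hmo1")):
        chip = nm.simulate_alignments(model, n, factor, seed=seed)
        chip_rpm = nm.scale_track(
            nm.shifted_coverage(chip, "fragment", model.chrom_sizes)
        )
        tracks[factor] = nm.log2_enrichment(chip_rpm, input_rpm)
    return {"input_rpm": input_rpm, "log2fe": tracks}


@pytest.fixture(scope="session")
def protection_run():
    """Default protection-assay simulation taken through UMI dedup."""
    pcfg = nm.ProtectionSimConfig(seed=5)
    reads, truth = nm.simulate_protection_reads(pcfg)
    from nucmap.simulate import protection_reads_to_alignments

    marked, _ = nm.mark_duplicates(
        protection_reads_to_alignments(reads), mode="umi"
    )
    molecules = [r for r in marked if not r.is_dup]
    matrix = nm.scale_matrix(
        nm.protection_matrix(molecules, pcfg.template_len)
    )
    return {
        "pcfg": pcfg,
        "reads": reads,
        "truth": truth,
        "molecules": molecules,
        "matrix": matrix,
    }


@pytest.fixture()
def two_nuc_model():
    """Hand-built two-nucleosome model for weight/share arithmetic."""
    cfg = nm.SimConfig(seed=0, fragment_len_sd=1e-9)
    model = nm.GenomeModel(
        chrom_sizes={"chrX": 20_000},
        genes=[],
        nucleosomes=[
            nm.simulate.Nucleosome("chrX", 5_000, 0.5, 0.0, "body"),
            nm.simulate.Nucleosome("chrX", 10_000, 0.5, 0.0, "body"),
        ],
        promoter_truth={},
        divergent_pairs=[],
        affinities={"fac": np.array([4.0, 1.0])},
        config=cfg,
    )
    return model
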