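#!/usr/bin/env python
"""Simulate the study's two data types with full ground truth.

Builds a two-chromosome ~200 kb genome with ~1,000 planted nucleosomes
(promoter NDRs in a narrow/wide mixture, fragile interposed nucleosomes at
wide promoters, tDNAs with nucleosome-free bodies), then samples:

* an MNase input sample and three ChIP samples (Rsc1-, Rsc2-, Hmo1-like)
  at ~30x fragment coverage, two replicates each, with coordinate PCR
  duplicates injected at the observed 65% rate;
* 20,000 ExoIII-S1 protection-assay molecules on the 174 bp template with
  8 bp UMIs and PCR copies.

Everything lands under results/data/ (SAM alignments, FASTQ reads, truth
tables) for the downstream scripts.
"""

from pathlib import Path

import nucmap as nm
from nucmap import io as nio
from nucmap.simulate import protection_reads_to_alignments

SEED = 7
DEPTH = 30.0
FACTORS = ["rsc1", "rsc2", "hmo1"]
N_REPLICATES = 2

out = Path("results/data")
out.mkdir(parents=True, exist_ok=True)

cfg = nm.SimConfig(seed=SEED, n_genes=130)
model = nm.build_genome_model(cfg)
genome = sum(model.chrom_sizes.values())
n_frags = int(DEPTH * genome / cfg.fragment_len_mean)

model.nucleosome_table().to_csv(out / "truth_nucleosomes.tsv", sep="\t",
                                index=False)
model.gene_table().to_csv(out / "truth_genes.tsv", sep="\t", index=False)
model.promoter_table().to_csv(out / "truth_promoters.tsv", sep="\t",
                              index=False)
nio.write_annotation_bed(model.gene_table(), out / "genes.bed")
nio.dump_config(
    {"seed": SEED, "n_genes": cfg.n_genes, "depth": DEPTH,
     "n_fragments_per_sample": n_frags, "dup_rate": cfg.dup_rate_target,
     "chrom_sizes": {k: int(v) for k, v in model.chrom_sizes.items()}},
    out / "sim_config.yaml",
)

print(f"genome: {genome:,} bp over {len(model.chrom_sizes)} chromosomes")
print(f"planted: {len(model.nucleosomes)} nucleosomes, "
      f"{len(model.genes)} genes "
      f"({sum(g.biotype == 'tDNA' for g in model.genes)} tDNAs, "
      f"{len(model.divergent_pairs)} divergent pairs)")

sub_seed = 0
for factor in ["input"] + FACTORS:
    for rep in range(1, N_REPLICATES + 1):
        sub_seed += 1
        recs = nm.simulate_alignments(model, n_frags, factor,
                                      seed=SEED * 100 + sub_seed)
        recs = nm.inject_duplicates(recs, cfg.dup_rate_target,
                                    seed=SEED * 100 + 50 + sub_seed)
        nio.write_sam(recs, out / f"{factor}_rep{rep}.sam",
                      model.chrom_sizes)
        print(f"  {factor} rep{rep}: {n_frags:,} molecules -> "
              f"{len(recs):,} alignments at 65% duplicates")

pcfg = nm.ProtectionSimConfig(seed=SEED)
reads, truth = nm.simulate_protection_reads(pcfg)
nio.write_fastq(reads, out / "protection.fastq")
nio.write_alignments_tsv(protection_reads_to_alignments(reads),
                         out / "protection_spans.tsv")
truth.to_csv(out / "truth_molecules.tsv", sep="\t", index=False)
print(f"protection assay: {pcfg.n_molecules:,} molecules -> "
      f"{len(reads):,} reads (mean PCR copies {pcfg.pcr_mean_copies})")
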