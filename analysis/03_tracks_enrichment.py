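#!/usr/bin/env python
"""Build coverage tracks and log2 fold-enrichment for each ChIP factor.

Fragment coverage extends each alignment 160 bp in the 3' direction;
replicates are RPM-normalised and averaged; enrichment is
log2((ChIP+0.1)/(input+0.1)) per base, without background-lambda
correction.  Also builds the input sample's skinny coverage (shift 37,
extend 74) for nucleosome calling.  Writes bedGraph tracks.
"""

from pathlib import Path

import yaml

import nucmap as nm
from nucmap import io as nio

data = Path("results/data")
processed = Path("results/processed")
tracks = Path("results/tracks")
tracks.mkdir(parents=True, exist_ok=True)

chrom_sizes = {
    k: int(v)
    for k, v in yaml.safe_load(
        (data / "sim_config.yaml").read_text()
    )["chrom_sizes"].items()
}


def rpm_fragment_track(sample: str) -> nm.CoverageTrack:
    recs = nio.read_alignments(processed / f"{sample}.tsv", format="tsv")
    return nm.scale_track(
        nm.shifted_coverage(recs, "fragment", chrom_sizes)
    )


samples = sorted(p.stem for p in processed.glob("*_rep*.tsv"))
factors = sorted({s.rsplit("_rep", 1)[0] for s in samples} - {"input"})

input_reps = [s for s in samples if s.startswith("input_rep")]
input_rpm = nm.mean_tracks([rpm_fragment_track(s) for s in input_reps])
nio.write_bedgraph(input_rpm, tracks / "input_fragment_rpm.bedgraph")
print(f"input: averaged {len(input_reps)} RPM replicates")

for factor in factors:
    reps = [s for s in samples if s.startswith(f"{factor}_rep")]
    chip_rpm = nm.mean_tracks([rpm_fragment_track(s) for s in reps])
    fe = nm.log2_enrichment(chip_rpm, input_rpm, pseudocount=0.1)
    nio.write_bedgraph(fe, tracks / f"{factor}_log2fe.bedgraph")
    peak = max(a.max() for a in fe.data.values())
    print(f"{factor}: log2FE over input from {len(reps)} replicates "
          f"(max {peak:.2f})")

# pooled input skinny coverage for the nucleosome caller
pooled = []
for s in input_reps:
    pooled.extend(nio.read_alignments(processed / f"{s}.tsv", format="tsv"))
skinny = nm.shifted_coverage(pooled, "skinny", chrom_sizes)
nio.write_bedgraph(skinny, tracks / "input_skinny_raw.bedgraph")
print(f"skinny coverage: {skinny.n_alignments_used:,} pooled input "
      f"alignments, mean {skinny.mean():.2f} per bp")
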