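#!/usr/bin/env python
"""Complex rearrangement events: fold-back inversions, breakage-fusion-
bridge inference, kataegis and chromothripsis calls, and the per-sample
event summary.  Writes results/events/."""

import json
from pathlib import Path

import pandas as pd

from somakit import io_formats as iof
from somakit.complex_events import (detect_chromothripsis, detect_foldbacks,
                                    detect_kataegis, infer_bfb, rainfall)
from somakit.summary import event_summary, percent_positive

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort"
OUT = ROOT / "results" / "events"


def main() -> None:
    snvs = iof.read_snv_table(COHORT / "snvs.tsv")
    svs = iof.read_sv_bedpe(ROOT / "results" / "sv" / "kept.bedpe")
    segments = iof.read_seg(COHORT / "segments.seg")
    genes = iof.read_gene_bed(COHORT / "genes.bed")
    clinical = iof.read_clinical(COHORT / "clinical.tsv")
    OUT.mkdir(parents=True, exist_ok=True)

    foldbacks = detect_foldbacks(svs, segments)
    bfb = infer_bfb(foldbacks, segments, genes)
    kataegis = detect_kataegis(snvs, svs=svs)
    ct = detect_chromothripsis(svs, segments)

    pd.DataFrame([(f.sample_id, f.chrom, f.pos_low, f.pos_high, f.span)
                  for f in foldbacks],
                 columns=["sample_id", "chrom", "pos_low", "pos_high", "span"]
                 ).to_csv(OUT / "foldbacks.tsv", sep="\t", index=False)
    pd.DataFrame([(c.sample_id, c.chrom, len(c.foldbacks),
                   ",".join(c.amplified_genes), c.telomere_loss) for c in bfb],
                 columns=["sample_id", "chrom", "n_foldbacks",
                          "amplified_genes", "telomere_loss"]
                 ).to_csv(OUT / "bfb.tsv", sep="\t", index=False)
    pd.DataFrame([(l.sample_id, l.chrom, l.start, l.end, l.n_mutations,
                   l.mean_imd, l.nearest_sv_distance) for l in kataegis],
                 columns=["sample_id", "chrom", "start", "end", "n_mutations",
                          "mean_imd", "nearest_sv_distance"]
                 ).to_csv(OUT / "kataegis.tsv", sep="\t", index=False)
    pd.DataFrame([(c.sample_id, c.chrom, c.window_start, c.window_end,
                   c.n_breakpoints, c.oscillation_fraction, c.passes)
                  for c in ct],
                 columns=["sample_id", "chrom", "window_start", "window_end",
                          "n_breakpoints", "oscillation_fraction", "passes"]
                 ).to_csv(OUT / "chromothripsis.tsv", sep="\t", index=False)
    rainfall(snvs).to_csv(OUT / "rainfall.tsv", sep="\t", index=False)

    flags = event_summary(list(clinical.index), kataegis, bfb, ct)
    flags.to_csv(OUT / "event_summary.tsv", sep="\t")
    pct = {name: percent_positive(flags[name])
           for name in ("kataegis", "bfb", "chromothripsis", "any_event")}
    with open(OUT / "percentages.json", "w") as fh:
        json.dump(pct, fh, indent=1)
    print(f"{len(foldbacks)} fold-back inversions in "
          f"{len({f.sample_id for f in foldbacks})} samples; "
          f"{len(kataegis)} kataegis loci in "
          f"{len({l.sample_id for l in kataegis})} samples; "
          f"{sum(c.passes for c in ct)} chromothripsis call(s)")
    print("cohort percentages:", pct)


if __name__ == "__main__":
    main()
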