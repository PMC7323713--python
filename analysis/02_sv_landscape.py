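#!/usr/bin/env python
"""Structural-variant landscape: split the simulated truth set into two
noisy caller call sets, merge them back, filter, and summarize class shares
and per-gene recurrence.  Writes results/sv/."""

from pathlib import Path

import pandas as pd

from somakit import io_formats as iof
from somakit.sv import (classify_all, filter_svs, gene_sv_recurrence,
                        mean_svs_per_sample, merge_callsets,
                        summarize_sv_classes)
from somakit.synthetic import inject_caller_noise

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort"
OUT = ROOT / "results" / "sv"


def main() -> None:
    svs = iof.read_sv_bedpe(COHORT / "svs.bedpe")
    clinical = iof.read_clinical(COHORT / "clinical.tsv")
    genes = iof.read_gene_bed(COHORT / "genes.bed")
    OUT.mkdir(parents=True, exist_ok=True)

    # two-caller merge: jittered/dropped views of the same somatic truth
    set_a, set_b = inject_caller_noise(svs, dup_rate=0.05, drop_rate=0.1,
                                       jitter_bp=20, seed=7)
    merged = merge_callsets(classify_all(set_a), classify_all(set_b),
                            tol_bp=100)
    kept, tally = filter_svs(merged)
    iof.write_sv_bedpe(kept, OUT / "kept.bedpe")
    pd.Series(tally, name="n_rejected").rename_axis("rule").to_csv(
        OUT / "rejections.tsv", sep="\t")

    summary = summarize_sv_classes(kept)
    pd.DataFrame({"count": summary["counts"], "share_pct": summary["shares"]}
                 ).rename_axis("sv_class").to_csv(OUT / "class_summary.tsv",
                                                  sep="\t")
    rec = gene_sv_recurrence(kept, genes, list(clinical.index))
    pd.DataFrame([(g.gene, len(g.affected_samples), g.frequency) for g in rec],
                 columns=["gene", "n_samples", "frequency"]
                 ).to_csv(OUT / "gene_recurrence.tsv", sep="\t", index=False)

    both = sum(1 for r in kept if len(r.caller_ids) == 2)
    print(f"merged {len(set_a)}+{len(set_b)} caller records -> "
          f"{len(merged)} ({both} supported by both callers); "
          f"kept {len(kept)} after filtering (rejected: {dict(tally)})")
    print("class shares (%):", summary["shares"])
    print(f"mean SVs/sample: "
          f"{mean_svs_per_sample(summary['total'], len(clinical))}")
    if rec:
        top = rec[0]
        print(f"most recurrent gene: {top.gene} "
              f"({100 * top.frequency:.0f}% of samples)")


if __name__ == "__main__":
    main()
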