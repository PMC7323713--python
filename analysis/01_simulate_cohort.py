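#!/usr/bin/env python
"""Generate the default 20-sample synthetic cohort and write its five input
files plus the ground-truth record under results/cohort/.

The default conditions plant: ~5,000 SNVs/sample from four signatures (one
covariate-linked), kataegis clusters in 6 samples, fold-back inversions in
14 samples (8 at the recurrent amplicon), one chromothripsis sample, a
recurrent amplification in 14 samples and a recurrent deletion in 16.
"""

from pathlib import Path

from somakit import io_formats as iof
from somakit.synthetic import (SimulationConfig, simulate_cohort,
                               synthetic_drug_table, synthetic_genes,
                               synthetic_reference_catalog)

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main(seed: int = 1) -> None:
    cfg = SimulationConfig(seed=seed)
    snvs, svs, segments, clinical, truth = simulate_cohort(cfg)
    genes = synthetic_genes(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    iof.write_snv_table(snvs, OUT / "snvs.tsv")
    iof.write_sv_bedpe(svs, OUT / "svs.bedpe")
    iof.write_seg(segments, OUT / "segments.seg")
    iof.write_clinical(clinical, OUT / "clinical.tsv")
    iof.write_gene_bed(genes, OUT / "genes.bed")
    iof.write_reference_signatures(
        synthetic_reference_catalog(truth.true_signatures),
        OUT / "reference_signatures.tsv")
    synthetic_drug_table(genes).to_csv(OUT / "drug_table.tsv", sep="\t",
                                       index=False)
    truth.to_json(OUT / "ground_truth.json")
    print(f"cohort: {cfg.n_samples} samples, {len(snvs)} SNVs, "
          f"{len(svs)} SVs, {len(segments)} CN segments -> {OUT}")


if __name__ == "__main__":
    main()
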