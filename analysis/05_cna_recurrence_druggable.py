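#!/usr/bin/env python
"""Recurrent copy-number regions and druggable genes: bin the segment
profiles, score recurrence against the cyclic-permutation null, call
per-sample status of the significant regions, and intersect altered genes
with the local gene-drug table.  Writes results/cna/."""

import json
from pathlib import Path

import pandas as pd

from somakit import io_formats as iof
from somakit.cna import (CnaCallParams, bin_copy_number,
                         call_sample_region_status, druggable_intersection,
                         score_recurrence)
from somakit.sv import gene_sv_recurrence
from somakit.channels import channel_of

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort"
OUT = ROOT / "results" / "cna"


def main(seed: int = 0) -> None:
    segments = iof.read_seg(COHORT / "segments.seg")
    genes = iof.read_gene_bed(COHORT / "genes.bed")
    clinical = iof.read_clinical(COHORT / "clinical.tsv")
    drug_table = iof.read_drug_table(COHORT / "drug_table.tsv")
    svs = iof.read_sv_bedpe(ROOT / "results" / "sv" / "kept.bedpe")
    snvs = iof.read_snv_table(COHORT / "snvs.tsv")
    OUT.mkdir(parents=True, exist_ok=True)

    genome = {}
    for s in segments:
        genome[s.chrom] = max(genome.get(s.chrom, 0), s.end)
    params = CnaCallParams(seed=seed)
    binned = bin_copy_number(segments, tuple(genome.items()), params)
    regions = score_recurrence(binned, params, genes=genes)
    pd.DataFrame([(r.chrom, r.start, r.end, r.direction, r.frequency,
                   r.g_score, r.q_value, ",".join(r.genes)) for r in regions],
                 columns=["chrom", "start", "end", "direction", "frequency",
                          "g_score", "q_value", "genes"]
                 ).to_csv(OUT / "regions.tsv", sep="\t", index=False)

    status_rows = []
    for r in regions:
        status = call_sample_region_status(segments, (r.chrom, r.start, r.end),
                                           params)
        for sample, st in status.items():
            status_rows.append((r.chrom, r.start, r.end, r.direction, sample,
                                st))
    pd.DataFrame(status_rows, columns=["chrom", "start", "end", "direction",
                                       "sample_id", "status"]
                 ).to_csv(OUT / "region_status.tsv", sep="\t", index=False)

    # altered gene sets per mutation type for the druggability intersection
    cna_genes = {g for r in regions for g in r.genes}
    sv_genes = {g.gene for g in gene_sv_recurrence(svs, genes,
                                                   list(clinical.index))}
    gene_lookup = {(g.chrom): [] for g in genes}
    for g in genes:
        gene_lookup[g.chrom].append(g)
    snv_genes = {g.gene for r in snvs for g in gene_lookup.get(r.chrom, ())
                 if g.start <= r.pos <= g.end}
    druggable, venn = druggable_intersection(
        {"snv": snv_genes, "sv": sv_genes, "cna": cna_genes}, drug_table)
    pd.DataFrame([(d.gene, d.n_interactions,
                   ",".join(sorted(d.alteration_sources))) for d in druggable],
                 columns=["gene", "n_interactions", "sources"]
                 ).to_csv(OUT / "druggable.tsv", sep="\t", index=False)
    with open(OUT / "venn.json", "w") as fh:
        json.dump(venn, fh, indent=1)

    print(f"{len(regions)} recurrent region(s):")
    for r in regions:
        print(f"  {r.direction} {r.chrom}:{r.start}-{r.end} "
              f"frequency {r.frequency:.2f}, q = {r.q_value:.3g}, "
              f"genes: {', '.join(r.genes) or '-'}")
    print(f"{len(druggable)} druggable gene(s) among "
          f"{sum(venn.values())} altered; Venn cells: {venn}")


if __name__ == "__main__":
    main()
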