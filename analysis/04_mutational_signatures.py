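#!/usr/bin/env python
"""Mutational signatures: build the 96-channel catalog, extract signatures
by ARD KL-NMF, match them against the reference catalog by cosine
similarity, and test exposure association with the smoking-like covariate.
Writes results/signatures/."""

from pathlib import Path

import pandas as pd

from somakit import io_formats as iof
from somakit.signatures import (build_catalog, exposure_association,
                                extract_signatures, match_signatures)

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort"
OUT = ROOT / "results" / "signatures"


def main(seed: int = 0) -> None:
    snvs = iof.read_snv_table(COHORT / "snvs.tsv")
    clinical = iof.read_clinical(COHORT / "clinical.tsv")
    ref = iof.read_reference_signatures(COHORT / "reference_signatures.tsv")
    OUT.mkdir(parents=True, exist_ok=True)

    catalog = build_catalog(snvs, list(clinical.index))
    catalog.to_frame().rename_axis("channel").to_csv(OUT / "catalog.tsv",
                                                     sep="\t")
    model = extract_signatures(catalog, k_max=8, seed=seed)
    names = [f"W{i + 1}" for i in range(model.k)]
    pd.DataFrame(model.W, index=list(catalog.channels), columns=names
                 ).rename_axis("channel").to_csv(OUT / "signatures.tsv",
                                                 sep="\t")
    pd.DataFrame(model.H, index=names, columns=list(catalog.samples)
                 ).rename_axis("signature").to_csv(OUT / "exposures.tsv",
                                                   sep="\t")
    matches = match_signatures(model, ref)
    pd.DataFrame([(names[m.extracted_index], m.reference_name, m.cosine,
                   m.matched) for m in matches],
                 columns=["signature", "best_reference", "cosine", "matched"]
                 ).to_csv(OUT / "matches.tsv", sep="\t", index=False)
    assoc = exposure_association(model, clinical, "smoker", test="wilcoxon",
                                 signature_names=names)
    assoc.to_csv(OUT / "association.tsv", sep="\t", index=False)

    print(f"extracted k={model.k} signatures from "
          f"{int(catalog.counts.sum())} mutations")
    for m in matches:
        print(f"  {names[m.extracted_index]} -> {m.reference_name} "
              f"(cosine {m.cosine:.3f}, "
              f"{'matched' if m.matched else 'unmatched'})")
    best = assoc.iloc[assoc["p_value"].iloc[:model.k].idxmin()]
    print(f"smoking-linked signature: {best['signature']} "
          f"(rank-sum p = {best['p_value']:.4g})")
    burden = assoc[assoc["signature"] == "total_burden"].iloc[0]
    print(f"total burden smoker vs non-smoker: p = {burden['p_value']:.3g}")


if __name__ == "__main__":
    main()
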