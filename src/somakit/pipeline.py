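"""End-to-end cohort analysis over a simulated (or loaded) cohort.

`analyze_cohort` chains the stages in their canonical order — classify and
filter SVs, detect fold-backs / BFB / kataegis / chromothripsis, call
per-sample status of the recurrent regions, and flag per-sample complex
events — returning every intermediate product for inspection.
"""

from __future__ import annotations

from . import cna as cna_mod
from . import complex_events as ce
from . import summary as summary_mod
from . import sv as sv_mod
from .synthetic import SimulationConfig, simulate_cohort, synthetic_genes


def analyze_cohort(config: SimulationConfig | None = None, genes=None) -> dict:
    cfg = config or SimulationConfig()
    snvs, svs, segments, clinical, truth = simulate_cohort(cfg)
    if genes is None:
        genes = synthetic_genes(cfg)
    kept, tally = sv_mod.filter_svs(sv_mod.classify_all(svs))
    foldbacks = ce.detect_foldbacks(kept, segments)
    bfb = ce.infer_bfb(foldbacks, segments, genes)
    kataegis = ce.detect_kataegis(snvs, svs=kept)
    chromothripsis = ce.detect_chromothripsis(kept, segments)
    flags = summary_mod.event_summary(truth.sample_ids, kataegis, bfb,
                                      chromothripsis)
    return {
        "config": cfg, "snvs": snvs, "svs": svs, "kept": kept,
        "rejections": tally, "segments": segments, "clinical": clinical,
        "truth": truth, "genes": genes, "foldbacks": foldbacks, "bfb": bfb,
        "kataegis": kataegis, "chromothripsis": chromothripsis,
        "event_flags": flags,
    }


def bfb_amplification_share(result: dict) -> tuple[int, int, int]:
    """Of the samples amplified at the recurrent amplicon, how many carry a
    BFB call on that chromosome listing the amplicon gene.

    Returns (n_amplified, n_bfb_associated, integer percent).
    """
    cfg = result["config"]
    chrom, start, end = cfg.amp_region
    status = cna_mod.call_sample_region_status(result["segments"],
                                               cfg.amp_region)
    amplified = {s for s, v in status.items() if v == "amp"}
    associated = {c.sample_id for c in result["bfb"]
                  if c.chrom == chrom and cfg.amp_gene in c.amplified_genes}
    n_amp = len(amplified)
    n_assoc = len(amplified & associated)
    return n_amp, n_assoc, round(100.0 * n_assoc / n_amp) if n_amp else 0
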