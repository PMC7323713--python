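"""Cohort-level event summaries: per-sample complex-event flags and the
assembled cohort report table."""

from __future__ import annotations

import numpy as np
import pandas as pd


def event_summary(cohort, kataegis_loci=(), bfb_calls=(),
                  chromothripsis_calls=()) -> pd.DataFrame:
    """Per-sample boolean flags for kataegis, BFB and chromothripsis plus an
    ``any_event`` column; one row per cohort sample."""
    cohort = list(cohort)
    kat = {l.sample_id for l in kataegis_loci}
    bfb = {c.sample_id for c in bfb_calls}
    ct = {c.sample_id for c in chromothripsis_calls if c.passes}
    df = pd.DataFrame({
        "kataegis": [s in kat for s in cohort],
        "bfb": [s in bfb for s in cohort],
        "chromothripsis": [s in ct for s in cohort],
    }, index=pd.Index(cohort, name="sample_id"))
    df["any_event"] = df.any(axis=1)
    return df


def percent_positive(flags) -> float:
    """Share of true flags as a percentage rounded to the nearest integer."""
    flags = np.asarray(list(flags), dtype=bool)
    if flags.size == 0:
        raise ValueError("empty flag list")
    return round(100.0 * flags.sum() / flags.size)


def cohort_report(cohort, sv_records=(), snvs=(), event_flags=None,
                  exposures=None, signature_names=None,
                  clinical=None) -> pd.DataFrame:
    """Assemble one row per sample: SNV/SV counts, complex-event flags,
    signature exposures and clinical covariates."""
    cohort = list(cohort)
    df = pd.DataFrame(index=pd.Index(cohort, name="sample_id"))
    snv_counts = pd.Series(0, index=df.index, dtype=int)
    for r in snvs:
        if r.sample_id in snv_counts.index:
            snv_counts[r.sample_id] += 1
    sv_counts = pd.Series(0, index=df.index, dtype=int)
    for r in sv_records:
        if r.sample_id in sv_counts.index:
            sv_counts[r.sample_id] += 1
    df["n_snvs"] = snv_counts
    df["n_svs"] = sv_counts
    if event_flags is not None:
        df = df.join(event_flags)
    if exposures is not None:
        exposures = np.asarray(exposures, dtype=float)
        names = (list(signature_names) if signature_names is not None
                 else [f"W{i + 1}" for i in range(exposures.shape[0])])
        for i, name in enumerate(names):
            df[f"exposure_{name}"] = exposures[i, :len(cohort)]
    if clinical is not None:
        df = df.join(clinical)
    return df
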