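"""Readers and writers for every external format the pipeline touches.

Conventions
-----------
* Internal coordinates are 1-based inclusive.  BED and BEDPE are 0-based
  half-open on disk and converted at this boundary (breakend position =
  start + 1); SEG starts are 0-based on disk and converted the same way.
* Chromosome names are normalized by stripping a leading ``chr`` on read;
  writers re-add it when ``chr_prefix=True``.
* Every reader is paired with a writer and read ∘ write ∘ read is the
  identity on the in-memory representation.

BEDPE dialect: the 10 standard columns (chrom1, start1, end1, chrom2, start2,
end2, name, score, strand1, strand2) with the *name* column carrying the
sample id, followed by six extension columns (support_reads, control_reads,
vaf, overhang, control_depth, in_repeat) and two provenance columns
(sv_class, caller_ids).  Missing extension columns are filled with
documented sentinels (zeros / False) and a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .channels import CHANNEL_LABELS
from .records import (BASES, CnSegment, GeneInterval, SnvRecord, SvRecord,
                      chrom_sort_key, normalize_chrom)

logger = logging.getLogger(__name__)

SV_SENTINELS = {"support_reads": 0, "control_reads": 0, "vaf": 0.0,
                "overhang": 0, "control_depth": 0, "in_repeat": False}


class FormatError(ValueError):
    """Malformed input that cannot be recovered at record level."""


# ---------------------------------------------------------------------------
# reference signature catalog
# ---------------------------------------------------------------------------

@dataclass
class ReferenceSignatureCatalog:
    """A 96 x R catalog of reference signature probability vectors."""

    channel_labels: tuple
    matrix: np.ndarray          # 96 x R, columns sum to 1
    names: tuple

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (96, len(self.names)):
            raise FormatError(f"catalog matrix must be 96 x {len(self.names)}, "
                              f"got {self.matrix.shape}")

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


def read_reference_signatures(path) -> ReferenceSignatureCatalog:
    """Read a reference catalog TSV (first column ``channel``, one column per
    signature), reorder rows into the canonical channel order and validate.

    Columns whose sum is within 1e-3 of 1 are silently renormalized; larger
    deviations are a hard error.  A catalog without exactly the 96 canonical
    channels raises an error naming the missing labels.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    present = set(df.index.astype(str))
    missing = [c for c in CHANNEL_LABELS if c not in present]
    if missing:
        raise FormatError(f"reference catalog is missing {len(missing)} "
                          f"channel(s): {', '.join(missing[:8])}"
                          + ("..." if len(missing) > 8 else ""))
    extra = present - set(CHANNEL_LABELS)
    if extra:
        raise FormatError(f"reference catalog has unknown channels: {sorted(extra)[:8]}")
    df = df.loc[list(CHANNEL_LABELS)]
    mat = df.to_numpy(dtype=float)
    if (mat < 0).any():
        raise FormatError("reference catalog has negative entries")
    sums = mat.sum(axis=0)
    off = np.abs(sums - 1.0)
    if (off > 1e-3).any():
        bad = [df.columns[i] for i in np.nonzero(off > 1e-3)[0]]
        raise FormatError(f"catalog columns do not sum to 1 (tolerance 1e-3): {bad}")
    mat = mat / sums
    return ReferenceSignatureCatalog(CHANNEL_LABELS, mat, tuple(df.columns))


def write_reference_signatures(catalog: ReferenceSignatureCatalog, path) -> None:
    pd.DataFrame(catalog.matrix, index=list(catalog.channel_labels),
                 columns=list(catalog.names)).rename_axis("channel").to_csv(
        path, sep="\t", float_format="%.8g")


# ---------------------------------------------------------------------------
# SNVs
# ---------------------------------------------------------------------------

SNV_COLUMNS = ("sample_id", "chrom", "pos", "ref", "alt", "context")


def read_snv_table(path, dialect: str = "tsv", sample_id: str | None = None,
                   fasta=None) -> list[SnvRecord]:
    """Read somatic SNVs from a TSV (columns sample_id, chrom, pos, ref, alt,
    context) or a VCF.

    Multiallelic rows are split into one record per alternate base; rows that
    are not simple substitutions (indels, MNVs) are skipped and the skip count
    logged.  For the VCF dialect the trinucleotide context is taken from the
    ``CONTEXT`` INFO field, or derived from ``fasta`` (a `pyfaidx.Fasta` or
    path) when absent; a VCF without either is a hard error.
    """
    if dialect == "tsv":
        return _read_snv_tsv(path)
    if dialect == "vcf":
        return _read_snv_vcf(path, sample_id=sample_id, fasta=fasta)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_snv_tsv(path) -> list[SnvRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if not set(SNV_COLUMNS) <= set(df.columns):
        # headerless fallback: assume canonical column order
        df = pd.read_csv(path, sep="\t", dtype=str, header=None,
                         names=SNV_COLUMNS, comment="#")
    records, skipped = [], 0
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        try:
            pos = int(row.pos)
        except (TypeError, ValueError):
            raise FormatError(f"{path}: line {lineno}: malformed position {row.pos!r}")
        for a in alt.split(","):
            if len(ref) != 1 or len(a) != 1 or ref not in BASES or a not in BASES:
                skipped += 1
                continue
            records.append(SnvRecord(str(row.sample_id), normalize_chrom(row.chrom),
                                     pos, ref, a, str(row.context).upper()))
    if skipped:
        logger.info("read_snv_table: skipped %d non-SNV allele(s) in %s",
                    skipped, path)
    return records


def _read_snv_vcf(path, sample_id=None, fasta=None) -> list[SnvRecord]:
    import pysam

    if fasta is not None and not hasattr(fasta, "__getitem__"):
        from pyfaidx import Fasta
        fasta = Fasta(str(fasta))
    records, skipped = [], 0
    with pysam.VariantFile(str(path)) as vcf:
        default_sample = sample_id or (list(vcf.header.samples) or [None])[0]
        if default_sample is None:
            import os
            default_sample = os.path.basename(str(path)).split(".")[0]
        for rec in vcf:
            ref = (rec.ref or "").upper()
            for alt in rec.alts or ():
                alt = alt.upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
                    skipped += 1
                    continue
                ctx = rec.info.get("CONTEXT") if "CONTEXT" in rec.info else None
                if isinstance(ctx, tuple):
                    ctx = ctx[0]
                if ctx is None:
                    if fasta is None:
                        raise FormatError(
                            f"{path}: no CONTEXT INFO field and no FASTA supplied")
                    chrom = rec.chrom
                    if chrom not in fasta and normalize_chrom(chrom) in fasta:
                        chrom = normalize_chrom(chrom)
                    ctx = str(fasta[chrom][rec.pos - 2:rec.pos + 1]).upper()
                records.append(SnvRecord(default_sample, normalize_chrom(rec.chrom),
                                         rec.pos, ref, alt, str(ctx).upper()))
    if skipped:
        logger.info("read_snv_table: skipped %d non-SNV allele(s) in %s",
                    skipped, path)
    return records


def write_snv_table(records, path) -> None:
    pd.DataFrame(
        [(r.sample_id, r.chrom, r.pos, r.ref, r.alt, r.context) for r in records],
        columns=SNV_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SVs (BEDPE)
# ---------------------------------------------------------------------------

BEDPE_STANDARD = ("chrom1", "start1", "end1", "chrom2", "start2", "end2",
                  "name", "score", "strand1", "strand2")
BEDPE_EXTENSION = ("support_reads", "control_reads", "vaf", "overhang",
                   "control_depth", "in_repeat")
BEDPE_PROVENANCE = ("sv_class", "caller_ids")


def read_sv_bedpe(path, caller_id: str | None = None) -> list[SvRecord]:
    """Read SVs from BEDPE; breakend position = BEDPE start + 1.

    Records are canonicalized (lower breakend first, strands travelling with
    their breakend) and ``sv_class`` is reset to ``unclassified`` unless the
    file carries the provenance column.  ``caller_id`` overrides any stored
    caller provenance.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom1\t"):
                continue
            rows.append((lineno, line.split("\t")))
    warned_missing = False
    records = []
    for lineno, f in rows:
        if len(f) < 10:
            raise FormatError(f"{path}: line {lineno}: expected >= 10 BEDPE "
                              f"columns, got {len(f)}")
        try:
            start1, start2 = int(f[1]), int(f[4])
        except ValueError:
            raise FormatError(f"{path}: line {lineno}: malformed coordinate")
        strand1, strand2 = f[8], f[9]
        if strand1 not in "+-" or strand2 not in "+-":
            raise FormatError(f"{path}: line {lineno}: strand must be + or -, "
                              f"got {strand1!r}/{strand2!r}")
        ext = list(f[10:16])
        if len(ext) < 6:
            if not warned_missing:
                logger.warning("read_sv_bedpe: %s lacks extension columns; "
                               "filling sentinels %s", path, SV_SENTINELS)
                warned_missing = True
            ext += [None] * (6 - len(ext))
        sup, ctrl, vaf, over, depth, rep = ext
        sv_class = f[16] if len(f) > 16 else "unclassified"
        callers = frozenset([caller_id]) if caller_id else (
            frozenset(c for c in f[17].split(",") if c) if len(f) > 17
            else frozenset())
        rec = SvRecord(
            sample_id=f[6], chrom1=normalize_chrom(f[0]), pos1=start1 + 1,
            strand1=strand1, chrom2=normalize_chrom(f[3]), pos2=start2 + 1,
            strand2=strand2,
            support_reads=int(sup) if sup is not None else 0,
            control_reads=int(ctrl) if ctrl is not None else 0,
            vaf=float(vaf) if vaf is not None else 0.0,
            overhang=int(over) if over is not None else 0,
            control_depth=int(depth) if depth is not None else 0,
            in_repeat=_parse_bool(rep) if rep is not None else False,
            sv_class=sv_class, caller_ids=callers)
        records.append(rec.canonical())
    return records


def _parse_bool(x) -> bool:
    return str(x).strip().lower() in ("1", "true", "t", "yes")


def write_sv_bedpe(records, path, chr_prefix: bool = False) -> None:
    pre = "chr" if chr_prefix else ""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(BEDPE_STANDARD + BEDPE_EXTENSION
                                 + BEDPE_PROVENANCE) + "\n")
        for r in records:
            fh.write("\t".join(map(str, (
                pre + r.chrom1, r.pos1 - 1, r.pos1, pre + r.chrom2,
                r.pos2 - 1, r.pos2, r.sample_id, ".", r.strand1, r.strand2,
                r.support_reads, r.control_reads, repr(r.vaf), r.overhang,
                r.control_depth, int(r.in_repeat), r.sv_class,
                ",".join(sorted(r.caller_ids))))) + "\n")


# ---------------------------------------------------------------------------
# copy-number segments (SEG)
# ---------------------------------------------------------------------------

SEG_COLUMNS = ("sample_id", "chrom", "start", "end", "copy_number", "log2_ratio")


def read_seg(path) -> list[CnSegment]:
    """Read a SEG-style table (0-based starts on disk, converted to 1-based)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if not set(SEG_COLUMNS) <= set(df.columns):
        df = pd.read_csv(path, sep="\t", dtype=str, header=None,
                         names=SEG_COLUMNS, comment="#")
    segs = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            start, end = int(row.start), int(row.end)
        except ValueError:
            raise FormatError(f"{path}: line {lineno}: malformed coordinate")
        segs.append(CnSegment(str(row.sample_id), normalize_chrom(row.chrom),
                              start + 1, end, float(row.copy_number),
                              float(row.log2_ratio)))
    return sort_segments(segs)


def write_seg(segments, path, chr_prefix: bool = False) -> None:
    pre = "chr" if chr_prefix else ""
    pd.DataFrame(
        [(s.sample_id, pre + s.chrom, s.start - 1, s.end, repr(s.copy_number),
          repr(s.log2_ratio)) for s in segments],
        columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)


def sort_segments(segments) -> list[CnSegment]:
    out = sorted(segments, key=lambda s: (s.sample_id, chrom_sort_key(s.chrom),
                                          s.start))
    prev = None
    for s in out:
        if (prev is not None and prev.sample_id == s.sample_id
                and prev.chrom == s.chrom and s.start <= prev.end):
            raise FormatError(f"overlapping segments for {s.sample_id} "
                              f"chr{s.chrom}: {prev.start}-{prev.end} and "
                              f"{s.start}-{s.end}")
        prev = s
    return out


# ---------------------------------------------------------------------------
# genes (BED), clinical and drug tables
# ---------------------------------------------------------------------------

def read_gene_bed(path) -> list[GeneInterval]:
    """BED (>= 4 columns: chrom, start, end, name); half-open 0-based on disk."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise FormatError(f"{path}: line {lineno}: need >= 4 BED columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: malformed coordinate")
            genes.append(GeneInterval(f[3], normalize_chrom(f[0]), start + 1, end))
    return genes


def write_gene_bed(genes, path, chr_prefix: bool = False) -> None:
    pre = "chr" if chr_prefix else ""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{pre + g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene}\n")


def read_clinical(path) -> pd.DataFrame:
    """Clinical covariate TSV: one row per sample, indexed by ``sample_id``."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: clinical table needs a sample_id column")
    return df.set_index("sample_id")


def write_clinical(table: pd.DataFrame, path) -> None:
    table.rename_axis("sample_id").to_csv(path, sep="\t")


def read_drug_table(path) -> pd.DataFrame:
    """Gene-drug interaction TSV with columns gene, drug, interaction_type."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"gene", "drug"}
    if not needed <= set(df.columns):
        raise FormatError(f"{path}: drug table needs columns {sorted(needed)}")
    if df.empty:
        raise FormatError(f"{path}: drug table is empty")
    df["gene"] = df["gene"].str.upper()
    return df
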