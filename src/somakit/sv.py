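"""Classification, filtering, merging and cohort summaries of somatic SVs.

The four-class scheme follows read-pair orientation: on one chromosome a
(+,-) junction is a deletion, (-,+) a tandem duplication, and (+,+)/(-,-)
an inversion; breakends on two chromosomes are a translocation.

Filtering applies record-level evidence thresholds in the style of a
two-caller tumor/normal pipeline: minimum supporting junction reads,
maximum variant reads in the matched control, minimum variant allele
fraction, a control-depth quality floor, minimum breakpoint overhang, a
minimum inversion size, and removal of calls inside simple repeats.  The
call-stage thresholds (junction 2, control 10, overhang 50) are retained in
:class:`SvFilterParams` for provenance, but the stricter filter-stage values
govern, since the package consumes call records rather than raw reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from intervaltree import IntervalTree

from .records import GeneInterval, SvRecord, chrom_sort_key, sv_sort_key

logger = logging.getLogger(__name__)


@dataclass
class SvFilterParams:
    """Evidence thresholds for somatic SV filtering (all inclusive)."""

    min_support: int = 2
    max_control_reads_call: int = 10
    max_control_reads_filter: int = 1
    min_vaf: float = 0.07
    min_control_depth: int = 10
    min_overhang_call: int = 50
    min_overhang_filter: int = 100
    min_inversion_size: int = 1000
    drop_repeats: bool = True

    def __post_init__(self):
        if not 0.0 <= self.min_vaf <= 1.0:
            raise ValueError("min_vaf must be in [0, 1]")
        for name in ("min_support", "max_control_reads_call",
                     "max_control_reads_filter", "min_control_depth",
                     "min_overhang_call", "min_overhang_filter",
                     "min_inversion_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GeneRecurrence:
    gene: str
    affected_samples: frozenset
    frequency: float


def classify_sv(record: SvRecord) -> str:
    """Return the orientation class of a canonical breakend pair."""
    record = record.canonical()
    if record.chrom1 != record.chrom2:
        return "translocation"
    pair = (record.strand1, record.strand2)
    if pair == ("+", "-"):
        return "deletion"
    if pair == ("-", "+"):
        return "tandem_duplication"
    return "inversion"


def classify_all(records) -> list[SvRecord]:
    return [replace(r.canonical(), sv_class=classify_sv(r)) for r in records]


# Documented rejection-rule order: first failing rule is tallied.
FILTER_RULES = ("support", "control_reads", "vaf", "control_depth",
                "overhang", "inversion_size", "repeat")


def filter_svs(records, params: SvFilterParams | None = None
               ) -> tuple[list[SvRecord], dict[str, int]]:
    """Apply evidence thresholds; return (kept records, rejection tally).

    A record is kept iff every rule passes; a rejected record increments the
    first failing rule in :data:`FILTER_RULES` order.  Thresholds are
    inclusive: e.g. ``vaf == min_vaf`` passes.
    """
    params = params or SvFilterParams()
    kept, tally = [], {}
    for r in records:
        rule = _first_failure(r, params)
        if rule is None:
            kept.append(r)
        else:
            tally[rule] = tally.get(rule, 0) + 1
    return kept, tally


def _first_failure(r: SvRecord, p: SvFilterParams) -> str | None:
    if r.support_reads < p.min_support:
        return "support"
    if r.control_reads > p.max_control_reads_filter:
        return "control_reads"
    if r.vaf < p.min_vaf:
        return "vaf"
    if r.control_depth < p.min_control_depth:
        return "control_depth"
    if r.overhang < p.min_overhang_filter:
        return "overhang"
    if (r.sv_class == "inversion" and r.span is not None
            and r.span < p.min_inversion_size):
        return "inversion_size"
    if p.drop_repeats and r.in_repeat:
        return "repeat"
    return None


# ---------------------------------------------------------------------------
# two-callset merging
# ---------------------------------------------------------------------------

def _records_match(a: SvRecord, b: SvRecord, tol_bp: int) -> bool:
    return (a.sample_id == b.sample_id and a.sv_class == b.sv_class
            and a.chrom1 == b.chrom1 and a.chrom2 == b.chrom2
            and abs(a.pos1 - b.pos1) <= tol_bp
            and abs(a.pos2 - b.pos2) <= tol_bp)


def _pair_distance(a: SvRecord, b: SvRecord) -> int:
    return abs(a.pos1 - b.pos1) + abs(a.pos2 - b.pos2)


def merge_callsets(set_a, set_b, tol_bp: int = 100) -> list[SvRecord]:
    """Merge two canonical call sets by greedy nearest-pair-first matching.

    Two records match iff same sample, same class, and both breakends within
    ``tol_bp``.  Matched pairs collapse to one record carrying the union of
    caller ids and the evidence fields of the higher-support member (ties
    favour set A).  Matching is run to maximality, so no unmatched A record
    still matches an unmatched B record; unmatched records pass through.
    Deterministic: candidate pairs are processed by (distance, sort key).
    """
    a_list = sorted(set_a, key=sv_sort_key)
    b_list = sorted(set_b, key=sv_sort_key)
    candidates = []
    for i, a in enumerate(a_list):
        for j, b in enumerate(b_list):
            if _records_match(a, b, tol_bp):
                candidates.append((_pair_distance(a, b), i, j))
    candidates.sort()
    used_a, used_b, merged = set(), set(), []
    for _dist, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        a, b = a_list[i], b_list[j]
        winner = a if a.support_reads >= b.support_reads else b
        merged.append(replace(winner, caller_ids=a.caller_ids | b.caller_ids))
    merged.extend(a for i, a in enumerate(a_list) if i not in used_a)
    merged.extend(b for j, b in enumerate(b_list) if j not in used_b)
    return sorted(merged, key=sv_sort_key)


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------

def summarize_sv_classes(records) -> dict:
    """Per-class counts and percentage shares (2-dp), plus the total."""
    counts = {}
    for r in records:
        counts[r.sv_class] = counts.get(r.sv_class, 0) + 1
    total = sum(counts.values())
    shares = {c: round(100.0 * n / total, 2) for c, n in counts.items()} if total else {}
    return {"counts": counts, "shares": shares, "total": total}


def mean_svs_per_sample(total: int, n_samples: int) -> int:
    """Cohort mean SV burden, rounded to the nearest integer."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    return round(total / n_samples)


def gene_sv_recurrence(records, genes: list[GeneInterval], cohort,
                       breakend_rule: bool = True, span_rule: bool = True
                       ) -> list[GeneRecurrence]:
    """Per-gene SV recurrence across the cohort.

    A gene is affected in a sample if either breakend of one of that
    sample's (kept) SVs falls inside the gene interval (inclusive), or a
    deletion-class SV spans the gene entirely.  Each sample counts once per
    gene.  Output sorted by descending frequency then symbol.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # IntervalTree is half-open; +1 keeps the 1-based inclusive end inside
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.gene)
    by_chrom_genes: dict[str, list[GeneInterval]] = {}
    for g in genes:
        by_chrom_genes.setdefault(g.chrom, []).append(g)
    hits: dict[str, set] = {g.gene: set() for g in genes}
    for r in records:
        if breakend_rule:
            for chrom, pos in ((r.chrom1, r.pos1), (r.chrom2, r.pos2)):
                tree = trees.get(chrom)
                if tree is not None:
                    for iv in tree.at(pos):
                        hits[iv.data].add(r.sample_id)
        if span_rule and r.sv_class == "deletion" and r.chrom1 == r.chrom2:
            for g in by_chrom_genes.get(r.chrom1, ()):
                if r.pos1 <= g.start and g.end <= r.pos2:
                    hits[g.gene].add(r.sample_id)
    n = len(cohort)
    out = [GeneRecurrence(g, frozenset(s), len(s) / n)
           for g, s in hits.items() if s]
    out.sort(key=lambda gr: (-gr.frequency, gr.gene))
    return out
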