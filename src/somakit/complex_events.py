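"""Detection of complex somatic events: fold-back inversions and
breakage-fusion-bridge (BFB), kataegis, and chromothripsis.

Fold-back inversions — the structural hallmark of BFB cycles — are called
from three criteria: (i) a single inversion with no reciprocal partner,
(ii) a copy-number change against the adjacent position, and (iii) breakends
separated by less than 20 kb.  Kataegis is a run of six or more consecutive
mutations whose mean inter-mutation distance is at most 1 kb.  Chromothripsis
requires more than ten SV breakpoints inside a 50 kb window together with
regular oscillation of copy-number states between two levels.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .channels import channel_of
from .records import CnSegment, SnvRecord, SvRecord, chrom_sort_key

logger = logging.getLogger(__name__)


@dataclass
class FoldbackInversion:
    sample_id: str
    chrom: str
    pos_low: int
    pos_high: int
    strand_pair: tuple
    cn_left: float | None
    cn_right: float | None

    @property
    def span(self) -> int:
        return self.pos_high - self.pos_low


@dataclass
class KataegisLocus:
    sample_id: str
    chrom: str
    start: int
    end: int
    n_mutations: int
    mean_imd: float
    nearest_sv_distance: int | None = None


@dataclass
class ChromothripsisCall:
    sample_id: str
    chrom: str
    window_start: int
    window_end: int
    n_breakpoints: int
    oscillation_fraction: float
    passes: bool


@dataclass
class BfbCall:
    sample_id: str
    chrom: str
    foldbacks: list
    amplified_genes: tuple
    telomere_loss: bool


# ---------------------------------------------------------------------------
# fold-back inversions / BFB
# ---------------------------------------------------------------------------

def _segments_by_sample_chrom(segments):
    out: dict[tuple, list[CnSegment]] = {}
    for s in segments:
        out.setdefault((s.sample_id, s.chrom), []).append(s)
    for key in out:
        out[key].sort(key=lambda s: s.start)
    return out


def _containing_index(segs: list[CnSegment], pos: int) -> int:
    """Index of the segment containing pos, or of the nearest segment."""
    best, best_d = 0, math.inf
    for i, s in enumerate(segs):
        if s.start <= pos <= s.end:
            return i
        d = min(abs(pos - s.start), abs(pos - s.end))
        if d < best_d:
            best, best_d = i, d
    return best


def detect_foldbacks(svs, segments, max_span: int = 20000,
                     partner_window: int = 1000, min_cn_step: float = 1.0
                     ) -> list[FoldbackInversion]:
    """Call fold-back inversions from filtered, classified SVs plus segments.

    A candidate is an inversion-class SV whose breakends are separated by
    less than ``max_span``.  It is rejected if a reciprocal partner exists —
    another inversion of the opposite strand pair with both breakends within
    ``partner_window`` — or if no copy-number step of at least ``min_cn_step``
    is found adjacent to either breakend.  Samples without segments yield no
    calls (the CN criterion is treated as failed) with a warning.
    """
    seg_index = _segments_by_sample_chrom(segments)
    inversions = [r for r in svs if r.sv_class == "inversion"
                  and r.chrom1 == r.chrom2]
    out = []
    warned = set()
    for r in inversions:
        if r.span is None or r.span >= max_span:
            continue
        pair = (r.strand1, r.strand2)
        if pair not in (("+", "+"), ("-", "-")):
            continue
        opposite = ("-", "-") if pair == ("+", "+") else ("+", "+")
        has_partner = any(
            o is not r and o.chrom1 == r.chrom1 and o.sample_id == r.sample_id
            and (o.strand1, o.strand2) == opposite
            and abs(o.pos1 - r.pos1) <= partner_window
            and abs(o.pos2 - r.pos2) <= partner_window
            for o in inversions)
        if has_partner:
            continue
        segs = seg_index.get((r.sample_id, r.chrom1))
        if not segs:
            if r.sample_id not in warned:
                logger.warning("detect_foldbacks: no CN segments for sample %s; "
                               "CN criterion treated as failed", r.sample_id)
                warned.add(r.sample_id)
            continue
        i1 = _containing_index(segs, r.pos1)
        i2 = _containing_index(segs, r.pos2)
        if not (_has_cn_step(segs, i1, min_cn_step)
                or _has_cn_step(segs, i2, min_cn_step)):
            continue
        out.append(FoldbackInversion(
            sample_id=r.sample_id, chrom=r.chrom1, pos_low=r.pos1,
            pos_high=r.pos2, strand_pair=pair,
            cn_left=segs[i1].copy_number, cn_right=segs[i2].copy_number))
    return out


def _has_cn_step(segs, i, min_step) -> bool:
    cn = segs[i].copy_number
    for j in (i - 1, i + 1):
        if 0 <= j < len(segs) and abs(cn - segs[j].copy_number) >= min_step:
            return True
    return False


def infer_bfb(foldbacks, segments, genes=(), telomere_margin: int = 100_000,
              min_amp_cn: float = 5.0) -> list[BfbCall]:
    """One BFB call per (sample, chromosome) with at least one fold-back.

    ``telomere_loss`` is advisory (it does not gate the call): true when a
    terminal segment within ``telomere_margin`` of a chromosome end has copy
    number below the sample's modal copy number.  ``amplified_genes`` are
    genes overlapping fold-back-adjacent segments whose copy number is at
    least ``min_amp_cn``.
    """
    seg_index = _segments_by_sample_chrom(segments)
    modal = _modal_cn_by_sample(segments)
    groups: dict[tuple, list[FoldbackInversion]] = {}
    for fb in foldbacks:
        groups.setdefault((fb.sample_id, fb.chrom), []).append(fb)
    calls = []
    for (sample, chrom), fbs in sorted(groups.items(),
                                       key=lambda kv: (kv[0][0],
                                                       chrom_sort_key(kv[0][1]))):
        segs = seg_index.get((sample, chrom), [])
        amp_segments = set()
        for fb in fbs:
            for pos in (fb.pos_low, fb.pos_high):
                if not segs:
                    continue
                i = _containing_index(segs, pos)
                for j in (i - 1, i, i + 1):
                    if 0 <= j < len(segs) and segs[j].copy_number >= min_amp_cn:
                        amp_segments.add(j)
        amp_genes = sorted({g.gene for g in genes if g.chrom == chrom
                            for j in amp_segments
                            if g.start <= segs[j].end and segs[j].start <= g.end})
        calls.append(BfbCall(sample, chrom, sorted(fbs, key=lambda f: f.pos_low),
                             tuple(amp_genes),
                             _telomere_loss(segs, modal.get(sample, 2.0),
                                            telomere_margin)))
    return calls


def _modal_cn_by_sample(segments) -> dict[str, float]:
    weights: dict[str, Counter] = {}
    for s in segments:
        weights.setdefault(s.sample_id, Counter())[round(s.copy_number)] += s.length
    return {sample: float(c.most_common(1)[0][0]) for sample, c in weights.items()}


def _telomere_loss(segs, modal_cn, margin) -> bool:
    if not segs:
        return False
    chrom_end = max(s.end for s in segs)
    terminal = [s for s in segs if s.start <= margin or s.end >= chrom_end - margin]
    return any(s.copy_number < modal_cn for s in terminal)


# ---------------------------------------------------------------------------
# kataegis
# ---------------------------------------------------------------------------

def _snvs_by_sample_chrom(snvs):
    out: dict[tuple, list[SnvRecord]] = {}
    for r in snvs:
        out.setdefault((r.sample_id, r.chrom), []).append(r)
    for key in out:
        out[key].sort(key=lambda r: r.pos)
    return out


def detect_kataegis(snvs, min_mutations: int = 6, max_mean_imd: float = 1000,
                    svs=None) -> list[KataegisLocus]:
    """Scan per sample per chromosome for hypermutation clusters.

    A qualifying run is ``n >= min_mutations`` consecutive sorted mutations
    whose n-1 inter-mutation distances average at most ``max_mean_imd``.
    Maximal qualifying runs that overlap are merged left-to-right when the
    merged run itself still qualifies (so no reported locus violates its own
    definition); otherwise both are reported.  When SVs are supplied each
    locus carries the distance to the nearest SV breakend on its chromosome.
    """
    loci = []
    for (sample, chrom), recs in sorted(_snvs_by_sample_chrom(snvs).items(),
                                        key=lambda kv: (kv[0][0],
                                                        chrom_sort_key(kv[0][1]))):
        pos = np.array([r.pos for r in recs], dtype=np.int64)
        for i, j in _maximal_runs(pos, min_mutations, max_mean_imd):
            loci.append(KataegisLocus(
                sample, chrom, int(pos[i]), int(pos[j]), j - i + 1,
                (pos[j] - pos[i]) / (j - i)))
    if svs is not None:
        _annotate_nearest_sv(loci, svs)
    return loci


def _maximal_runs(pos: np.ndarray, min_n: int, max_imd: float):
    """Maximal qualifying runs as (i, j) index pairs, conditionally merged."""
    n = len(pos)
    if n < min_n:
        return []
    idx = np.arange(n)
    maxj = np.full(n, -1)
    for i in range(n - min_n + 1):
        js = idx[i + min_n - 1:]
        ok = (pos[i + min_n - 1:] - pos[i]) <= max_imd * (js - i)
        hits = js[ok]
        if hits.size:
            maxj[i] = hits.max()
    runs = []
    best = -1
    for i in range(n):
        if maxj[i] > best and maxj[i] >= i + min_n - 1:
            runs.append((i, int(maxj[i])))
            best = int(maxj[i])
    return _merge_runs(pos, runs, max_imd)


def _merge_runs(pos, runs, max_imd):
    """Left-to-right merge of index-overlapping runs when the union qualifies."""
    if not runs:
        return []
    merged = [runs[0]]
    for i, j in runs[1:]:
        ci, cj = merged[-1]
        if i <= cj:
            ui, uj = ci, max(cj, j)
            if (pos[uj] - pos[ui]) / (uj - ui) <= max_imd:
                merged[-1] = (ui, uj)
                continue
        merged.append((i, j))
    return merged


def _annotate_nearest_sv(loci, svs):
    breakends: dict[tuple, list[int]] = {}
    for r in svs:
        breakends.setdefault((r.sample_id, r.chrom1), []).append(r.pos1)
        breakends.setdefault((r.sample_id, r.chrom2), []).append(r.pos2)
    for locus in loci:
        bps = breakends.get((locus.sample_id, locus.chrom))
        if not bps:
            continue
        locus.nearest_sv_distance = int(min(
            0 if locus.start <= p <= locus.end
            else min(abs(p - locus.start), abs(p - locus.end))
            for p in bps))


# ---------------------------------------------------------------------------
# chromothripsis
# ---------------------------------------------------------------------------

def breakpoints_by_sample_chrom(svs) -> dict[tuple, np.ndarray]:
    out: dict[tuple, list[int]] = {}
    for r in svs:
        out.setdefault((r.sample_id, r.chrom1), []).append(r.pos1)
        out.setdefault((r.sample_id, r.chrom2), []).append(r.pos2)
    return {k: np.array(sorted(v), dtype=np.int64) for k, v in out.items()}


def detect_chromothripsis(svs, segments, window: int = 50_000,
                          min_breakpoints: int = 10,
                          min_oscillation: float = 0.8
                          ) -> list[ChromothripsisCall]:
    """Call chromothripsis per sample per chromosome.

    Every window of ``window`` bases holding strictly more than
    ``min_breakpoints`` SV breakends is a candidate; overlapping candidate
    windows merge into one cluster extent.  A cluster passes when, among CN
    segments overlapping its extent, the fraction of adjacent segment pairs
    alternating between the two modal (most frequent, rounded) copy-number
    states is at least ``min_oscillation``.
    """
    seg_index = _segments_by_sample_chrom(segments)
    calls = []
    for (sample, chrom), bps in sorted(breakpoints_by_sample_chrom(svs).items(),
                                       key=lambda kv: (kv[0][0],
                                                       chrom_sort_key(kv[0][1]))):
        for lo, hi in _breakpoint_clusters(bps, window, min_breakpoints):
            n_bp = int(((bps >= lo) & (bps <= hi)).sum())
            frac = oscillation_fraction(
                [s for s in seg_index.get((sample, chrom), [])
                 if s.start <= hi and lo <= s.end])
            calls.append(ChromothripsisCall(
                sample, chrom, int(lo), int(hi), n_bp, frac,
                passes=n_bp > min_breakpoints and frac >= min_oscillation))
    return calls


def _breakpoint_clusters(bps: np.ndarray, window: int, min_bp: int):
    """Merged extents of windows holding > min_bp breakpoints."""
    clusters = []
    n = len(bps)
    j = 0
    for i in range(n):
        j = max(j, i)
        while j + 1 < n and bps[j + 1] - bps[i] <= window:
            j += 1
        if j - i + 1 > min_bp:
            lo, hi = bps[i], bps[j]
            if clusters and lo <= clusters[-1][1]:
                clusters[-1][1] = max(clusters[-1][1], hi)
            else:
                clusters.append([lo, hi])
    return [(lo, hi) for lo, hi in clusters]


def oscillation_fraction(segs) -> float:
    """Fraction of adjacent segment pairs alternating between the two modal
    rounded copy-number states; 0.0 with fewer than two segments."""
    states = [round(s.copy_number) for s in sorted(segs, key=lambda s: s.start)]
    if len(states) < 2:
        return 0.0
    counts = Counter(states)
    modal = [s for s, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:2]]
    if len(modal) < 2:
        return 0.0
    s1, s2 = modal
    pairs = list(zip(states, states[1:]))
    alternating = sum(1 for a, b in pairs if {a, b} == {s1, s2})
    return alternating / len(pairs)


# ---------------------------------------------------------------------------
# rainfall
# ---------------------------------------------------------------------------

def rainfall(snvs) -> pd.DataFrame:
    """Inter-mutation distances for rainfall plots.

    One row per mutation with columns sample_id, chrom, pos, distance (to the
    previous mutation on the same chromosome; NA for the first), and the
    pyrimidine-normalized substitution class.  Distances never cross
    chromosome boundaries.
    """
    rows = []
    for (sample, chrom), recs in sorted(_snvs_by_sample_chrom(snvs).items(),
                                        key=lambda kv: (kv[0][0],
                                                        chrom_sort_key(kv[0][1]))):
        prev = None
        for r in recs:
            label = channel_of(r.ref, r.alt, r.context)
            rows.append((sample, chrom, r.pos,
                         float(r.pos - prev) if prev is not None else np.nan,
                         label[2:5]))
            prev = r.pos
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "distance",
                                       "sub_class"])
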