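"""Recurrent copy-number alteration scoring and druggable-gene intersection.

Recurrence is scored with a documented simplification of peak-finding
algorithms like GISTIC: the genome is cut into fixed bins, each bin's
per-sample value is the length-weighted mean log2 ratio of overlapping
segments, and each bin/direction gets a G-score,

    g = (fraction of samples beyond the threshold)
        x (mean |log2| among those samples),

tested against a null built by cyclically permuting every sample's bin
vector with independent offsets.  Empirical p-values are converted to
Benjamini-Hochberg q-values per direction, and adjacent significant bins
merge into regions.  This preserves the cohort-recurrence concept, not any
particular peak-arbitration scheme; region boundaries are bin-resolution.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .records import CnSegment, chrom_sort_key

logger = logging.getLogger(__name__)


@dataclass
class CnaCallParams:
    amp_log2: float = 0.3
    del_log2: float = -0.3
    bin_size: int = 1_000_000
    n_permutations: int = 1000
    q_threshold: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if not self.amp_log2 > 0 > self.del_log2:
            raise ValueError("need amp_log2 > 0 > del_log2")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")


@dataclass
class BinnedMatrix:
    """Per-sample per-bin length-weighted mean log2 ratios (NaN = uncovered)."""

    values: np.ndarray                 # S x B
    bins: list                         # (chrom, start, end) 1-based inclusive
    samples: list


@dataclass
class RecurrentRegion:
    chrom: str
    start: int
    end: int
    direction: str                     # "amp" | "del"
    frequency: float                   # altered-sample fraction at the peak bin
    g_score: float
    q_value: float
    genes: tuple = ()


@dataclass
class DruggableGene:
    gene: str
    n_interactions: int
    alteration_sources: frozenset


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def make_bins(genome, bin_size: int) -> list:
    bins = []
    for chrom, length in genome:
        start = 1
        while start <= length:
            bins.append((chrom, start, min(start + bin_size - 1, length)))
            start += bin_size
    return bins


def bin_copy_number(segments, genome, params: CnaCallParams | None = None
                    ) -> BinnedMatrix:
    """Length-weighted mean log2 per fixed-size bin per sample.

    A bin's value is the mean of overlapping segment log2 ratios weighted by
    overlap length; bins with no coverage are NaN.
    """
    params = params or CnaCallParams()
    bins = make_bins(genome, params.bin_size)
    samples = sorted({s.sample_id for s in segments})
    sidx = {s: i for i, s in enumerate(samples)}
    bin_index: dict[str, list] = {}
    for b, (chrom, start, end) in enumerate(bins):
        bin_index.setdefault(chrom, []).append((start, end, b))
    weight = np.zeros((len(samples), len(bins)))
    acc = np.zeros((len(samples), len(bins)))
    for seg in segments:
        for start, end, b in bin_index.get(seg.chrom, ()):
            lo, hi = max(start, seg.start), min(end, seg.end)
            if lo > hi:
                continue
            w = hi - lo + 1
            acc[sidx[seg.sample_id], b] += w * seg.log2_ratio
            weight[sidx[seg.sample_id], b] += w
    with np.errstate(invalid="ignore"):
        values = np.where(weight > 0, acc / np.maximum(weight, 1), np.nan)
    return BinnedMatrix(values, bins, samples)


# ---------------------------------------------------------------------------
# recurrence scoring
# ---------------------------------------------------------------------------

def _g_scores(values: np.ndarray, threshold: float, direction: str) -> np.ndarray:
    """Frequency x mean-amplitude score per bin (0 where no sample altered)."""
    if direction == "amp":
        altered = values >= threshold
    else:
        altered = values <= threshold
    amp = np.abs(np.where(altered, values, 0.0))
    n_alt = altered.sum(axis=0)
    freq = n_alt / values.shape[0]
    with np.errstate(invalid="ignore"):
        mean_amp = np.where(n_alt > 0, amp.sum(axis=0) / np.maximum(n_alt, 1), 0.0)
    return freq * mean_amp


def _bh_q(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests
    return multipletests(p, method="fdr_bh")[1]


def score_recurrence(bin_matrix: BinnedMatrix,
                     params: CnaCallParams | None = None,
                     genes=(), exhaustive: bool = False
                     ) -> list[RecurrentRegion]:
    """Score cohort recurrence per bin and direction against a cyclic-
    permutation null; merge adjacent significant bins into regions.

    The null cyclically rotates each sample's whole bin vector by an
    independent offset (``n_permutations`` draws, or every offset combination
    when ``exhaustive``), which preserves each sample's value multiset and
    spatial autocorrelation.  Empirical p = fraction of null G-scores >=
    observed; q = Benjamini-Hochberg within direction; regions never join
    bins of opposite direction or different chromosomes.  Uncovered bins are
    treated as log2 0 for the null rotation.
    """
    params = params or CnaCallParams()
    V = np.nan_to_num(bin_matrix.values, nan=0.0)
    S, B = V.shape
    if S < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(params.seed)
    regions = []
    for direction, thr in (("amp", params.amp_log2), ("del", params.del_log2)):
        obs = _g_scores(V, thr, direction)
        exceed = np.zeros(B)
        if exhaustive:
            n_null = 0
            for offsets in itertools.product(range(B), repeat=S):
                null_g = _g_scores(_rotate(V, offsets), thr, direction)
                exceed += null_g >= obs
                n_null += 1
        else:
            n_null = params.n_permutations
            for _ in range(n_null):
                offsets = rng.integers(0, B, size=S)
                null_g = _g_scores(_rotate(V, offsets), thr, direction)
                exceed += null_g >= obs
        p = exceed / n_null
        q = _bh_q(p)
        regions.extend(_merge_bins(bin_matrix, V, thr, direction, obs, q, params,
                                   genes))
    regions.sort(key=lambda r: (chrom_sort_key(r.chrom), r.start, r.direction))
    return regions


def _rotate(V: np.ndarray, offsets) -> np.ndarray:
    return np.stack([np.roll(V[s], offsets[s]) for s in range(V.shape[0])])


def _merge_bins(bin_matrix, V, thr, direction, g, q, params, genes):
    sig = q <= params.q_threshold
    sig &= g > 0
    regions = []
    bins = bin_matrix.bins
    i = 0
    while i < len(bins):
        if not sig[i]:
            i += 1
            continue
        j = i
        while (j + 1 < len(bins) and sig[j + 1]
               and bins[j + 1][0] == bins[i][0]):
            j += 1
        peak = i + int(np.argmax(g[i:j + 1]))
        altered = (V[:, peak] >= thr) if direction == "amp" else (V[:, peak] <= thr)
        start, end = bins[i][1], bins[j][2]
        chrom = bins[i][0]
        overlapping = tuple(sorted(gn.gene for gn in genes
                                   if gn.chrom == chrom and gn.start <= end
                                   and start <= gn.end))
        regions.append(RecurrentRegion(
            chrom, start, end, direction,
            frequency=float(altered.mean()), g_score=float(g[peak]),
            q_value=float(q[i:j + 1].min()), genes=overlapping))
        i = j + 1
    return regions


# ---------------------------------------------------------------------------
# per-sample region status
# ---------------------------------------------------------------------------

def call_sample_region_status(segments, region,
                              params: CnaCallParams | None = None) -> dict:
    """Per-sample {amp, del, neutral} over a (chrom, start, end) region by
    length-weighted mean log2 (thresholds inclusive); uncovered -> neutral."""
    params = params or CnaCallParams()
    chrom, start, end = region
    acc: dict[str, list] = {}
    samples = sorted({s.sample_id for s in segments})
    for seg in segments:
        if seg.chrom != chrom:
            continue
        lo, hi = max(start, seg.start), min(end, seg.end)
        if lo > hi:
            continue
        acc.setdefault(seg.sample_id, []).append((hi - lo + 1, seg.log2_ratio))
    status = {}
    for sample in samples:
        parts = acc.get(sample)
        if not parts:
            logger.warning("call_sample_region_status: %s has no coverage of "
                           "%s:%d-%d; neutral", sample, chrom, start, end)
            status[sample] = "neutral"
            continue
        w = sum(p[0] for p in parts)
        mean = sum(p[0] * p[1] for p in parts) / w
        if mean >= params.amp_log2:
            status[sample] = "amp"
        elif mean <= params.del_log2:
            status[sample] = "del"
        else:
            status[sample] = "neutral"
    return status


# ---------------------------------------------------------------------------
# druggable genes
# ---------------------------------------------------------------------------

VENN_CELLS = ("snv_only", "sv_only", "cna_only", "snv_sv", "snv_cna",
              "sv_cna", "snv_sv_cna")


def druggable_intersection(altered: dict, drug_table) -> tuple[list, dict]:
    """Intersect per-source altered gene sets with a gene-drug table.

    ``altered`` maps source names (snv, sv, cna) to gene-symbol sets (matched
    upper-case).  A gene is druggable when it has at least one interaction in
    the table; the returned Venn summary counts all seven membership cells
    over the union of the input sets (druggable or not).
    """
    if drug_table is None or len(drug_table) == 0:
        raise ValueError("empty drug table")
    sets = {src: {str(g).upper() for g in gs} for src, gs in altered.items()}
    for src in ("snv", "sv", "cna"):
        sets.setdefault(src, set())
    drugs_per_gene = drug_table.groupby("gene")["drug"].nunique().to_dict()
    union = sets["snv"] | sets["sv"] | sets["cna"]
    druggable = []
    for gene in sorted(union):
        n = drugs_per_gene.get(gene, 0)
        if n < 1:
            continue
        sources = frozenset(src for src in ("snv", "sv", "cna")
                            if gene in sets[src])
        druggable.append(DruggableGene(gene, n, sources))
    venn = {cell: 0 for cell in VENN_CELLS}
    for gene in union:
        members = tuple(src for src in ("snv", "sv", "cna") if gene in sets[src])
        venn["_".join(members) + ("_only" if len(members) == 1 else "")] += 1
    return druggable, venn
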