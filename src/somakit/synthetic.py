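"""Synthetic tumor-cohort generator with known ground truth.

Emulates the statistical structure of a 20-sample whole-genome somatic
study: per-sample SNV burdens drawn from mixtures of known 96-channel
signatures, planted kataegis clusters, the four SV orientation classes with
fold-back inversions at copy-number step edges, an oscillating
chromothripsis region, focal recurrent amplifications/deletions, and a
binary clinical covariate multiplying one signature's exposure.

Default conditions mirror the cohort scale the package targets: 20 samples,
~5,000 SNVs per sample, 6 kataegis-positive samples, 14 fold-back/BFB
samples (8 of which fold back at the recurrent amplicon), one
chromothripsis sample inside the BFB set, and a 15-sample union of samples
carrying any complex event.  Copy-number truth is emitted directly as
segments (segmentation is an input contract, not simulated), and background
SNV positions are uniform per chromosome so the kataegis detector's false
positive behaviour is analytically known.  All randomness flows from a
single seed; outputs are byte-identical across runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .channels import CHANNEL_LABELS, channel_parts
from .io_formats import ReferenceSignatureCatalog
from .records import (COMPLEMENT, CnSegment, GeneInterval, SnvRecord, SvRecord,
                      revcomp)

DEFAULT_GENOME = tuple((str(c), 50_000_000) for c in range(1, 9))

# APOBEC-flavoured channels used for planted kataegis clusters
_KATAEGIS_CHANNELS = ("T[C>T]A", "T[C>T]T", "T[C>G]A", "T[C>G]T")

_SV_CLASS_PROBS = {"deletion": 0.4127, "inversion": 0.3003,
                   "translocation": 0.1480, "tandem_duplication": 0.1390}


def synthetic_signatures(k: int = 4, seed: int = 12345,
                         concentration: float = 0.03) -> np.ndarray:
    """Draw ``k`` synthetic 96-channel signatures (sparse Dirichlet columns).

    Low concentration gives well-separated, signature-like profiles
    (pairwise cosine typically < 0.2).  Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    W = rng.dirichlet(np.full(96, concentration), size=k).T
    return W / W.sum(axis=0)


@dataclass
class SimulationConfig:
    """Cohort-level truth specification; defaults are the study conditions."""

    n_samples: int = 20
    genome: tuple = DEFAULT_GENOME
    signature_matrix: np.ndarray | None = None    # 96 x K; default synthetic K=4
    mean_burden: float = 5000.0
    dirichlet_alpha: float = 0.5
    linked_signature_beta: tuple = (2.5, 10.0)
    anchor_samples: int = 3
    anchor_weight: float = 0.9
    covariate_name: str = "smoker"
    covariate_positive: int = 14                  # smokers in the cohort
    covariate_effect: float = 3.0                 # exposure multiplier
    covariate_signature: int = 3                  # index of the linked signature
    # kataegis
    kataegis_samples: tuple = tuple(range(9, 15))
    kataegis_clusters_per_sample: int = 2
    kataegis_cluster_size: int = 8
    kataegis_max_gap: int = 400
    # background SVs
    sv_per_sample_mean: float = 30.0
    # fold-backs / BFB / recurrent amplification
    foldback_samples: tuple = tuple(range(14))
    foldback_at_amp: int = 8
    foldback_span: tuple = (5_000, 15_000)
    foldback_cn: float = 6.0
    amp_region: tuple = ("5", 30_000_000, 30_500_000)
    amp_samples: tuple = tuple(range(14))
    amp_gene: str = "CCND1"
    alt_foldback_chrom: str = "2"
    alt_foldback_region: tuple = (20_000_000, 20_800_000)
    # recurrent deletion
    del_region: tuple = ("6", 25_000_000, 26_000_000)
    del_samples: tuple = tuple(range(4, 20))
    del_cn: float = 0.8
    del_gene: str = "CDKN2A"
    # chromothripsis
    chromothripsis_samples: tuple = (8,)
    chromothripsis_chrom: str = "4"
    chromothripsis_center: int = 25_000_000
    chromothripsis_states: tuple = (2, 3)
    baseline_log2_sd: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.signature_matrix is None:
            self.signature_matrix = synthetic_signatures()
        self.signature_matrix = np.asarray(self.signature_matrix, dtype=float)
        if self.signature_matrix.shape[0] != 96:
            raise ValueError("signature_matrix must have 96 rows")
        if not np.allclose(self.signature_matrix.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("signature columns must sum to 1")
        if not 0 <= self.covariate_positive <= self.n_samples:
            raise ValueError("covariate_positive must be in [0, n_samples]")
        for name in ("kataegis_samples", "foldback_samples", "amp_samples",
                     "del_samples", "chromothripsis_samples"):
            idx = getattr(self, name)
            if any(i < 0 or i >= self.n_samples for i in idx):
                raise ValueError(f"{name} indices must lie in [0, n_samples)")
        chrom_len = dict(self.genome)
        for chrom, lo, hi in (self.amp_region, self.del_region):
            if chrom not in chrom_len or hi > chrom_len[chrom]:
                raise ValueError(f"region {chrom}:{lo}-{hi} outside genome")
        if self.chromothripsis_chrom not in chrom_len:
            raise ValueError("chromothripsis chromosome not in genome")
        if self.chromothripsis_center + 50_000 > chrom_len[self.chromothripsis_chrom]:
            raise ValueError("chromothripsis region outside chromosome")

    @property
    def n_signatures(self) -> int:
        return self.signature_matrix.shape[1]

    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]


@dataclass
class GroundTruth:
    sample_ids: list
    true_signatures: np.ndarray          # 96 x K
    true_exposures: np.ndarray           # K x S mutation counts
    kataegis_loci: list                  # (sample, chrom, start, end)
    foldback_loci: list                  # (sample, chrom, pos1, pos2)
    bfb_samples: set
    chromothripsis_regions: list         # (sample, chrom, start, end)
    cna_truth: list                      # (chrom, start, end, direction, samples)
    covariate_name: str
    covariate_positive_samples: set
    covariate_signature: int

    def complex_event_samples(self) -> set:
        out = set(self.bfb_samples)
        out |= {s for s, *_ in self.kataegis_loci}
        out |= {s for s, *_ in self.chromothripsis_regions}
        return out

    def to_json(self, path) -> None:
        payload = {
            "sample_ids": self.sample_ids,
            "true_exposures": self.true_exposures.tolist(),
            "kataegis_loci": self.kataegis_loci,
            "foldback_loci": self.foldback_loci,
            "bfb_samples": sorted(self.bfb_samples),
            "chromothripsis_regions": self.chromothripsis_regions,
            "cna_truth": [(c, s, e, d, sorted(ss))
                          for c, s, e, d, ss in self.cna_truth],
            "covariate_name": self.covariate_name,
            "covariate_positive_samples": sorted(self.covariate_positive_samples),
            "covariate_signature": self.covariate_signature,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# SNVs
# ---------------------------------------------------------------------------

def _channel_to_snv(rng, sample, chrom, pos, channel_label) -> SnvRecord:
    ref, alt, context = channel_parts(channel_label)
    if rng.random() < 0.5:   # report on the purine strand half the time
        ref, alt, context = ({"C": "G", "T": "A"}[ref],
                             {"A": "T", "C": "G", "G": "C", "T": "A"}[alt],
                             revcomp(context))
    return SnvRecord(sample, chrom, pos, ref, alt, context)


def _draw_signature_counts(cfg: SimulationConfig, rng, s_idx, positive):
    """Per-sample mutation counts attributed to each signature.

    The covariate-linked signature has a moderately concentrated Beta
    baseline weight (it is present in every sample, like the flat
    smoking/age-related processes); the remaining mass is split among the
    sporadic signatures by a sparse Dirichlet.  The first
    ``anchor_samples`` samples are each dominated by one sporadic
    signature (weight ``anchor_weight`` of the sporadic mass), emulating
    the signature-dominated tumors real cohorts contain and anchoring the
    mixture so the factorization is separable.  In covariate-positive
    samples the linked signature's mutation count (exposure) is multiplied
    by ``covariate_effect``.
    """
    K = cfg.n_signatures
    linked = cfg.covariate_signature
    others = [k for k in range(K) if k != linked]
    w_linked = rng.beta(*cfg.linked_signature_beta)
    d = rng.dirichlet(np.full(K - 1, cfg.dirichlet_alpha))
    if s_idx < cfg.anchor_samples:
        anchor = s_idx % (K - 1)
        d = (1 - cfg.anchor_weight) * d
        d[anchor] += cfg.anchor_weight
    weights = np.empty(K)
    weights[linked] = w_linked
    weights[others] = (1 - w_linked) * d
    counts = rng.multinomial(rng.poisson(cfg.mean_burden), weights)
    if s_idx in positive:
        counts = counts.astype(np.int64)
        counts[linked] = int(round(cfg.covariate_effect * counts[linked]))
    return counts


def _simulate_snvs(cfg: SimulationConfig, rng) -> tuple[list, np.ndarray, list, set]:
    samples = cfg.sample_ids()
    K = cfg.n_signatures
    chroms, lengths = zip(*cfg.genome)
    lengths = np.array(lengths, dtype=float)
    chrom_p = lengths / lengths.sum()

    positive = set(rng.choice(cfg.n_samples, size=cfg.covariate_positive,
                              replace=False).tolist())
    exposures = np.zeros((K, cfg.n_samples))
    snvs = []
    for s_idx, sample in enumerate(samples):
        sig_counts = _draw_signature_counts(cfg, rng, s_idx, positive)
        exposures[:, s_idx] = sig_counts
        channel_ids = np.concatenate([
            np.repeat(np.arange(96),
                      rng.multinomial(sig_counts[k], cfg.signature_matrix[:, k]))
            for k in range(K)]) if sig_counts.sum() else np.empty(0, dtype=int)
        n = len(channel_ids)
        chrom_ids = rng.choice(len(chroms), size=n, p=chrom_p)
        pos = rng.integers(2, lengths[chrom_ids] - 1)
        flips = rng.random(n) < 0.5
        for ch, ci, p, flip in zip(channel_ids, chrom_ids, pos, flips):
            ref, alt, context = channel_parts(CHANNEL_LABELS[ch])
            if flip:
                ref, alt, context = (COMPLEMENT[ref], COMPLEMENT[alt],
                                     revcomp(context))
            snvs.append(SnvRecord(sample, chroms[ci], int(p), ref, alt, context))

    kataegis_loci = []
    for s_idx in cfg.kataegis_samples:
        sample = samples[s_idx]
        for _ in range(cfg.kataegis_clusters_per_sample):
            ci = int(rng.integers(len(chroms)))
            start = int(rng.integers(1_000_000, lengths[ci] - 1_000_000))
            pos = start
            positions = [pos]
            for _ in range(cfg.kataegis_cluster_size - 1):
                pos += int(rng.integers(1, cfg.kataegis_max_gap + 1))
                positions.append(pos)
            for p in positions:
                label = _KATAEGIS_CHANNELS[rng.integers(len(_KATAEGIS_CHANNELS))]
                snvs.append(_channel_to_snv(rng, sample, chroms[ci], p, label))
            kataegis_loci.append((sample, chroms[ci], positions[0], positions[-1]))
    covariate_positive = {samples[i] for i in positive}
    return snvs, exposures, kataegis_loci, covariate_positive


# ---------------------------------------------------------------------------
# SVs
# ---------------------------------------------------------------------------

def _evidence(rng) -> dict:
    """Evidence fields that pass the default filter thresholds."""
    return dict(support_reads=int(rng.integers(5, 50)),
                control_reads=0,
                vaf=float(np.round(rng.uniform(0.15, 0.6), 4)),
                overhang=int(rng.integers(120, 200)),
                control_depth=int(rng.integers(30, 60)),
                in_repeat=False)


def _background_svs(cfg: SimulationConfig, rng, sample) -> list[SvRecord]:
    chroms, lengths = zip(*cfg.genome)
    lengths = np.array(lengths, dtype=float)
    chrom_p = lengths / lengths.sum()
    classes = list(_SV_CLASS_PROBS)
    probs = np.array([_SV_CLASS_PROBS[c] for c in classes])
    n = rng.poisson(cfg.sv_per_sample_mean)
    out = []
    for _ in range(n):
        sv_class = classes[rng.choice(len(classes), p=probs)]
        if sv_class == "translocation":
            c1, c2 = rng.choice(len(chroms), size=2, replace=False)
            s1 = "+" if rng.random() < 0.5 else "-"
            s2 = "+" if rng.random() < 0.5 else "-"
            out.append(SvRecord(sample, chroms[c1],
                                int(rng.integers(1_000_000, lengths[c1] - 1_000_000)),
                                s1, chroms[c2],
                                int(rng.integers(1_000_000, lengths[c2] - 1_000_000)),
                                s2, **_evidence(rng)).canonical())
        else:
            ci = rng.choice(len(chroms), p=chrom_p)
            # background sizes 50 kb - 2 Mb: above the fold-back span bound,
            # so background inversions never enter the fold-back candidate set
            size = int(rng.integers(50_000, 2_000_000))
            pos1 = int(rng.integers(1_000_000, lengths[ci] - size - 1_000_000))
            if sv_class == "inversion":
                strands = ("+", "+") if rng.random() < 0.5 else ("-", "-")
            else:
                strands = {"deletion": ("+", "-"),
                           "tandem_duplication": ("-", "+")}[sv_class]
            out.append(SvRecord(sample, chroms[ci], pos1, strands[0],
                                chroms[ci], pos1 + size, strands[1],
                                **_evidence(rng)))
    return out


def _chromothripsis_svs(cfg, rng, sample) -> tuple[list[SvRecord], list[int]]:
    """Plant 12 breakpoints in ~31 kb: two deletions, two duplications and a
    reciprocal inversion pair (so no unpaired inversion becomes a fold-back)."""
    base = cfg.chromothripsis_center
    c = cfg.chromothripsis_chrom
    ev = lambda: _evidence(rng)
    recs = [
        SvRecord(sample, c, base, "+", c, base + 3_000, "-", **ev()),
        SvRecord(sample, c, base + 7_000, "-", c, base + 10_000, "+", **ev()),
        SvRecord(sample, c, base + 14_000, "+", c, base + 17_000, "+", **ev()),
        SvRecord(sample, c, base + 14_200, "-", c, base + 17_200, "-", **ev()),
        SvRecord(sample, c, base + 21_000, "+", c, base + 24_000, "-", **ev()),
        SvRecord(sample, c, base + 28_000, "-", c, base + 31_000, "+", **ev()),
    ]
    breakpoints = sorted(p for r in recs for p in (r.pos1, r.pos2))
    return recs, breakpoints


def _simulate_svs_and_segments(cfg: SimulationConfig, rng):
    samples = cfg.sample_ids()
    chrom_len = dict(cfg.genome)
    svs: list[SvRecord] = []
    segments: list[CnSegment] = []
    foldback_loci = []
    bfb_samples = set()
    ct_regions = []

    amp_chrom, amp_lo, amp_hi = cfg.amp_region
    del_chrom, del_lo, del_hi = cfg.del_region
    alt_lo, alt_hi = cfg.alt_foldback_region

    for s_idx, sample in enumerate(samples):
        svs.extend(_background_svs(cfg, rng, sample))
        # carve events per chromosome: (start, end, copy_number)
        carves: dict[str, list] = {}
        if s_idx in cfg.amp_samples:
            carves.setdefault(amp_chrom, []).append((amp_lo, amp_hi,
                                                     cfg.foldback_cn))
        if s_idx in cfg.del_samples:
            carves.setdefault(del_chrom, []).append((del_lo, del_hi, cfg.del_cn))
        if s_idx in cfg.foldback_samples:
            rank = list(cfg.foldback_samples).index(s_idx)
            span = int(rng.integers(*cfg.foldback_span))
            if rank < cfg.foldback_at_amp:
                fb_chrom, edge = amp_chrom, amp_hi
            else:
                fb_chrom, edge = cfg.alt_foldback_chrom, alt_hi
                carves.setdefault(fb_chrom, []).append((alt_lo, alt_hi,
                                                        cfg.foldback_cn))
            pos1 = edge - int(rng.integers(500, 2_000))
            strands = ("+", "+") if rng.random() < 0.5 else ("-", "-")
            svs.append(SvRecord(sample, fb_chrom, pos1, strands[0], fb_chrom,
                                pos1 + span, strands[1], **_evidence(rng)))
            foldback_loci.append((sample, fb_chrom, pos1, pos1 + span))
            bfb_samples.add(sample)
        ct_breakpoints = None
        if s_idx in cfg.chromothripsis_samples:
            recs, ct_breakpoints = _chromothripsis_svs(cfg, rng, sample)
            svs.extend(recs)
            ct_regions.append((sample, cfg.chromothripsis_chrom,
                               ct_breakpoints[0], ct_breakpoints[-1]))
        for chrom, length in cfg.genome:
            if ct_breakpoints is not None and chrom == cfg.chromothripsis_chrom:
                segments.extend(_oscillating_segments(
                    cfg, rng, sample, chrom, length, ct_breakpoints))
            else:
                segments.extend(_carved_segments(
                    cfg, rng, sample, chrom, length, carves.get(chrom, [])))

    cna_truth = [
        (amp_chrom, amp_lo, amp_hi, "amp",
         {samples[i] for i in cfg.amp_samples}),
        (del_chrom, del_lo, del_hi, "del",
         {samples[i] for i in cfg.del_samples}),
    ]
    return svs, segments, foldback_loci, bfb_samples, ct_regions, cna_truth


def _baseline_log2(cfg, rng) -> float:
    return float(np.round(rng.normal(0.0, cfg.baseline_log2_sd), 4))


def _carved_segments(cfg, rng, sample, chrom, length, events) -> list[CnSegment]:
    segs = []
    cursor = 1
    for start, end, cn in sorted(events):
        if start > cursor:
            segs.append(CnSegment(sample, chrom, cursor, start - 1, 2.0,
                                  _baseline_log2(cfg, rng)))
        segs.append(CnSegment(sample, chrom, start, end, cn,
                              float(np.round(math.log2(max(cn, 0.01) / 2.0), 4))))
        cursor = end + 1
    if cursor <= length:
        segs.append(CnSegment(sample, chrom, cursor, length, 2.0,
                              _baseline_log2(cfg, rng)))
    return segs


def _oscillating_segments(cfg, rng, sample, chrom, length, breakpoints):
    lo_state, hi_state = cfg.chromothripsis_states
    segs = [CnSegment(sample, chrom, 1, breakpoints[0] - 1, float(lo_state),
                      _baseline_log2(cfg, rng))]
    bounds = breakpoints + [length + 1]
    for i in range(len(breakpoints)):
        state = hi_state if i % 2 == 0 else lo_state
        segs.append(CnSegment(sample, chrom, bounds[i], bounds[i + 1] - 1,
                              float(state),
                              float(np.round(math.log2(state / 2.0), 4))))
    return segs


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig | None = None):
    """Generate (snvs, svs, segments, clinical, ground_truth) from the config.

    Fully reproducible: equal configs (including seed) give identical output.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    snvs, exposures, kataegis_loci, cov_pos = _simulate_snvs(cfg, rng)
    (svs, segments, foldback_loci, bfb_samples, ct_regions,
     cna_truth) = _simulate_svs_and_segments(cfg, rng)
    samples = cfg.sample_ids()
    clinical = pd.DataFrame(
        {cfg.covariate_name: [1 if s in cov_pos else 0 for s in samples]},
        index=pd.Index(samples, name="sample_id"))
    truth = GroundTruth(
        sample_ids=samples, true_signatures=cfg.signature_matrix.copy(),
        true_exposures=exposures, kataegis_loci=kataegis_loci,
        foldback_loci=foldback_loci, bfb_samples=bfb_samples,
        chromothripsis_regions=ct_regions, cna_truth=cna_truth,
        covariate_name=cfg.covariate_name,
        covariate_positive_samples=cov_pos,
        covariate_signature=cfg.covariate_signature)
    from .io_formats import sort_segments
    return snvs, sorted(svs, key=lambda r: (r.sample_id, r.chrom1, r.pos1)), \
        sort_segments(segments), clinical, truth


def inject_caller_noise(svs, dup_rate: float = 0.0, drop_rate: float = 0.0,
                        jitter_bp: int = 0, seed: int = 0,
                        caller_names: tuple = ("callerA", "callerB")):
    """Derive two caller-specific call sets from a truth set.

    Each caller independently drops records at ``drop_rate``, emits an extra
    jittered duplicate at ``dup_rate``, and jitters breakend positions by at
    most ``jitter_bp``; provenance ``caller_ids`` is set per caller.
    """
    for rate in (dup_rate, drop_rate):
        if not 0.0 <= rate <= 1.0:
            raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for name in caller_names:
        calls = []
        for r in svs:
            if rng.random() < drop_rate:
                continue
            calls.append(_jitter(r, rng, jitter_bp, name))
            if rng.random() < dup_rate:
                calls.append(_jitter(r, rng, jitter_bp, name))
        out.append(calls)
    return tuple(out)


def _jitter(r: SvRecord, rng, jitter_bp: int, caller: str) -> SvRecord:
    d1 = int(rng.integers(-jitter_bp, jitter_bp + 1)) if jitter_bp else 0
    d2 = int(rng.integers(-jitter_bp, jitter_bp + 1)) if jitter_bp else 0
    return replace(r, pos1=max(1, r.pos1 + d1), pos2=max(1, r.pos2 + d2),
                   caller_ids=frozenset([caller])).canonical()


def simulate_signature_catalog(config: SimulationConfig | None = None):
    """Fast path for signature studies: draw the 96 x S mutation catalog,
    true exposures and clinical table directly, without placing mutations on
    the genome.  Same exposure law as :func:`simulate_cohort`.

    Returns (counts, exposures, clinical) with counts 96 x S and exposures
    K x S in mutation counts.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    K, S = cfg.n_signatures, cfg.n_samples
    positive = set(rng.choice(S, size=cfg.covariate_positive,
                              replace=False).tolist())
    counts = np.zeros((96, S))
    exposures = np.zeros((K, S))
    for s_idx in range(S):
        sig_counts = _draw_signature_counts(cfg, rng, s_idx, positive)
        exposures[:, s_idx] = sig_counts
        for k in range(K):
            counts[:, s_idx] += rng.multinomial(sig_counts[k],
                                                cfg.signature_matrix[:, k])
    samples = cfg.sample_ids()
    clinical = pd.DataFrame(
        {cfg.covariate_name: [1 if i in positive else 0 for i in range(S)]},
        index=pd.Index(samples, name="sample_id"))
    return counts, exposures, clinical


# ---------------------------------------------------------------------------
# auxiliary synthetic tables
# ---------------------------------------------------------------------------

def synthetic_genes(config: SimulationConfig | None = None,
                    n_background: int = 30, seed: int = 777) -> list[GeneInterval]:
    """Synthetic gene intervals: one gene inside the recurrent amplicon, one
    inside the recurrent deletion, and evenly spread background genes."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    amp_chrom, amp_lo, amp_hi = cfg.amp_region
    del_chrom, del_lo, del_hi = cfg.del_region
    mid_a, mid_d = (amp_lo + amp_hi) // 2, (del_lo + del_hi) // 2
    genes = [GeneInterval(cfg.amp_gene, amp_chrom, mid_a - 25_000, mid_a + 25_000),
             GeneInterval(cfg.del_gene, del_chrom, mid_d - 25_000, mid_d + 25_000)]
    chroms = [c for c, _ in cfg.genome]
    lengths = dict(cfg.genome)
    for i in range(n_background):
        chrom = chroms[i % len(chroms)]
        start = int(rng.integers(1_000_000, lengths[chrom] - 2_000_000))
        genes.append(GeneInterval(f"G{i + 1:03d}", chrom, start,
                                  start + int(rng.integers(50_000, 500_000))))
    return genes


def synthetic_reference_catalog(true_signatures: np.ndarray,
                                n_decoys: int = 10, seed: int = 999
                                ) -> ReferenceSignatureCatalog:
    """A synthetic stand-in for a 96-channel reference signature catalog:
    the truth signatures (named ``Signature_1..K``) followed by ``n_decoys``
    sparse Dirichlet decoy columns."""
    rng = np.random.default_rng(seed)
    truth = np.asarray(true_signatures, dtype=float)
    decoys = rng.dirichlet(np.full(96, 0.05), size=n_decoys).T
    mat = np.hstack([truth, decoys])
    mat = mat / mat.sum(axis=0)
    names = tuple(f"Signature_{i + 1}" for i in range(mat.shape[1]))
    return ReferenceSignatureCatalog(CHANNEL_LABELS, mat, names)


def synthetic_drug_table(genes, seed: int = 555, druggable_fraction: float = 0.5
                         ) -> pd.DataFrame:
    """A synthetic local gene-drug interaction table over the given genes."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in genes:
        name = g.gene if hasattr(g, "gene") else str(g)
        if rng.random() > druggable_fraction:
            continue
        for d in range(int(rng.integers(1, 4))):
            rows.append((name.upper(), f"DRUG_{name}_{d + 1}", "inhibitor"))
    if not rows:  # keep the table non-empty for downstream contracts
        name = (genes[0].gene if hasattr(genes[0], "gene") else str(genes[0]))
        rows.append((name.upper(), f"DRUG_{name}_1", "inhibitor"))
    return pd.DataFrame(rows, columns=["gene", "drug", "interaction_type"])
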