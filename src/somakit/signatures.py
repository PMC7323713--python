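"""Mutational-signature analysis on the 96 trinucleotide channels.

Per-sample catalogs are modeled as nonnegative mixtures, ``V ≈ W H``, where
the columns of W are signatures (probability vectors over the 96 channels)
and H holds per-sample exposures in mutation counts.  Extraction minimizes
the generalized Kullback–Leibler divergence by multiplicative updates with
automatic-relevance-determination (ARD) shrinkage — exponential priors whose
per-component scales are re-estimated every sweep — so redundant components
collapse and the effective number of signatures is selected automatically,
up to ``k_max``.  Extracted signatures are matched to a reference catalog by
cosine similarity; an extracted signature with best cosine below the match
threshold (0.7 by default) is reported as unmatched.  Exposure–covariate
association uses the Wilcoxon rank-sum test (exact enumeration for small
groups, normal approximation with tie and continuity corrections otherwise)
or Welch's t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .channels import CHANNEL_LABELS, N_CHANNELS, channel_index
from .io_formats import ReferenceSignatureCatalog

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class MutationCatalog:
    """96 x S matrix of mutation counts with fixed channel order."""

    counts: np.ndarray
    samples: tuple
    channels: tuple = CHANNEL_LABELS

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.samples = tuple(self.samples)
        if self.counts.shape != (N_CHANNELS, len(self.samples)):
            raise ValueError(f"counts must be 96 x {len(self.samples)}, got "
                             f"{self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.channels),
                            columns=list(self.samples))

    def column_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass
class SignatureModel:
    W: np.ndarray              # 96 x K, columns sum to 1
    H: np.ndarray              # K x S exposures (mutation counts)
    k: int
    objective_value: float
    seed_set: tuple
    samples: tuple = ()


@dataclass
class SignatureMatch:
    extracted_index: int
    reference_name: str
    cosine: float
    matched: bool
    scores: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# catalog construction
# ---------------------------------------------------------------------------

def build_catalog(snvs, samples) -> MutationCatalog:
    """Tabulate SNVs into the 96-channel catalog (pyrimidine-normalized).

    Column order follows ``samples``; an SNV whose sample is not in the
    cohort list is an error, as is a context whose middle base disagrees
    with the reference allele.  Order of input records is irrelevant.
    """
    samples = tuple(samples)
    col = {s: i for i, s in enumerate(samples)}
    counts = np.zeros((N_CHANNELS, len(samples)))
    for r in snvs:
        if r.sample_id not in col:
            raise ValueError(f"sample {r.sample_id!r} not in cohort list")
        counts[channel_index(r.ref, r.alt, r.context), col[r.sample_id]] += 1
    return MutationCatalog(counts, samples)


# ---------------------------------------------------------------------------
# KL-NMF with ARD shrinkage
# ---------------------------------------------------------------------------

def kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH)."""
    WH = np.maximum(WH, _EPS)
    mask = V > 0
    term = np.zeros_like(V)
    term[mask] = V[mask] * np.log(V[mask] / WH[mask])
    return float(term.sum() - V.sum() + WH.sum())


def _kl_nmf(V, k, rng, n_iter=2000, tol=1e-10, W=None, H=None,
            callback=None):
    """Plain multiplicative-update KL-NMF; objective is non-increasing."""
    F, N = V.shape
    scale = np.sqrt(V.mean() / k)
    if W is None:
        W = rng.random((F, k)) * scale + _EPS
    if H is None:
        H = rng.random((k, N)) * scale + _EPS
    prev = np.inf
    for it in range(n_iter):
        WH = W @ H + _EPS
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        WH = W @ H + _EPS
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        obj = kl_divergence(V, W @ H)
        if callback is not None:
            callback(it, obj)
        if prev - obj < tol * max(1.0, abs(prev)) and it > 10:
            break
        prev = obj
    return W, H, kl_divergence(V, W @ H)


def _ard_objective(V, W, H, lam, b, c):
    pen = float(np.sum((W.sum(axis=0) + H.sum(axis=1) + b) / lam)
                + c * np.sum(np.log(lam)))
    return kl_divergence(V, W @ H) + pen


def _ard_kl_nmf(V, k, rng, a=10.0, n_iter=3000, tol=1e-10, callback=None):
    """L1-ARD KL-NMF: exponential priors on W and H columns with per-component
    relevance scales re-estimated in closed form each sweep."""
    F, N = V.shape
    b = np.sqrt((a - 1) * (a - 2) * V.mean() / k)
    c = F + N + a + 1
    scale = np.sqrt(V.mean() / k)
    W = rng.random((F, k)) * scale + _EPS
    H = rng.random((k, N)) * scale + _EPS
    lam = (W.sum(axis=0) + H.sum(axis=1) + b) / c
    prev = np.inf
    for it in range(n_iter):
        WH = W @ H + _EPS
        W *= ((V / WH) @ H.T) / (H.sum(axis=1)[None, :] + 1.0 / lam[None, :])
        WH = W @ H + _EPS
        H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + 1.0 / lam[:, None])
        lam = (W.sum(axis=0) + H.sum(axis=1) + b) / c
        obj = _ard_objective(V, W, H, lam, b, c)
        if callback is not None:
            callback(it, obj)
        if prev - obj < tol * max(1.0, abs(prev)) and it > 20:
            break
        prev = obj
    return W, H, obj


def extract_signatures(catalog: MutationCatalog, k_max: int,
                       n_restarts: int = 5, seed: int = 0,
                       prune_threshold: float = 0.01,
                       n_iter: int = 10000) -> SignatureModel:
    """Extract up to ``k_max`` signatures from a catalog.

    Procedure: (1) ARD-shrunk KL-NMF at rank ``k_max`` from ``n_restarts``
    random initializations, keeping the restart with the lowest penalized
    objective; (2) components whose share of total exposure falls below
    ``prune_threshold`` are removed; (3) a plain KL-NMF polish re-fits the
    surviving components; (4) W columns are renormalized to sum to 1, with
    the mass moved into H so the reconstruction W·H is unchanged.
    Deterministic given ``seed``.
    """
    V = np.asarray(catalog.counts, dtype=float)
    if V.sum() <= 0:
        raise ValueError("all-zero catalog")
    S = V.shape[1]
    if S < 2:
        raise ValueError("need at least 2 samples")
    if k_max > S:
        logger.warning("k_max %d > %d samples; clipping", k_max, S)
        k_max = S
    child_seeds = np.random.SeedSequence(seed).spawn(n_restarts)
    best = None
    for ss in child_seeds:
        rng = np.random.default_rng(ss)
        W, H, obj = _ard_kl_nmf(V, k_max, rng, n_iter=n_iter)
        if best is None or obj < best[2]:
            best = (W, H, obj, rng)
    W, H, _, rng = best
    exposure = H.sum(axis=1)
    share = exposure / max(exposure.sum(), _EPS)
    keep = share >= prune_threshold
    if not keep.any():
        keep[np.argmax(share)] = True
    W, H = W[:, keep].copy(), H[keep, :].copy()
    W, H, obj = _kl_nmf(V, W.shape[1], rng, n_iter=n_iter, W=W, H=H)
    colsum = np.maximum(W.sum(axis=0), _EPS)
    W = W / colsum
    H = H * colsum[:, None]
    return SignatureModel(W=W, H=H, k=W.shape[1], objective_value=obj,
                          seed_set=tuple(int(s.entropy) if s.entropy is not None
                                         else 0 for s in child_seeds),
                          samples=catalog.samples)


# ---------------------------------------------------------------------------
# reference matching
# ---------------------------------------------------------------------------

def cosine_similarity(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity of an all-zero vector is undefined")
    return float(a @ b / (na * nb))


def match_signatures(model: SignatureModel, ref: ReferenceSignatureCatalog,
                     threshold: float = 0.7) -> list[SignatureMatch]:
    """Best-cosine reference signature for each extracted signature."""
    mat = ref.matrix
    if tuple(ref.channel_labels) != CHANNEL_LABELS:
        order = [list(ref.channel_labels).index(c) for c in CHANNEL_LABELS]
        mat = mat[order, :]
    matches = []
    for i in range(model.k):
        scores = {name: cosine_similarity(model.W[:, i], mat[:, j])
                  for j, name in enumerate(ref.names)}
        best_name = max(scores, key=lambda nm: (scores[nm], nm))
        matches.append(SignatureMatch(i, best_name, scores[best_name],
                                      scores[best_name] >= threshold, scores))
    return matches


# ---------------------------------------------------------------------------
# exposure-covariate association
# ---------------------------------------------------------------------------

def exact_rank_sum_p(x, y) -> float:
    """Two-sided exact Wilcoxon rank-sum p-value by full enumeration.

    The null distribution of the rank sum of the first group is computed by
    dynamic programming over all C(n, m) arrangements of the pooled
    (mid)ranks, so ties are handled exactly;
    p = min(1, 2 * min(P(W <= w), P(W >= w))).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks2 = np.rint(2 * stats.rankdata(pooled)).astype(int)  # doubled midranks
    m, n = len(x), len(pooled)
    w_obs = int(ranks2[:m].sum())
    max_sum = int(ranks2.sum())
    # dp[j, s] = number of j-subsets of the processed values with doubled-rank sum s
    dp = np.zeros((m + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks2:
        dp[1:, r:] += dp[:-1, :max_sum + 1 - r]
    dist = dp[m]
    total = dist.sum()
    cdf = dist[:w_obs + 1].sum() / total
    sf = dist[w_obs:].sum() / total
    return float(min(1.0, 2.0 * min(cdf, sf)))


def rank_sum_test(x, y, exact_max: int = 10) -> tuple[float, float]:
    """Wilcoxon rank-sum statistic (rank sum of x) and two-sided p-value.

    Exact enumeration when both groups have at most ``exact_max`` members;
    otherwise the normal approximation with tie and continuity corrections
    (via the equivalent Mann-Whitney U test).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = float(stats.rankdata(np.concatenate([x, y]))[:len(x)].sum())
    if len(x) <= exact_max and len(y) <= exact_max:
        return w, exact_rank_sum_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return w, float(res.pvalue)


def exposure_association(model: SignatureModel, clinical: pd.DataFrame,
                         covariate: str, test: str = "wilcoxon",
                         signature_names=None) -> pd.DataFrame:
    """Association of per-signature exposures (and total burden) with a
    binary covariate.

    Returns one row per signature plus a ``total_burden`` row, with the test
    statistic, raw two-sided p-value and Benjamini–Hochberg q-value (q over
    the signature rows only).  A covariate group with fewer than two samples
    yields absent p-values and a warning.
    """
    if test not in ("wilcoxon", "t_test"):
        raise ValueError(f"unknown test {test!r}")
    samples = list(model.samples)
    cov = clinical.loc[samples, covariate]
    levels = sorted(pd.unique(cov.dropna()))
    if len(levels) != 2:
        raise ValueError(f"covariate {covariate!r} must be binary, "
                         f"levels={levels}")
    pos = np.asarray(cov == levels[1])
    neg = np.asarray(cov == levels[0])
    names = list(signature_names) if signature_names is not None else [
        f"W{i + 1}" for i in range(model.k)]
    rows = []
    degenerate = pos.sum() < 2 or neg.sum() < 2
    if degenerate:
        logger.warning("exposure_association: degenerate covariate groups "
                       "(%d vs %d); p-values absent", int(pos.sum()),
                       int(neg.sum()))
    series = [model.H[i] for i in range(model.k)]
    series.append(model.H.sum(axis=0))
    for name, values in zip(names + ["total_burden"], series):
        if degenerate:
            rows.append((name, np.nan, np.nan))
            continue
        xs, ys = values[pos], values[neg]
        if test == "wilcoxon":
            stat, p = rank_sum_test(xs, ys)
        else:
            res = stats.ttest_ind(xs, ys, equal_var=False)
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append((name, stat, p))
    df = pd.DataFrame(rows, columns=["signature", "statistic", "p_value"])
    df["q_value"] = np.nan
    sig_rows = df.index[:model.k]
    if not degenerate and model.k > 0:
        from statsmodels.stats.multitest import multipletests
        df.loc[sig_rows, "q_value"] = multipletests(
            df.loc[sig_rows, "p_value"], method="fdr_bh")[1]
    return df
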