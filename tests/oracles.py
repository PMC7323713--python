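"""Independent brute-force reference implementations used as oracles.

Each function here recomputes a detector's answer by naive enumeration,
sharing no code with the package implementations it checks.
"""

import itertools

import numpy as np


def kataegis_runs_bruteforce(positions, min_n=6, max_mean_imd=1000):
    """All maximal qualifying runs by quadratic enumeration, merged
    left-to-right when the union still satisfies the mean-IMD rule."""
    pos = sorted(positions)
    n = len(pos)
    qualifying = [(i, j) for i in range(n) for j in range(i + min_n - 1, n)
                  if (pos[j] - pos[i]) / (j - i) <= max_mean_imd]
    maximal = [(i, j) for (i, j) in qualifying
               if not any((a <= i and j <= b and (a, b) != (i, j))
                          for (a, b) in qualifying)]
    maximal.sort()
    merged = []
    for i, j in maximal:
        if merged and i <= merged[-1][1]:
            ui, uj = merged[-1][0], max(merged[-1][1], j)
            if (pos[uj] - pos[ui]) / (uj - ui) <= max_mean_imd:
                merged[-1] = (ui, uj)
                continue
        merged.append((i, j))
    return [(pos[i], pos[j], j - i + 1) for i, j in merged]


def breakpoint_clusters_bruteforce(positions, window=50_000, min_bp=10):
    """Merged extents of all breakpoint windows holding > min_bp breakends,
    by all-pairs enumeration."""
    pos = sorted(positions)
    n = len(pos)
    windows = [(pos[i], pos[j]) for i in range(n) for j in range(i, n)
               if pos[j] - pos[i] <= window
               and sum(1 for p in pos if pos[i] <= p <= pos[j]) > min_bp
               # maximal within the window bound
               and (j + 1 >= n or pos[j + 1] - pos[i] > window)]
    merged = []
    for lo, hi in sorted(windows):
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [tuple(m) for m in merged]


def max_bipartite_matching_size(pairs, n_a, n_b):
    """Maximum-cardinality bipartite matching via networkx (independent of
    the package's greedy matcher)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from((0, i) for i in range(n_a))
    g.add_nodes_from((1, j) for j in range(n_b))
    g.add_edges_from(((0, i), (1, j)) for i, j in pairs)
    matching = nx.algorithms.matching.max_weight_matching(g, maxcardinality=True)
    return len(matching)


def bin_means_bruteforce(segments, genome, bin_size):
    """Per-base accumulation of log2 values into fixed bins (tiny genomes)."""
    samples = sorted({s.sample_id for s in segments})
    bins = []
    for chrom, length in genome:
        start = 1
        while start <= length:
            bins.append((chrom, start, min(start + bin_size - 1, length)))
            start += bin_size
    values = np.full((len(samples), len(bins)), np.nan)
    for si, sample in enumerate(samples):
        base_val = {}
        for seg in segments:
            if seg.sample_id != sample:
                continue
            for p in range(seg.start, seg.end + 1):
                base_val[(seg.chrom, p)] = seg.log2_ratio
        for bi, (chrom, lo, hi) in enumerate(bins):
            vals = [base_val[(chrom, p)] for p in range(lo, hi + 1)
                    if (chrom, p) in base_val]
            if vals:
                values[si, bi] = np.mean(vals)
    return values, bins, samples


def rank_sum_p_enumeration(x, y):
    """Two-sided exact rank-sum p by explicit enumeration of all
    combinations (midranks for ties)."""
    from scipy.stats import rankdata

    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    ranks = rankdata(pooled)
    m = len(x)
    w_obs = ranks[:m].sum()
    sums = [ranks[list(c)].sum()
            for c in itertools.combinations(range(len(pooled)), m)]
    sums = np.asarray(sums)
    tol = 1e-9
    cdf = np.mean(sums <= w_obs + tol)
    sf = np.mean(sums >= w_obs - tol)
    return min(1.0, 2.0 * min(cdf, sf))


def recurrence_p_bruteforce(values, threshold, direction):
    """Empirical per-bin p-values over ALL cyclic-offset combinations, by
    direct looping (tiny instances only)."""
    S, B = values.shape

    def g(v):
        alt = (v >= threshold) if direction == "amp" else (v <= threshold)
        out = np.zeros(B)
        for b in range(B):
            n = alt[:, b].sum()
            if n:
                out[b] = (n / S) * np.abs(v[alt[:, b], b]).mean()
        return out

    obs = g(values)
    exceed = np.zeros(B)
    total = 0
    for offsets in itertools.product(range(B), repeat=S):
        rolled = np.stack([np.roll(values[s], offsets[s]) for s in range(S)])
        exceed += g(rolled) >= obs
        total += 1
    return exceed / total
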