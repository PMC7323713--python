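import numpy as np
import pytest

import oracles
from somakit.complex_events import (ChromothripsisCall, detect_chromothripsis,
                                    detect_foldbacks, detect_kataegis,
                                    infer_bfb, oscillation_fraction, rainfall)
from somakit.records import CnSegment, GeneInterval, SnvRecord, SvRecord
from somakit.sv import classify_all


def inversion(sample="S1", chrom="1", pos1=100_000, span=5_000,
              strands=("+", "+")):
    return SvRecord(sample, chrom, pos1, strands[0], chrom, pos1 + span,
                    strands[1], support_reads=9, vaf=0.3, overhang=150,
                    control_depth=40, sv_class="inversion")


def step_segments(sample="S1", chrom="1", boundary=100_000, cn=(8.0, 4.0),
                  length=1_000_000):
    return [CnSegment(sample, chrom, 1, boundary, cn[0], np.log2(cn[0] / 2)),
            CnSegment(sample, chrom, boundary + 1, length, cn[1],
                      np.log2(cn[1] / 2))]


def snv(sample, chrom, pos):
    return SnvRecord(sample, chrom, pos, "C", "T", "TCA")


# ---------------------------------------------------------------------------
# fold-backs
# ---------------------------------------------------------------------------

class TestFoldbacks:
    def test_planted_foldback_detected(self):
        segs = step_segments()
        (fb,) = detect_foldbacks([inversion()], segs)
        assert (fb.pos_low, fb.pos_high, fb.strand_pair) == (100_000, 105_000,
                                                             ("+", "+"))
        assert {fb.cn_left, fb.cn_right} == {8.0, 4.0}

    def test_reciprocal_partner_excludes_single_inversion_rule(self):
        segs = step_segments()
        pair = [inversion(), inversion(pos1=100_200, strands=("-", "-"))]
        assert detect_foldbacks(pair, segs) == []

    def test_span_bound_is_strict_at_20kb(self):
        segs = step_segments()
        assert detect_foldbacks([inversion(span=25_000)], segs) == []
        assert detect_foldbacks([inversion(span=20_000)], segs) == []
        assert len(detect_foldbacks([inversion(span=19_999)], segs)) == 1

    def test_no_copy_number_step_no_call(self):
        flat = [CnSegment("S1", "1", 1, 10**6, 2.0, 0.0)]
        assert detect_foldbacks([inversion()], flat) == []

    def test_missing_segments_warns_and_fails_cn_rule(self, caplog):
        with caplog.at_level("WARNING"):
            assert detect_foldbacks([inversion()], []) == []
        assert "no CN segments" in caplog.text

    def test_anti_monotone_in_span_and_step(self, rng):
        svs = [inversion(pos1=int(p), span=int(s),
                         strands=("+", "+") if rng.random() < 0.5 else ("-", "-"))
               for p, s in zip(rng.integers(10_000, 900_000, 30),
                               rng.integers(1_000, 30_000, 30))]
        segs = step_segments(cn=(5.0, 3.0))
        base = {(f.pos_low, f.pos_high)
                for f in detect_foldbacks(svs, segs, max_span=20_000,
                                          min_cn_step=1.0)}
        tighter_span = {(f.pos_low, f.pos_high)
                        for f in detect_foldbacks(svs, segs, max_span=10_000,
                                                  min_cn_step=1.0)}
        tighter_step = {(f.pos_low, f.pos_high)
                        for f in detect_foldbacks(svs, segs, max_span=20_000,
                                                  min_cn_step=3.0)}
        assert tighter_span <= base and tighter_step <= base


class TestBfb:
    def test_amplified_gene_flanked_by_foldback_is_reported(self):
        segs = [CnSegment("S1", "11", 1, 69_000_000, 2.0, 0.0),
                CnSegment("S1", "11", 69_000_001, 69_500_000, 8.0, 2.0),
                CnSegment("S1", "11", 69_500_001, 135_000_000, 2.0, 0.0)]
        fb = detect_foldbacks([inversion(chrom="11", pos1=69_499_000,
                                         span=6_000)], segs)
        genes = [GeneInterval("CCND1", "11", 69_455_873, 69_469_242)]
        (call,) = infer_bfb(fb, segs, genes)
        assert call.amplified_genes == ("CCND1",)
        assert call.chrom == "11"

    def test_sample_without_foldbacks_gets_no_call(self):
        assert infer_bfb([], [], []) == []

    def test_bfb_membership_matches_planted_truth(self, cohort):
        fbs = detect_foldbacks(cohort["kept"], cohort["segments"])
        calls = infer_bfb(fbs, cohort["segments"], cohort["genes"])
        assert {c.sample_id for c in calls} == cohort["truth"].bfb_samples
        # structural consistency: each call's chromosome carries a fold-back
        for c in calls:
            assert c.foldbacks and all(f.chrom == c.chrom for f in c.foldbacks)


# ---------------------------------------------------------------------------
# kataegis
# ---------------------------------------------------------------------------

class TestKataegis:
    def test_six_mutations_at_200bp_gaps_form_one_locus(self):
        snvs = [snv("S1", "1", 10_000 + 200 * i) for i in range(6)]
        (locus,) = detect_kataegis(snvs)
        assert (locus.n_mutations, locus.mean_imd) == (6, 200.0)

    def test_five_mutations_never_qualify(self):
        snvs = [snv("S1", "1", 10_000 + 10 * i) for i in range(5)]
        assert detect_kataegis(snvs) == []

    def test_mean_rule_is_on_the_average_not_each_gap(self):
        # gaps (10, 10, 10, 10, 4000): mean 808 <= 1000 qualifies
        pos = np.cumsum([10_000, 10, 10, 10, 10, 4000])
        snvs = [snv("S1", "1", int(p)) for p in pos]
        (locus,) = detect_kataegis(snvs)
        assert locus.n_mutations == 6

    def test_outputs_never_violate_their_own_definition(self, cohort):
        for locus in detect_kataegis(cohort["snvs"]):
            assert locus.n_mutations >= 6
            assert locus.mean_imd <= 1000

    def test_planted_cluster_recall_is_complete(self, cohort):
        loci = detect_kataegis(cohort["snvs"])
        for sample, chrom, start, end in cohort["truth"].kataegis_loci:
            assert any(l.sample_id == sample and l.chrom == chrom
                       and l.start <= start and end <= l.end for l in loci), \
                (sample, chrom, start, end)

    def test_nearest_sv_distance_annotation(self):
        snvs = [snv("S1", "1", 10_000 + 100 * i) for i in range(6)]
        sv = classify_all([SvRecord("S1", "1", 12_000, "+", "1", 50_000, "-",
                                    support_reads=5)])
        (locus,) = detect_kataegis(snvs, svs=sv)
        assert locus.nearest_sv_distance == 12_000 - locus.end

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_bruteforce_scan_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        # dense-ish background plus a planted cluster
        pos = sorted(set(rng.integers(1, 300_000, size=120).tolist()
                         + (60_000 + np.cumsum(
                             rng.integers(1, 800, size=8))).tolist()))
        snvs = [snv("S1", "1", int(p)) for p in pos]
        got = [(l.start, l.end, l.n_mutations) for l in detect_kataegis(snvs)]
        expected = oracles.kataegis_runs_bruteforce(pos)
        assert got == expected


# ---------------------------------------------------------------------------
# chromothripsis
# ---------------------------------------------------------------------------

def _cluster_svs(sample, chrom, positions):
    """Pair up consecutive positions into intrachromosomal SVs."""
    recs = []
    for a, b in zip(positions[::2], positions[1::2]):
        recs.append(SvRecord(sample, chrom, int(a), "+", chrom, int(b), "-",
                             support_reads=9, vaf=0.3, overhang=150,
                             control_depth=40, sv_class="deletion"))
    return recs


def _oscillating(sample, chrom, breakpoints, states=(2, 3), length=10**6):
    segs = [CnSegment(sample, chrom, 1, breakpoints[0] - 1, states[0], 0.0)]
    bounds = list(breakpoints) + [length]
    for i in range(len(breakpoints)):
        cn = states[(i + 1) % 2]
        segs.append(CnSegment(sample, chrom, bounds[i], bounds[i + 1] - 1,
                              float(cn), float(np.log2(cn / 2))))
    return segs


class TestChromothripsis:
    def test_planted_region_passes(self):
        bps = sorted(10_000 + 3_300 * i for i in range(12))
        svs = _cluster_svs("S1", "1", bps)
        segs = _oscillating("S1", "1", bps)
        calls = detect_chromothripsis(svs, segs)
        assert [c.passes for c in calls] == [True]
        assert calls[0].n_breakpoints == 12
        assert calls[0].oscillation_fraction == 1.0

    def test_monotone_staircase_fails_oscillation(self):
        bps = sorted(10_000 + 3_300 * i for i in range(12))
        svs = _cluster_svs("S1", "1", bps)
        segs = []
        bounds = [1] + bps + [10**6]
        for i in range(len(bounds) - 1):
            cn = 2.0 + i
            segs.append(CnSegment("S1", "1", bounds[i], bounds[i + 1] - 1, cn,
                                  float(np.log2(cn / 2))))
        (call,) = detect_chromothripsis(svs, segs)
        assert not call.passes
        assert call.oscillation_fraction < 0.5

    def test_exactly_ten_breakpoints_is_no_candidate(self):
        bps = sorted(10_000 + 3_000 * i for i in range(10))
        svs = _cluster_svs("S1", "1", bps)
        segs = _oscillating("S1", "1", bps)
        assert detect_chromothripsis(svs, segs) == []
        # one more breakend crosses the strict > 10 rule
        svs11 = svs + [SvRecord("S1", "1", 41_000, "+", "2", 500_000, "+",
                                support_reads=9, sv_class="translocation")]
        calls = detect_chromothripsis(svs11, segs)
        assert len(calls) == 1 and calls[0].n_breakpoints == 11

    @pytest.mark.parametrize("seed", range(6))
    def test_cluster_extents_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        bps = sorted(rng.integers(1, 400_000, size=40).tolist())
        if len(bps) % 2:
            bps = bps[:-1]
        svs = _cluster_svs("S1", "7", bps)
        positions = sorted(p for r in svs for p in (r.pos1, r.pos2))
        calls = detect_chromothripsis(svs, [], window=50_000, min_breakpoints=5)
        got = [(c.window_start, c.window_end) for c in calls]
        assert got == oracles.breakpoint_clusters_bruteforce(
            positions, window=50_000, min_bp=5)

    def test_planted_cohort_region_is_only_passing_call(self, cohort):
        calls = detect_chromothripsis(cohort["kept"], cohort["segments"])
        passing = [c for c in calls if c.passes]
        truth = cohort["truth"].chromothripsis_regions
        assert len(passing) == len(truth) == 1
        (call,), (exp,) = passing, truth
        assert (call.sample_id, call.chrom) == (exp[0], exp[1])
        assert call.window_start <= exp[2] and exp[3] <= call.window_end


def test_oscillation_fraction_two_state_alternation():
    segs = [CnSegment("S1", "1", 1 + i * 10, (i + 1) * 10, 2.0 + (i % 2), 0.0)
            for i in range(6)]
    assert oscillation_fraction(segs) == 1.0
    assert oscillation_fraction(segs[:1]) == 0.0


# ---------------------------------------------------------------------------
# rainfall
# ---------------------------------------------------------------------------

class TestRainfall:
    def test_distances_are_successive_differences(self):
        snvs = [snv("S1", "1", p) for p in (100, 350, 10_350)]
        df = rainfall(snvs)
        assert np.isnan(df["distance"].iloc[0])
        assert df["distance"].iloc[1:].tolist() == [250.0, 10_000.0]

    def test_single_mutation_has_absent_distance(self):
        df = rainfall([snv("S1", "1", 5)])
        assert len(df) == 1 and np.isnan(df["distance"].iloc[0])

    def test_distances_never_cross_chromosomes(self):
        snvs = [snv("S1", "1", 100), snv("S1", "1", 300), snv("S1", "2", 150)]
        df = rainfall(snvs)
        by_chrom = df.groupby("chrom")["distance"].apply(
            lambda s: np.isnan(s.iloc[0]))
        assert by_chrom.all()
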