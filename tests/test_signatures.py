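import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oracles
from somakit.channels import CHANNEL_LABELS, channel_of
from somakit.io_formats import ReferenceSignatureCatalog
from somakit.records import SnvRecord
from somakit.signatures import (MutationCatalog, SignatureModel,
                                _ard_kl_nmf, _kl_nmf, build_catalog,
                                cosine_similarity, exact_rank_sum_p,
                                exposure_association, extract_signatures,
                                kl_divergence, match_signatures,
                                rank_sum_test)
from somakit.synthetic import synthetic_signatures


# ---------------------------------------------------------------------------
# channel alphabet
# ---------------------------------------------------------------------------

def test_channel_alphabet_order_and_uniqueness():
    assert len(CHANNEL_LABELS) == 96
    assert len(set(CHANNEL_LABELS)) == 96
    assert CHANNEL_LABELS[0] == "A[C>A]A"
    assert CHANNEL_LABELS[16] == "A[C>G]A"
    assert CHANNEL_LABELS[-1] == "T[T>G]T"


def test_purine_reference_is_strand_normalized():
    # G>A in context TGC reads C>T in context GCA on the pyrimidine strand
    assert channel_of("G", "A", "TGC") == "G[C>T]A"
    assert channel_of("C", "T", "GCA") == "G[C>T]A"


# ---------------------------------------------------------------------------
# catalog building
# ---------------------------------------------------------------------------

class TestBuildCatalog:
    def test_column_sums_conserve_record_counts(self, cohort):
        catalog = build_catalog(cohort["snvs"], cohort["truth"].sample_ids)
        per_sample = {}
        for r in cohort["snvs"]:
            per_sample[r.sample_id] = per_sample.get(r.sample_id, 0) + 1
        for s, total in zip(catalog.samples, catalog.column_sums()):
            assert total == per_sample[s]

    def test_single_channel_sample_is_one_hot(self):
        snvs = [SnvRecord("S1", "1", i + 1, "C", "T", "ACA") for i in range(7)]
        catalog = build_catalog(snvs, ["S1", "S2"])
        col = catalog.counts[:, 0]
        assert col.sum() == 7
        assert col[CHANNEL_LABELS.index("A[C>T]A")] == 7

    def test_order_invariance(self):
        snvs = [SnvRecord("S1", "1", 10, "C", "T", "ACA"),
                SnvRecord("S1", "2", 5, "G", "A", "TGC"),
                SnvRecord("S2", "1", 7, "T", "G", "TTT")]
        a = build_catalog(snvs, ["S1", "S2"]).counts
        b = build_catalog(snvs[::-1], ["S1", "S2"]).counts
        np.testing.assert_array_equal(a, b)

    def test_unknown_sample_is_error(self):
        with pytest.raises(ValueError, match="not in cohort"):
            build_catalog([SnvRecord("SX", "1", 1, "C", "T", "ACA")], ["S1"])


# ---------------------------------------------------------------------------
# NMF machinery
# ---------------------------------------------------------------------------

class TestNmf:
    def test_multiplicative_updates_never_increase_objective(self, rng):
        V = rng.poisson(5.0, size=(96, 8)).astype(float)
        history = []
        _kl_nmf(V, 3, np.random.default_rng(0), n_iter=300,
                callback=lambda it, obj: history.append(obj))
        assert all(b <= a + 1e-8 for a, b in zip(history, history[1:]))

    def test_ard_penalized_objective_never_increases(self, rng):
        V = rng.poisson(5.0, size=(96, 8)).astype(float)
        history = []
        _ard_kl_nmf(V, 6, np.random.default_rng(0), n_iter=300,
                    callback=lambda it, obj: history.append(obj))
        assert all(b <= a + 1e-8 for a, b in zip(history, history[1:]))

    def test_rank_one_catalog_prunes_to_single_signature(self):
        w = synthetic_signatures(1, seed=4)[:, 0]
        h = np.array([3000.0, 1500.0, 800.0, 2200.0, 5000.0])
        V = np.outer(w, h) * 10  # exact rank-1 catalog
        catalog = MutationCatalog(V, [f"S{i}" for i in range(5)])
        model = extract_signatures(catalog, k_max=4, n_restarts=3, seed=0)
        assert model.k == 1
        assert kl_divergence(V, model.W @ model.H) <= 1e-6 * V.sum()
        assert cosine_similarity(model.W[:, 0], w) > 0.9999

    def test_equal_seed_gives_identical_model(self):
        rng = np.random.default_rng(1)
        V = rng.poisson(4.0, size=(96, 6)).astype(float)
        catalog = MutationCatalog(V, [f"S{i}" for i in range(6)])
        m1 = extract_signatures(catalog, k_max=3, n_restarts=2, seed=7,
                                n_iter=500)
        m2 = extract_signatures(catalog, k_max=3, n_restarts=2, seed=7,
                                n_iter=500)
        np.testing.assert_array_equal(m1.W, m2.W)
        np.testing.assert_array_equal(m1.H, m2.H)

    def test_signature_columns_sum_to_one_and_exposures_conserve_mass(self):
        rng = np.random.default_rng(2)
        V = rng.poisson(8.0, size=(96, 6)).astype(float)
        catalog = MutationCatalog(V, [f"S{i}" for i in range(6)])
        model = extract_signatures(catalog, k_max=3, n_restarts=2, seed=0)
        np.testing.assert_allclose(model.W.sum(axis=0), 1.0, atol=1e-6)
        np.testing.assert_allclose(model.H.sum(axis=0), V.sum(axis=0),
                                   rtol=0.01)

    def test_all_zero_catalog_is_error(self):
        catalog = MutationCatalog(np.zeros((96, 3)), ["a", "b", "c"])
        with pytest.raises(ValueError, match="all-zero"):
            extract_signatures(catalog, k_max=2)

    def test_matches_sklearn_kl_nmf_fit_quality(self, rng):
        """Independent cross-check: our plain KL-NMF reaches the same
        divergence as scikit-learn's multiplicative-update KL solver."""
        from sklearn.decomposition import NMF

        V = rng.poisson(6.0, size=(96, 10)).astype(float) + 0.01
        _, _, ours = _kl_nmf(V, 3, np.random.default_rng(0), n_iter=2000)
        best = np.inf
        for rs in range(3):
            m = NMF(n_components=3, solver="mu", beta_loss="kullback-leibler",
                    init="random", random_state=rs, max_iter=2000, tol=1e-10)
            Wsk = m.fit_transform(V)
            best = min(best, kl_divergence(V, Wsk @ m.components_))
        assert ours <= best * 1.05 + 1.0


# ---------------------------------------------------------------------------
# cosine + matching
# ---------------------------------------------------------------------------

class TestCosine:
    def test_identical_vectors(self):
        v = np.arange(1.0, 97.0)
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint_support(self):
        a = np.zeros(96)
        b = np.zeros(96)
        a[:10], b[10:20] = 1, 1
        assert cosine_similarity(a, b) == 0.0

    def test_hand_computed_value(self):
        a = np.zeros(96)
        b = np.zeros(96)
        a[:3] = (1, 2, 2)
        b[:3] = (2, 1, 2)
        assert cosine_similarity(a, b) == pytest.approx(8 / 9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(96), np.ones(96))


class TestMatching:
    def _model(self, W):
        return SignatureModel(W=W, H=np.ones((W.shape[1], 2)), k=W.shape[1],
                              objective_value=0.0, seed_set=(),
                              samples=("a", "b"))

    def test_exact_reference_column_matches_at_one(self):
        ref_mat = synthetic_signatures(3, seed=8)
        ref = ReferenceSignatureCatalog(CHANNEL_LABELS, ref_mat,
                                        ("R1", "R2", "R3"))
        matches = match_signatures(self._model(ref_mat[:, [1]]), ref)
        assert matches[0].reference_name == "R2"
        assert matches[0].cosine == pytest.approx(1.0)
        assert matches[0].matched

    def test_dissimilar_signature_reported_unmatched(self):
        ref_mat = np.zeros((96, 1))
        ref_mat[:48, 0] = 1 / 48
        ref = ReferenceSignatureCatalog(CHANNEL_LABELS, ref_mat, ("R1",))
        W = np.zeros((96, 1))
        W[48:, 0] = 1 / 48
        (m,) = match_signatures(self._model(W), ref, threshold=0.7)
        assert not m.matched and m.cosine == 0.0

    def test_invariant_to_reference_channel_permutation(self, rng):
        W = synthetic_signatures(2, seed=3)
        perm = rng.permutation(96)
        labels = tuple(CHANNEL_LABELS[i] for i in perm)
        ref_plain = ReferenceSignatureCatalog(CHANNEL_LABELS,
                                              synthetic_signatures(3, seed=5),
                                              ("R1", "R2", "R3"))
        ref_perm = ReferenceSignatureCatalog(labels, ref_plain.matrix[perm, :],
                                             ("R1", "R2", "R3"))
        a = match_signatures(self._model(W), ref_plain)
        b = match_signatures(self._model(W), ref_perm)
        assert [(m.reference_name, pytest.approx(m.cosine)) for m in a] \
            == [(m.reference_name, m.cosine) for m in b]


# ---------------------------------------------------------------------------
# rank-sum machinery
# ---------------------------------------------------------------------------

class TestRankSum:
    def test_fully_separated_small_groups(self):
        assert exact_rank_sum_p([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_identical_values_give_p_one(self):
        assert exact_rank_sum_p([5, 5, 5], [5, 5, 5]) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_scipy_exact_on_tie_free_data(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(40)[:6].astype(float)
        y = rng.permutation(40)[6:14].astype(float) + 0.5
        expected = stats.mannwhitneyu(x, y, alternative="two-sided",
                                      method="exact").pvalue
        assert exact_rank_sum_p(x, y) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_oracle_with_ties(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.integers(0, 4, size=5).astype(float)
        y = rng.integers(0, 4, size=6).astype(float)
        assert exact_rank_sum_p(x, y) == pytest.approx(
            oracles.rank_sum_p_enumeration(x, y))

    def test_large_groups_use_normal_approximation(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.5, 1, 35)
        _, p = rank_sum_test(x, y)
        expected = stats.mannwhitneyu(x, y, alternative="two-sided",
                                      method="asymptotic").pvalue
        assert p == pytest.approx(expected)


class TestExposureAssociation:
    def _model_from_H(self, H, samples):
        W = synthetic_signatures(H.shape[0], seed=1)
        return SignatureModel(W=W, H=H, k=H.shape[0], objective_value=0.0,
                              seed_set=(), samples=tuple(samples))

    def _clinical(self, flags, samples):
        return pd.DataFrame({"smoker": flags},
                            index=pd.Index(samples, name="sample_id"))

    def test_linked_signature_has_smallest_p(self, rng):
        samples = [f"S{i}" for i in range(20)]
        H = rng.gamma(5.0, 100.0, size=(4, 20))
        flags = np.array([1] * 10 + [0] * 10)
        H[2, flags == 1] *= 4.0
        df = exposure_association(self._model_from_H(H, samples),
                                  self._clinical(flags, samples), "smoker")
        sig_rows = df.iloc[:4]
        assert sig_rows.loc[sig_rows["p_value"].idxmin(), "signature"] == "W3"
        assert df.iloc[-1]["signature"] == "total_burden"
        assert sig_rows["q_value"].notna().all()

    def test_identical_exposures_in_both_groups_give_p_one(self):
        samples = [f"S{i}" for i in range(8)]
        H = np.tile(np.array([[3.0], [7.0]]), (1, 8))
        df = exposure_association(
            self._model_from_H(H, samples),
            self._clinical([1, 1, 1, 1, 0, 0, 0, 0], samples), "smoker")
        assert df["p_value"].iloc[:2].tolist() == [1.0, 1.0]

    def test_t_test_flag_uses_welch(self, rng):
        samples = [f"S{i}" for i in range(12)]
        H = rng.gamma(5.0, 100.0, size=(2, 12))
        flags = [1] * 6 + [0] * 6
        df = exposure_association(self._model_from_H(H, samples),
                                  self._clinical(flags, samples), "smoker",
                                  test="t_test")
        expected = stats.ttest_ind(H[0, :6], H[0, 6:], equal_var=False).pvalue
        assert df["p_value"].iloc[0] == pytest.approx(expected)

    def test_degenerate_group_yields_absent_p(self, caplog):
        samples = [f"S{i}" for i in range(5)]
        H = np.ones((2, 5))
        with caplog.at_level("WARNING"):
            df = exposure_association(
                self._model_from_H(H, samples),
                self._clinical([1, 0, 0, 0, 0], samples), "smoker")
        assert df["p_value"].isna().all()
        assert "degenerate" in caplog.text
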